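"""Spearman correlation networks over merged omics feature tables.

A network is built from the Spearman correlation matrix of a merged
feature table: nodes are features (typed microbiome / volatilome /
metabolome_nmr) and an undirected, unweighted edge joins two features
whose correlation exceeds a threshold t (strictly).  The adjacency is the
binary Nfeats x Nfeats matrix with zero diagonal.

Three threshold policies are supported:

* ``fixed`` — an explicit t (the protocol default: 0.5 for the larger
  baseline groups, 0.7 for the smaller endpoint groups);
* ``significance`` — the smallest rho whose two-sided p-value under the
  Spearman t-approximation is below alpha for the group's sample size;
* ``soft`` — WGCNA-style soft thresholding: correlations are raised to the
  smallest power giving an adequate scale-free fit of the weighted
  connectivity, and the binarisation threshold is mapped through that
  power.

Rank-based correlation makes every network invariant to strictly
increasing per-feature transforms, so upstream log transforms affect
readability only, never edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError
from .tables_io import FeatureTable, check_design_covers, validate_design

MODES = ("signed", "absolute")


@dataclass
class NetworkProvenance:
    group: Optional[str]
    n_samples: int
    t: float
    mode: str = "signed"
    method: str = "spearman"
    policy: str = "fixed"


@dataclass(eq=False)
class OmicsNetwork:
    """Undirected, unweighted graph over typed feature nodes."""

    graph: nx.Graph
    provenance: NetworkProvenance

    @property
    def nodes(self) -> List[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def omics_type(self, node: str) -> str:
        return self.graph.nodes[node].get("omics_type", "")

    def adjacency_matrix(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        """Binary Nfeats x Nfeats adjacency with zero diagonal."""
        order = list(order) if order is not None else self.nodes
        a = nx.to_numpy_array(self.graph, nodelist=order, dtype=float)
        return (a > 0).astype(int)


@dataclass
class ThresholdPolicy:
    """How the numeric correlation threshold of a group is chosen."""

    kind: str = "fixed"
    t: Optional[float] = None
    alpha: float = 0.05
    powers: Optional[Sequence[int]] = None
    base_cut: float = 0.5  # pre-power cut used by the soft policy

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "significance", "soft"):
            raise ValidationError(f"unknown policy kind {self.kind!r}")
        if self.kind == "fixed":
            if self.t is None or not (-1 < self.t <= 1):
                raise ValidationError("fixed policy requires t in (-1, 1]")
        if self.kind == "significance" and not (0 < self.alpha < 1):
            raise ValidationError("significance policy requires alpha in (0, 1)")


def spearman_matrix(table: FeatureTable) -> pd.DataFrame:
    """Spearman correlation matrix of a feature table.

    Ties receive average ranks.  Zero-variance features have undefined
    correlations; their rows and columns are set to 0 (no link can form)
    with a warning.
    """
    if table.n_features == 0:
        raise ValidationError("cannot correlate an empty feature table")
    if table.n_samples < 3:
        raise ValidationError("Spearman correlation requires at least 3 samples")
    if table.has_missing():
        raise ValidationError(
            "missing values present; resolve them before correlation "
            "(default policy is a hard error)"
        )
    X = table.values.to_numpy(float)
    n_feat = X.shape[1]
    constant = X.std(axis=0, ddof=0) <= 1e-12 * (1.0 + np.abs(X.mean(axis=0)))
    if constant.any():
        bad = [f for f, c in zip(table.feature_ids, constant) if c]
        warnings.warn(f"zero-variance features, correlations set to 0: {bad}",
                      stacklevel=2)
    rho = np.zeros((n_feat, n_feat))
    idx = np.where(~constant)[0]
    if idx.size == 1:
        rho[idx[0], idx[0]] = 1.0
    elif idx.size >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = stats.spearmanr(X[:, idx], axis=0).statistic
        r = np.asarray(r, dtype=float)
        if r.ndim == 0:  # scipy collapses the 2-feature case to a scalar
            r = np.array([[1.0, float(r)], [float(r), 1.0]])
        rho[np.ix_(idx, idx)] = r
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    return pd.DataFrame(rho, index=table.feature_ids, columns=table.feature_ids)


# ---------------------------------------------------------------------------
# significance-driven minimum threshold
# ---------------------------------------------------------------------------

def spearman_pvalue_t(rho: float, n: int) -> float:
    """Two-sided p-value of a Spearman rho via the t-approximation."""
    if n < 4:
        raise ValidationError("p-value approximation requires n >= 4")
    r = min(abs(float(rho)), 1.0 - 1e-15)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(t, df=n - 2)


def spearman_null_exact(n: int) -> np.ndarray:
    """Exact permutation null of Spearman rho for small n (n <= 8)."""
    if n > 8:
        raise ValidationError("exact null enumeration limited to n <= 8")
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1) / 6.0
    rhos = []
    for perm in permutations(range(n)):
        d = base - base[list(perm)]
        rhos.append(1.0 - (d @ d) / denom)
    return np.asarray(rhos)


def min_significant_threshold(n: int, alpha: float = 0.05,
                              method: str = "t") -> float:
    """Smallest rho whose two-sided p-value is below alpha at sample size n.

    ``method="t"`` (default) inverts the t-approximation
    t = rho * sqrt((n-2)/(1-rho^2)), df = n-2, by root finding (to 1e-9).
    ``method="exact"`` uses the exact permutation null (n <= 8 only) and
    returns the smallest achievable |rho| with tail probability < alpha.
    """
    if n < 4:
        raise ValidationError("minimum significant threshold requires n >= 4")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    if method == "exact":
        null = np.abs(spearman_null_exact(n))
        values = np.unique(null)
        m = null.size
        for v in values:
            if np.sum(null >= v - 1e-12) / m < alpha:
                return float(v)
        raise ValidationError(f"no achievable rho is significant at alpha={alpha} for n={n}")
    if method != "t":
        raise ValidationError(f"unknown method {method!r}")

    def f(r: float) -> float:
        return spearman_pvalue_t(r, n) - alpha

    lo, hi = 1e-12, 1.0 - 1e-12
    if f(hi) > 0:
        raise ValidationError(f"no rho < 1 reaches significance at alpha={alpha}, n={n}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-9))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(
    corr: pd.DataFrame,
    t: float,
    types: Mapping[str, str],
    mode: str = "signed",
    group: Optional[str] = None,
    n_samples: int = 0,
    policy: str = "fixed",
) -> OmicsNetwork:
    """Binarise a correlation matrix into an unweighted network.

    Edge (i, j) exists iff rho_ij > t (signed mode) or |rho_ij| > t
    (absolute mode), with strict inequality.  Every feature becomes a
    node; isolated nodes are retained.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}")
    feats = list(corr.index)
    if list(corr.columns) != feats:
        raise ValidationError("correlation matrix must be square with matching labels")
    rho = corr.to_numpy(float)
    if not np.allclose(rho, rho.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    if mode == "signed" and t >= 1:
        warnings.warn("threshold t >= 1 in signed mode yields an empty edge set",
                      stacklevel=2)
    g = nx.Graph()
    for f in feats:
        g.add_node(f, omics_type=types.get(f, ""))
    vals = np.abs(rho) if mode == "absolute" else rho
    n = len(feats)
    iu, ju = np.triu_indices(n, k=1)
    hit = vals[iu, ju] > t
    for a, b in zip(iu[hit], ju[hit]):
        g.add_edge(feats[a], feats[b])
    prov = NetworkProvenance(group=group, n_samples=n_samples, t=float(t),
                             mode=mode, policy=policy)
    return OmicsNetwork(graph=g, provenance=prov)


def resolve_policy(policy: ThresholdPolicy, n_samples: int,
                   corr: Optional[pd.DataFrame] = None) -> float:
    """Turn a threshold policy into the numeric t recorded in provenance."""
    if policy.kind == "fixed":
        return float(policy.t)
    if policy.kind == "significance":
        return min_significant_threshold(n_samples, policy.alpha)
    # soft: pick the scale-free power and map the pre-power cut through it
    if corr is None:
        raise ValidationError("soft policy requires the correlation matrix")
    res = soft_threshold_power(corr, powers=policy.powers or range(1, 21))
    return float(policy.base_cut ** (1.0 / res.power))


DEFAULT_GROUP_POLICIES = {
    "T0": ThresholdPolicy(kind="fixed", t=0.5),
    "Te": ThresholdPolicy(kind="fixed", t=0.7),
}


def group_samples(design: pd.DataFrame, sample_ids: Sequence[str]) -> Dict[str, List[str]]:
    """Partition samples into analysis groups.

    Baseline (T0) groups pool both arms within each sex; endpoint (Te)
    groups split by sex and arm.
    """
    sub = design.loc[list(sample_ids)]
    groups: Dict[str, List[str]] = {}
    for sid, row in sub.iterrows():
        if row["timepoint"] == "T0":
            key = f"T0_{row['sex']}"
        else:
            key = f"Te_{row['sex']}_{row['arm']}"
        groups.setdefault(key, []).append(sid)
    return groups


def apply_group_policy(
    table: FeatureTable,
    design: pd.DataFrame,
    policies: Optional[Mapping[str, ThresholdPolicy]] = None,
    mode: str = "signed",
) -> Dict[str, OmicsNetwork]:
    """Build one network per analysis group of the samples in ``table``.

    ``policies`` maps either full group names (``Te_F_A``) or timepoint
    prefixes (``T0`` / ``Te``) to a :class:`ThresholdPolicy`; the default
    is fixed t = 0.5 at T0 and t = 0.7 at Te (the larger pooled baseline
    groups tolerate a softer threshold).
    """
    validate_design(design)
    check_design_covers(table, design)
    policies = dict(policies or {})
    groups = group_samples(design, table.sample_ids)
    te_groups = [g for g in groups if g.startswith("Te_")]
    arms_seen = {g.rsplit("_", 1)[-1] for g in te_groups}
    if te_groups and len(arms_seen) < 2:
        warnings.warn(
            f"only one intervention arm present at Te ({sorted(arms_seen)}); "
            "fewer endpoint networks will be produced",
            stacklevel=2,
        )
    nets: Dict[str, OmicsNetwork] = {}
    for name in sorted(groups):
        samples = groups[name]
        if len(samples) < 4:
            raise ValidationError(
                f"group {name!r} has only {len(samples)} samples; "
                "correlation networks need at least 4"
            )
        pol = policies.get(name) or policies.get(name.split("_")[0]) \
            or DEFAULT_GROUP_POLICIES[name.split("_")[0]]
        sub = table.subset_samples(samples)
        corr = spearman_matrix(sub)
        t = resolve_policy(pol, len(samples), corr)
        nets[name] = build_network(corr, t, table.feature_type, mode=mode,
                                   group=name, n_samples=len(samples),
                                   policy=pol.kind)
    return nets


# ---------------------------------------------------------------------------
# soft thresholding (scale-free fit on weighted connectivity)
# ---------------------------------------------------------------------------

@dataclass
class SoftThresholdResult:
    power: int
    fit_table: pd.DataFrame  # power, rsq, slope, mean_k, median_k, max_k


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> Tuple[float, float]:
    """R^2 and slope of log10(frequency) vs log10(mean connectivity) bins."""
    k = k[k > 0]
    if k.size < 3:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            xs.append(np.mean(k[mask]))
            ys.append(np.sum(mask) / k.size)
    if len(xs) < 3:
        return 0.0, 0.0
    lx, ly = np.log10(xs), np.log10(ys)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return rsq, float(slope)


def soft_threshold_power(
    corr: pd.DataFrame,
    powers: Iterable[int] = range(1, 21),
    rsq_target: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Choose the soft-thresholding power by the scale-free fit criterion.

    For each candidate power beta the weighted connectivity is
    k_i = sum_j |rho_ij|^beta (j != i); the fit index is the R^2 of the
    log-log regression of binned connectivity frequencies.  Returns the
    smallest beta whose R^2 reaches ``rsq_target``, else the argmax-R^2
    beta, together with the full fit table.
    """
    powers = [int(b) for b in powers]
    if not powers or any(b < 1 or b > 30 for b in powers):
        raise ValidationError("powers must be a non-empty subset of 1..30")
    rho = np.abs(corr.to_numpy(float)).copy()
    np.fill_diagonal(rho, 0.0)
    if np.all(rho == 0):
        raise ValidationError("all off-diagonal correlations are zero")
    rows = []
    for b in sorted(powers):
        k = (rho ** b).sum(axis=1)
        rsq, slope = _scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": b, "rsq": rsq, "slope": slope,
                     "mean_k": float(k.mean()), "median_k": float(np.median(k)),
                     "max_k": float(k.max())})
    table = pd.DataFrame(rows)
    ok = table[table["rsq"] >= rsq_target]
    power = int(ok.iloc[0]["power"]) if len(ok) else int(table.loc[table["rsq"].idxmax(), "power"])
    return SoftThresholdResult(power=power, fit_table=table)
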