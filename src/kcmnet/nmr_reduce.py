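"""Two-step reduction of binned NMR spectra to pooled agglomerate features.

Binned spectra are heavily redundant: adjacent buckets ride the same peak
and distinct peaks of one molecule move together.  Left untreated, those
buckets form a densely connected giant component that drowns every other
structure in a correlation network.  The reduction therefore

1. drops uninformative buckets with a self-optimising multi-class logistic
   regression under an L1 penalty (buckets unrelated to the class labels
   receive exactly-zero coefficients), and
2. groups the surviving, highly correlated buckets by average-linkage
   hierarchical clustering on the distance 1 - Pearson r, cutting the
   dendrogram at the smallest cophenetic height that leaves no singleton
   cluster (capped, by default at 0.7), then pooling each cluster to a
   single feature by the per-sample median.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .tables_io import UNIT_POOLED, FeatureTable

COEF_TOL = 1e-8


def _constant_mask(X: np.ndarray) -> np.ndarray:
    """Columns with (numerically) zero variance."""
    sd = X.std(axis=0, ddof=0)
    scale = 1.0 + np.abs(X.mean(axis=0))
    return sd <= 1e-12 * scale


def _anova_f(Z: np.ndarray, y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic per column (vectorised)."""
    n = Z.shape[0]
    grand = Z.mean(axis=0)
    ss_between = np.zeros(Z.shape[1])
    ss_within = np.zeros(Z.shape[1])
    for c in classes:
        sub = Z[y == c]
        mu = sub.mean(axis=0)
        ss_between += sub.shape[0] * (mu - grand) ** 2
        ss_within += ((sub - mu) ** 2).sum(axis=0)
    df_b = len(classes) - 1
    df_w = n - len(classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / np.where(ss_within > 0, ss_within / df_w, np.nan)
    return np.nan_to_num(f, nan=0.0)


def _labels_informative(Z: np.ndarray, y: np.ndarray, classes: np.ndarray,
                        seed: int, n_perm: int = 200, alpha: float = 0.01) -> bool:
    """Westfall-Young maxT screen: is any bucket-label association beyond
    chance?  Compares the observed max F across buckets with its label-
    permutation null."""
    observed = _anova_f(Z, y, classes).max()
    rng = np.random.default_rng((seed + 987654321) % (2 ** 31))
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _anova_f(Z, rng.permutation(y), classes).max()
    p = (1 + np.sum(null >= observed)) / (1 + n_perm)
    return p <= alpha


@dataclass
class SelectionResult:
    """Outcome of the L1 bucket selection."""

    kept_feature_ids: List[str]
    coefficient_summary: Dict[str, float]  # feature -> max |coef| over classes
    optimizer_trace: Dict[str, object]     # grid, CV scores, chosen strength


def select_informative_buckets(
    binned: FeatureTable,
    labels: Sequence,
    folds: int = 5,
    c_grid: Optional[Sequence[float]] = None,
    seed: int = 0,
    max_iter: int = 5000,
) -> SelectionResult:
    """L1-penalised multinomial logistic selection of informative buckets.

    Features are z-scored internally; constant features are pre-dropped
    (their coefficient would be undefined after standardisation and they
    can never be informative).  The inverse regularisation strength C is
    chosen by stratified cross-validated mean accuracy over a log-spaced
    grid (default 10 points, 1e-3 ... 1e3) under the one-standard-error
    rule: the strongest penalty within one SE of the best score wins, so
    exact ties and chance-level fluctuations both resolve toward sparsity.

    Two no-information guards return an empty selection: a Westfall-Young
    max-F permutation screen run before any model fitting (labels that
    carry no signal otherwise let the L1 path latch onto chance-predictive
    buckets), and a post-CV check that the best model beats the
    majority-class rate by more than its standard error.

    A feature is kept if any class row of the refitted coefficient matrix
    exceeds ``1e-8`` in absolute value.
    """
    y = np.asarray(labels)
    if len(y) != binned.n_samples:
        raise ValidationError("labels length must equal the number of samples")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("bucket selection needs at least 2 classes")
    if counts.min() < folds:
        small = classes[counts.argmin()]
        raise ValidationError(
            f"class {small!r} has only {counts.min()} samples, fewer than "
            f"{folds} folds; use fewer folds"
        )
    if c_grid is None:
        c_grid = np.logspace(-3, 3, 10)
    c_grid = np.asarray(sorted(c_grid), dtype=float)

    X = binned.values.to_numpy(float)
    variable = ~_constant_mask(X)
    feats = [f for f, v in zip(binned.feature_ids, variable) if v]
    Xv = X[:, variable]
    Z = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0, ddof=0)

    # permutation screen before any model fitting: with labels carrying no
    # signal, an L1 path tuned by cross-validation can still latch onto
    # chance-predictive buckets, so selection proceeds only when the
    # strongest bucket-label association exceeds its permutation null
    if not _labels_informative(Z, y, classes, seed=seed):
        trace = {
            "c_grid": [float(c) for c in c_grid],
            "cv_mean_accuracy": None,
            "cv_se": None,
            "chosen_C": None,
            "folds": folds,
            "seed": seed,
            "n_constant_dropped": int((~variable).sum()),
            "no_information": True,
        }
        return SelectionResult([], {f: 0.0 for f in feats}, trace)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, y))
    cv_scores, cv_ses = [], []
    for C in c_grid:
        accs = []
        for tr, te in splits:
            clf = LogisticRegression(penalty="l1", C=C, solver="saga",
                                     max_iter=max_iter, tol=1e-4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Z[tr], y[tr])
            accs.append(clf.score(Z[te], y[te]))
        cv_scores.append(float(np.mean(accs)))
        cv_ses.append(float(np.std(accs, ddof=1) / np.sqrt(len(accs))))
    # one-standard-error rule: strongest penalty whose mean accuracy is
    # within 1 SE of the best, so chance-level fluctuations cannot favour
    # a weak penalty that keeps noise features
    best_idx = int(np.argmax(cv_scores))
    threshold = cv_scores[best_idx] - cv_ses[best_idx]
    # no-information guard: when even the best model cannot beat the
    # majority-class rate by more than its standard error, no bucket is
    # demonstrably informative
    n_samples = counts.sum()
    majority = counts.max() / n_samples
    majority_se = float(np.sqrt(majority * (1 - majority) / n_samples))
    if threshold <= majority + majority_se:
        trace = {
            "c_grid": [float(c) for c in c_grid],
            "cv_mean_accuracy": cv_scores,
            "cv_se": cv_ses,
            "chosen_C": None,
            "folds": folds,
            "seed": seed,
            "n_constant_dropped": int((~variable).sum()),
            "no_information": True,
        }
        return SelectionResult([], {f: 0.0 for f in feats}, trace)
    for i, s in enumerate(cv_scores):
        if s >= threshold:
            best_idx = i
            break
    chosen_C = float(c_grid[best_idx])

    final = LogisticRegression(penalty="l1", C=chosen_C, solver="saga",
                               max_iter=max_iter, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Z, y)
    coef = np.atleast_2d(final.coef_)
    summary = {f: float(np.max(np.abs(coef[:, j]))) for j, f in enumerate(feats)}
    kept = [f for f in feats if summary[f] > COEF_TOL]
    trace = {
        "c_grid": [float(c) for c in c_grid],
        "cv_mean_accuracy": cv_scores,
        "cv_se": cv_ses,
        "chosen_C": chosen_C,
        "folds": folds,
        "seed": seed,
        "n_constant_dropped": int((~variable).sum()),
        "no_information": False,
    }
    return SelectionResult(kept, summary, trace)


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------

@dataclass
class AgglomerationMap:
    """Assignment of selected buckets to clusters plus pooled-feature names."""

    cluster_of: Dict[str, int]
    cut_height: float
    pooled_ids: Dict[int, str]
    members: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = {}
            for f, c in self.cluster_of.items():
                self.members.setdefault(self.pooled_ids[c], []).append(f)

    def to_dict(self) -> dict:
        return {
            "cut_height": self.cut_height,
            "clusters": {pid: sorted(m) for pid, m in self.members.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "AgglomerationMap":
        with open(path) as fh:
            data = json.load(fh)
        pooled_ids = {}
        cluster_of = {}
        members = {}
        for i, (pid, feats) in enumerate(sorted(data["clusters"].items()), start=1):
            pooled_ids[i] = pid
            members[pid] = list(feats)
            for f in feats:
                cluster_of[f] = i
        return cls(cluster_of, float(data["cut_height"]), pooled_ids, members)


def correlation_linkage(selected: FeatureTable):
    """Average-linkage dendrogram on the distance 1 - Pearson r."""
    if selected.n_features < 2:
        raise ValidationError("agglomeration requires at least 2 features")
    X = selected.values.to_numpy(float)
    const = _constant_mask(X)
    if const.any():
        bad = [f for f, c in zip(selected.feature_ids, const) if c]
        raise ValidationError(f"zero-variance features (undefined correlation): {bad}")
    r = np.corrcoef(X, rowvar=False)
    d = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    return linkage(condensed, method="average")


def select_cophenetic_threshold(Z: np.ndarray, cap: Optional[float] = None) -> float:
    """Smallest merge height at which cutting leaves no singleton cluster.

    Candidate cuts are the dendrogram's merge heights; at each candidate
    the flat clustering bounds intra-cluster cophenetic distance by the
    cut.  If the smallest singleton-free height exceeds ``cap``, the cap
    is returned with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    n_leaves = Z.shape[0] + 1
    if n_leaves < 2:
        raise ValidationError("dendrogram must cover at least 2 leaves")
    heights = np.unique(Z[:, 2])
    chosen = None
    for h in heights:
        labels = fcluster(Z, t=h, criterion="distance")
        _, sizes = np.unique(labels, return_counts=True)
        if sizes.min() >= 2:
            chosen = float(h)
            break
    if chosen is None:  # cutting at the top yields one cluster of >= 2 leaves
        chosen = float(heights[-1])
    if cap is not None and chosen > cap:
        warnings.warn(
            f"no singleton-free cut below cap {cap}; clipping cut height "
            f"from {chosen:.4f} to the cap",
            stacklevel=2,
        )
        return float(cap)
    return chosen


def agglomerate_features(
    selected: FeatureTable,
    cut: Union[float, str] = "auto",
    cap: float = 0.7,
    prefix: str = "nmr_agg",
) -> AgglomerationMap:
    """Cluster correlated buckets and name one pooled feature per cluster.

    ``cut="auto"`` picks the smallest singleton-free cophenetic height,
    clipped to ``cap`` (default 0.7).  Cluster labels are ordered by first
    member position so pooled ids are stable under reruns.
    """
    Z = correlation_linkage(selected)
    if cut == "auto":
        height = select_cophenetic_threshold(Z, cap=cap)
    else:
        height = float(cut)
        if height < 0:
            raise ValidationError("cut height must be >= 0")
    raw = fcluster(Z, t=height, criterion="distance")
    # relabel clusters in order of first appearance for reproducible names
    order: Dict[int, int] = {}
    for lab in raw:
        if lab not in order:
            order[lab] = len(order) + 1
    n_digits = max(2, len(str(len(order))))
    cluster_of = {f: order[lab] for f, lab in zip(selected.feature_ids, raw)}
    pooled_ids = {c: f"{prefix}_{c:0{n_digits}d}" for c in sorted(order.values())}
    return AgglomerationMap(cluster_of, float(height), pooled_ids)


def pool_agglomerates(selected: FeatureTable, amap: AgglomerationMap) -> FeatureTable:
    """Summarise each cluster by the per-sample median of its buckets."""
    missing = [f for f in selected.feature_ids if f not in amap.cluster_of]
    if missing:
        raise ValidationError(f"features missing from agglomeration map: {missing}")
    cols = {}
    for c in sorted(amap.pooled_ids):
        pid = amap.pooled_ids[c]
        members = [f for f in selected.feature_ids if amap.cluster_of[f] == c]
        if not members:
            raise ValidationError(f"cluster {pid!r} has no members in the table")
        cols[pid] = selected.values[members].median(axis=1)
    df = pd.DataFrame(cols, index=selected.values.index)
    return FeatureTable(df, {p: "metabolome_nmr" for p in df.columns},
                        {p: UNIT_POOLED for p in df.columns})
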