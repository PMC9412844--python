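"""Synthetic multiomics cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a nutritional-intervention
cohort at the feature-table level:

* microbial taxa and volatile compounds with log-normal marginals,
  renormalised per sample to 100 % (compositional relative abundances),
  including a handful of rare features that the 0.5 % median filter is
  expected to discard;
* binned NMR buckets organised into "molecule blocks" whose members share
  a latent per-molecule intensity (intra-block correlation >= 0.9 by
  construction, mimicking intramolecular resonances), plus unstructured
  noise buckets;
* planted inter-omics consortia: sets of taxa, volatiles and molecule
  blocks loading on a common latent factor with correlation ``rho``, so
  their pairwise Spearman correlations are high by construction (the
  Gaussian-copula + exp construction keeps planted rank correlations
  exact in expectation, since Spearman is invariant to the monotone
  marginal transform);
* an endpoint arm effect: at Te, samples of the intervention arm shift the
  responsive features (consortium members and molecule blocks) on the log
  scale, making those buckets informative for the L1 selection step.

A feature listed in two consortia loads on both factors and becomes a
bridge candidate between the corresponding network communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables_io import (
    UNIT_INTENSITY,
    UNIT_PERCENT_RA,
    FeatureTable,
    validate_design,
)


@dataclass
class Consortium:
    """A planted cross-omics correlation module."""

    taxa: List[int] = field(default_factory=list)
    vocs: List[int] = field(default_factory=list)
    bucket_blocks: List[int] = field(default_factory=list)
    rho: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.rho < 1):
            raise ValidationError("consortium rho must be in (0, 1)")


@dataclass
class SimConfig:
    """Cohort-generator settings.

    Defaults emulate the study conditions the framework was designed for:
    ~90 subjects split over sex x arm cells, two timepoints per subject,
    ~50 taxa of which the rare ones fall below the 0.5 % median filter
    (leaving ~42), 16 volatiles (leaving 14), and 400 spectral buckets of
    which 34 molecule blocks of 4 buckets (roughly one third of the
    buckets) carry structure and respond to the intervention.
    """

    n_subjects_per_cell: int = 22          # cells = sex x arm
    n_taxa: int = 50
    n_vocs: int = 16
    n_buckets: int = 400
    n_rare_taxa: int = 8
    n_rare_vocs: int = 2
    molecule_blocks: Optional[List[List[int]]] = None   # default: 34 blocks of 4
    consortia: Optional[List[Consortium]] = None
    intra_block_corr: float = 0.95
    factor_corr: float = 0.6               # coupling between consortium factors;
                                           # a feature shared by two consortia can
                                           # correlate at most sqrt(rho*(1+r)/2)
                                           # with either, so bridges over a 0.7
                                           # threshold need substantial coupling
    arm_effect: float = 0.5                # log-scale Te shift in arm A (~1.65x)
    noise_sd: float = 0.6                  # log-scale marginal sd
    rare_log_offset: float = -4.5          # log-abundance offset of rare features
    consortium_log_offset: float = -1.0    # consortium members are minor
                                           # community members, keeping the
                                           # compositional closure from
                                           # coupling to the planted signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.molecule_blocks is None:
            n_blocks = min(34, self.n_buckets // 4)
            self.molecule_blocks = [list(range(4 * i, 4 * i + 4)) for i in range(n_blocks)]
        if self.consortia is None:
            # two taxa+volatile consortia bridged by one shared molecule
            # block (the spectral agglomerate becomes the overlap node);
            # consortium members deliberately hold no further NMR blocks,
            # because any spectral feature correlated with a community is
            # by construction correlated with the shared block and would
            # be agglomerated with it
            self.consortia = [
                Consortium(taxa=[0, 1, 2], vocs=[0, 1, 2], bucket_blocks=[0]),
                Consortium(taxa=[3, 4, 5], vocs=[3, 4, 5], bucket_blocks=[0]),
            ]
        self.validate()

    def validate(self) -> None:
        if self.n_subjects_per_cell < 1:
            raise ValidationError("need at least one subject per cell")
        if not (0 < self.intra_block_corr < 1):
            raise ValidationError("intra_block_corr must be in (0, 1)")
        if not (0 <= self.factor_corr < 1):
            raise ValidationError("factor_corr must be in [0, 1)")
        seen: set = set()
        for blk in self.molecule_blocks:
            for b in blk:
                if not 0 <= b < self.n_buckets:
                    raise ValidationError(f"bucket index {b} out of range")
                if b in seen:
                    raise ValidationError(f"bucket {b} assigned to two molecule blocks")
                seen.add(b)
        for c in self.consortia:
            for t in c.taxa:
                if not 0 <= t < self.n_taxa:
                    raise ValidationError(f"taxon index {t} out of range")
            for v in c.vocs:
                if not 0 <= v < self.n_vocs:
                    raise ValidationError(f"voc index {v} out of range")
            for b in c.bucket_blocks:
                if not 0 <= b < len(self.molecule_blocks):
                    raise ValidationError(f"molecule-block index {b} out of range")
        if self.n_rare_taxa >= self.n_taxa or self.n_rare_vocs >= self.n_vocs:
            raise ValidationError("rare features must be a strict subset")


def taxa_id(i: int) -> str:
    return f"taxon_{i + 1:03d}"


def voc_id(i: int) -> str:
    return f"voc_{i + 1:02d}"


def bucket_id(i: int) -> str:
    return f"bucket_{i + 1:04d}"


def _factor_cholesky(n_factors: int, r: float) -> np.ndarray:
    cov = np.full((n_factors, n_factors), r)
    np.fill_diagonal(cov, 1.0)
    return np.linalg.cholesky(cov)


def _shared_loading(memberships: Sequence[int], G: np.ndarray, r: float) -> np.ndarray:
    """Unit-variance combination of several consortium factors."""
    m = len(memberships)
    s = G[:, list(memberships)].sum(axis=1)
    var = m + m * (m - 1) * r
    return s / np.sqrt(var)


def simulate_cohort(cfg: SimConfig) -> Tuple[FeatureTable, FeatureTable, pd.DataFrame, dict]:
    """Generate (table at T0, table at Te, sample design, ground truth).

    Each table holds all three omics blocks side by side (feature_type
    labels distinguish them); taxa and volatiles are percent relative
    abundances summing to 100 per sample, buckets are raw intensities.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    cells = [(sex, arm) for sex in ("F", "M") for arm in ("A", "P")]
    subjects = []
    for ci, (sex, arm) in enumerate(cells):
        for j in range(cfg.n_subjects_per_cell):
            subjects.append((f"S{ci * cfg.n_subjects_per_cell + j + 1:04d}", sex, arm))

    sample_rows = []
    for tp in ("T0", "Te"):
        for sid, sex, arm in subjects:
            sample_rows.append((f"{sid}_{tp}", sid, sex, tp, arm))
    design = pd.DataFrame(
        sample_rows, columns=["sample_id", "subject_id", "sex", "timepoint", "arm"]
    ).set_index("sample_id")
    validate_design(design)
    n_total = len(sample_rows)
    is_te_armA = ((design["timepoint"] == "Te") & (design["arm"] == "A")).to_numpy()

    # --- latent structure -------------------------------------------------
    n_cons = len(cfg.consortia)
    if n_cons:
        L = _factor_cholesky(n_cons, cfg.factor_corr)
        G = rng.standard_normal((n_total, n_cons)) @ L.T
    else:
        G = np.zeros((n_total, 0))

    def member_map(kind: str, size: int) -> Dict[int, List[int]]:
        out: Dict[int, List[int]] = {}
        for ci, c in enumerate(cfg.consortia):
            for idx in getattr(c, kind):
                out.setdefault(idx, []).append(ci)
        return out

    taxa_members = member_map("taxa", cfg.n_taxa)
    voc_members = member_map("vocs", cfg.n_vocs)
    block_members = member_map("bucket_blocks", len(cfg.molecule_blocks))

    def latent_for(members: Optional[List[int]], rho: float) -> np.ndarray:
        noise = rng.standard_normal(n_total)
        if not members:
            return noise
        if len(members) == 1:
            g = G[:, members[0]]
            return np.sqrt(rho) * g + np.sqrt(1 - rho) * noise
        return _shared_loading(members, G, cfg.factor_corr)

    def rho_of(members: Optional[List[int]]) -> float:
        if not members:
            return 0.0
        return cfg.consortia[members[0]].rho

    Z_taxa = np.column_stack([
        latent_for(taxa_members.get(i), rho_of(taxa_members.get(i)))
        for i in range(cfg.n_taxa)
    ])
    Z_voc = np.column_stack([
        latent_for(voc_members.get(i), rho_of(voc_members.get(i)))
        for i in range(cfg.n_vocs)
    ])
    H = np.column_stack([
        latent_for(block_members.get(b), rho_of(block_members.get(b)))
        for b in range(len(cfg.molecule_blocks))
    ]) if cfg.molecule_blocks else np.zeros((n_total, 0))

    w = cfg.intra_block_corr
    Z_buckets = rng.standard_normal((n_total, cfg.n_buckets))
    for b, blk in enumerate(cfg.molecule_blocks):
        for idx in blk:
            Z_buckets[:, idx] = np.sqrt(w) * H[:, b] + np.sqrt(1 - w) * Z_buckets[:, idx]

    # --- responsive features and arm effect -------------------------------
    cons_taxa = sorted(taxa_members)
    cons_vocs = sorted(voc_members)
    block_dirs = rng.choice([-1.0, 1.0], size=len(cfg.molecule_blocks))
    taxa_dirs = {i: rng.choice([-1.0, 1.0]) for i in cons_taxa}
    voc_dirs = {i: rng.choice([-1.0, 1.0]) for i in cons_vocs}

    shift_taxa = np.zeros(cfg.n_taxa)
    for i in cons_taxa:
        shift_taxa[i] = cfg.arm_effect * taxa_dirs[i]
    shift_voc = np.zeros(cfg.n_vocs)
    for i in cons_vocs:
        shift_voc[i] = cfg.arm_effect * voc_dirs[i]
    shift_buckets = np.zeros(cfg.n_buckets)
    for b, blk in enumerate(cfg.molecule_blocks):
        for idx in blk:
            shift_buckets[idx] = cfg.arm_effect * block_dirs[b]

    # --- marginals --------------------------------------------------------
    mu_taxa = np.zeros(cfg.n_taxa)
    mu_taxa[cons_taxa] = cfg.consortium_log_offset
    rare_taxa = list(range(cfg.n_taxa - cfg.n_rare_taxa, cfg.n_taxa))
    mu_taxa[rare_taxa] = cfg.rare_log_offset
    mu_voc = np.zeros(cfg.n_vocs)
    mu_voc[cons_vocs] = cfg.consortium_log_offset
    rare_vocs = list(range(cfg.n_vocs - cfg.n_rare_vocs, cfg.n_vocs))
    mu_voc[rare_vocs] = cfg.rare_log_offset
    mu_buckets = rng.uniform(-0.5, 0.5, size=cfg.n_buckets)

    arm_mask = is_te_armA.astype(float)[:, None]
    X_taxa = np.exp(mu_taxa + cfg.noise_sd * Z_taxa + arm_mask * shift_taxa)
    X_voc = np.exp(mu_voc + cfg.noise_sd * Z_voc + arm_mask * shift_voc)
    X_buckets = np.exp(mu_buckets + cfg.noise_sd * Z_buckets + arm_mask * shift_buckets)

    # compositional closure for the two relative-abundance blocks
    X_taxa = 100.0 * X_taxa / X_taxa.sum(axis=1, keepdims=True)
    X_voc = 100.0 * X_voc / X_voc.sum(axis=1, keepdims=True)

    sample_ids = [r[0] for r in sample_rows]
    taxa_ids = [taxa_id(i) for i in range(cfg.n_taxa)]
    voc_ids = [voc_id(i) for i in range(cfg.n_vocs)]
    buck_ids = [bucket_id(i) for i in range(cfg.n_buckets)]
    values = pd.DataFrame(
        np.hstack([X_taxa, X_voc, X_buckets]),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=taxa_ids + voc_ids + buck_ids,
    )
    ftype = {**{f: "microbiome" for f in taxa_ids},
             **{f: "volatilome" for f in voc_ids},
             **{f: "metabolome_nmr" for f in buck_ids}}
    units = {**{f: UNIT_PERCENT_RA for f in taxa_ids + voc_ids},
             **{f: UNIT_INTENSITY for f in buck_ids}}

    t0_samples = [s for s in sample_ids if s.endswith("_T0")]
    te_samples = [s for s in sample_ids if s.endswith("_Te")]
    table_t0 = FeatureTable(values.loc[t0_samples].copy(), dict(ftype), dict(units))
    table_te = FeatureTable(values.loc[te_samples].copy(), dict(ftype), dict(units))

    blocks_as_ids = [[bucket_id(i) for i in blk] for blk in cfg.molecule_blocks]
    truth = {
        "consortia": [
            {
                "taxa": [taxa_id(i) for i in c.taxa],
                "vocs": [voc_id(i) for i in c.vocs],
                "bucket_blocks": [blocks_as_ids[b] for b in c.bucket_blocks],
                "block_indices": list(c.bucket_blocks),
                "rho": c.rho,
            }
            for c in cfg.consortia
        ],
        "shared_blocks": [
            blocks_as_ids[b] for b, mem in block_members.items() if len(mem) > 1
        ],
        "shared_taxa": [taxa_id(i) for i, m in taxa_members.items() if len(m) > 1],
        "shared_vocs": [voc_id(i) for i, m in voc_members.items() if len(m) > 1],
        "molecule_blocks": blocks_as_ids,
        "rare_features": [taxa_id(i) for i in rare_taxa] + [voc_id(i) for i in rare_vocs],
        "responsive_buckets": [bucket_id(i) for blk in cfg.molecule_blocks for i in blk],
    }
    return table_t0, table_te, design, truth


def planted_bridge_recovery(
    seed: int,
    n_subjects_per_cell: int = 100,
    n_buckets: int = 60,
    n_blocks: int = 8,
    group: str = "Te_F_A",
    k: int = 3,
    min_jaccard: float = 0.8,
) -> dict:
    """Run the full analysis chain on one simulated cohort and score how
    well it recovers the planted structure.

    The default planted design has two cross-omics consortia bridged by a
    shared NMR molecule block.  The chain is: 0.5 % median filter -> log
    transform -> L1 bucket selection (arm labels at Te) -> cophenetic
    agglomeration (fit at baseline) -> median pooling -> merge -> fixed
    0.7-threshold network for one endpoint group -> k-clique communities.

    Returns per-consortium best Jaccard against ground truth (translated
    through the agglomeration map), whether the shared pooled feature is
    the sole bridge node, and a combined success flag (both Jaccards >=
    ``min_jaccard`` and the bridge identified).
    """
    from . import cliquecomm, netbuild, nmr_reduce, preprocess, tables_io

    blocks = [list(range(4 * i, 4 * i + 4)) for i in range(n_blocks)]
    cfg = SimConfig(seed=seed, n_subjects_per_cell=n_subjects_per_cell,
                    n_buckets=n_buckets, molecule_blocks=blocks)
    t0, te, design, truth = simulate_cohort(cfg)
    full = tables_io.FeatureTable(
        pd.concat([t0.values, te.values]), dict(t0.feature_type), dict(t0.units))

    fcfg = preprocess.FilterConfig()
    mic, _ = preprocess.filter_by_median_abundance(
        full.select_type("microbiome"), fcfg, design)
    voc, _ = preprocess.filter_by_median_abundance(
        full.select_type("volatilome"), fcfg, design)
    mic, voc = preprocess.log_transform(mic), preprocess.log_transform(voc)

    nmr = full.select_type("metabolome_nmr")
    te_samples = [s for s in nmr.sample_ids if design.loc[s, "timepoint"] == "Te"]
    t0_samples = [s for s in nmr.sample_ids if design.loc[s, "timepoint"] == "T0"]
    sel = nmr_reduce.select_informative_buckets(
        nmr.subset_samples(te_samples),
        design.loc[te_samples, "arm"].to_numpy(), seed=seed)
    selected = nmr.subset_features(sel.kept_feature_ids)
    amap = nmr_reduce.agglomerate_features(
        selected.subset_samples(t0_samples), cut="auto", cap=0.7)
    pooled = nmr_reduce.pool_agglomerates(selected, amap)

    merged = tables_io.merge_tables([mic, voc, pooled], design)
    te_tab = merged.subset_samples(
        [s for s in merged.sample_ids if design.loc[s, "timepoint"] == "Te"])
    nets = netbuild.apply_group_policy(te_tab, design)
    cs = cliquecomm.k_clique_communities(nets[group], k)

    def pooled_of(bucket_ids):
        return {pid for f in bucket_ids
                for pid, members in amap.members.items() if f in members}

    jaccards = []
    for cons in truth["consortia"]:
        target = set(cons["taxa"]) | set(cons["vocs"])
        for blk in cons["bucket_blocks"]:
            target |= pooled_of(blk)
        best = max((len(target & set(c)) / len(target | set(c))
                    for c in cs.communities), default=0.0)
        jaccards.append(best)
    shared = set()
    for blk in truth["shared_blocks"]:
        shared |= pooled_of(blk)
    bridges = {n for n, m in cs.membership.items() if m >= 2}
    bridge_ok = bool(shared) and bridges == shared
    return {
        "jaccards": jaccards,
        "bridge_ok": bridge_ok,
        "n_communities": cs.n_communities,
        "n_selected_buckets": len(sel.kept_feature_ids),
        "success": bridge_ok and all(j >= min_jaccard for j in jaccards),
    }
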