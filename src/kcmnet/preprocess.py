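"""Per-omics filtering and transforms.

Four steps feed the merged dataset:

* median relative-abundance filtering of taxa and volatile compounds
  (default threshold 0.5 %, evaluated per timepoint);
* natural-log transform of the kept relative abundances, so that the
  roughly log-normal abundance distributions approach normality;
* probabilistic quotient normalisation (PQN) of NMR spectra applied
  regionally (aromatic / hydroxylic / aliphatic regions scaled
  independently), correcting per-sample dilution;
* fixed-width binning of the normalised spectra into bucket features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables_io import (
    UNIT_INTENSITY,
    FeatureTable,
    SpectraMatrix,
    check_design_covers,
)

logger = logging.getLogger(__name__)

FILTER_SCOPES = ("per_timepoint_union", "per_timepoint_intersection", "pooled")


@dataclass
class FilterConfig:
    """Median relative-abundance filter settings.

    ``ra_threshold`` is in percent.  ``scope`` controls how the per-feature
    median is evaluated: ``per_timepoint_union`` keeps a feature if its
    median passes at T0 *or* Te (default, so baseline and endpoint networks
    share a node set), ``per_timepoint_intersection`` requires both, and
    ``pooled`` uses a single median over all samples.
    """

    ra_threshold: float = 0.5
    scope: str = "per_timepoint_union"

    def __post_init__(self) -> None:
        if self.ra_threshold < 0:
            raise ValidationError("ra_threshold must be >= 0")
        if self.scope not in FILTER_SCOPES:
            raise ValidationError(f"unknown filter scope {self.scope!r}")


@dataclass
class RegionSpec:
    """Half-open ppm intervals over which PQN is applied independently."""

    regions: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        regs = [(float(lo), float(hi)) for lo, hi in self.regions]
        for lo, hi in regs:
            if not lo < hi:
                raise ValidationError(f"empty region ({lo}, {hi})")
        for i, (lo1, hi1) in enumerate(regs):
            for lo2, hi2 in regs[i + 1:]:
                if lo1 < hi2 and lo2 < hi1:
                    raise ValidationError("PQN regions must not overlap")
        self.regions = regs


def filter_by_median_abundance(
    table: FeatureTable,
    cfg: Optional[FilterConfig] = None,
    design: Optional[pd.DataFrame] = None,
) -> Tuple[FeatureTable, Dict[str, Dict[str, float]]]:
    """Drop features whose median relative abundance falls below threshold.

    Returns the kept table and a log mapping each removed feature to the
    per-scope medians that condemned it.  An empty result is legal but
    warned about; downstream network construction refuses empty tables.
    """
    cfg = cfg or FilterConfig()
    v = table.values
    if cfg.scope == "pooled":
        groups = {"pooled": np.ones(table.n_samples, dtype=bool)}
    else:
        if design is None:
            raise ValidationError("per-timepoint filter scopes require a design table")
        check_design_covers(table, design)
        tp = design.loc[table.sample_ids, "timepoint"].to_numpy()
        groups = {t: tp == t for t in ("T0", "Te") if (tp == t).any()}
        if not groups:
            raise ValidationError("design assigns no samples to T0 or Te")

    medians = {name: v.loc[mask].median(axis=0) for name, mask in groups.items()}
    passes = pd.DataFrame({name: m >= cfg.ra_threshold for name, m in medians.items()})
    if cfg.scope == "per_timepoint_intersection":
        keep_mask = passes.all(axis=1)
    else:  # union, or the single pooled column
        keep_mask = passes.any(axis=1)

    kept = [f for f in table.feature_ids if keep_mask[f]]
    removed = {
        f: {name: float(m[f]) for name, m in medians.items()}
        for f in table.feature_ids
        if not keep_mask[f]
    }
    if not kept:
        warnings.warn(
            "median-abundance filter removed every feature; the resulting "
            "table is empty and cannot seed a network",
            stacklevel=2,
        )
        out = FeatureTable(v.iloc[:, :0].copy(), {}, {})
        return out, removed
    return table.subset_features(kept), removed


def default_pseudocount(table: FeatureTable) -> float:
    """Half the smallest positive value in the table; 0 if no zeros occur."""
    arr = table.values.to_numpy(float)
    if not np.any(arr == 0):
        return 0.0
    pos = arr[arr > 0]
    if pos.size == 0:
        raise ValidationError("table is all zeros; cannot derive a pseudocount")
    return float(pos.min() / 2.0)


def log_transform(table: FeatureTable, pseudocount: Optional[float] = None) -> FeatureTable:
    """Replace values by ln(value + pseudocount); updates the units tag.

    By default the pseudocount is half the smallest positive value of the
    table when zeros are present, and 0 otherwise.
    """
    arr = table.values.to_numpy(float)
    if np.any(arr < 0):
        raise ValidationError("log transform requires non-negative values")
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and np.any(arr == 0):
        raise ValidationError("zero values present; a positive pseudocount is required")
    out = pd.DataFrame(np.log(arr + pseudocount), index=table.values.index,
                       columns=table.values.columns)
    units = {f: f"log_{table.units[f]}" if not table.units[f].startswith("log_")
             else table.units[f] for f in table.feature_ids}
    return FeatureTable(out, dict(table.feature_type), units)


def pqn_normalize(spectra: SpectraMatrix, regions: RegionSpec) -> SpectraMatrix:
    """Regional probabilistic quotient normalisation.

    Per region, each sample is first integral-normalised (divided by its
    regional total); the reference is the point-wise median of those
    normalised profiles, and each sample is then divided by the median of
    its point-wise quotients against the reference.  Regions are scaled
    independently (regional scaling); points outside every region are
    left untouched.

    The initial integral normalisation makes the whole operation exactly
    invariant to any per-sample per-region positive rescaling (the
    dilution model): the output lives on the consensus scale of the
    cohort, so a sample diluted by any factor normalises to precisely the
    same profile as its undiluted twin.
    """
    if spectra.n_samples < 2:
        raise ValidationError("PQN requires at least 2 samples")
    v = spectra.values.copy()
    axis = spectra.axis
    for lo, hi in regions.regions:
        mask = (axis >= lo) & (axis < hi)
        if not mask.any():
            raise ValidationError(f"region ({lo}, {hi}) contains no spectral points")
        seg = v[:, mask]
        totals = seg.sum(axis=1)
        for sid, tot in zip(spectra.sample_ids, totals):
            if tot <= 0:
                raise ValidationError(
                    f"sample {sid!r} has a non-positive total in region ({lo}, {hi}); "
                    "cannot normalise"
                )
        unit = seg / totals[:, None]
        ref = np.median(unit, axis=0)
        if np.all(ref == 0):
            raise ValidationError(f"reference spectrum is all zero in region ({lo}, {hi})")
        valid = ref > 0
        for i, sid in enumerate(spectra.sample_ids):
            q = unit[i, valid] / ref[valid]
            factor = np.median(q)
            if factor <= 0:
                raise ValidationError(
                    f"sample {sid!r}: non-positive quotient median in region ({lo}, {hi})"
                )
            v[i, mask] = unit[i] / factor
    return SpectraMatrix(v, axis.copy(), list(spectra.sample_ids))


def bin_spectrum(spectra: SpectraMatrix, width: int) -> FeatureTable:
    """Pool consecutive windows of ``width`` points into bucket features.

    Windows are pooled by mean.  A trailing partial window is kept when it
    holds at least width/2 points, otherwise dropped (and logged).  Bucket
    ids record the ppm interval covered; all buckets are labelled
    ``metabolome_nmr``.
    """
    if width < 1:
        raise ValidationError("bin width must be >= 1")
    n = spectra.n_points
    if width > n:
        raise ValidationError(f"bin width {width} exceeds spectrum length {n}")
    n_full = n // width
    remainder = n - n_full * width
    edges = [(i * width, (i + 1) * width) for i in range(n_full)]
    if remainder:
        if remainder >= width / 2:
            edges.append((n_full * width, n))
        else:
            logger.info("dropping trailing partial window of %d points (< width/2)", remainder)

    cols = {}
    ids = []
    for j, (a, b) in enumerate(edges):
        lo = min(spectra.axis[a], spectra.axis[b - 1])
        hi = max(spectra.axis[a], spectra.axis[b - 1])
        fid = f"bucket_{j + 1:04d}_{lo:.3f}_{hi:.3f}ppm"
        ids.append(fid)
        cols[fid] = spectra.values[:, a:b].mean(axis=1)
    df = pd.DataFrame(cols, index=pd.Index(spectra.sample_ids, name="sample_id"))
    return FeatureTable(df, {f: "metabolome_nmr" for f in ids},
                        {f: UNIT_INTENSITY for f in ids})
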