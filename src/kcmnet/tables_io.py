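"""Feature tables, sample design metadata and network import/export.

The universal data currency of the package is the :class:`FeatureTable`:
a samples x features numeric matrix with a per-feature omics-type label
(``microbiome``, ``volatilome`` or ``metabolome_nmr``) and a per-feature
units tag.  Tables are read from and written to delimited text
(CSV/TSV, samples in rows, features in columns, first column = sample id);
omics-type labels travel in a sidecar metadata TSV so that feature ids stay
format-safe.

Networks are exported as GraphML (Cytoscape-compatible, with an
``omics_type`` node attribute and build provenance as graph attributes),
SIF, or a plain tab-separated edge list.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

OMICS_TYPES = ("microbiome", "volatilome", "metabolome_nmr")

#: units tags used by the preprocessing steps
UNIT_PERCENT_RA = "percent_ra"
UNIT_LOG_RA = "log_ra"
UNIT_INTENSITY = "intensity"
UNIT_POOLED = "pooled_intensity"

SEXES = ("F", "M")
TIMEPOINTS = ("T0", "Te")
ARMS = ("A", "P")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(eq=False)
class FeatureTable:
    """Samples x features matrix with per-feature omics-type and units tags.

    Parameters
    ----------
    values
        DataFrame with sample ids as index and feature ids as columns.
    feature_type
        Mapping feature id -> one of :data:`OMICS_TYPES`.
    units
        Mapping feature id -> units tag; missing entries default to
        ``"intensity"``.
    """

    values: pd.DataFrame
    feature_type: Dict[str, str]
    units: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "sample")
        _check_unique(list(self.values.columns), "feature")
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        for f in self.values.columns:
            t = self.feature_type.get(f)
            if t is None:
                raise ValidationError(f"feature {f!r} has no omics-type label")
            if t not in OMICS_TYPES:
                raise ValidationError(f"feature {f!r} has unknown omics type {t!r}")
            self.units.setdefault(f, UNIT_INTENSITY)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, features: Sequence[str]) -> "FeatureTable":
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown features: {missing}")
        return FeatureTable(
            self.values.loc[:, list(features)].copy(),
            {f: self.feature_type[f] for f in features},
            {f: self.units[f] for f in features},
        )

    def subset_samples(self, samples: Sequence[str]) -> "FeatureTable":
        missing = [s for s in samples if s not in self.values.index]
        if missing:
            raise ValidationError(f"unknown samples: {missing}")
        return FeatureTable(
            self.values.loc[list(samples)].copy(),
            dict(self.feature_type),
            dict(self.units),
        )

    def select_type(self, omics_type: str) -> "FeatureTable":
        feats = [f for f in self.feature_ids if self.feature_type[f] == omics_type]
        return self.subset_features(feats)

    def with_values(self, new_values: pd.DataFrame,
                    units: Optional[Mapping[str, str]] = None) -> "FeatureTable":
        u = dict(self.units)
        if units:
            u.update(units)
        return FeatureTable(new_values, dict(self.feature_type),
                            {f: u[f] for f in new_values.columns if f in u})

    def equals(self, other: "FeatureTable", tol: float = 0.0) -> bool:
        if self.sample_ids != other.sample_ids or self.feature_ids != other.feature_ids:
            return False
        if self.feature_type != other.feature_type:
            return False
        a, b = self.values.to_numpy(float), other.values.to_numpy(float)
        both_nan = np.isnan(a) & np.isnan(b)
        diff = np.abs(a - b)
        diff[both_nan] = 0.0
        return bool(np.all(diff <= tol))

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ("subject_id", "sex", "timepoint", "arm")


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-design table (index = sample id).

    Required columns: subject_id, sex (F/M), timepoint (T0/Te), arm (A/P).
    """
    for col in DESIGN_COLUMNS:
        if col not in design.columns:
            raise ValidationError(f"design table missing column {col!r}")
    _check_unique(list(design.index), "design sample")
    for col, allowed in (("sex", SEXES), ("timepoint", TIMEPOINTS), ("arm", ARMS)):
        bad = set(design[col]) - set(allowed)
        if bad:
            raise ValidationError(f"design column {col!r} has invalid values {sorted(bad)}")
    return design


def check_design_covers(table: FeatureTable, design: pd.DataFrame) -> None:
    missing = [s for s in table.sample_ids if s not in design.index]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError("design table must have a 'sample_id' column")
    df = df.set_index("sample_id")
    return validate_design(df)


def write_design(design: pd.DataFrame, path) -> None:
    validate_design(design)
    design.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class SpectraMatrix:
    """Pre-binning NMR profiles: samples x spectral points with a ppm axis."""

    values: np.ndarray  # (n_samples, n_points)
    axis: np.ndarray    # (n_points,) chemical shift in ppm, strictly monotone
    sample_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("spectra values must be 2-D (samples x points)")
        if self.axis.shape[0] != self.values.shape[1]:
            raise ValidationError("ppm axis length must equal number of spectral points")
        d = np.diff(self.axis)
        if self.axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be strictly monotone")
        _check_unique(self.sample_ids, "sample")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValidationError("sample_ids length must match number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "nan", "na", "null", "none"}


def _sniff_delimiter(header_line: str) -> str:
    if "\t" in header_line:
        return "\t"
    return ","


def read_feature_table(path, omics_type: str, delimiter: Optional[str] = None,
                       units: str = UNIT_INTENSITY) -> FeatureTable:
    """Read a delimited samples-x-features table, labelling all features.

    First column holds sample ids, header row holds feature ids, the body
    is numeric.  Missing cells are tolerated on read (they must be resolved
    before any correlation step); any other non-numeric cell raises
    :class:`ParseError` naming its row and column.
    """
    if omics_type not in OMICS_TYPES:
        raise ValidationError(f"unknown omics type {omics_type!r}")
    path = Path(path)
    with open(path, newline="") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ParseError(f"{path}: empty file")
    if delimiter is None:
        delimiter = _sniff_delimiter(header_line)
    header = next(csv.reader([header_line], delimiter=delimiter))
    feature_ids = [h.strip() for h in header[1:]]
    _check_unique(feature_ids, "feature")

    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                      skipinitialspace=True)
    raw.index = raw.index.astype(str)
    _check_unique(list(raw.index), "sample")

    numeric = pd.DataFrame(index=raw.index, columns=feature_ids, dtype=float)
    for col in feature_ids:
        conv = pd.to_numeric(raw[col], errors="coerce")
        bad = conv.isna() & raw[col].notna() & ~raw[col].astype(str).str.strip().str.lower().isin(_MISSING_TOKENS)
        if bad.any():
            row = bad.idxmax()
            raise ParseError(
                f"{path}: non-numeric value {raw.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        numeric[col] = conv
    return FeatureTable(numeric, {f: omics_type for f in feature_ids},
                        {f: units for f in feature_ids})


def write_feature_table(table: FeatureTable, path, delimiter: str = ",") -> None:
    table.values.to_csv(path, sep=delimiter, index_label="sample_id")


def write_feature_metadata(table: FeatureTable, path) -> None:
    """Sidecar TSV: feature_id, omics_type, units, display_name."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["feature_id", "omics_type", "units", "display_name"])
        for f in table.feature_ids:
            w.writerow([f, table.feature_type[f], table.units[f], f])


def read_feature_metadata(path) -> Dict[str, Dict[str, str]]:
    meta: Dict[str, Dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["feature_id"]] = row
    return meta


def apply_feature_metadata(table: FeatureTable, meta: Mapping[str, Mapping[str, str]]) -> FeatureTable:
    ftype = dict(table.feature_type)
    units = dict(table.units)
    for f in table.feature_ids:
        if f in meta:
            ftype[f] = meta[f]["omics_type"]
            units[f] = meta[f].get("units", units[f])
    return FeatureTable(table.values.copy(), ftype, units)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_tables(tables: Sequence[FeatureTable],
                 design: Optional[pd.DataFrame] = None) -> FeatureTable:
    """Concatenate omics blocks over a shared sample set.

    All tables must cover the same sample ids (any order); feature ids must
    be disjoint across blocks.  Samples are aligned to the order of the
    first block.
    """
    if not tables:
        raise ValidationError("merge_tables requires at least one table")
    ref = tables[0]
    ref_set = set(ref.sample_ids)
    for t in tables[1:]:
        other = set(t.sample_ids)
        if other != ref_set:
            diff = sorted(ref_set.symmetric_difference(other))
            raise ValidationError(f"sample sets differ between blocks; symmetric difference: {diff}")
    seen: Dict[str, int] = {}
    for i, t in enumerate(tables):
        for f in t.feature_ids:
            if f in seen:
                raise ValidationError(
                    f"feature id {f!r} appears in blocks {seen[f]} and {i}"
                )
            seen[f] = i
    order = ref.sample_ids
    merged = pd.concat([t.values.loc[order] for t in tables], axis=1)
    ftype: Dict[str, str] = {}
    units: Dict[str, str] = {}
    for t in tables:
        ftype.update(t.feature_type)
        units.update(t.units)
    out = FeatureTable(merged, ftype, units)
    if design is not None:
        validate_design(design)
        check_design_covers(out, design)
    return out


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "sif", "edgelist")


def export_network(net, path, format: str = "graphml") -> None:
    """Write an OmicsNetwork to GraphML, SIF or a TSV edge list.

    GraphML carries the ``omics_type`` node attribute and the build
    provenance (threshold ``t``, group, mode, sample count, correlation
    method) as graph attributes; SIF uses the interaction label ``cor``.
    """
    if format not in NETWORK_FORMATS:
        raise ValidationError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    g = net.graph
    path = Path(path)
    if format == "graphml":
        h = nx.Graph()
        prov = net.provenance
        h.graph.update({
            "group": prov.group or "",
            "t": float(prov.t),
            "mode": prov.mode,
            "n_samples": int(prov.n_samples),
            "method": prov.method,
        })
        for node, data in g.nodes(data=True):
            h.add_node(node, omics_type=data.get("omics_type", ""))
        h.add_edges_from(g.edges())
        nx.write_graphml(h, path)
    elif format == "sif":
        with open(path, "w") as fh:
            isolated = [n for n in g.nodes if g.degree[n] == 0]
            for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
                fh.write(f"{u}\tcor\t{v}\n")
            for n in sorted(isolated):
                fh.write(f"{n}\n")
    else:  # edgelist
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
                fh.write(f"{u}\t{v}\n")


def import_network(path):
    """Read a GraphML file written by :func:`export_network`."""
    from .netbuild import NetworkProvenance, OmicsNetwork

    h = nx.read_graphml(Path(path))
    g = nx.Graph()
    for node, data in h.nodes(data=True):
        g.add_node(node, omics_type=data.get("omics_type", ""))
    g.add_edges_from(h.edges())
    prov = NetworkProvenance(
        group=h.graph.get("group") or None,
        n_samples=int(h.graph.get("n_samples", 0)),
        t=float(h.graph.get("t", float("nan"))),
        mode=h.graph.get("mode", "signed"),
        method=h.graph.get("method", "spearman"),
    )
    return OmicsNetwork(graph=g, provenance=prov)


# ---------------------------------------------------------------------------
# report serialisation
# ---------------------------------------------------------------------------

def write_json_report(obj, path) -> None:
    """Serialise a report object (dataclass with ``to_dict``) to JSON."""
    data = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# optional outlier screen (the upstream discard rule is not defined by the
# protocol; this z-score filter is exposed as an explicit opt-in)
# ---------------------------------------------------------------------------

def flag_outlier_samples(table: FeatureTable, z_max: float = 4.0) -> List[str]:
    """Flag samples whose maximum per-feature |z-score| exceeds ``z_max``."""
    v = table.values.to_numpy(float)
    mu = np.nanmean(v, axis=0)
    sd = np.nanstd(v, axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = np.abs((v - mu) / sd)
    flagged = np.nanmax(z, axis=1) > z_max
    return [s for s, f in zip(table.sample_ids, flagged) if f]
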