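"""Network summary statistics and the power-law degree-distribution fit.

The group comparison relies on a handful of global parameters: density,
average degree, average clustering coefficient, connected components,
isolated nodes, and — as a scale-freeness diagnostic — an ordinary
least-squares fit of the degree histogram on log-log axes
(y = a x^b, with the fit's R^2).  The fit is a descriptive curve fit on
raw degree-frequency points, not a maximum-likelihood exponent estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import networkx as nx
import numpy as np

from .errors import ValidationError


@dataclass
class PowerLawFit:
    a: float           # prefactor on the frequency (count) scale
    b: float           # exponent
    r_squared: float
    a_probability: float  # prefactor when counts are normalised to probabilities

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "r_squared": self.r_squared,
                "a_probability": self.a_probability}


@dataclass
class TopologyReport:
    n_nodes: int
    n_edges: int
    density: float
    avg_degree: float
    avg_clustering: float
    n_components: int
    n_isolated: int
    degree_histogram: Dict[int, int]
    powerlaw: Optional[PowerLawFit]

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density": self.density,
            "avg_degree": self.avg_degree,
            "avg_clustering": self.avg_clustering,
            "n_components": self.n_components,
            "n_isolated": self.n_isolated,
            "degree_histogram": {str(k): v for k, v in sorted(self.degree_histogram.items())},
            "powerlaw": self.powerlaw.to_dict() if self.powerlaw else None,
        }


def fit_power_law(degree_histogram: Mapping[int, int]) -> Optional[PowerLawFit]:
    """OLS fit of log10(count) on log10(degree) over the degree histogram.

    Degree-0 nodes are excluded (log 0 undefined).  Requires at least 3
    distinct positive degrees with positive counts; otherwise returns
    ``None`` with a warning.  ``a`` is reported on the frequency scale and,
    alongside, normalised to the probability scale (same b and R^2).
    """
    pts = sorted((float(d), float(c)) for d, c in degree_histogram.items()
                 if float(d) >= 1 and float(c) > 0)
    if len(pts) < 3:
        warnings.warn("fewer than 3 usable degree points; power-law fit omitted",
                      stacklevel=2)
        return None
    deg = np.array([p[0] for p in pts], dtype=float)
    cnt = np.array([p[1] for p in pts], dtype=float)
    lx, ly = np.log10(deg), np.log10(cnt)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    a = float(10.0 ** intercept)
    total = float(cnt.sum())
    return PowerLawFit(a=a, b=float(slope), r_squared=float(rsq),
                       a_probability=a / total)


def topology_report(net) -> TopologyReport:
    """Compute the global parameters of one omics network."""
    g: nx.Graph = net if isinstance(net, nx.Graph) else net.graph
    n = g.number_of_nodes()
    if n < 1:
        raise ValidationError("topology report requires at least 1 node")
    m = g.number_of_edges()
    degrees = [d for _, d in g.degree()]
    density = 0.0 if n < 2 else m / (n * (n - 1) / 2)
    avg_degree = float(np.mean(degrees))
    # local clustering = triangles / (deg choose 2), zero for deg < 2
    avg_clustering = float(nx.average_clustering(g)) if n else 0.0
    hist: Dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_power_law(hist)
    return TopologyReport(
        n_nodes=n,
        n_edges=m,
        density=float(density),
        avg_degree=avg_degree,
        avg_clustering=avg_clustering,
        n_components=nx.number_connected_components(g),
        n_isolated=len(list(nx.isolates(g))),
        degree_histogram=hist,
        powerlaw=fit,
    )
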