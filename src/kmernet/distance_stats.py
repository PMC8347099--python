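"""Sequence-similarity statistics along network edges.

The k-mer distance between two regions is the Euclidean distance of
their k-mer count vectors (length 256 for k = 4).  The local average
k-mer distance (lakd) of a node is the mean k-mer distance over all the
promoter-enhancer edges incident to it: for a promoter, how dissimilar
it is on average to its interacting enhancers, and conversely.  The
lakd is not symmetric between the two groupings - the edge set is the
same, but the averaging is per promoter in one case and per enhancer in
the other - which is exactly what makes it informative: it localizes
the global promoter/enhancer composition difference to the interacting
pairs.

This module also provides the degree-trend statistics (OLS slope and
Spearman correlation of lakd or of composition metrics against node
degree) and the two-sample Kolmogorov-Smirnov comparison of the lakd
distributions.  Regression and correlation are computed over individual
nodes, not per-degree means (per-degree means are reported alongside
for plotting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kmer_core import CompositionStats, KmerVector
from .network import InteractionNetwork, subset_network

logger = logging.getLogger(__name__)

COMPOSITION_METRICS = ["GG", "CC", "GC", "CG", "gc_percent"]


def kmer_distance(a, b) -> float:
    """Euclidean distance between two k-mer count vectors."""
    av = a.counts if isinstance(a, KmerVector) else np.asarray(a, dtype=float)
    bv = b.counts if isinstance(b, KmerVector) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"vector length mismatch: {av.shape} vs {bv.shape}")
    return float(np.linalg.norm(av.astype(float) - bv.astype(float)))


def edge_distances(network: InteractionNetwork, vectors: dict) -> dict:
    """k-mer distance for every edge whose endpoints both have vectors."""
    out = {}
    for p, e in network.edges:
        if p in vectors and e in vectors:
            out[(p, e)] = kmer_distance(vectors[p], vectors[e])
    return out


def lakd(network: InteractionNetwork, vectors: dict) -> pd.DataFrame:
    """Local average k-mer distance of every node.

    ``vectors`` maps node_id to :class:`KmerVector`.  Nodes without a
    vector (dropped during region extraction) are removed from the
    network first, together with their edges; nodes isolated by that
    removal yield no record (logged).  Returns a DataFrame with columns
    ``node_id, node_type, degree, lakd``.
    """
    missing = (network.promoters | network.enhancers) - set(vectors)
    net = subset_network(network, set(vectors)) if missing else network
    dists = edge_distances(net, vectors)
    sums: dict = {}
    for (p, e), d in dists.items():
        sums[p] = sums.get(p, 0.0) + d
        sums[e] = sums.get(e, 0.0) + d
    rows = []
    isolated = 0
    for node in sorted(net.promoters | net.enhancers):
        deg = net.degree[node]
        if deg == 0:
            isolated += 1
            continue
        rows.append({
            "node_id": node,
            "node_type": net.node_type(node),
            "degree": deg,
            "lakd": sums[node] / deg,
        })
    if isolated:
        logger.info("lakd: skipped %d isolated nodes (degree 0 after drops)", isolated)
    return pd.DataFrame(rows, columns=["node_id", "node_type", "degree", "lakd"])


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of the absolute ECDF difference; the p-value comes
    from the asymptotic Kolmogorov distribution with effective sample
    size n_x n_y / (n_x + n_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have size >= 2")
    result = stats.ks_2samp(x, y, method="asymp")
    return float(result.statistic), float(result.pvalue)


@dataclass
class TrendResult:
    """Degree trend of a per-node statistic within one node type."""

    grouping: str
    slope: float
    slope_p: float
    spearman_rho: float
    spearman_p: float
    per_degree_means: pd.Series
    n: int


def _trend(values: np.ndarray, degrees: np.ndarray, grouping: str) -> TrendResult:
    if np.unique(degrees).size < 2:
        raise ValueError("degree is constant; no trend is defined")
    ols = stats.linregress(degrees, values)
    rho, rho_p = stats.spearmanr(degrees, values)
    means = (
        pd.Series(values, index=pd.Index(degrees, name="degree"))
        .groupby(level="degree").mean()
    )
    return TrendResult(
        grouping=grouping,
        slope=float(ols.slope), slope_p=float(ols.pvalue),
        spearman_rho=float(rho), spearman_p=float(rho_p),
        per_degree_means=means, n=int(values.size),
    )


def degree_trend(
    records: pd.DataFrame,
    grouping: str,
    degree_range: tuple[int, int] | None = None,
) -> TrendResult:
    """OLS slope and Spearman correlation of lakd against node degree.

    ``records`` is the output of :func:`lakd`; ``grouping`` selects the
    node type.  Computed over individual nodes.  ``degree_range``
    optionally restricts the degrees used (default: all).
    """
    sub = records[records["node_type"] == grouping]
    if degree_range is not None:
        lo, hi = degree_range
        sub = sub[(sub["degree"] >= lo) & (sub["degree"] <= hi)]
    if sub["degree"].nunique() < 3:
        raise ValueError(
            f"need >= 3 distinct degrees for {grouping!r}, got {sub['degree'].nunique()}"
        )
    return _trend(sub["lakd"].to_numpy(float), sub["degree"].to_numpy(float), grouping)


def composition_frame(stats_list: list[CompositionStats]) -> pd.DataFrame:
    """Tabulate :class:`CompositionStats` records."""
    return pd.DataFrame([{
        "node_id": s.node_id, "node_type": s.node_type, "degree": s.degree,
        "GG": s.GG, "CC": s.CC, "GC": s.GC, "CG": s.CG,
        "gc_percent": s.gc_percent,
    } for s in stats_list])


@dataclass
class CompositionTrendTable:
    """Composition-vs-degree statistics per metric and node type.

    ``stats`` has one row per (node_type, metric) with the correlation,
    its p-value and the OLS slope; ``means`` has per-degree means and the
    fold change relative to degree 1.
    """

    stats: pd.DataFrame
    means: pd.DataFrame
    method: str


def composition_trends(
    comp: pd.DataFrame | list[CompositionStats],
    grouping: str | list[str] | None = None,
    degree_range: tuple[int, int] | None = None,
    method: str = "spearman",
) -> CompositionTrendTable:
    """Correlation/slope of GC%, GG, CC, GC and CG counts with node degree.

    The correlation is Spearman by default (``method="pearson"`` for a
    sensitivity check; the choice is logged).  Fold change is the ratio
    of the per-degree mean to the degree-1 mean, exactly 1 at degree 1;
    absence of degree-1 nodes is an error.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    logger.info("composition_trends: correlation column is %s", method)
    if not isinstance(comp, pd.DataFrame):
        comp = composition_frame(comp)
    if grouping is None:
        groupings = sorted(comp["node_type"].unique())
    elif isinstance(grouping, str):
        groupings = [grouping]
    else:
        groupings = list(grouping)
    stat_rows, mean_rows = [], []
    for g in groupings:
        sub = comp[comp["node_type"] == g]
        if degree_range is not None:
            lo, hi = degree_range
            sub = sub[(sub["degree"] >= lo) & (sub["degree"] <= hi)]
        if sub.empty:
            raise ValueError(f"no nodes of type {g!r}")
        degrees = sub["degree"].to_numpy(float)
        if (sub["degree"] == 1).sum() == 0:
            raise ValueError(
                f"no degree-1 nodes of type {g!r}: fold change undefined"
            )
        for metric in COMPOSITION_METRICS:
            values = sub[metric].to_numpy(float)
            if np.ptp(values) == 0:  # constant metric: correlation undefined
                corr, p = np.nan, np.nan
            elif method == "spearman":
                corr, p = stats.spearmanr(degrees, values)
            else:
                corr, p = stats.pearsonr(degrees, values)
            ols = stats.linregress(degrees, values)
            stat_rows.append({
                "node_type": g, "metric": metric,
                "correlation": float(corr), "p_value": float(p),
                "slope": float(ols.slope),
            })
            by_degree = (
                pd.Series(values, index=sub["degree"].to_numpy())
                .groupby(level=0).mean()
            )
            base = by_degree.loc[1]
            for d, m in by_degree.items():
                fc = 1.0 if d == 1 else (m / base if base != 0 else np.nan)
                mean_rows.append({
                    "node_type": g, "metric": metric, "degree": int(d),
                    "mean": float(m), "fold_change": float(fc),
                })
    return CompositionTrendTable(
        stats=pd.DataFrame(stat_rows),
        means=pd.DataFrame(mean_rows),
        method=method,
    )


def lakd_distribution_report(records: pd.DataFrame) -> dict:
    """Compare the promoter- and enhancer-grouped lakd distributions.

    Returns the per-type lakd vectors and means, the KS statistic and
    p-value, and which grouping is shifted toward smaller distances.
    """
    prom = records.loc[records["node_type"] == "promoter", "lakd"].to_numpy(float)
    enh = records.loc[records["node_type"] == "enhancer", "lakd"].to_numpy(float)
    if prom.size == 0 or enh.size == 0:
        raise ValueError("both node types must be present")
    d, p = ks_two_sample(prom, enh)
    prom_mean, enh_mean = float(prom.mean()), float(enh.mean())
    return {
        "promoter_lakd": prom,
        "enhancer_lakd": enh,
        "promoter_mean": prom_mean,
        "enhancer_mean": enh_mean,
        "ks_D": d,
        "ks_p": p,
        "shifted_smaller": "promoter" if prom_mean < enh_mean else "enhancer",
    }


def lakd_histogram(records: pd.DataFrame, bin_width: float = 5.0) -> pd.DataFrame:
    """Binned per-type lakd densities for tabular export."""
    lo = records["lakd"].min()
    hi = records["lakd"].max() + bin_width
    edges = np.arange(np.floor(lo / bin_width) * bin_width, hi + bin_width, bin_width)
    rows = []
    for g, sub in records.groupby("node_type"):
        hist, _ = np.histogram(sub["lakd"], bins=edges, density=True)
        for left, right, dens in zip(edges[:-1], edges[1:], hist):
            rows.append({
                "node_type": g, "bin_left": left, "bin_right": right,
                "density": dens,
            })
    return pd.DataFrame(rows)
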