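"""Degree profiles of k-mer counts and their k-medoid clustering.

For each k-mer, its degree profile in one node type is the mean count
over all nodes of that type and degree, for degrees 1..D (default
D = 10).  The promoter and enhancer profiles of the same k-mer are
joined head to tail (promoter half first) and centered by subtracting
the joint mean, and the resulting vectors - one per k-mer - are
clustered with PAM k-medoids under Euclidean distance, with the number
of clusters selected by the gap statistic.  Clusters are annotated with
their CpG / GC composition and the monotonicity of their median half
profiles, which is how the association between CpG content and
degree-dependent count increase becomes testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .kmer_core import KmerVector, kmer_list

logger = logging.getLogger(__name__)

DEFAULT_DEGREE_CAP = 10
MONOTONE_RHO_THRESHOLD = 0.5


@dataclass
class DegreeProfiles:
    """Per-k-mer mean-count profiles over degrees 1..D for one node type.

    ``values`` is a DataFrame indexed by k-mer with one column per
    degree (NaN where the degree has no nodes); ``n_nodes`` counts the
    nodes per degree.
    """

    node_type: str
    values: pd.DataFrame
    n_nodes: pd.Series


def degree_profiles(
    vectors: list[KmerVector], node_type: str, degree_cap: int = DEFAULT_DEGREE_CAP
) -> DegreeProfiles:
    """Average k-mer count per degree 1..degree_cap for one node type.

    Nodes with degree above the cap are excluded from the profiles (they
    stay in the network; only the profile indexing is capped).
    """
    if degree_cap < 1:
        raise ValueError(f"degree_cap must be >= 1, got {degree_cap}")
    selected = [v for v in vectors if v.node_type == node_type]
    if not selected:
        raise ValueError(f"no k-mer vectors of type {node_type!r}")
    width = selected[0].counts.size
    k = int(round(np.log(width) / np.log(4)))
    kmers = kmer_list(k)
    degrees = np.arange(1, degree_cap + 1)
    matrix = np.stack([v.counts for v in selected]).astype(float)
    node_degrees = np.array([v.degree for v in selected])
    values = np.full((width, degree_cap), np.nan)
    n_nodes = np.zeros(degree_cap, dtype=int)
    for i, d in enumerate(degrees):
        mask = node_degrees == d
        n_nodes[i] = int(mask.sum())
        if n_nodes[i]:
            values[:, i] = matrix[mask].mean(axis=0)
    return DegreeProfiles(
        node_type=node_type,
        values=pd.DataFrame(values, index=pd.Index(kmers, name="kmer"),
                            columns=pd.Index(degrees, name="degree")),
        n_nodes=pd.Series(n_nodes, index=pd.Index(degrees, name="degree")),
    )


def join_and_center(p_values: np.ndarray, e_values: np.ndarray) -> np.ndarray:
    """Concatenate promoter and enhancer profiles (promoter first) and
    subtract the mean of the joint vector."""
    p_values = np.asarray(p_values, dtype=float)
    e_values = np.asarray(e_values, dtype=float)
    if p_values.shape != e_values.shape:
        raise ValueError("promoter and enhancer profiles must have equal length")
    joint = np.concatenate([p_values, e_values])
    return joint - joint.mean()


def joint_profiles(
    prom: DegreeProfiles, enh: DegreeProfiles
) -> tuple[pd.DataFrame, list[int]]:
    """Centered joint profiles over degrees populated in both node types.

    Returns ``(matrix, degrees_used)``: the matrix has one row per
    k-mer and 2*D' columns (promoter half then enhancer half), centered
    per row; ``degrees_used`` lists the degrees retained.  Degrees where
    either type has no nodes are excluded (logged if any of 1..D was
    empty).
    """
    if not prom.values.index.equals(enh.values.index):
        raise ValueError("promoter and enhancer profiles index different k-mers")
    populated = [
        int(d) for d in prom.values.columns
        if prom.n_nodes[d] > 0 and enh.n_nodes[d] > 0
    ]
    if not populated:
        raise ValueError("no degree populated in both node types")
    dropped = [int(d) for d in prom.values.columns if int(d) not in populated]
    if dropped:
        logger.info(
            "joint_profiles: degrees %s empty in one node type; using %s",
            dropped, populated,
        )
    p = prom.values[populated].to_numpy()
    e = enh.values[populated].to_numpy()
    joint = np.hstack([p, e])
    joint = joint - joint.mean(axis=1, keepdims=True)
    columns = [f"P{d}" for d in populated] + [f"E{d}" for d in populated]
    return (
        pd.DataFrame(joint, index=prom.values.index.copy(), columns=columns),
        populated,
    )


@dataclass
class KMedoidsResult:
    labels: np.ndarray
    medoid_indices: np.ndarray
    cost: float


def _pam_build(dist: np.ndarray, k: int) -> np.ndarray:
    """Greedy PAM BUILD: start from the 1-medoid optimum, then add the
    point with the largest total distance reduction at each step."""
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    d1 = dist[:, medoids[0]].copy()
    for _ in range(k - 1):
        reduction = np.maximum(d1[:, None] - dist, 0.0).sum(axis=0)
        reduction[medoids] = -np.inf
        h = int(np.argmax(reduction))
        medoids.append(h)
        d1 = np.minimum(d1, dist[:, h])
    return np.array(medoids)


def _pam_swap(dist: np.ndarray, medoids: np.ndarray, max_iter: int = 200):
    """PAM SWAP phase: repeatedly apply the best (medoid, non-medoid)
    exchange until no swap lowers the total cost."""
    n = dist.shape[0]
    medoids = np.array(medoids)
    k = medoids.size
    for _ in range(max_iter):
        dm = dist[:, medoids]
        if k > 1:
            order = np.argsort(dm, axis=1)
            near = order[:, 0]
            d1 = dm[np.arange(n), near]
            d2 = dm[np.arange(n), order[:, 1]]
        else:
            near = np.zeros(n, dtype=int)
            d1 = dm[:, 0]
            d2 = np.full(n, np.inf)
        cost = float(d1.sum())
        best_total = cost
        best_swap = None
        for i in range(k):
            mask = (near == i)[:, None]
            cand = np.where(
                mask, np.minimum(dist, d2[:, None]), np.minimum(dist, d1[:, None])
            )
            totals = cand.sum(axis=0)
            totals[medoids] = np.inf
            h = int(np.argmin(totals))
            if totals[h] < best_total - 1e-12:
                best_total = float(totals[h])
                best_swap = (i, h)
        if best_swap is None:
            labels = near
            return labels, medoids, cost
        medoids[best_swap[0]] = best_swap[1]
    dm = dist[:, medoids]
    labels = np.argmin(dm, axis=1)
    return labels, medoids, float(dm[np.arange(n), labels].sum())


def kmedoids(
    points: np.ndarray, k: int, seed: int = 0, restarts: int = 10
) -> KMedoidsResult:
    """PAM k-medoids under Euclidean distance.

    One run starts from the greedy BUILD configuration and the
    remaining ``restarts - 1`` from seeded random medoid sets; every run
    descends with best-improvement SWAP exchanges and the lowest-cost
    solution wins.  Medoids are always members of the input set; the
    cost is the sum of distances of every point to its medoid.
    Deterministic given ``seed``.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    dist = squareform(pdist(points)) if n > 1 else np.zeros((1, 1))
    rng = np.random.default_rng(seed)
    best: KMedoidsResult | None = None
    inits = [_pam_build(dist, k)]
    inits += [rng.choice(n, size=k, replace=False) for _ in range(max(restarts - 1, 0))]
    for init in inits:
        labels, medoids, cost = _pam_swap(dist, init)
        if best is None or cost < best.cost - 1e-12:
            best = KMedoidsResult(labels=labels, medoid_indices=medoids, cost=cost)
    return best


@dataclass
class GapResult:
    k_selected: int
    curve: pd.DataFrame  # columns: k, log_w, e_log_w, gap, s


def gap_statistic_select(
    points: np.ndarray,
    k_max: int = 10,
    B: int = 50,
    seed: int = 0,
    restarts: int = 5,
) -> GapResult:
    """Select the number of clusters with the gap statistic.

    Gap(k) = E*[log W_k] - log W_k, where W_k is the k-medoids cost and
    E* averages over ``B`` reference sets drawn uniformly over the
    per-coordinate range of the data.  The selected k is the smallest
    with Gap(k) >= Gap(k+1) - s_{k+1}, where s_k is the reference
    standard deviation inflated by sqrt(1 + 1/B).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if B < 10:
        raise ValueError(f"B must be >= 10, got {B}")
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    if k_max >= n:
        logger.warning("k_max=%d clamped to %d (number of points - 1)", k_max, n - 1)
        k_max = max(1, n - 1)
    rng = np.random.default_rng(seed)
    lo = points.min(axis=0)
    hi = points.max(axis=0)

    def log_w(data: np.ndarray, k: int, run_seed: int) -> float:
        cost = kmedoids(data, k, seed=run_seed, restarts=restarts).cost
        return float(np.log(max(cost, 1e-300)))

    ks = np.arange(1, k_max + 1)
    log_wk = np.array([
        log_w(points, k, int(rng.integers(2**31))) for k in ks
    ])
    ref_log = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=points.shape)
        for i, k in enumerate(ks):
            ref_log[b, i] = log_w(ref, k, int(rng.integers(2**31)))
    e_log = ref_log.mean(axis=0)
    sk = ref_log.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    gap = e_log - log_wk
    k_selected = int(ks[-1])
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            k_selected = int(ks[i])
            break
    curve = pd.DataFrame({
        "k": ks, "log_w": log_wk, "e_log_w": e_log, "gap": gap, "s": sk,
    })
    return GapResult(k_selected=k_selected, curve=curve)


@dataclass
class ClusteringResult:
    """k-medoid clustering of centered joint profiles."""

    assignments: pd.Series      # kmer -> cluster label (1-based)
    medoids: pd.DataFrame       # one joint profile per cluster
    k_selected: int
    gap_curve: pd.DataFrame
    degrees_used: list[int]


def cluster_joint_profiles(
    joint: pd.DataFrame,
    degrees_used: list[int],
    k_max: int = 10,
    B: int = 50,
    restarts: int = 10,
    seed: int = 0,
) -> ClusteringResult:
    """Gap-statistic-selected k-medoid clustering of joint profiles."""
    points = joint.to_numpy()
    gap = gap_statistic_select(points, k_max=k_max, B=B, seed=seed, restarts=restarts)
    fit = kmedoids(points, gap.k_selected, seed=seed, restarts=restarts)
    assignments = pd.Series(fit.labels + 1, index=joint.index, name="cluster")
    medoids = joint.iloc[fit.medoid_indices].copy()
    medoids.index = pd.Index(range(1, gap.k_selected + 1), name="cluster")
    medoids.insert(0, "medoid_kmer", joint.index[fit.medoid_indices])
    return ClusteringResult(
        assignments=assignments, medoids=medoids,
        k_selected=gap.k_selected, gap_curve=gap.curve,
        degrees_used=degrees_used,
    )


def _monotonicity(median_half: np.ndarray, degrees: list[int]) -> tuple[float, str]:
    rho, _ = stats.spearmanr(degrees, median_half)
    if np.isnan(rho) or abs(rho) < MONOTONE_RHO_THRESHOLD:
        return (0.0 if np.isnan(rho) else float(rho)), "flat"
    return float(rho), ("increasing" if rho > 0 else "decreasing")


def annotate_clusters(
    joint: pd.DataFrame,
    assignments: pd.Series,
    cpg_set: set[str],
    degrees_used: list[int],
) -> pd.DataFrame:
    """Per-cluster composition and trend summary.

    For each cluster: member k-mers, how many contain a CpG, how many
    are GC-only / AT-only, the Spearman rho of the median promoter and
    enhancer half profiles against degree, and a monotonicity label
    (increasing / decreasing / flat / mixed at |rho| >= 0.5, requiring
    both halves to agree for a monotone label).
    """
    ndeg = len(degrees_used)
    rows = []
    for cluster in sorted(assignments.unique()):
        members = assignments.index[assignments == cluster].tolist()
        block = joint.loc[members].to_numpy()
        median = np.median(block, axis=0)
        p_half, e_half = median[:ndeg], median[ndeg:]
        rho_p, label_p = _monotonicity(p_half, degrees_used)
        rho_e, label_e = _monotonicity(e_half, degrees_used)
        if label_p == label_e:
            label = label_p
        elif "flat" in (label_p, label_e):
            label = "mixed"
        else:
            label = "mixed"
        n_cpg = sum(1 for m in members if m in cpg_set)
        n_gc_only = sum(1 for m in members if set(m) <= {"G", "C"})
        n_at_only = sum(1 for m in members if set(m) <= {"A", "T"})
        rows.append({
            "cluster": int(cluster),
            "n_members": len(members),
            "members": ";".join(members),
            "n_cpg": n_cpg,
            "cpg_fraction": n_cpg / len(members),
            "n_gc_only": n_gc_only,
            "n_at_only": n_at_only,
            "rho_promoter": rho_p,
            "rho_enhancer": rho_e,
            "trend": label,
            "median_promoter_half": ";".join(f"{v:.6g}" for v in p_half),
            "median_enhancer_half": ";".join(f"{v:.6g}" for v in e_half),
        })
    return pd.DataFrame(rows)


def cpg_enrichment_test(summary: pd.DataFrame) -> tuple[float, float]:
    """One-sided Fisher test: are CpG-containing k-mers enriched in
    clusters with increasing median profiles relative to decreasing ones?

    Returns (odds ratio, p-value) on the 2x2 table of k-mer membership
    (increasing vs decreasing cluster) x (CpG-containing vs not).
    """
    inc = summary[summary["trend"] == "increasing"]
    dec = summary[summary["trend"] == "decreasing"]
    if inc.empty or dec.empty:
        raise ValueError("need at least one increasing and one decreasing cluster")
    a = int(inc["n_cpg"].sum())
    b = int(inc["n_members"].sum()) - a
    c = int(dec["n_cpg"].sum())
    d = int(dec["n_members"].sum()) - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)
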