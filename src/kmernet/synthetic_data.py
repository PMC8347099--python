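"""Synthetic promoter-enhancer networks with degree-dependent sequences.

The generator emulates the statistical structure the analysis assumes,
so the whole pipeline can run and be tested without genome downloads:

* a bipartite network in which promoters have a broad degree
  distribution (zero-truncated negative binomial) while enhancers
  mostly have degree 1 with a geometric tail, wired with a
  configuration model (degree-exact, simple graph);
* 1 kb sequences from a first-order Markov chain over {A,C,G,T} whose
  GC propensity increases linearly with the node degree and is higher
  in promoters than in enhancers, and whose C->G transition is damped
  by a per-type CpG-depletion factor (strong in enhancers).

All randomness flows from a single seed through named substreams, and
each node's sequence stream is indexed by the node, so every stage is
independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    Genome, InteractionRecord, write_genome, write_interaction_table, write_tsv,
)
from .network import InteractionNetwork, build_network
from .regions import GenomicRegion

logger = logging.getLogger(__name__)

_STREAMS = {"degrees": 1, "wiring": 2, "sequences": 3}

#: half-width of the synthetic enhancer fragment (real enhancer
#: fragments average ~0.7 kb, so the pipeline's midpoint-anchoring is
#: exercised on a realistic fragment size)
ENHANCER_FRAGMENT_HALF = 350

GC_CLAMP = (0.05, 0.95)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the shape of a capture Hi-C promoter-enhancer
    dataset scaled to ~2,000 nodes: promoters average ~6 partners,
    ~80% of enhancers have a single partner, promoters are GC-richer
    than enhancers, GC propensity rises with degree, and enhancers are
    strongly CpG-depleted.
    """

    n_promoters: int = 350
    n_enhancers: int = 1650
    promoter_degree_mean: float = 6.0
    promoter_degree_dispersion: float = 2.0
    enhancer_p1: float = 0.8
    enhancer_tail_p: float = 0.6
    window: int = 1000
    pad: int = 100
    gc_base_promoter: float = 0.55
    gc_base_enhancer: float = 0.45
    gc_degree_slope: float = 0.01
    cpg_depletion_promoter: float = 0.8
    cpg_depletion_enhancer: float = 0.3
    seed: int = 20210728

    def __post_init__(self) -> None:
        if not (0 < self.gc_base_promoter < 1 and 0 < self.gc_base_enhancer < 1):
            raise ValueError("gc_base fractions must lie in (0, 1)")
        for f in (self.cpg_depletion_promoter, self.cpg_depletion_enhancer):
            if not (0 < f <= 1):
                raise ValueError("cpg_depletion factors must lie in (0, 1]")
        if self.n_promoters < 1 or self.n_enhancers < 1:
            raise ValueError("need at least one node of each type")


def _rng(seed: int, stream: str, index: int | None = None) -> np.random.Generator:
    key = (seed, _STREAMS[stream]) if index is None else (seed, _STREAMS[stream], index)
    return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# degree laws

def promoter_degree_pmf(d: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Zero-truncated negative binomial pmf of promoter degrees."""
    r = config.promoter_degree_dispersion
    p = r / (r + config.promoter_degree_mean)
    base = stats.nbinom(r, p)
    return base.pmf(d) / (1.0 - base.pmf(0))


def enhancer_degree_pmf(d: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Enhancer degree pmf: 1 with probability p1, else 1 + geometric."""
    d = np.asarray(d)
    tail = (1.0 - config.enhancer_p1) * stats.geom(config.enhancer_tail_p).pmf(d - 1)
    return np.where(d == 1, config.enhancer_p1 + 0.0 * tail, tail)


def _sample_promoter_degrees(n: int, config: SyntheticConfig, rng) -> np.ndarray:
    if config.promoter_degree_mean <= 1:
        # degenerate law: every promoter has exactly one partner
        return np.ones(n, dtype=np.int64)
    r = config.promoter_degree_dispersion
    p = r / (r + config.promoter_degree_mean)
    out = rng.negative_binomial(r, p, size=n)
    while (out == 0).any():  # zero truncation by resampling
        zeros = out == 0
        out[zeros] = rng.negative_binomial(r, p, size=int(zeros.sum()))
    return out.astype(np.int64)


def _sample_enhancer_degrees(n: int, config: SyntheticConfig, rng) -> np.ndarray:
    tail = rng.random(n) >= config.enhancer_p1
    out = np.ones(n, dtype=np.int64)
    out[tail] += rng.geometric(config.enhancer_tail_p, size=int(tail.sum()))
    return out


def _redraw_until_sum(
    sampler, n: int, target: int, rng, batch: int = 200, max_batches: int = 50
) -> np.ndarray | None:
    """Rejection-sample a degree vector of length ``n`` whose sum equals
    ``target`` by drawing whole vectors; exact conditioning on the sum,
    so every node's degree keeps the law's conditional distribution."""
    for _ in range(max_batches):
        draws = np.stack([sampler(n, rng) for _ in range(batch)])
        hits = np.flatnonzero(draws.sum(axis=1) == target)
        if hits.size:
            return draws[hits[0]]
    return None


def _reconcile_stub_totals(
    p_deg: np.ndarray, e_deg: np.ndarray, config: SyntheticConfig, rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize the promoter and enhancer stub totals.

    The side with fewer stubs is redrawn from its law conditioned (by
    rejection) on matching the other side's total, which preserves the
    degree law exactly.  If the two laws' expected totals are too far
    apart for rejection to land, the gap is closed by gap-shrinking
    single-node resamples and, as a last resort, unit increments; both
    fallbacks distort the smaller side's law and are logged.
    """
    sp, se = int(p_deg.sum()), int(e_deg.sum())
    if sp == se:
        return p_deg, e_deg
    p_sampler = lambda n, r: _sample_promoter_degrees(n, config, r)
    e_sampler = lambda n, r: _sample_enhancer_degrees(n, config, r)
    # redraw the side whose sum distribution is most likely to reach the
    # other side's total: fewer stubs is the tie-break, but a gap that
    # is many standard deviations away for one law may be easily within
    # reach of the other (promoter sums are usually the wider)
    sd_p = float(np.sqrt(max(p_deg.var() * p_deg.size, 1.0)))
    sd_e = float(np.sqrt(max(e_deg.var() * e_deg.size, 1.0)))
    gap = abs(sp - se)
    if abs(gap / sd_p - gap / sd_e) < 1.0:
        order = ("p", "e") if sp < se else ("e", "p")
    else:
        order = ("p", "e") if sd_p > sd_e else ("e", "p")
    for side in order:
        if side == "p":
            redrawn = _redraw_until_sum(p_sampler, p_deg.size, se, rng)
            if redrawn is not None:
                return redrawn, e_deg
        else:
            redrawn = _redraw_until_sum(e_sampler, e_deg.size, sp, rng)
            if redrawn is not None:
                return p_deg, redrawn
    logger.warning(
        "stub totals differ by %d and rejection sampling did not land; "
        "closing the gap greedily (the smaller side's law is distorted)",
        abs(sp - se),
    )
    for _ in range(10_000 + 100 * abs(sp - se)):
        if sp == se:
            return p_deg, e_deg
        if sp < se:
            i = int(rng.integers(p_deg.size))
            new = int(p_sampler(1, rng)[0])
            cand = sp - int(p_deg[i]) + new
            if abs(cand - se) < abs(sp - se):
                p_deg[i], sp = new, cand
        else:
            i = int(rng.integers(e_deg.size))
            new = int(e_sampler(1, rng)[0])
            cand = se - int(e_deg[i]) + new
            if abs(sp - cand) < abs(sp - se):
                e_deg[i], se = new, cand
    deficit, side = (se - sp, p_deg) if sp < se else (sp - se, e_deg)
    logger.warning("stub reconciliation fell back to %d unit increments", deficit)
    for i in rng.choice(side.size, size=deficit, replace=True):
        side[i] += 1
    return p_deg, e_deg


def _wire(
    p_deg: np.ndarray, e_deg: np.ndarray, rng, max_rounds: int = 1000
) -> list[tuple[int, int]]:
    """Configuration-model pairing of degree stubs; duplicate edges are
    broken up by random swaps, leftover duplicates dropped (logged)."""
    p_stubs = np.repeat(np.arange(p_deg.size), p_deg)
    e_stubs = rng.permutation(np.repeat(np.arange(e_deg.size), e_deg))
    m = p_stubs.size
    for _ in range(max_rounds):
        pairs = list(zip(p_stubs.tolist(), e_stubs.tolist()))
        seen: set = set()
        dup_pos = []
        for i, pr in enumerate(pairs):
            if pr in seen:
                dup_pos.append(i)
            else:
                seen.add(pr)
        if not dup_pos:
            return pairs
        for i in dup_pos:  # swap each conflicting endpoint with a random one
            j = int(rng.integers(m))
            e_stubs[i], e_stubs[j] = e_stubs[j], e_stubs[i]
    unique, dropped = [], 0
    seen = set()
    for pr in zip(p_stubs.tolist(), e_stubs.tolist()):
        if pr in seen:
            dropped += 1
        else:
            seen.add(pr)
            unique.append(pr)
    logger.warning("dropped %d irreducible duplicate edges", dropped)
    return unique


def generate_network(
    config: SyntheticConfig,
) -> tuple[InteractionNetwork, dict]:
    """Generate the bipartite network; returns it with the per-node
    target degrees (realized degrees can differ only if duplicate edges
    had to be dropped)."""
    rng_deg = _rng(config.seed, "degrees")
    p_deg = _sample_promoter_degrees(config.n_promoters, config, rng_deg)
    e_deg = _sample_enhancer_degrees(config.n_enhancers, config, rng_deg)
    p_deg, e_deg = _reconcile_stub_totals(p_deg, e_deg, config, rng_deg)
    pairs = _wire(p_deg, e_deg, _rng(config.seed, "wiring"))
    pid = [f"P{i:05d}" for i in range(config.n_promoters)]
    eid = [f"E{i:05d}" for i in range(config.n_enhancers)]
    edges = [(pid[p], eid[e]) for p, e in pairs]
    targets = {pid[i]: int(d) for i, d in enumerate(p_deg)}
    targets.update({eid[i]: int(d) for i, d in enumerate(e_deg)})
    return build_network(edges), targets


# ---------------------------------------------------------------------------
# sequences

def _transition_cum(g: float, depletion: float) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative transition rows (4x4) and initial distribution (4,) of
    the first-order chain with GC propensity ``g`` and the C->G
    transition damped by ``depletion``."""
    base = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    trans = np.tile(base, (4, 1))
    c_row = base.copy()
    c_row[2] *= depletion  # C -> G
    trans[1] = c_row / c_row.sum()
    return np.cumsum(trans, axis=1), np.cumsum(base)


def _markov_batch(
    gs: np.ndarray, depletions: np.ndarray, length: int, uniforms: np.ndarray
) -> np.ndarray:
    """Generate ``n`` chains of ``length`` states (0..3) in lockstep;
    row i uses GC propensity gs[i], depletion depletions[i] and the
    pre-drawn uniforms[i]."""
    n = gs.size
    cums = np.empty((n, 4, 4))
    inits = np.empty((n, 4))
    cache: dict = {}
    for i in range(n):
        key = (float(gs[i]), float(depletions[i]))
        if key not in cache:
            cache[key] = _transition_cum(*key)
        cums[i], inits[i] = cache[key]
    states = np.empty((n, length), dtype=np.int8)
    states[:, 0] = (uniforms[:, 0, None] > inits).sum(axis=1)
    rows = np.arange(n)
    for t in range(1, length):
        cum = cums[rows, states[:, t - 1]]
        states[:, t] = (uniforms[:, t, None] > cum).sum(axis=1)
    return states


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _states_to_str(states: np.ndarray) -> str:
    return _BASES[states].tobytes().decode("ascii")


def node_gc_propensity(node_type: str, degree: int, config: SyntheticConfig) -> float:
    """Target GC propensity of a node: base + slope * (degree - 1),
    clamped to [0.05, 0.95]."""
    base = (
        config.gc_base_promoter if node_type == "promoter"
        else config.gc_base_enhancer
    )
    g = base + config.gc_degree_slope * (degree - 1)
    return float(np.clip(g, *GC_CLAMP))


def generate_sequence(
    node_type: str, degree: int, config: SyntheticConfig, node_index: int = 0,
    length: int | None = None,
) -> str:
    """One synthetic sequence (length ``window`` unless overridden),
    deterministic given the config seed and ``node_index``."""
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    length = config.window if length is None else length
    depletion = (
        config.cpg_depletion_promoter if node_type == "promoter"
        else config.cpg_depletion_enhancer
    )
    g = node_gc_propensity(node_type, degree, config)
    rng = _rng(config.seed, "sequences", node_index)
    u = rng.random((1, length))
    states = _markov_batch(
        np.array([g]), np.array([depletion]), length, u
    )
    return _states_to_str(states[0])


# ---------------------------------------------------------------------------
# full dataset

@dataclass
class SyntheticDataset:
    """A complete synthetic input set plus ground truth."""

    config: SyntheticConfig
    records: list
    genome: Genome
    network: InteractionNetwork
    truth: pd.DataFrame  # node_id, node_type, degree, g

    def write(self, out_dir) -> dict:
        """Write interactions.tsv (generic_tsv), genome.fa and truth.tsv."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "interactions": out / "interactions.tsv",
            "genome": out / "genome.fa",
            "truth": out / "truth.tsv",
        }
        write_interaction_table(self.records, paths["interactions"])
        write_genome(self.genome, paths["genome"])
        write_tsv(self.truth, paths["truth"])
        return {k: str(v) for k, v in paths.items()}


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a network, per-node chromosomes and the truth table.

    Each node gets its own synthetic chromosome of ``window + 2 * pad``
    bases drawn from its Markov chain, with the promoter TSS (or
    enhancer fragment midpoint) at the chromosome center, so every
    standardized window is in bounds by construction.
    """
    config = config or SyntheticConfig()
    network, _targets = generate_network(config)
    chrom_len = config.window + 2 * config.pad
    center = chrom_len // 2

    node_ids = sorted(network.promoters) + sorted(network.enhancers)
    types = ["promoter"] * len(network.promoters) + ["enhancer"] * len(network.enhancers)
    degrees = np.array([network.degree[n] for n in node_ids])
    gs = np.array([
        node_gc_propensity(t, d, config) for t, d in zip(types, degrees)
    ])
    depletions = np.array([
        config.cpg_depletion_promoter if t == "promoter"
        else config.cpg_depletion_enhancer
        for t in types
    ])
    uniforms = np.empty((len(node_ids), chrom_len))
    for i in range(len(node_ids)):
        uniforms[i] = _rng(config.seed, "sequences", i).random(chrom_len)
    states = _markov_batch(gs, depletions, chrom_len, uniforms)
    genome = Genome(
        (node_ids[i], _states_to_str(states[i])) for i in range(len(node_ids))
    )

    half = ENHANCER_FRAGMENT_HALF
    records = []
    for p, e in network.edges:
        promoter = GenomicRegion(
            chrom=p, start=center, end=center + 1, strand="+",
            node_type="promoter", node_id=p,
        )
        enhancer = GenomicRegion(
            chrom=e, start=center - half, end=center + half,
            node_type="enhancer", node_id=e,
        )
        records.append(InteractionRecord(p, e, promoter, enhancer))

    truth = pd.DataFrame({
        "node_id": node_ids,
        "node_type": types,
        "degree": degrees,
        "g": gs,
    })
    return SyntheticDataset(
        config=config, records=records, genome=genome, network=network, truth=truth,
    )
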