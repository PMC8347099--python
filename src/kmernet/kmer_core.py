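"""k-mer, dinucleotide and GC-content counting on single-strand sequences.

All counting is on the + strand with overlapping windows and no
reverse-complement folding: AAAA and TTTT are distinct coordinates.
k-mers are indexed lexicographically over A<C<G<T, so index 0 is AA..A
and index 4^k - 1 is TT..T.  Windows containing a non-ACGT character
contribute to no k-mer (they are skipped entirely, not partially
matched).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"

#: byte-value lookup: A/C/G/T -> 0..3, anything else -> -1
_CODES = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i

# maximum supported k (vector length 4^8 = 65,536)
MAX_K = 8


def kmer_list(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order over A<C<G<T."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=k)]


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer string."""
    idx = 0
    for base in kmer:
        code = _CODES[ord(base)]
        if code < 0:
            raise ValueError(f"invalid base in k-mer {kmer!r}")
        idx = idx * 4 + code
    return idx


def count_kmers(sequence: str, k: int) -> np.ndarray:
    """Count overlapping k-mers on the + strand of ``sequence``.

    Returns an integer vector of length 4^k in lexicographic order.
    Windows containing a non-ACGT character are skipped.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > MAX_K:
        raise ValueError(f"k > {MAX_K} not supported")
    if k > len(sequence):
        raise ValueError(
            f"k={k} exceeds sequence length {len(sequence)}"
        )
    codes = _CODES[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    indices = windows[valid] @ powers
    return np.bincount(indices, minlength=4**k).astype(np.int64)


def cpg_kmer_set(k: int) -> set[str]:
    """All k-mers containing the CpG dinucleotide (C immediately
    followed by G, 5'->3').  Empty for k < 2."""
    if k < 2:
        return set()
    return {m for m in kmer_list(k) if "CG" in m}


@dataclass
class KmerVector:
    """Per-node k-mer count vector with node annotation."""

    node_id: str
    node_type: str
    degree: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("k-mer counts must be nonnegative")


@dataclass
class CompositionStats:
    """GC percentage and G/C-dinucleotide counts for one node."""

    node_id: str
    node_type: str
    degree: int
    gc_percent: float
    GG: int
    CC: int
    GC: int
    CG: int


def composition_stats(
    sequence: str, node_id: str = "", node_type: str = "", degree: int = 0
) -> CompositionStats | None:
    """GC% and overlapping GG/CC/GC/CG counts of a sequence.

    gc_percent = 100 * (#G + #C) / (#A + #C + #G + #T); ambiguous bases
    are excluded from the denominator.  Returns ``None`` (drop signal)
    for an all-N sequence, where GC% is undefined.
    """
    mono = count_kmers(sequence, 1)
    total = int(mono.sum())
    if total == 0:
        logger.warning("dropping node %r: no unambiguous bases", node_id)
        return None
    gc_percent = 100.0 * (mono[kmer_index("C")] + mono[kmer_index("G")]) / total
    di = count_kmers(sequence, 2) if len(sequence) >= 2 else np.zeros(16, dtype=np.int64)
    return CompositionStats(
        node_id=node_id, node_type=node_type, degree=degree,
        gc_percent=float(gc_percent),
        GG=int(di[kmer_index("GG")]), CC=int(di[kmer_index("CC")]),
        GC=int(di[kmer_index("GC")]), CG=int(di[kmer_index("CG")]),
    )


def mean_count_by_type(vectors: list[KmerVector], node_type: str) -> np.ndarray:
    """Unweighted per-k-mer mean count over all vectors of one node type."""
    counts = [v.counts for v in vectors if v.node_type == node_type]
    if not counts:
        raise ValueError(f"no k-mer vectors of type {node_type!r}")
    return np.mean(np.stack(counts), axis=0)


def rank_kmers(mean_promoter: np.ndarray, mean_enhancer: np.ndarray, by: str):
    """Rank k-mers by their mean count in one node type.

    Returns ``(table, head_run)`` where ``table`` is a pandas DataFrame
    with columns ``kmer, mean_promoter, mean_enhancer`` sorted in
    descending order of the chosen type's mean (ties broken
    lexicographically by k-mer), and ``head_run`` is the length of the
    maximal initial run of ranks where the chosen type's mean strictly
    exceeds the other type's (the "top 23 in promoters" / "top 6 in
    enhancers" construct).
    """
    import pandas as pd

    mean_promoter = np.asarray(mean_promoter, dtype=float)
    mean_enhancer = np.asarray(mean_enhancer, dtype=float)
    if mean_promoter.shape != mean_enhancer.shape:
        raise ValueError("mean vectors must have equal length")
    n = mean_promoter.size
    k = int(round(np.log(n) / np.log(4)))
    if 4**k != n:
        raise ValueError(f"vector length {n} is not a power of 4")
    if by not in ("promoter", "enhancer"):
        raise ValueError(f"by must be 'promoter' or 'enhancer', got {by!r}")
    table = pd.DataFrame({
        "kmer": kmer_list(k),
        "mean_promoter": mean_promoter,
        "mean_enhancer": mean_enhancer,
    })
    key = "mean_promoter" if by == "promoter" else "mean_enhancer"
    other = "mean_enhancer" if by == "promoter" else "mean_promoter"
    table = table.sort_values(
        [key, "kmer"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    head_run = 0
    for _, row in table.iterrows():
        if row[key] > row[other]:
            head_run += 1
        else:
            break
    return table, head_run
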