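"""Standardization of regulatory regions to fixed-width windows.

Promoters and enhancers come from interaction tables with heterogeneous
widths (restriction-fragment sized).  For k-mer count vectors to be
comparable between regions and between node types, every region is
standardized to the same window (default 1 kb) centered on an anchor:
the TSS for promoters, the fragment midpoint for enhancers.  Sequences
are always taken from the + strand of the genome; the promoter strand is
used only to locate the TSS, never to reverse-complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", "unknown")
NODE_TYPES = ("promoter", "enhancer")

DEFAULT_WINDOW = 1000


@dataclass(frozen=True)
class GenomicRegion:
    """A located, typed genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "unknown"
    node_type: str | None = None
    node_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"region end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.node_type is not None and self.node_type not in NODE_TYPES:
            raise ValueError(f"invalid node_type {self.node_type!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class StandardizedRegion:
    """A fixed-width region together with its + strand sequence."""

    region: GenomicRegion
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.region.width:
            raise ValueError("sequence length does not match region width")


def standardize(
    region: GenomicRegion, window: int = DEFAULT_WINDOW, anchor: int | None = None
) -> GenomicRegion:
    """Return ``region`` recentered to width exactly ``window``.

    The window is ``[anchor - window/2, anchor + window/2)``.  The anchor
    is, in order of precedence: the explicit ``anchor`` argument; for
    promoters the start of a width-1 region (a TSS point); for enhancers
    ``floor((start + end) / 2)``.  A region that already has the target
    width is returned unchanged (standardization is idempotent).
    """
    if window <= 0 or window % 2 != 0:
        raise ValueError(f"window must be a positive even integer, got {window}")
    if region.width == window:
        return region
    if anchor is None:
        if region.node_type == "promoter":
            if region.width != 1:
                raise ValueError(
                    f"promoter {region.node_id!r}: anchor (TSS) missing and region "
                    "is not a single TSS position"
                )
            anchor = region.start
        else:
            anchor = (region.start + region.end) // 2
    half = window // 2
    return replace(region, start=anchor - half, end=anchor + half)


def extract(genome, region: GenomicRegion) -> StandardizedRegion | None:
    """Extract the + strand sequence of a standardized region.

    Returns ``None`` (a drop signal) when the chromosome is absent from
    the genome or the window extends past the chromosome ends; dropping
    rather than clipping keeps all sequences the same length.
    """
    seq = genome.get(region.chrom)
    if seq is None:
        logger.warning(
            "dropping %s node %r: chromosome %r not in genome",
            region.node_type, region.node_id, region.chrom,
        )
        return None
    if region.start < 0 or region.end > len(seq):
        logger.warning(
            "dropping %s node %r: window [%d, %d) out of bounds for %s (length %d)",
            region.node_type, region.node_id, region.start, region.end,
            region.chrom, len(seq),
        )
        return None
    return StandardizedRegion(region, seq[region.start : region.end])


def extract_all(
    genome, regions: list[GenomicRegion]
) -> tuple[list[StandardizedRegion], int]:
    """Extract every region; return the retained list and the drop count."""
    kept: list[StandardizedRegion] = []
    dropped = 0
    for region in regions:
        std = extract(genome, region)
        if std is None:
            dropped += 1
        else:
            kept.append(std)
    if dropped:
        logger.warning("dropped %d of %d regions", dropped, len(regions))
    return kept, dropped
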