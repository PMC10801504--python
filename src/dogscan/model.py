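"""Core domain types shared by every pipeline stage.

All coordinates are 0-based half-open (the BED convention); GTF input is
converted at the parsing boundary. Strand is one of ``+``, ``-`` or ``.``
(unstranded); unstranded records behave like ``+`` for orientation-dependent
logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene: the anchor from which a DoG extension is called.

    ``tss`` / ``tes`` are derived from the interval and strand: for ``+``
    (and unstranded) genes the TSS is ``start`` and the TES (annotated 3'
    end, where a DoG begins) is ``end``; mirrored for ``-``.
    """

    gene_id: str
    interval: GenomicInterval

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.end if self.strand == "-" else self.interval.start

    @property
    def tes(self) -> int:
        return self.interval.start if self.strand == "-" else self.interval.end


@dataclass
class CoverageTrack:
    """Per-base read depth for one sample plus its mapped-library size.

    ``values`` maps chromosome name to a non-negative per-base depth array;
    positions beyond an array's extent (or on absent chromosomes) are depth
    zero. ``library_size`` is supplied externally (from the sample sheet),
    never inferred from coverage, because coverage files lose the
    unmapped/multi-mapped context of the alignment.
    """

    sample_id: str
    values: Dict[str, np.ndarray]
    library_size: int
    stranded: bool = False

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be a positive integer")
        for chrom, arr in self.values.items():
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")

    def chrom_length(self, chrom: str) -> int:
        arr = self.values.get(chrom)
        return 0 if arr is None else len(arr)

    def depth_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base depth over [start, end); out-of-extent bases are 0."""
        if end <= start:
            return 0.0
        arr = self.values.get(chrom)
        if arr is None:
            return 0.0
        lo = max(start, 0)
        hi = min(end, len(arr))
        if hi <= lo:
            return 0.0
        return float(arr[lo:hi].sum())


class PeakSet:
    """A sorted, queryable set of ChIP-seq peak intervals for one condition."""

    def __init__(self, peaks: Iterable[GenomicInterval], condition: str = ""):
        self.peaks: List[GenomicInterval] = sorted(
            peaks, key=lambda p: (p.chrom, p.start, p.end)
        )
        self.condition = condition
        self._trees: Dict[str, IntervalTree] = {}
        for p in self.peaks:
            self._trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.peaks)

    def overlapping(self, region: GenomicInterval) -> List[GenomicInterval]:
        """Peaks overlapping ``region`` by >= 1 bp, sorted by start."""
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(region.start, region.end)]
        return sorted(hits, key=lambda p: (p.start, p.end))

    def any_overlap(self, region: GenomicInterval) -> bool:
        tree = self._trees.get(region.chrom)
        return bool(tree is not None and tree.overlap(region.start, region.end))


@dataclass
class DoGParams:
    """Tunable parameters of the DoG caller and downstream layers.

    Defaults follow the discovery settings used throughout: minimum DoG
    length 4 kb, extension window 500 bp, minimum window FPKM 0.2; a +-500 bp
    promoter window for RNAP II peak evidence; |log2FC| >= 1.2 for the
    up/down classification and p <= 0.05 for significance.
    """

    min_length_bp: int = 4000
    window_bp: int = 500
    min_fpkm: float = 0.2
    promoter_window_bp: int = 500
    fc_threshold: float = 1.2
    p_threshold: float = 0.05
    max_gap_windows: int = 0

    def __post_init__(self) -> None:
        if not (self.min_length_bp >= self.window_bp > 0):
            raise ValueError("require min_length_bp >= window_bp > 0")
        if self.min_fpkm < 0:
            raise ValueError("min_fpkm must be >= 0")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be > 0")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must lie in (0, 1]")
        if self.max_gap_windows < 0:
            raise ValueError("max_gap_windows must be >= 0")
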