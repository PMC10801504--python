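"""Windowed DoG discovery.

A DoG (downstream-of-gene transcript) is called by walking consecutive
windows (default 500 bp) downstream of a gene's annotated 3' end and
extending while each window's FPKM stays at or above a floor (default 0.2).
Extension also stops at the TSS-side boundary of the nearest downstream
gene, so a call can run across the body of an antisense neighbour (whose TSS
faces away) but never across a promoter firing into the readthrough path.
A call is emitted only when the extension reaches the minimum DoG length
(default 4 kb, inclusive).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .model import CoverageTrack, DoGParams, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoGRecord:
    """A called readthrough region, anchored at its parent gene's TES."""

    gene_id: str
    region: GenomicInterval
    mean_fpkm: float
    sample_id: str = ""

    @property
    def length_bp(self) -> int:
        return self.region.length()


def fpkm(read_count: float, region_length_bp: int, library_size: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_length_bp <= 0:
        raise ValueError("region_length_bp must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    return read_count / ((region_length_bp / 1e3) * (library_size / 1e6))


def window_reads(track: CoverageTrack, window: GenomicInterval, read_length_bp: int) -> float:
    """Estimated read count over a window: sum of per-base depth / read length.

    Windows beyond the chromosome extent contribute zero depth.
    """
    if read_length_bp <= 0:
        raise ValueError("read_length_bp must be > 0")
    return track.depth_sum(window.chrom, window.start, window.end) / read_length_bp


def _tss_side_boundary(gene: GeneModel) -> int:
    """The coordinate of a gene's TSS-facing interval boundary."""
    return gene.interval.end if gene.strand == "-" else gene.interval.start


def _downstream_limit(
    gene: GeneModel, neighbors: Iterable[GeneModel], stranded: bool
) -> Optional[int]:
    """Nearest blocking coordinate downstream of ``gene``'s TES, or None.

    In unstranded mode any gene's TSS-side boundary blocks; in stranded mode
    only same-strand genes do.
    """
    plus = gene.strand != "-"
    tes = gene.tes
    limit: Optional[int] = None
    for g in neighbors:
        if g.gene_id == gene.gene_id or g.interval.chrom != gene.interval.chrom:
            continue
        if stranded and g.strand != gene.strand:
            continue
        b = _tss_side_boundary(g)
        if plus:
            if b > tes and (limit is None or b < limit):
                limit = b
        else:
            if b < tes and (limit is None or b > limit):
                limit = b
    return limit


def _extend(
    gene: GeneModel,
    track: CoverageTrack,
    limit: Optional[int],
    params: DoGParams,
    read_length_bp: int,
) -> int:
    """Walk windows downstream of the TES; return the far coordinate reached.

    The last passing window is included in full; a partial window clipped at
    the blocking boundary is evaluated at its clipped length. A run of more
    than ``max_gap_windows`` consecutive sub-threshold windows ends the scan
    at the last passing window.
    """
    plus = gene.strand != "-"
    tes = gene.tes
    w = params.window_bp
    chrom = gene.interval.chrom
    chrom_len = track.chrom_length(chrom)
    far = tes
    pos = tes
    gaps = 0
    while True:
        if plus:
            ws, we = pos, pos + w
            if limit is not None:
                we = min(we, limit)
            if we <= ws:
                break
            if ws >= chrom_len:
                break  # beyond coverage extent: depth identically zero
        else:
            ws, we = max(pos - w, 0), pos
            if limit is not None:
                ws = max(ws, limit)
            if we <= ws:
                break
            if we <= 0:
                break
        reads = track.depth_sum(chrom, ws, we) / read_length_bp
        if fpkm(reads, we - ws, track.library_size) >= params.min_fpkm:
            far = we if plus else ws
            gaps = 0
        else:
            gaps += 1
            if gaps > params.max_gap_windows:
                break
        pos = we if plus else ws
        if limit is not None and pos == limit:
            break
    return far


def call_dog(
    gene: GeneModel,
    track: CoverageTrack,
    neighbors: Iterable[GeneModel],
    params: DoGParams,
    read_length_bp: int = 50,
    sample_id: Optional[str] = None,
    _limit: Optional[int] = ...,
) -> Optional[DoGRecord]:
    """Call the DoG of one gene against one coverage track, or return None.

    ``neighbors`` supplies the genes that can block extension (any annotation
    subset containing the genes downstream of ``gene``). The emitted region
    always starts exactly at the parent TES and never overlaps the parent
    body.
    """
    limit = _downstream_limit(gene, neighbors, track.stranded) if _limit is ... else _limit
    plus = gene.strand != "-"
    tes = gene.tes
    if not plus and tes <= 0:
        logger.info("gene %s has no downstream space; skipped", gene.gene_id)
        return None
    far = _extend(gene, track, limit, params, read_length_bp)
    length = (far - tes) if plus else (tes - far)
    if length < params.min_length_bp:
        return None
    region = GenomicInterval(
        gene.interval.chrom, tes if plus else far, far if plus else tes, gene.strand
    )
    reads = track.depth_sum(region.chrom, region.start, region.end) / read_length_bp
    mean = fpkm(reads, region.length(), track.library_size)
    return DoGRecord(
        gene_id=gene.gene_id,
        region=region,
        mean_fpkm=mean,
        sample_id=sample_id if sample_id is not None else track.sample_id,
    )


class _BoundaryIndex:
    """Per-chromosome sorted TSS-side boundaries for O(log n) limit lookup."""

    def __init__(self, genes: Sequence[GeneModel], stranded: bool):
        self.stranded = stranded
        self._by_chrom: Dict[Tuple[str, str], List[Tuple[int, str]]] = {}
        for g in genes:
            key_strands = [g.strand] if stranded else ["*"]
            for ks in key_strands:
                self._by_chrom.setdefault((g.interval.chrom, ks), []).append(
                    (_tss_side_boundary(g), g.gene_id)
                )
        for v in self._by_chrom.values():
            v.sort()

    def limit_for(self, gene: GeneModel) -> Optional[int]:
        key = (gene.interval.chrom, gene.strand if self.stranded else "*")
        entries = self._by_chrom.get(key, [])
        bounds = [b for b, _ in entries]
        tes = gene.tes
        if gene.strand != "-":
            i = bisect.bisect_right(bounds, tes)
            while i < len(entries):
                if entries[i][1] != gene.gene_id:
                    return entries[i][0]
                i += 1
            return None
        i = bisect.bisect_left(bounds, tes) - 1
        while i >= 0:
            if entries[i][1] != gene.gene_id:
                return entries[i][0]
            i -= 1
        return None


def gene_body_fpkm(gene: GeneModel, track: CoverageTrack, read_length_bp: int = 50) -> float:
    reads = track.depth_sum(gene.interval.chrom, gene.interval.start, gene.interval.end) / read_length_bp
    return fpkm(reads, gene.interval.length(), track.library_size)


def call_dogs_all(
    annotation: Sequence[GeneModel],
    track: CoverageTrack,
    params: DoGParams,
    expressed_only: bool = False,
    read_length_bp: int = 50,
    sample_id: Optional[str] = None,
) -> List[DoGRecord]:
    """Call DoGs for every (optionally expressed) gene in an annotation.

    At most one DoGRecord per gene; output deterministic and sorted by
    (chrom, region start, gene_id).
    """
    index = _BoundaryIndex(annotation, track.stranded)
    dogs: List[DoGRecord] = []
    for gene in annotation:
        if expressed_only and gene_body_fpkm(gene, track, read_length_bp) < params.min_fpkm:
            continue
        rec = call_dog(
            gene,
            track,
            (),
            params,
            read_length_bp=read_length_bp,
            sample_id=sample_id,
            _limit=index.limit_for(gene),
        )
        if rec is not None:
            dogs.append(rec)
    dogs.sort(key=lambda d: (d.region.chrom, d.region.start, d.gene_id))
    return dogs


def merge_replicates(dog_sets: Sequence[Sequence[DoGRecord]], label: str = "merged") -> List[DoGRecord]:
    """Union DoG sets by gene_id, keeping the farthest downstream extent.

    The merged region spans from the parent TES to the farthest end seen in
    any replicate; mean_fpkm reported is the maximum across the merged calls
    (coverage is no longer available to recompute it over the union span).
    """
    by_gene: Dict[str, DoGRecord] = {}
    for dogs in dog_sets:
        for d in dogs:
            prev = by_gene.get(d.gene_id)
            if prev is None:
                by_gene[d.gene_id] = replace(d, sample_id=label)
                continue
            if prev.region.strand != d.region.strand or prev.region.chrom != d.region.chrom:
                raise ValueError(
                    f"conflicting parent placement for gene {d.gene_id} during merge"
                )
            if d.region.strand != "-":
                start = prev.region.start  # TES anchor, identical across replicates
                end = max(prev.region.end, d.region.end)
            else:
                start = min(prev.region.start, d.region.start)
                end = prev.region.end
            region = GenomicInterval(prev.region.chrom, start, end, prev.region.strand)
            by_gene[d.gene_id] = DoGRecord(
                gene_id=d.gene_id,
                region=region,
                mean_fpkm=max(prev.mean_fpkm, d.mean_fpkm),
                sample_id=label,
            )
    out = list(by_gene.values())
    out.sort(key=lambda d: (d.region.chrom, d.region.start, d.gene_id))
    return out
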