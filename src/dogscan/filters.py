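"""RNAP II ChIP-seq validation filters for DoG calls.

Non-stranded RNA-seq cannot tell a genuine readthrough from independent
transcription of a downstream gene. Two orthogonal filters use RNAP II
ChIP-seq peaks to resolve this:

* downstream-interference filter — a DoG whose region both covers another
  gene and contains an RNAP II peak is treated as likely transcription of
  that downstream gene and discarded;
* promoter-peak filter — a DoG is kept only if its parent gene carries an
  RNAP II peak near its TSS (promoter-proximal pausing leaves a peak at
  active promoters), evidence the parent was transcribed at all.

Both filters are contractive, idempotent and order-independent.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .discovery import DoGRecord
from .model import GeneModel, GenomicInterval, PeakSet

logger = logging.getLogger(__name__)


def _gene_overlapping_dog(dog: DoGRecord, annotation: Sequence[GeneModel]) -> Optional[GeneModel]:
    for g in annotation:
        if g.gene_id != dog.gene_id and g.interval.overlaps(dog.region):
            return g
    return None


def filter_downstream_interference(
    dogs: Sequence[DoGRecord],
    peaks: PeakSet,
    annotation: Sequence[GeneModel],
    peak_only: bool = False,
    audit: Optional[List[Dict]] = None,
) -> List[DoGRecord]:
    """Discard DoGs that look like transcription of a covered downstream gene.

    A DoG is removed iff its region overlaps (>= 1 bp) a gene other than its
    parent AND at least one peak lies (>= 1 bp) inside the DoG region. With
    ``peak_only=True`` the stricter reading applies: any interior peak
    removes the DoG regardless of gene overlap. Survivors are returned
    unchanged, in input order.
    """
    kept: List[DoGRecord] = []
    for dog in dogs:
        interior = peaks.overlapping(dog.region)
        covered = _gene_overlapping_dog(dog, annotation) if interior else None
        discard = bool(interior) if peak_only else bool(interior and covered)
        if discard:
            if audit is not None:
                audit.append(
                    {
                        "gene_id": dog.gene_id,
                        "filter": "downstream_interference",
                        "covered_gene": covered.gene_id if covered else "",
                        "peak": f"{interior[0].chrom}:{interior[0].start}-{interior[0].end}",
                    }
                )
            continue
        kept.append(dog)
    return kept


def promoter_interval(gene: GeneModel, promoter_window_bp: int) -> GenomicInterval:
    """The half-open window [tss - w, tss + w) around a gene's TSS."""
    start = max(gene.tss - promoter_window_bp, 0)
    return GenomicInterval(gene.interval.chrom, start, gene.tss + promoter_window_bp, gene.strand)


def filter_promoter_peak(
    dogs: Sequence[DoGRecord],
    peaks: PeakSet,
    annotation: Sequence[GeneModel],
    promoter_window_bp: int = 500,
    audit: Optional[List[Dict]] = None,
) -> List[DoGRecord]:
    """Keep only DoGs whose parent gene has an RNAP II peak at its promoter.

    The promoter is the window of +-``promoter_window_bp`` around the parent
    TSS. An empty PeakSet therefore discards everything (with a warning):
    no promoter evidence exists for any gene.
    """
    if promoter_window_bp <= 0:
        raise ValueError("promoter_window_bp must be > 0")
    if len(peaks) == 0 and dogs:
        logger.warning("empty peak set: promoter-peak filter will discard all %d DoGs", len(dogs))
    genes = {g.gene_id: g for g in annotation}
    kept: List[DoGRecord] = []
    for dog in dogs:
        parent = genes.get(dog.gene_id)
        if parent is None:
            raise KeyError(f"DoG parent gene {dog.gene_id} absent from annotation")
        if peaks.any_overlap(promoter_interval(parent, promoter_window_bp)):
            kept.append(dog)
        elif audit is not None:
            audit.append(
                {
                    "gene_id": dog.gene_id,
                    "filter": "promoter_peak",
                    "covered_gene": "",
                    "peak": "",
                }
            )
    return kept


def apply_filters(
    dogs: Sequence[DoGRecord],
    peaks: PeakSet,
    annotation: Sequence[GeneModel],
    promoter_window_bp: int = 500,
    peak_only: bool = False,
    audit: Optional[List[Dict]] = None,
) -> List[DoGRecord]:
    """Both ChIP-seq filters in sequence (the order does not affect the result)."""
    step1 = filter_downstream_interference(dogs, peaks, annotation, peak_only=peak_only, audit=audit)
    return filter_promoter_peak(step1, peaks, annotation, promoter_window_bp, audit=audit)
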