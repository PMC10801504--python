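"""DoG set algebra across conditions and cell lines, length distributions,
and the gene-body vs DoG expression correlation/classification layer.

Set identity is by parent gene_id (Ensembl-style), never by interval: two
conditions "share" a DoG when the same gene reads through in both, however
far each extension runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .discovery import DoGRecord
from .diffexp import DiffResult
from .model import DoGParams


def _gene_ids(dogs: Iterable) -> Set[str]:
    out = set()
    for d in dogs:
        out.add(d.gene_id if isinstance(d, DoGRecord) else str(d))
    return out


def common_dogs(a: Iterable, b: Iterable) -> Set[str]:
    """Gene IDs producing a DoG in both sets (symmetric intersection)."""
    return _gene_ids(a) & _gene_ids(b)


def exclusive_dogs(treated: Iterable, control: Iterable) -> Set[str]:
    """Gene IDs producing a DoG in ``treated`` but not in ``control``."""
    return _gene_ids(treated) - _gene_ids(control)


def union_dogs(a: Iterable, b: Iterable) -> Set[str]:
    return _gene_ids(a) | _gene_ids(b)


@dataclass
class GeneListOverlap:
    overlap: Set[str]  # shared gene symbols
    n_dogs: int
    n_external: int
    n_overlap: int
    n_unmapped: int
    unmapped: Set[str]


def overlap_with_gene_list(
    dogs: Iterable,
    external: Iterable[str],
    id_map: Mapping[str, str],
) -> GeneListOverlap:
    """Overlap DoG-producing genes with an external symbol list (e.g. the
    osmotic-stress readthrough genes), mapping Ensembl IDs to symbols first.

    IDs absent from ``id_map`` are excluded from the overlap and counted.
    """
    dog_ids = _gene_ids(dogs)
    ext = {str(s) for s in external}
    if dog_ids and ext and not id_map:
        raise ValueError("empty id_map with nonempty inputs")
    unmapped = {g for g in dog_ids if g not in id_map}
    symbols = {id_map[g] for g in dog_ids if g in id_map}
    shared = symbols & ext
    return GeneListOverlap(
        overlap=shared,
        n_dogs=len(dog_ids),
        n_external=len(ext),
        n_overlap=len(shared),
        n_unmapped=len(unmapped),
        unmapped=unmapped,
    )


def length_histogram(dogs: Sequence[DoGRecord], bin_edges_bp: Sequence[int]) -> np.ndarray:
    """Counts of DoG lengths in half-open bins [edge_i, edge_{i+1})."""
    edges = np.asarray(bin_edges_bp)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing, >= 2 of them")
    lengths = np.array([d.length_bp for d in dogs], dtype=float)
    if lengths.size and lengths.min() < edges[0]:
        raise AssertionError("DoG shorter than the first bin edge; caller invariant violated")
    counts = np.zeros(len(edges) - 1, dtype=int)
    if lengths.size:
        idx = np.searchsorted(edges, lengths, side="right") - 1
        for i in idx[(idx >= 0) & (idx < len(counts))]:
            counts[i] += 1
    return counts


class ExpressionClass(str, Enum):
    """Gene-body response class at a |log2FC| threshold (inclusive bounds)."""

    UPREGULATED = "Upregulated"
    DOWNREGULATED = "Downregulated"
    NO_CHANGE = "NoChange"


def classify_expression(log2fc: float, fc_threshold: float = 1.2) -> ExpressionClass:
    if log2fc >= fc_threshold:
        return ExpressionClass.UPREGULATED
    if log2fc <= -fc_threshold:
        return ExpressionClass.DOWNREGULATED
    return ExpressionClass.NO_CHANGE


@dataclass
class CorrelationResult:
    table: pd.DataFrame  # gene_id, gene_log2fc, dog_log2fc, gene_p, dog_p, expression_class
    pearson_r: float
    p_value: float
    n_pairs: int
    class_percentages: Dict[str, float]  # rounded to 1 decimal


def gene_dog_correlation(
    gene_results: Sequence[DiffResult],
    dog_results: Sequence[DiffResult],
    params: Optional[DoGParams] = None,
) -> CorrelationResult:
    """Correlate gene-body and DoG fold changes over genes significant in both.

    Pairs are restricted to p <= p_threshold in both the gene body and the
    DoG region, matching by gene_id. Pearson's r is the product-moment
    coefficient with its two-sided t-distributed p-value; each paired gene
    is classified on its gene-body log2FC and class percentages are reported
    to one decimal.
    """
    params = params or DoGParams()
    genes = {r.region_id: r for r in gene_results}
    rows = []
    for dr in dog_results:
        gr = genes.get(dr.region_id)
        if gr is None:
            continue
        if gr.p_value <= params.p_threshold and dr.p_value <= params.p_threshold:
            rows.append(
                {
                    "gene_id": dr.region_id,
                    "gene_log2fc": gr.log2fc,
                    "dog_log2fc": dr.log2fc,
                    "gene_p": gr.p_value,
                    "dog_p": dr.p_value,
                    "expression_class": classify_expression(gr.log2fc, params.fc_threshold).value,
                }
            )
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} significant gene/DoG pairs; need >= 3 for Pearson r")
    table = pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
    r, p = stats.pearsonr(table["gene_log2fc"], table["dog_log2fc"])
    pcts = {
        cls.value: round(
            100.0 * (table["expression_class"] == cls.value).sum() / len(table), 1
        )
        for cls in ExpressionClass
    }
    return CorrelationResult(
        table=table,
        pearson_r=float(r),
        p_value=float(p),
        n_pairs=len(table),
        class_percentages=pcts,
    )
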