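"""End-to-end orchestration: discover -> filter -> merge -> diff ->
correlate -> compare, with a manifest recording parameters and input
checksums so reruns are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io
from .compare import common_dogs, exclusive_dogs, gene_dog_correlation, length_histogram, union_dogs
from .diffexp import Region, count_regions, diff_test, results_table
from .discovery import DoGRecord, call_dogs_all, merge_replicates
from .filters import apply_filters
from .model import DoGParams, GeneModel

logger = logging.getLogger(__name__)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def params_from_dict(d: Optional[Dict]) -> DoGParams:
    d = dict(d or {})
    allowed = set(DoGParams.__dataclass_fields__)
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return DoGParams(**d)


def run_all(config: Dict, out_dir) -> Path:
    """Run the whole analysis graph from a flat config mapping.

    Required config keys: ``annotation`` (GTF), ``samples`` (TSV sheet),
    ``control`` and ``treated`` condition labels. Optional: ``peaks``
    (mapping condition -> BED; the ChIP-seq filter stage is skipped when
    absent, with a notice in the manifest), ``params`` (DoGParams fields),
    ``expressed_only``, ``stranded``, ``base_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fail_marker = out / "FAILED"
    if fail_marker.exists():
        fail_marker.unlink()
    try:
        result = _run_all_inner(config, out)
    except Exception as exc:
        fail_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    return result


def _run_all_inner(config: Dict, out: Path) -> Path:
    for key in ("annotation", "samples", "control", "treated"):
        if key not in config:
            raise ValueError(f"config missing required key {key!r}")
    base = Path(config.get("base_dir", "."))

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    annotation_path = resolve(config["annotation"])
    samples_path = resolve(config["samples"])
    peaks_cfg = config.get("peaks") or {}
    for p in [annotation_path, samples_path] + [resolve(v) for v in peaks_cfg.values()]:
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")

    params = params_from_dict(config.get("params"))
    stranded = bool(config.get("stranded", False))
    expressed_only = bool(config.get("expressed_only", False))
    control = str(config["control"])
    treated = str(config["treated"])

    genes = io.read_annotation(annotation_path)
    sheet = io.read_sample_sheet(samples_path)
    for cond in (control, treated):
        if cond not in set(sheet["condition"]):
            raise ValueError(f"condition {cond!r} absent from sample sheet")
    tracks = io.load_tracks(sheet, base_dir=samples_path.parent, stranded=stranded)
    by_sample = dict(zip(sheet["sample_id"], tracks))

    (out / "dogs").mkdir(exist_ok=True)
    (out / "filtered").mkdir(exist_ok=True)
    (out / "diff").mkdir(exist_ok=True)
    (out / "compare").mkdir(exist_ok=True)

    # 1) per-sample discovery
    per_sample: Dict[str, List[DoGRecord]] = {}
    for _, row in sheet.iterrows():
        sid = row["sample_id"]
        dogs = call_dogs_all(
            genes,
            by_sample[sid],
            params,
            expressed_only=expressed_only,
            read_length_bp=int(row["read_length"]),
        )
        per_sample[sid] = dogs
        io.write_dogs_tsv(dogs, out / "dogs" / f"{sid}.tsv")
        io.write_dogs_bed(dogs, out / "dogs" / f"{sid}.bed")
        logger.info("stage=get-dogs sample=%s n_dogs=%d", sid, len(dogs))

    # 2) replicate union per condition
    merged: Dict[str, List[DoGRecord]] = {}
    for cond in (control, treated):
        sids = sheet.loc[sheet["condition"] == cond, "sample_id"]
        merged[cond] = merge_replicates([per_sample[s] for s in sids], label=cond)
        io.write_dogs_tsv(merged[cond], out / "dogs" / f"{cond}.merged.tsv")
        io.write_dogs_bed(merged[cond], out / "dogs" / f"{cond}.merged.bed")

    # 3) ChIP-seq filters (optional)
    filter_notice = None
    filtered: Dict[str, List[DoGRecord]] = {}
    if peaks_cfg:
        for cond in (control, treated):
            if cond not in peaks_cfg:
                raise ValueError(f"peaks config missing condition {cond!r}")
            ps = io.read_peaks(resolve(peaks_cfg[cond]), condition=cond)
            audit: List[Dict] = []
            filtered[cond] = apply_filters(
                merged[cond], ps, genes, promoter_window_bp=params.promoter_window_bp, audit=audit
            )
            io.write_dogs_tsv(filtered[cond], out / "filtered" / f"{cond}.tsv")
            io.write_dogs_bed(filtered[cond], out / "filtered" / f"{cond}.bed")
            pd.DataFrame(audit, columns=["gene_id", "filter", "covered_gene", "peak"]).to_csv(
                out / "filtered" / f"{cond}.audit.tsv", sep="\t", index=False
            )
            logger.info(
                "stage=filter condition=%s in=%d out=%d removed=%d",
                cond, len(merged[cond]), len(filtered[cond]), len(audit),
            )
    else:
        filter_notice = "no peaks supplied; ChIP-seq filter stage skipped"
        logger.info("stage=filter skipped (no peaks)")
        filtered = merged

    # 4) differential expression over the union of condition DoG sets
    union = merge_replicates([filtered[control], filtered[treated]], label="union")
    gene_by_id = {g.gene_id: g for g in genes}
    dog_regions = [Region(d.gene_id, d.region, "dog") for d in union]
    body_regions = [
        Region(d.gene_id, gene_by_id[d.gene_id].interval, "gene_body")
        for d in union
        if d.gene_id in gene_by_id
    ]
    read_length = int(sheet["read_length"].iloc[0])
    dog_results = []
    gene_results = []
    if union:
        sub = sheet[sheet["condition"].isin([control, treated])].reset_index(drop=True)
        sub_tracks = [by_sample[s] for s in sub["sample_id"]]
        dog_matrix = count_regions(dog_regions, sub_tracks, sub, read_length)
        gene_matrix = count_regions(body_regions, sub_tracks, sub, read_length)
        dog_results = diff_test(dog_matrix, control, treated)
        gene_results = diff_test(gene_matrix, control, treated)
        results_table(dog_results).to_csv(out / "diff" / "dogs.tsv", sep="\t", index=False)
        results_table(gene_results).to_csv(out / "diff" / "genes.tsv", sep="\t", index=False)

    # 5) correlation of gene-body vs DoG fold changes
    correlation_summary: Dict = {}
    try:
        corr = gene_dog_correlation(gene_results, dog_results, params)
        corr.table.to_csv(out / "compare" / "correlation.tsv", sep="\t", index=False)
        correlation_summary = {
            "pearson_r": corr.pearson_r,
            "p_value": corr.p_value,
            "n_pairs": corr.n_pairs,
            "class_percentages": corr.class_percentages,
        }
    except ValueError as exc:
        correlation_summary = {"error": str(exc)}
        logger.warning("stage=correlate skipped: %s", exc)

    # 6) cross-condition set comparison + length histogram
    shared = common_dogs(filtered[treated], filtered[control])
    excl = exclusive_dogs(filtered[treated], filtered[control])
    both = union_dogs(filtered[treated], filtered[control])
    lengths = [d.length_bp for d in union]
    max_len = max(lengths) if lengths else params.min_length_bp + 1000
    edges = list(range(params.min_length_bp, max_len + 1001, 1000))
    hist = length_histogram(union, edges)
    pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": hist}
    ).to_csv(out / "compare" / "length_histogram.tsv", sep="\t", index=False)
    membership = pd.DataFrame(
        {
            "gene_id": sorted(both),
            "in_treated": [g in {d.gene_id for d in filtered[treated]} for g in sorted(both)],
            "in_control": [g in {d.gene_id for d in filtered[control]} for g in sorted(both)],
        }
    )
    membership.to_csv(out / "compare" / "membership.tsv", sep="\t", index=False)

    report = pd.DataFrame(
        [
            {"metric": f"n_dogs_{control}", "value": len(filtered[control])},
            {"metric": f"n_dogs_{treated}", "value": len(filtered[treated])},
            {"metric": "n_shared", "value": len(shared)},
            {"metric": f"n_exclusive_{treated}", "value": len(excl)},
            {"metric": "n_union", "value": len(both)},
        ]
    )
    report.to_csv(out / "report.tsv", sep="\t", index=False)

    manifest = {
        "params": asdict(params),
        "control": control,
        "treated": treated,
        "expressed_only": expressed_only,
        "stranded": stranded,
        "inputs": {
            "annotation": {"path": str(annotation_path), "sha256": _sha256(annotation_path)},
            "samples": {"path": str(samples_path), "sha256": _sha256(samples_path)},
            "peaks": {
                cond: {"path": str(resolve(p)), "sha256": _sha256(resolve(p))}
                for cond, p in peaks_cfg.items()
            },
        },
        "notices": [n for n in [filter_notice] if n],
        "correlation": correlation_summary,
        "counts": {row["metric"]: int(row["value"]) for _, row in report.iterrows()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
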