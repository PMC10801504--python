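"""File ingestion and emission: GTF annotation, bedGraph coverage, BED peaks,
sample sheets and DoG tables.

Conventions: GTF is 1-based inclusive and converted to 0-based half-open on
read; bedGraph and BED are natively 0-based half-open and preserved as-is.
Chromosome names are never harmonized silently ("chr1" != "1"); an explicit
alias mapping may be supplied instead.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import CoverageTrack, GeneModel, GenomicInterval, PeakSet

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = ("sample_id", "condition", "replicate", "coverage_path", "library_size")


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


def _apply_alias(chrom: str, alias: Optional[Mapping[str, str]]) -> str:
    if alias:
        return alias.get(chrom, chrom)
    return chrom


def read_annotation(
    path,
    dialect: str = "gene_id",
    chrom_alias: Optional[Mapping[str, str]] = None,
) -> List[GeneModel]:
    """Load gene models from a GTF file (Ensembl-style attributes).

    Each gene's span is the union of all records carrying its ``gene_id``
    (gene-level spans, not per-transcript). 1-based inclusive GTF coordinates
    become 0-based half-open. A gene_id appearing with conflicting strands is
    rejected with a warning rather than silently merged.

    Returns the genes sorted by (chrom, start).
    """
    attr_re = re.compile(dialect + r'\s+"([^"]+)"')
    spans: Dict[str, List] = {}
    dropped: set = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 tab-separated fields")
            chrom, _, _, start_s, end_s, _, strand, _, attrs = fields[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}: line {lineno}: invalid coordinate range")
            m = attr_re.search(attrs)
            if m is None:
                raise ParseError(f"{path}: line {lineno}: missing {dialect} attribute")
            gid = m.group(1)
            chrom = _apply_alias(chrom, chrom_alias)
            if strand not in ("+", "-"):
                strand = "."
            start0, end0 = start1 - 1, end1  # to 0-based half-open
            rec = spans.get(gid)
            if rec is None:
                spans[gid] = [chrom, start0, end0, strand]
            else:
                if rec[0] != chrom or (rec[3] != strand and "." not in (rec[3], strand)):
                    dropped.add(gid)
                    continue
                rec[1] = min(rec[1], start0)
                rec[2] = max(rec[2], end0)
    if n_lines == 0:
        logger.warning("annotation %s contains no records", path)
    for gid in dropped:
        logger.warning("gene %s has records on conflicting strands/chromosomes; dropped", gid)
        spans.pop(gid, None)
    genes = [
        GeneModel(gid, GenomicInterval(c, s, e, st)) for gid, (c, s, e, st) in spans.items()
    ]
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes


def read_coverage(
    path,
    library_size: int,
    sample_id: Optional[str] = None,
    stranded: bool = False,
    chrom_alias: Optional[Mapping[str, str]] = None,
) -> CoverageTrack:
    """Load a bedGraph file into a per-base depth track.

    Intervals must be non-overlapping within a chromosome; bases not covered
    by any record have depth 0.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    name = sample_id if sample_id is not None else Path(path).stem
    rows: List = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            chrom = _apply_alias(parts[0], chrom_alias)
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric field") from None
            if start < 0 or end <= start:
                raise ParseError(f"{path}: line {lineno}: require 0 <= start < end")
            if value < 0:
                raise ParseError(f"{path}: line {lineno}: negative coverage value")
            rows.append((chrom, start, end, value, lineno))
    values: Dict[str, np.ndarray] = {}
    if rows:
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "lineno"])
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values(["start", "end"])
            ends = sub["end"].to_numpy()
            starts = sub["start"].to_numpy()
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if bad.size:
                i = bad[0]
                l1 = int(sub["lineno"].iloc[i])
                l2 = int(sub["lineno"].iloc[i + 1])
                raise ParseError(
                    f"{path}: overlapping intervals on {chrom} (lines {l1} and {l2})"
                )
            arr = np.zeros(int(ends.max()), dtype=np.float64)
            for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
                arr[s:e] = v
            values[chrom] = arr
    return CoverageTrack(name, values, int(library_size), stranded=stranded)


def read_peaks(
    path, condition: str = "", chrom_alias: Optional[Mapping[str, str]] = None
) -> PeakSet:
    """Load a BED3+ peak file; coordinates kept 0-based half-open, output sorted.

    Peaks on chromosomes absent from the annotation are retained: peaks need
    no annotation match.
    """
    peaks: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(_apply_alias(parts[0], chrom_alias), start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            peaks.append(iv)
    return PeakSet(peaks, condition=condition)


def write_peaks_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def read_sample_sheet(path) -> pd.DataFrame:
    """Load the TSV sample sheet; columns sample_id, condition, replicate,
    coverage_path, library_size (+ optional read_length, default 50)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "condition": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    if "read_length" not in df.columns:
        df["read_length"] = 50
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id in sample sheet")
    if (df["library_size"] <= 0).any():
        raise ParseError(f"{path}: library_size must be positive")
    return df


def load_tracks(sheet: pd.DataFrame, base_dir=None, stranded: bool = False) -> List[CoverageTrack]:
    """Load one CoverageTrack per sample-sheet row, resolving relative paths."""
    tracks = []
    for _, row in sheet.iterrows():
        p = Path(row["coverage_path"])
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        tracks.append(
            read_coverage(p, int(row["library_size"]), sample_id=row["sample_id"], stranded=stranded)
        )
    return tracks


# --- DoG table emission / ingestion -------------------------------------------------

DOG_TSV_COLUMNS = ("gene_id", "chrom", "start", "end", "strand", "length_bp", "mean_fpkm", "sample_id")


def write_dogs_bed(dogs: Sequence, path) -> None:
    """Emit DoGs as BED6: name = parent gene_id, score = round(1000*min(fpkm,1))."""
    with open(path, "w") as fh:
        for d in sorted(dogs, key=lambda d: (d.region.chrom, d.region.start)):
            score = int(round(1000 * min(d.mean_fpkm, 1.0)))
            fh.write(
                f"{d.region.chrom}\t{d.region.start}\t{d.region.end}\t"
                f"{d.gene_id}\t{score}\t{d.region.strand}\n"
            )


def write_dogs_tsv(dogs: Sequence, path) -> None:
    rows = [
        {
            "gene_id": d.gene_id,
            "chrom": d.region.chrom,
            "start": d.region.start,
            "end": d.region.end,
            "strand": d.region.strand,
            "length_bp": d.length_bp,
            "mean_fpkm": d.mean_fpkm,
            "sample_id": d.sample_id,
        }
        for d in sorted(dogs, key=lambda d: (d.region.chrom, d.region.start))
    ]
    pd.DataFrame(rows, columns=list(DOG_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_dogs_tsv(path) -> List:
    from .discovery import DoGRecord

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "sample_id": str})
    dogs = []
    for _, row in df.iterrows():
        region = GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"]), str(row["strand"]))
        sid = row.get("sample_id", "")
        dogs.append(
            DoGRecord(
                gene_id=str(row["gene_id"]),
                region=region,
                mean_fpkm=float(row["mean_fpkm"]),
                sample_id="" if pd.isna(sid) else str(sid),
            )
        )
    return dogs


def read_dogs_bed(path) -> List:
    """Re-read an emitted DoG BED6 (mean_fpkm reconstructed from the score)."""
    from .discovery import DoGRecord

    dogs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: line {lineno}: expected BED6")
            region = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), parts[5])
            dogs.append(
                DoGRecord(gene_id=parts[3], region=region, mean_fpkm=int(parts[4]) / 1000.0)
            )
    return dogs
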