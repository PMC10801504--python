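"""Synthetic dataset generator for the readthrough-detection pipeline.

Emulates a transcription-inhibition experiment on a single linear
chromosome: genes with variable expression, a subset with planted
readthrough (DoG) extensions downstream of their 3' ends, antisense
"interferer" genes transcribed inside some DoG spans (the false-positive
mode the ChIP-seq filters exist to catch), promoter-proximal RNAP II peaks,
and two conditions x N replicates of per-base Poisson coverage noise.

Treated cells carry more and stronger readthrough than control cells, with
a configured fraction of DoG genes shared between the conditions —
mirroring the qualitative structure of drug-induced transcriptional stress.
Everything is driven by one seed; a fixed seed gives byte-identical output
files. The planted truth table is emitted before any caller runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import CoverageTrack, GeneModel, GenomicInterval, PeakSet

PEAK_WIDTH = 300  # fixed promoter-peak width, centered on the TSS

CONTROL = "control"
TREATED = "treated"


@dataclass
class SimulationConfig:
    n_genes: int = 100
    gene_length_range_bp: Tuple[int, int] = (1500, 3000)
    intergenic_gap_range_bp: Tuple[int, int] = (20000, 26000)
    expressed_fraction: float = 0.85
    readthrough_fraction_treated: float = 0.30
    readthrough_fraction_control: float = 0.12
    control_shared_fraction: float = 0.6
    dog_length_range_bp: Tuple[int, int] = (4000, 9000)
    base_expression_fpkm_range: Tuple[float, float] = (2.0, 50.0)
    dog_to_gene_coverage_ratio: float = 0.5
    de_fraction: float = 0.2
    de_log2fc: float = 3.0
    n_replicates: int = 2
    library_size: int = 20_000_000
    read_length_bp: int = 50
    interference_fraction: float = 0.15
    promoter_peak_fraction: float = 0.9
    replicate_sigma: float = 0.1
    window_bp: int = 500  # planted DoG lengths are multiples of this
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "expressed_fraction",
            "readthrough_fraction_treated",
            "readthrough_fraction_control",
            "control_shared_fraction",
            "de_fraction",
            "interference_fraction",
            "promoter_peak_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("gene_length_range_bp", "intergenic_gap_range_bp", "dog_length_range_bp"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be an ordered positive range")
        if self.dog_to_gene_coverage_ratio <= 0 or self.dog_to_gene_coverage_ratio > 1:
            raise ValueError("dog_to_gene_coverage_ratio must lie in (0, 1]")
        # each intergenic gap may need to host the flanking DoG of the genes
        # on both of its sides plus a safety margin
        need = 2 * self.dog_length_range_bp[1] + 1000
        if self.intergenic_gap_range_bp[0] < need:
            raise ValueError(
                f"genome too short for requested genes/gaps: minimum intergenic gap "
                f"{self.intergenic_gap_range_bp[0]} < {need} required by DoG lengths"
            )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: List[GeneModel]  # includes interferer genes
    tracks: List[CoverageTrack]
    sample_sheet: pd.DataFrame
    peaks: Dict[str, PeakSet]  # per condition
    truth: pd.DataFrame
    expected_depth: Dict[str, np.ndarray]  # per condition, pre-noise
    chrom: str = "chrS"

    def truth_dog_genes(self, condition: str) -> set:
        col = f"dog_length_{condition}"
        return set(self.truth.loc[self.truth[col] > 0, "gene_id"])


def _fpkm_to_depth(fpkm: float, cfg: SimulationConfig) -> float:
    # FPKM -> expected per-base depth: reads = fpkm * (L/1e3) * (lib/1e6),
    # depth = reads * read_length / L
    return fpkm * cfg.read_length_bp * cfg.library_size / 1e9


def simulate(config: SimulationConfig, out_dir=None) -> SimulatedDataset:
    """Generate a complete synthetic dataset (and optionally write it).

    Returns the in-memory dataset; when ``out_dir`` is given, also writes
    genes.gtf, <sample>.bedGraph per sample, peaks_<condition>.bed,
    truth.tsv and samples.tsv — exactly the formats the pipeline consumes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chrom = "chrS"
    w = cfg.window_bp

    glo, ghi = cfg.gene_length_range_bp
    lengths = rng.integers(glo, ghi + 1, size=cfg.n_genes)
    gaps = rng.integers(*cfg.intergenic_gap_range_bp, size=cfg.n_genes)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")

    pad = cfg.dog_length_range_bp[1] + 2000
    starts = np.empty(cfg.n_genes, dtype=np.int64)
    cursor = pad
    for i in range(cfg.n_genes):
        starts[i] = cursor
        cursor += lengths[i] + gaps[i]
    genome_len = int(cursor + pad)

    n = cfg.n_genes
    idx = np.arange(n)
    expressed_idx = rng.choice(idx, size=round(cfg.expressed_fraction * n), replace=False)
    expressed = np.zeros(n, dtype=bool)
    expressed[expressed_idx] = True

    n_treated = round(cfg.readthrough_fraction_treated * n)
    n_control = round(cfg.readthrough_fraction_control * n)
    if n_treated > expressed.sum():
        raise ValueError("readthrough fraction exceeds expressed gene count")
    treated_dog_idx = rng.choice(np.sort(expressed_idx), size=n_treated, replace=False)
    n_shared = min(round(cfg.control_shared_fraction * n_control), n_treated)
    shared_idx = rng.choice(treated_dog_idx, size=n_shared, replace=False)
    pool = np.setdiff1d(expressed_idx, treated_dog_idx)
    n_only = min(n_control - n_shared, len(pool))
    control_only_idx = rng.choice(pool, size=n_only, replace=False) if n_only else np.array([], dtype=int)
    control_dog_idx = np.concatenate([shared_idx, control_only_idx]).astype(int)

    treated_dog = np.zeros(n, dtype=bool)
    treated_dog[treated_dog_idx] = True
    control_dog = np.zeros(n, dtype=bool)
    control_dog[control_dog_idx] = True

    def sample_dog_len(size):
        lo = math.ceil(cfg.dog_length_range_bp[0] / w)
        hi = cfg.dog_length_range_bp[1] // w
        return rng.integers(lo, hi + 1, size=size) * w

    dog_len_t = np.where(treated_dog, 0, 0).astype(int)
    dog_len_t[treated_dog] = sample_dog_len(int(treated_dog.sum()))
    dog_len_c = np.zeros(n, dtype=int)
    dog_len_c[control_dog] = sample_dog_len(int(control_dog.sum()))

    flo, fhi = cfg.base_expression_fpkm_range
    base_fpkm = np.where(
        expressed, np.exp(rng.uniform(np.log(flo), np.log(fhi), size=n)), 0.0
    )

    # planted gene-body fold changes: down-regulation is never planted on a
    # treated-DoG gene (a strongly silenced body cannot sustain a readthrough
    # signal above the discovery floor; keeps the planted truth realizable)
    gene_lfc = np.zeros(n)
    de_pool = np.setdiff1d(expressed_idx, treated_dog_idx)
    n_de = min(round(cfg.de_fraction * n), len(de_pool))
    de_idx = rng.choice(de_pool, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    half = len(de_idx) // 2
    gene_lfc[de_idx[:half]] = cfg.de_log2fc
    gene_lfc[de_idx[half:]] = -cfg.de_log2fc

    has_peak = np.zeros(n, dtype=bool)
    peak_pool = np.sort(expressed_idx)
    n_peaks = round(cfg.promoter_peak_fraction * len(peak_pool))
    has_peak[rng.choice(peak_pool, size=n_peaks, replace=False)] = True

    n_if = round(cfg.interference_fraction * n_treated)
    interfered_idx = (
        rng.choice(treated_dog_idx, size=n_if, replace=False) if n_if else np.array([], dtype=int)
    )
    interfered = np.zeros(n, dtype=bool)
    interfered[interfered_idx] = True

    genes: List[GeneModel] = []
    gene_ids = [f"SIMG{i:05d}" for i in range(n)]
    for i in range(n):
        iv = GenomicInterval(chrom, int(starts[i]), int(starts[i] + lengths[i]), str(strands[i]))
        genes.append(GeneModel(gene_ids[i], iv))

    def dog_span(i: int, length: int) -> Optional[Tuple[int, int]]:
        if length <= 0:
            return None
        g = genes[i]
        if g.strand != "-":
            return (g.interval.end, g.interval.end + length)
        return (g.interval.start - length, g.interval.start)

    # antisense interferer genes planted inside treated DoG spans
    interferers: List[GeneModel] = []
    if_fpkm: List[float] = []
    if_parent: Dict[str, str] = {}
    for i in interfered_idx:
        span = dog_span(int(i), int(dog_len_t[i]))
        assert span is not None
        a = int(rng.integers(500, 901))
        parent = genes[int(i)]
        if parent.strand != "-":
            iv = GenomicInterval(chrom, span[0] + a, span[1], "-")  # TSS at far edge
        else:
            iv = GenomicInterval(chrom, span[0], span[1] - a, "+")
        gid = f"SIMG{i:05d}_IF"
        interferers.append(GeneModel(gid, iv))
        if_parent[gid] = parent.gene_id
        if_fpkm.append(float(np.exp(rng.uniform(np.log(flo), np.log(fhi)))))

    # expected per-base depth per condition (before replicate scaling/noise)
    expected: Dict[str, np.ndarray] = {
        CONTROL: np.zeros(genome_len),
        TREATED: np.zeros(genome_len),
    }
    for i in range(n):
        g = genes[i]
        d_ctrl = _fpkm_to_depth(base_fpkm[i], cfg)
        d_trt = d_ctrl * 2.0 ** gene_lfc[i]
        expected[CONTROL][g.interval.start : g.interval.end] += d_ctrl
        expected[TREATED][g.interval.start : g.interval.end] += d_trt
        for cond, dog_len, d_gene in (
            (CONTROL, dog_len_c[i], d_ctrl),
            (TREATED, dog_len_t[i], d_trt),
        ):
            span = dog_span(i, int(dog_len))
            if span is not None:
                expected[cond][span[0] : span[1]] += d_gene * cfg.dog_to_gene_coverage_ratio
    for g, f in zip(interferers, if_fpkm):
        d = _fpkm_to_depth(f, cfg)
        for cond in (CONTROL, TREATED):
            expected[cond][g.interval.start : g.interval.end] += d

    tracks: List[CoverageTrack] = []
    sheet_rows = []
    for cond in (CONTROL, TREATED):
        for rep in range(1, cfg.n_replicates + 1):
            factor = float(rng.lognormal(mean=0.0, sigma=cfg.replicate_sigma))
            depth = rng.poisson(expected[cond] * factor).astype(np.float64)
            sid = f"{cond}_rep{rep}"
            tracks.append(
                CoverageTrack(sid, {chrom: depth}, cfg.library_size, stranded=False)
            )
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "condition": cond,
                    "replicate": rep,
                    "coverage_path": f"{sid}.bedGraph",
                    "library_size": cfg.library_size,
                    "read_length": cfg.read_length_bp,
                }
            )
    sample_sheet = pd.DataFrame(sheet_rows)

    peak_ivs: List[GenomicInterval] = []
    for i in range(n):
        if has_peak[i]:
            tss = genes[i].tss
            peak_ivs.append(
                GenomicInterval(chrom, max(tss - PEAK_WIDTH // 2, 0), tss + PEAK_WIDTH // 2)
            )
    for g in interferers:
        peak_ivs.append(
            GenomicInterval(chrom, max(g.tss - PEAK_WIDTH // 2, 0), g.tss + PEAK_WIDTH // 2)
        )
    peaks = {cond: PeakSet(peak_ivs, condition=cond) for cond in (CONTROL, TREATED)}

    truth_rows = []
    for i in range(n):
        truth_rows.append(
            {
                "gene_id": gene_ids[i],
                "strand": str(strands[i]),
                "expressed": bool(expressed[i]),
                "base_fpkm": float(base_fpkm[i]),
                "gene_log2fc": float(gene_lfc[i]),
                f"dog_length_{CONTROL}": int(dog_len_c[i]),
                f"dog_length_{TREATED}": int(dog_len_t[i]),
                "has_promoter_peak": bool(has_peak[i]),
                "interfering": False,
                "interfered": bool(interfered[i]),
            }
        )
    for g, f in zip(interferers, if_fpkm):
        truth_rows.append(
            {
                "gene_id": g.gene_id,
                "strand": g.strand,
                "expressed": True,
                "base_fpkm": f,
                "gene_log2fc": 0.0,
                f"dog_length_{CONTROL}": 0,
                f"dog_length_{TREATED}": 0,
                "has_promoter_peak": True,
                "interfering": True,
                "interfered": False,
            }
        )
    truth = pd.DataFrame(truth_rows)

    all_genes = sorted(genes + interferers, key=lambda g: (g.interval.chrom, g.interval.start))
    ds = SimulatedDataset(
        config=cfg,
        genes=all_genes,
        tracks=tracks,
        sample_sheet=sample_sheet,
        peaks=peaks,
        truth=truth,
        expected_depth=expected,
        chrom=chrom,
    )
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def _write_bedgraph(depth: np.ndarray, chrom: str, path) -> None:
    # run-length encode the per-base depth, omitting zero runs
    change = np.nonzero(np.diff(depth))[0] + 1
    bounds = np.concatenate([[0], change, [len(depth)]])
    with open(path, "w") as fh:
        for s, e in zip(bounds[:-1], bounds[1:]):
            v = depth[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_dataset(ds: SimulatedDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genes.gtf", "w") as fh:
        for g in ds.genes:
            fh.write(
                f"{g.interval.chrom}\tdogscan_sim\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\tgene_id \"{g.gene_id}\";\n"
            )
    for t in ds.tracks:
        _write_bedgraph(t.values[ds.chrom], ds.chrom, out / f"{t.sample_id}.bedGraph")
    for cond, ps in ds.peaks.items():
        with open(out / f"peaks_{cond}.bed", "w") as fh:
            for p in ps:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
    ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    ds.sample_sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    return out


def make_stress_response_dataset(scale: str = "small", seed: int = 0) -> SimulatedDataset:
    """A two-condition, two-replicate dataset with the structure the analysis
    assumes: treated cells read through more genes than control cells, and a
    configured fraction of readthrough gene IDs is shared between conditions.

    ``small`` is 100 genes with 30 planted treated DoGs and zero background
    noise outside transcribed regions; ``medium`` is 250 genes.
    """
    if scale == "small":
        cfg = SimulationConfig(n_genes=100, seed=seed)
    elif scale == "medium":
        cfg = SimulationConfig(n_genes=250, seed=seed)
    else:
        raise ValueError("scale must be 'small' or 'medium'")
    return simulate(cfg)
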