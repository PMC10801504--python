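import numpy as np
import pytest

from dogscan.model import CoverageTrack, DoGParams, GeneModel, GenomicInterval


def make_track(
    segments,
    chrom="chr1",
    chrom_len=None,
    library_size=1_000_000,
    sample_id="s1",
    stranded=False,
):
    """Build a CoverageTrack from (start, end, depth) segments."""
    end_max = max((e for _, e, _ in segments), default=0)
    n = chrom_len if chrom_len is not None else end_max
    arr = np.zeros(max(n, 1), dtype=float)
    for s, e, d in segments:
        arr[s:e] = d
    return CoverageTrack(sample_id, {chrom: arr}, library_size, stranded=stranded)


def gene(gene_id, start, end, strand="+", chrom="chr1"):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))


def brute_force_dog(g, track, annotation, params, read_length=50):
    """Independent per-base re-scan of the windowed DoG-calling rule.

    Recomputes every window FPKM from the raw depth values with plain Python
    sums and no incremental bookkeeping; used as the oracle the fast caller
    is checked against. Returns (start, end) of the called region or None.
    """
    plus = g.strand != "-"
    tes = g.tes
    chrom = g.interval.chrom
    depth = track.values.get(chrom, np.zeros(0))

    def base(i):
        return float(depth[i]) if 0 <= i < len(depth) else 0.0

    def win_fpkm(s, e):
        reads = sum(base(i) for i in range(s, e)) / read_length
        return reads / (((e - s) / 1e3) * (track.library_size / 1e6))

    # blocking coordinate: nearest TSS-side boundary downstream of the TES
    limit = None
    for other in annotation:
        if other.gene_id == g.gene_id or other.interval.chrom != chrom:
            continue
        if track.stranded and other.strand != g.strand:
            continue
        b = other.interval.end if other.strand == "-" else other.interval.start
        if plus and b > tes and (limit is None or b < limit):
            limit = b
        if not plus and b < tes and (limit is None or b > limit):
            limit = b

    far = tes
    pos = tes
    while True:
        if plus:
            ws, we = pos, pos + params.window_bp
            if limit is not None:
                we = min(we, limit)
            if we <= ws or ws >= len(depth):
                break
        else:
            ws, we = max(pos - params.window_bp, 0), pos
            if limit is not None:
                ws = max(ws, limit)
            if we <= ws:
                break
        if win_fpkm(ws, we) >= params.min_fpkm:
            far = we if plus else ws
        else:
            break
        pos = we if plus else ws
        if limit is not None and pos == limit:
            break
        if not plus and pos <= 0:
            break
    length = (far - tes) if plus else (tes - far)
    if length < params.min_length_bp:
        return None
    return (tes, far) if plus else (far, tes)


def random_instance(seed):
    """<= 50 genes with random strands plus random piecewise coverage."""
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(2, 51))
    cursor = int(rng.integers(0, 3000))
    genes = []
    for i in range(n_genes):
        length = int(rng.integers(300, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(gene(f"R{i}", cursor, cursor + length, strand=strand))
        cursor += length + int(rng.integers(200, 15_000))
    chrom_len = cursor + int(rng.integers(0, 20_000))
    n_seg = int(rng.integers(5, 60))
    arr = np.zeros(chrom_len)
    for _ in range(n_seg):
        s = int(rng.integers(0, chrom_len - 1))
        e = min(chrom_len, s + int(rng.integers(100, 8000)))
        arr[s:e] = float(rng.choice([0.0, 0.02, 0.1, 0.5, 2.0, 5.0]))
    track = CoverageTrack("rand", {"chr1": arr}, 1_000_000)
    return genes, track


@pytest.fixture
def default_params():
    return DoGParams()
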