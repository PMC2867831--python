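import numpy as np
import pytest

from depthcn import normalize, simulate, windows
from depthcn.iolib import Chromosome, GenomeLayout
from depthcn.windows import CountTable, Element, WindowSet


@pytest.fixture(scope="session")
def toy_layout():
    return GenomeLayout(
        [
            Chromosome("chr1", 1_000_000, "autosome"),
            Chromosome("chr2", 600_000, "autosome"),
            Chromosome("chrX", 400_000, "allosome_X"),
            Chromosome("chrM", 16_569, "mitochondrial"),
        ]
    )


def make_count_pair(x, y, layout=None, window=1000):
    """Build aligned sample/reference CountTables from raw count vectors
    on a single synthetic autosome (helper for normalization tests)."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n = x.size
    if layout is None:
        layout = GenomeLayout([Chromosome("c1", n * window, "autosome")])
    els = [Element(f"w{i}", layout.names[0], i * window, (i + 1) * window) for i in range(n)]
    ws = WindowSet(els, layout, "sliding", window, window)
    return (
        CountTable("sample", ws, x, int(x.sum())),
        CountTable("reference", ws, y, int(y.sum())),
    )


@pytest.fixture(scope="session")
def tumor_run():
    """One full pipeline run on the aneuploid simulation: counts on
    non-overlapping 150 kb windows, normalized profile, and per-window
    true copy number. Shared across tests because it is the expensive
    fixture."""
    cfg = simulate.tumor_mix_config(20260921)
    reads_s = simulate.simulate_read_coordinates(cfg, "sample")
    reads_r = simulate.simulate_read_coordinates(cfg, "reference")
    ws = windows.make_windows(cfg.layout, 150_000, 150_000)
    counts_s = windows.count_reads(reads_s, ws)
    counts_r = windows.count_reads(reads_r, ws)
    dist = normalize.estimate_mode(counts_s, counts_r, cfg.layout)
    profile = normalize.normalize_to_reference(
        counts_s, counts_r, dist, normalize.default_ploidy_map(cfg.layout)
    )
    truth = {}
    for e in ws.elements:
        for seg in cfg.cn_segments:
            if seg.chrom == e.chrom and seg.start <= e.start and e.end <= seg.end:
                truth[e.element_id] = seg.cn
    return {
        "config": cfg,
        "reads_sample": reads_s,
        "reads_reference": reads_r,
        "windows": ws,
        "counts_sample": counts_s,
        "counts_reference": counts_r,
        "dist": dist,
        "profile": profile,
        "truth": truth,
    }
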