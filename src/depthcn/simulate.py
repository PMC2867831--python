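"""Ground-truth simulator for the whole assay.

Emulates exactly the data-generating process the counting statistics
assume: read 5' positions fall independently and uniformly within
piecewise-constant copy-number segments, with landing probability
proportional to local copy number — so per-window counts are
Poisson-dispersed by construction. No fragment-length, GC or sequencing-
error model is included (the assay deliberately avoids depending on them).

A single mandatory seed drives everything; each output stream (sample
coordinates, reference coordinates, sample FASTQ, reference FASTQ) derives
its generator from ``(seed, stream_id)`` so partial re-runs reproduce
byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .iolib import (
    Chromosome,
    DepthCNError,
    GenomeLayout,
    ReadCoordinates,
    write_alignments_tabular,
)
from .windows import revcomp

TELOMERE_MOTIF = "TTAGGG"

_STREAMS = {
    ("reads", "sample"): 1,
    ("reads", "reference"): 2,
    ("fastq", "sample"): 3,
    ("fastq", "reference"): 4,
}


class CNSegment(NamedTuple):
    chrom: str
    start: int
    end: int
    cn: float


@dataclass
class SimConfig:
    """Study conditions for one simulated sample/reference pair."""

    seed: int
    layout: GenomeLayout
    cn_segments: list[CNSegment]
    reference_ploidy: dict[str, float]
    n_reads_sample: int
    n_reads_reference: int
    mito_rate_sample: float = 0.0
    mito_rate_reference: float = 0.0
    telomere_fraction_sample: float = 0.0
    telomere_fraction_reference: float = 0.0
    n_fastq_sample: int | None = None
    n_fastq_reference: int | None = None
    read_length: int = 33

    def __post_init__(self) -> None:
        segs = [CNSegment(*s) for s in self.cn_segments]
        self.cn_segments = segs
        nuclear = [c for c in self.layout if c.role != "mitochondrial"]
        by_chrom: dict[str, list[CNSegment]] = {c.name: [] for c in nuclear}
        for s in segs:
            if s.chrom not in by_chrom:
                raise ValueError(
                    f"segment on {s.chrom!r}: not a nuclear chromosome of the layout"
                )
            if s.cn < 0:
                raise ValueError(f"segment {s}: copy number must be >= 0")
            by_chrom[s.chrom].append(s)
        for c in nuclear:
            chrom_segs = sorted(by_chrom[c.name], key=lambda s: s.start)
            if not chrom_segs:
                raise ValueError(f"chromosome {c.name!r} has no cn_segments")
            cursor = 0
            for s in chrom_segs:
                if s.start != cursor:
                    raise ValueError(
                        f"cn_segments must tile {c.name!r} without gaps or "
                        f"overlap (expected start {cursor}, got {s.start})"
                    )
                cursor = s.end
            if cursor != c.length:
                raise ValueError(
                    f"cn_segments on {c.name!r} end at {cursor}, "
                    f"chromosome length is {c.length}"
                )
        for name, frac in [
            ("mito_rate_sample", self.mito_rate_sample),
            ("mito_rate_reference", self.mito_rate_reference),
            ("telomere_fraction_sample", self.telomere_fraction_sample),
            ("telomere_fraction_reference", self.telomere_fraction_reference),
        ]:
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if any(
            frac > 0
            for frac in (self.mito_rate_sample, self.mito_rate_reference)
        ) and self.layout.mitochondrial is None:
            raise ValueError("mito rates set but layout has no mitochondrial contig")

    def rng(self, kind: str, which: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[(kind, which)]])


def _segment_weights(config: SimConfig, which: str) -> tuple[list[CNSegment], np.ndarray]:
    if which == "sample":
        segs = config.cn_segments
        cn = np.array([s.cn for s in segs], dtype=float)
    elif which == "reference":
        segs = config.cn_segments
        cn = np.array([config.reference_ploidy[s.chrom] for s in segs], dtype=float)
    else:
        raise ValueError(f"which must be 'sample' or 'reference', got {which!r}")
    lengths = np.array([s.end - s.start for s in segs], dtype=float)
    return segs, cn * lengths


def simulate_read_coordinates(config: SimConfig, which: str = "sample") -> ReadCoordinates:
    """Draw a sample's unique-read 5' coordinates.

    Nuclear positions land in copy-number segments with probability
    proportional to segment length x copy number (sample) or x reference
    ploidy (reference), uniformly within the segment; a binomial share of
    reads given by the mtDNA rate lands uniformly on the mitochondrial
    contig. The total equals ``n_reads`` exactly and the draw is a pure
    function of (seed, which).
    """
    n = config.n_reads_sample if which == "sample" else config.n_reads_reference
    rng = config.rng("reads", which)
    segs, weights = _segment_weights(config, which)
    mito = config.layout.mitochondrial
    mito_rate = (
        config.mito_rate_sample if which == "sample" else config.mito_rate_reference
    )
    per_chrom: dict[str, list[np.ndarray]] = {}

    n_mito = int(rng.binomial(n, mito_rate)) if (mito and mito_rate > 0) else 0
    if n_mito:
        per_chrom[mito] = [
            rng.integers(0, config.layout.length(mito), size=n_mito, dtype=np.int64)
        ]
    n_nuclear = n - n_mito
    total_weight = weights.sum()
    if n_nuclear > 0 and total_weight <= 0:
        raise DepthCNError(
            f"{which}: every nuclear segment has copy number zero; "
            f"cannot place {n_nuclear} reads"
        )
    if n_nuclear > 0:
        counts = rng.multinomial(n_nuclear, weights / total_weight)
        for seg, cnt in zip(segs, counts):
            if cnt == 0:
                continue
            per_chrom.setdefault(seg.chrom, []).append(
                rng.integers(seg.start, seg.end, size=int(cnt), dtype=np.int64)
            )
    positions = {c: np.concatenate(chunks) for c, chunks in per_chrom.items()}
    return ReadCoordinates(f"sim-{which}", positions, config.layout,
                           n_total_reads=n, n_aligned=n)


def simulate_fastq(config: SimConfig, which: str, path: str | os.PathLike) -> str:
    """Write a FASTQ whose reads are, with the configured telomere
    fraction, pure tandem telomere-repeat arrays (random phase, random
    strand) and otherwise random background guaranteed free of the
    (TTAGGG)4 pattern on both strands. Constant quality strings; byte-
    identical for a fixed (seed, which)."""
    if which == "sample":
        n = config.n_fastq_sample or config.n_reads_sample
        frac = config.telomere_fraction_sample
    elif which == "reference":
        n = config.n_fastq_reference or config.n_reads_reference
        frac = config.telomere_fraction_reference
    else:
        raise ValueError(f"which must be 'sample' or 'reference', got {which!r}")
    L = config.read_length
    pattern = TELOMERE_MOTIF * 4
    if frac > 0 and L < len(pattern):
        raise DepthCNError(
            f"read_length {L} < {len(pattern)} nt telomere motif span; "
            "telomeric reads would be undetectable"
        )
    rng = config.rng("fastq", which)
    n_tel = int(rng.binomial(n, frac)) if frac > 0 else 0
    is_tel = np.zeros(n, dtype=bool)
    if n_tel:
        is_tel[rng.choice(n, size=n_tel, replace=False)] = True

    tandem = TELOMERE_MOTIF * (L // len(TELOMERE_MOTIF) + 2)
    phases = rng.integers(0, len(TELOMERE_MOTIF), size=n)
    strands = rng.integers(0, 2, size=n)
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    bg = letters[rng.integers(0, 4, size=(n, L))].tobytes()
    rc_pattern = revcomp(pattern)

    qual = "I" * L
    with open(path, "w") as fh:
        for i in range(n):
            if is_tel[i]:
                seq = tandem[phases[i] : phases[i] + L]
                if strands[i]:
                    seq = revcomp(seq)
            else:
                seq = bg[i * L : (i + 1) * L].decode()
                while pattern in seq or rc_pattern in seq:  # pragma: no cover
                    seq = letters[rng.integers(0, 4, size=L)].tobytes().decode()
            fh.write(f"@{which}_{i}\n{seq}\n+\n{qual}\n")
    return str(path)


def write_truth_bed(config: SimConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(config.cn_segments):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tseg{i}_cn{s.cn:g}\t{s.cn:g}\n")


def simulate_to_files(config: SimConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Emit the full fixture set: tabular read coordinates for sample and
    reference, layout TSV, ground-truth BED, and (when telomere fractions
    or FASTQ sizes are set) FASTQ files."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "layout": os.path.join(outdir, "layout.tsv"),
        "truth": os.path.join(outdir, "truth.bed"),
        "sample_reads": os.path.join(outdir, "sample.reads.tsv"),
        "reference_reads": os.path.join(outdir, "reference.reads.tsv"),
    }
    config.layout.to_table(paths["layout"])
    write_truth_bed(config, paths["truth"])
    write_alignments_tabular(
        simulate_read_coordinates(config, "sample"), paths["sample_reads"]
    )
    write_alignments_tabular(
        simulate_read_coordinates(config, "reference"), paths["reference_reads"]
    )
    if config.telomere_fraction_sample > 0 or config.telomere_fraction_reference > 0:
        paths["sample_fastq"] = os.path.join(outdir, "sample.fastq")
        paths["reference_fastq"] = os.path.join(outdir, "reference.fastq")
        simulate_fastq(config, "sample", paths["sample_fastq"])
        simulate_fastq(config, "reference", paths["reference_fastq"])
    return paths


# ---------------------------------------------------------------------------
# canonical study conditions

MB = 1_000_000


def tumor_mix_config(seed: int) -> SimConfig:
    """An aneuploid-cell-line scenario against a diploid reference.

    Four 6 Mb autosomes carry segments at true copy number
    0, 1, 2, 3, 4, 5, 12, 25 and 29 with a diploid majority (about two
    thirds of 150 kb windows), spanning homozygous deletion through
    high-level amplification. Read totals give the reference ~1500 reads
    per 150 kb window — comfortably above both the 110-read design point
    and the 50-read mask. The sample carries five times the reference's
    mtDNA read share and a quarter of its telomeric read fraction,
    matching the biology of a cultured tumor line versus blood DNA.
    """
    layout = GenomeLayout(
        [
            Chromosome("chr1", 6 * MB, "autosome"),
            Chromosome("chr2", 6 * MB, "autosome"),
            Chromosome("chr3", 6 * MB, "autosome"),
            Chromosome("chr4", 6 * MB, "autosome"),
            Chromosome("chrM", 16_569, "mitochondrial"),
        ]
    )
    segments = [
        CNSegment("chr1", 0, 6 * MB, 2),
        CNSegment("chr2", 0, 1_500_000, 2),
        CNSegment("chr2", 1_500_000, 3_000_000, 3),
        CNSegment("chr2", 3_000_000, 4_500_000, 1),
        CNSegment("chr2", 4_500_000, 6_000_000, 2),
        CNSegment("chr3", 0, 900_000, 0),
        CNSegment("chr3", 900_000, 2_400_000, 2),
        CNSegment("chr3", 2_400_000, 3_300_000, 4),
        CNSegment("chr3", 3_300_000, 4_200_000, 5),
        CNSegment("chr3", 4_200_000, 6_000_000, 2),
        CNSegment("chr4", 0, 3_000_000, 2),
        CNSegment("chr4", 3_000_000, 3_900_000, 12),
        CNSegment("chr4", 3_900_000, 4_800_000, 25),
        CNSegment("chr4", 4_800_000, 5_400_000, 29),
        CNSegment("chr4", 5_400_000, 6_000_000, 2),
    ]
    return SimConfig(
        seed=seed,
        layout=layout,
        cn_segments=segments,
        reference_ploidy={f"chr{i}": 2.0 for i in range(1, 5)},
        n_reads_sample=483_000,
        n_reads_reference=240_000,
        mito_rate_sample=0.05,
        mito_rate_reference=0.01,
        telomere_fraction_sample=0.005,
        telomere_fraction_reference=0.02,
        n_fastq_sample=300_000,
        n_fastq_reference=300_000,
        read_length=33,
    )


def flat_config(
    seed: int,
    n_windows: int = 100,
    window: int = 150_000,
    reads_per_window_sample: int = 200,
    reads_per_window_reference: int = 200,
) -> SimConfig:
    """A uniformly diploid single-chromosome genome — the null scenario."""
    length = n_windows * window
    layout = GenomeLayout([Chromosome("chr1", length, "autosome")])
    return SimConfig(
        seed=seed,
        layout=layout,
        cn_segments=[CNSegment("chr1", 0, length, 2)],
        reference_ploidy={"chr1": 2.0},
        n_reads_sample=n_windows * reads_per_window_sample,
        n_reads_reference=n_windows * reads_per_window_reference,
    )


def sex_mismatch_config(seed: int) -> SimConfig:
    """A female-like sample (XX, no Y) against a male reference (X and Y
    haploid): X windows should be called at copy number 2, Y windows at 0."""
    layout = GenomeLayout(
        [
            Chromosome("chr1", 3 * MB, "autosome"),
            Chromosome("chrX", 1_800_000, "allosome_X"),
            Chromosome("chrY", 900_000, "allosome_Y"),
        ]
    )
    segments = [
        CNSegment("chr1", 0, 3 * MB, 2),
        CNSegment("chrX", 0, 1_800_000, 2),
        CNSegment("chrY", 0, 900_000, 0),
    ]
    return SimConfig(
        seed=seed,
        layout=layout,
        cn_segments=segments,
        reference_ploidy={"chr1": 2.0, "chrX": 1.0, "chrY": 1.0},
        n_reads_sample=60_000,
        n_reads_reference=60_000,
    )
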