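"""Non-window biological elements: mitochondrial DNA abundance and
telomere repeat content.

Mitochondrial level: the fraction of a sample's uniquely aligned reads
landing on the mitochondrial contig is proportional to the average number
of mtDNA genomes per cell; the ratio of that fraction between a sample and
a reference is the relative mitochondrial level.

Telomere level: alignment-free. Human telomeres are tandem TTAGGG arrays,
which do not align uniquely; instead, raw reads containing four tandem
copies of the motif — (TTAGGG)4, 24 nt — on either strand are counted, and
the counted fraction of all reads scanned is compared between sample and
reference. Both measures carry Poisson uncertainties on the raw counts.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pysam
from scipy import stats as sps

from .iolib import DepthCNError, GenomeLayout, ReadCoordinates
from .windows import revcomp

TELOMERE_MOTIF = "TTAGGG"
TELOMERE_REPEATS = 4


@dataclass
class ElementMeasure:
    """A rate-based element measurement relative to a reference sample."""

    sample_id: str
    reference_id: str
    element: str  # "mitochondria" | "telomere"
    raw_count: int
    denominator: int
    reference_count: int
    reference_denominator: int
    relative_level: float
    sigma: float
    p_value: float

    @property
    def rate(self) -> float:
        return self.raw_count / self.denominator

    @property
    def reference_rate(self) -> float:
        return self.reference_count / self.reference_denominator

    def to_tsv_row(self) -> str:
        return "\t".join(
            [
                self.sample_id,
                self.reference_id,
                self.element,
                str(self.raw_count),
                str(self.denominator),
                f"{self.rate:.6g}",
                str(self.reference_count),
                str(self.reference_denominator),
                f"{self.reference_rate:.6g}",
                f"{self.relative_level:.6g}",
                f"{self.sigma:.6g}",
                f"{self.p_value:.6e}",
            ]
        )


TSV_HEADER = "\t".join(
    [
        "sample", "reference", "element", "count", "denominator", "rate",
        "ref_count", "ref_denominator", "ref_rate", "relative_level",
        "sigma", "p_value",
    ]
)


def _relative_measure(
    sample_id: str,
    reference_id: str,
    element: str,
    x: int,
    nx: int,
    y: int,
    ny: int,
) -> ElementMeasure:
    """Rate ratio with Poisson errors on both counts in quadrature; a zero
    count contributes its x->1 variance so the uncertainty stays finite."""
    if y == 0:
        raise DepthCNError(
            f"{element}: reference sample {reference_id!r} has zero counts; "
            "relative level undefined"
        )
    rel = (x / nx) / (y / ny)
    x_eff = max(x, 1)
    rel_eff = (x_eff / nx) / (y / ny)
    sigma = rel_eff * math.sqrt(1.0 / x_eff + 1.0 / y)
    p = float(np.clip(2.0 * sps.norm.sf(abs(rel - 1.0) / sigma), 1e-300, 1.0))
    return ElementMeasure(
        sample_id, reference_id, element, x, nx, y, ny, rel, sigma, p
    )


def mito_level(
    reads: ReadCoordinates,
    layout: GenomeLayout,
    reference: ReadCoordinates,
) -> ElementMeasure:
    """Relative mitochondrial DNA level of ``reads`` versus ``reference``:
    ratio of per-sample mtDNA read fractions (denominator: unique aligned
    reads)."""
    mito = layout.mitochondrial
    if mito is None:
        raise DepthCNError(
            "layout declares no mitochondrial chromosome; cannot assay mtDNA"
        )
    return _relative_measure(
        reads.sample_id,
        reference.sample_id,
        "mitochondria",
        reads.count_on(mito),
        reads.n_unique,
        reference.count_on(mito),
        reference.n_unique,
    )


def count_motif_reads(
    fastq: str | os.PathLike,
    motif: str = TELOMERE_MOTIF,
    repeats: int = TELOMERE_REPEATS,
    both_strands: bool = True,
    trim5: int = 0,
) -> tuple[int, int]:
    """Scan a FASTQ (gzip-transparent) and return (reads containing the
    tandem motif, reads scanned). A read counts once if ``motif * repeats``
    occurs as an exact substring of the read or (with ``both_strands``) of
    its reverse complement; an optional fixed-length 5' barcode trim is
    applied first."""
    pattern = (motif * repeats).upper()
    rc_pattern = revcomp(pattern)
    span = len(pattern)
    n = hits = 0
    with pysam.FastxFile(str(fastq)) as fh:
        for rec in fh:
            seq = rec.sequence.upper()
            if trim5:
                seq = seq[trim5:]
            if len(seq) < span:
                raise DepthCNError(
                    f"{fastq}: read {rec.name!r} is {len(seq)} nt after trim, "
                    f"shorter than the {span} nt motif span "
                    f"({motif} x {repeats})"
                )
            n += 1
            if pattern in seq or (both_strands and rc_pattern in seq):
                hits += 1
    if n == 0:
        raise DepthCNError(f"{fastq}: no reads")
    return hits, n


def telomere_level(
    fastq: str | os.PathLike,
    reference_fastq: str | os.PathLike,
    motif: str = TELOMERE_MOTIF,
    repeats: int = TELOMERE_REPEATS,
    both_strands: bool = True,
    trim5: int = 0,
    sample_id: str | None = None,
    reference_id: str | None = None,
) -> ElementMeasure:
    """Relative telomere repeat content of ``fastq`` versus
    ``reference_fastq``: ratio of the fractions of reads containing the
    tandem telomere motif (denominator: all reads scanned)."""
    x, nx = count_motif_reads(fastq, motif, repeats, both_strands, trim5)
    y, ny = count_motif_reads(reference_fastq, motif, repeats, both_strands, trim5)
    return _relative_measure(
        sample_id or os.path.basename(str(fastq)),
        reference_id or os.path.basename(str(reference_fastq)),
        "telomere",
        x, nx, y, ny,
    )


def write_measures(measures, path) -> None:
    with open(path, "w") as fh:
        fh.write(TSV_HEADER + "\n")
        for m in measures:
            fh.write(m.to_tsv_row() + "\n")
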