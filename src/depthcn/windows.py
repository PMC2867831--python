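"""Biological elements to count reads in: sliding windows, gene loci,
whole contigs — plus the per-element Poisson counting itself and a k-mer
tile-uniqueness utility for mappability surveys on small genomes.

A read is assigned to every element whose half-open interval contains its
5' position; overlapping sliding windows therefore each count it. The
per-element uncertainty is the Poisson counting term sqrt(x).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .iolib import GenomeLayout, Locus, ReadCoordinates


class Element(NamedTuple):
    element_id: str
    chrom: str
    start: int
    end: int


@dataclass
class WindowSet:
    """Ordered counting elements over a genome layout."""

    elements: list[Element]
    layout: GenomeLayout
    mode: str  # sliding | locus | contig
    window_size: int | None = None
    step: int | None = None

    def __post_init__(self) -> None:
        self.elements = sorted(
            self.elements,
            key=lambda e: (self.layout.order(e.chrom), e.start, e.end),
        )

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WindowSet)
            and self.elements == other.elements
            and self.mode == other.mode
        )

    @property
    def chroms(self) -> np.ndarray:
        return np.array([e.chrom for e in self.elements])

    @property
    def starts(self) -> np.ndarray:
        return np.array([e.start for e in self.elements], dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return np.array([e.end for e in self.elements], dtype=np.int64)

    def autosomal_mask(self) -> np.ndarray:
        return np.array(
            [self.layout.role(e.chrom) == "autosome" for e in self.elements]
        )

    def to_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for e in self.elements:
                fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.element_id}\n")


def make_windows(layout: GenomeLayout, window_size: int, step: int) -> WindowSet:
    """Tile every non-mitochondrial chromosome with sliding windows.

    Full windows start at multiples of ``step`` while they fit; the final
    window per chromosome is extended to the chromosome end so no tail base
    is left uncovered, and a chromosome shorter than one window becomes a
    single truncated ``[0, L)`` window. Requiring ``step <= window_size``
    guarantees gap-free coverage.
    """
    if not (1 <= step <= window_size):
        raise ValueError(
            f"need 1 <= step ({step}) <= window_size ({window_size}); "
            "step > window_size would drop reads in the gaps"
        )
    elements: list[Element] = []
    for c in layout:
        if c.role == "mitochondrial":
            continue
        if c.length < window_size:
            spans = [(0, c.length)]
        else:
            starts = list(range(0, c.length - window_size + 1, step))
            spans = [(s, s + window_size) for s in starts]
            if spans[-1][1] < c.length:  # leftover tail (< step) -> extend
                spans[-1] = (spans[-1][0], c.length)
        for s, e in spans:
            elements.append(Element(f"{c.name}:{s}-{e}", c.name, s, e))
    return WindowSet(elements, layout, "sliding", window_size, step)


def make_locus_windows(
    loci: Sequence[Locus], layout: GenomeLayout, min_span: int = 60_000
) -> WindowSet:
    """Gene-centric elements: the locus span itself when it is at least
    ``min_span`` wide, otherwise a ``min_span`` interval centered on the
    locus midpoint, clipped to the chromosome by shifting inward so the
    element keeps its length whenever the chromosome allows."""
    elements: list[Element] = []
    for locus in loci:
        length = layout.length(locus.chrom)
        if locus.end - locus.start >= min_span:
            start, end = locus.start, locus.end
        else:
            mid = (locus.start + locus.end) // 2
            start = mid - min_span // 2
            end = start + min_span
            if start < 0:
                start, end = 0, min(min_span, length)
            elif end > length:
                end, start = length, max(0, length - min_span)
        elements.append(Element(locus.locus_id, locus.chrom, start, end))
    return WindowSet(elements, layout, "locus", None, None)


def make_contig_windows(layout: GenomeLayout,
                        include_mitochondrial: bool = True) -> WindowSet:
    """One element per whole chromosome."""
    elements = [
        Element(c.name, c.name, 0, c.length)
        for c in layout
        if include_mitochondrial or c.role != "mitochondrial"
    ]
    return WindowSet(elements, layout, "contig", None, None)


@dataclass
class CountTable:
    """Reads per element for one sample, with the sqrt(x) Poisson term."""

    sample_id: str
    windows: WindowSet
    x: np.ndarray  # int64, aligned with windows.elements
    total_unique: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        if self.x.shape != (len(self.windows),):
            raise ValueError(
                f"count vector length {self.x.size} != {len(self.windows)} elements"
            )
        if (self.x < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(self.x.astype(float))


def count_reads(reads: ReadCoordinates, windows: WindowSet) -> CountTable:
    """Count reads whose 5' position falls in each element (binary search
    on the per-chromosome sorted position arrays)."""
    x = np.zeros(len(windows), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, e in enumerate(windows.elements):
        by_chrom.setdefault(e.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        pos = reads.chrom_positions(chrom)
        if pos.size == 0:
            continue
        starts = np.array([windows.elements[i].start for i in idx], dtype=np.int64)
        ends = np.array([windows.elements[i].end for i in idx], dtype=np.int64)
        counts = np.searchsorted(pos, ends, side="left") - np.searchsorted(
            pos, starts, side="left"
        )
        x[np.array(idx)] = counts
    return CountTable(reads.sample_id, windows, x, reads.n_unique)


# ---------------------------------------------------------------------------
# tile uniqueness

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class UniquenessResult:
    tile_length: int
    n_tiles: int
    n_valid: int
    n_unique: int
    n_ambiguous: int
    n_skipped: int

    @property
    def fraction_unique(self) -> float:
        return self.n_unique / self.n_valid if self.n_valid else float("nan")

    @property
    def fraction_ambiguous(self) -> float:
        return self.n_ambiguous / self.n_valid if self.n_valid else float("nan")

    @property
    def fraction_skipped(self) -> float:
        return self.n_skipped / self.n_tiles if self.n_tiles else float("nan")


def tile_uniqueness(
    genome: str | os.PathLike | Mapping[str, str],
    tile_length: int,
    both_strands: bool = True,
) -> UniquenessResult:
    """Fraction of genome tiles of ``tile_length`` matching exactly one
    genomic location.

    Every position of every contig contributes one tile. A tile's locations
    are the positions where the genome equals the tile on the forward strand
    or, with ``both_strands`` (default), equals its reverse complement; a
    palindromic tile hitting both strands at one position counts that
    position once. Tiles containing non-ACGT characters (unsequenced
    regions) are excluded from the uniqueness denominator and reported as
    skipped. Intended for small model genomes — the table is held in memory.
    """
    seqs = _load_sequences(genome)
    if tile_length < 1:
        raise ValueError("tile_length must be >= 1")
    shortest = min(len(s) for s in seqs.values())
    if tile_length > shortest:
        raise ValueError(
            f"tile_length {tile_length} exceeds the shortest contig ({shortest} bp)"
        )
    locations: dict[str, set[tuple[str, int]]] = {}
    tiles: list[str | None] = []
    valid = set("ACGT")
    for name, seq in seqs.items():
        seq = seq.upper()
        for p in range(len(seq) - tile_length + 1):
            tile = seq[p : p + tile_length]
            if set(tile) <= valid:
                locations.setdefault(tile, set()).add((name, p))
                tiles.append(tile)
            else:
                tiles.append(None)
    n_tiles = len(tiles)
    n_skipped = sum(t is None for t in tiles)
    n_unique = 0
    empty: set[tuple[str, int]] = set()
    for tile in tiles:
        if tile is None:
            continue
        hits = locations[tile]
        if both_strands:
            hits = hits | locations.get(revcomp(tile), empty)
        if len(hits) == 1:
            n_unique += 1
    n_valid = n_tiles - n_skipped
    return UniquenessResult(
        tile_length, n_tiles, n_valid, n_unique, n_valid - n_unique, n_skipped
    )


def _load_sequences(genome) -> dict[str, str]:
    if isinstance(genome, Mapping):
        return dict(genome)
    import pyfaidx

    fa = pyfaidx.Fasta(str(genome))
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return seqs
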