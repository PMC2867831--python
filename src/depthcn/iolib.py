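"""Input/output and the genome/read coordinate contracts.

Every coordinate inside the package is 0-based, half-open. SAM/BAM (1-based
in the text form, but pysam already exposes 0-based leftmost positions) and
GFF (1-based closed) are converted on ingest; BED is native. Downstream
modules therefore never see a coordinate convention other than this one.

"Unique alignment" is approximated for SAM/BAM input by a mapping-quality
threshold on primary alignments, since aligner-specific uniqueness flags
vary. The tabular dialect (`chrom<TAB>pos0`) bypasses the question: it holds
only reads already filtered to an unambiguous match, one row per read, with
optional ``# key=value`` header directives carrying the library accounting
(total reads sequenced, reads aligned) that the filtering discarded.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

ROLES = frozenset(
    {"autosome", "allosome_X", "allosome_Y", "mitochondrial", "other"}
)

#: Copy number floored to this value before taking log2 for SEG output.
SEG_CN_EPSILON = 0.01

#: Default mapping-quality threshold standing in for "uniquely aligned".
DEFAULT_MAPQ = 30


class DepthCNError(Exception):
    """Base class for this package's errors."""


class UnknownReferenceError(DepthCNError):
    """A read or interval names a chromosome absent from the layout."""


class EmptyInputError(DepthCNError):
    """An input file contains no records at all (distinct from a file whose
    records are all filtered out, which is a valid, warned state)."""


class FormatError(DepthCNError):
    """A line of an input file cannot be parsed."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    role: str = "autosome"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"chromosome {self.name!r}: length must be >= 1")
        if self.role not in ROLES:
            raise ValueError(
                f"chromosome {self.name!r}: role {self.role!r} not in {sorted(ROLES)}"
            )


class GenomeLayout:
    """Ordered chromosomes with lengths and role labels.

    Roles are ``autosome``, ``allosome_X``, ``allosome_Y``, ``mitochondrial``
    or ``other``; at most one chromosome may be mitochondrial.
    """

    def __init__(self, chromosomes: Iterable[Chromosome | tuple]) -> None:
        chroms = [
            c if isinstance(c, Chromosome) else Chromosome(*c) for c in chromosomes
        ]
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names: {dupes}")
        n_mito = sum(c.role == "mitochondrial" for c in chroms)
        if n_mito > 1:
            raise ValueError("at most one chromosome may have role 'mitochondrial'")
        self.chromosomes: tuple[Chromosome, ...] = tuple(chroms)
        self._by_name = {c.name: c for c in chroms}
        self._order = {c.name: i for i, c in enumerate(chroms)}

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeLayout)
            and self.chromosomes == other.chromosomes
        )

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self)} chromosomes, {self.total_length:,} bp)"

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def length(self, name: str) -> int:
        return self._by_name[name].length

    def role(self, name: str) -> str:
        return self._by_name[name].role

    def order(self, name: str) -> int:
        """Rank of a chromosome in layout order (for sorting elements)."""
        return self._order[name]

    @property
    def autosomes(self) -> list[str]:
        return [c.name for c in self.chromosomes if c.role == "autosome"]

    @property
    def mitochondrial(self) -> str | None:
        for c in self.chromosomes:
            if c.role == "mitochondrial":
                return c.name
        return None

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_table(cls, path: str | os.PathLike) -> "GenomeLayout":
        """Load from a TSV of ``chrom<TAB>length[<TAB>role]``."""
        chroms: list[Chromosome] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: expected chrom<TAB>length")
                name = parts[0]
                try:
                    length = int(parts[1])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: length {parts[1]!r} is not an integer"
                    ) from exc
                role = parts[2] if len(parts) > 2 and parts[2] else infer_role(name)
                chroms.append(Chromosome(name, length, role))
        if not chroms:
            raise EmptyInputError(f"{path}: no chromosomes")
        return cls(chroms)

    @classmethod
    def from_fasta(cls, path: str | os.PathLike,
                   roles: Mapping[str, str] | None = None) -> "GenomeLayout":
        """Derive names and lengths from a FASTA; roles guessed from names
        (``chrM``/``MT`` mitochondrial, ``chrX``/``X`` and ``chrY``/``Y``
        allosomes) unless given explicitly."""
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        chroms = [
            Chromosome(
                name,
                len(fa[name]),
                (roles or {}).get(name, infer_role(name)),
            )
            for name in fa.keys()
        ]
        fa.close()
        if not chroms:
            raise EmptyInputError(f"{path}: no sequences")
        return cls(chroms)

    def to_table(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for c in self.chromosomes:
                fh.write(f"{c.name}\t{c.length}\t{c.role}\n")


def infer_role(name: str) -> str:
    base = name.lower().removeprefix("chr")
    if base in {"m", "mt", "mtdna"}:
        return "mitochondrial"
    if base == "x":
        return "allosome_X"
    if base == "y":
        return "allosome_Y"
    return "autosome"


class ReadCoordinates:
    """Per-sample multiset of unique-alignment 5' positions.

    Positions are stored per chromosome as sorted int64 arrays (duplicates
    preserved). ``n_total_reads >= n_aligned >= n_unique`` tracks the
    library accounting from sequencing through uniqueness filtering.
    """

    def __init__(
        self,
        sample_id: str,
        positions: Mapping[str, Sequence[int] | np.ndarray],
        layout: GenomeLayout,
        n_total_reads: int | None = None,
        n_aligned: int | None = None,
    ) -> None:
        self.sample_id = sample_id
        self.layout = layout
        pos: dict[str, np.ndarray] = {}
        for chrom, arr in positions.items():
            if chrom not in layout:
                raise UnknownReferenceError(
                    f"sample {sample_id!r}: chromosome {chrom!r} not in layout"
                )
            a = np.asarray(arr, dtype=np.int64)
            if a.size and (a.min() < 0 or a.max() >= layout.length(chrom)):
                bad = a[(a < 0) | (a >= layout.length(chrom))][0]
                raise ValueError(
                    f"sample {sample_id!r}: position {bad} out of bounds on "
                    f"{chrom} (length {layout.length(chrom)})"
                )
            pos[chrom] = np.sort(a)
        self.positions = pos
        n_unique = int(sum(a.size for a in pos.values()))
        self.n_unique = n_unique
        self.n_aligned = n_unique if n_aligned is None else int(n_aligned)
        self.n_total_reads = (
            self.n_aligned if n_total_reads is None else int(n_total_reads)
        )
        if not (self.n_unique <= self.n_aligned <= self.n_total_reads):
            raise ValueError(
                f"sample {sample_id!r}: accounting must satisfy "
                f"n_unique ({self.n_unique}) <= n_aligned ({self.n_aligned}) "
                f"<= n_total_reads ({self.n_total_reads})"
            )

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.positions.get(chrom, np.empty(0, dtype=np.int64))

    def count_on(self, chrom: str) -> int:
        return int(self.chrom_positions(chrom).size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReadCoordinates):
            return NotImplemented
        if (
            self.sample_id != other.sample_id
            or self.n_total_reads != other.n_total_reads
            or self.n_aligned != other.n_aligned
            or self.n_unique != other.n_unique
        ):
            return False
        keys = {c for c in self.positions if self.positions[c].size} | {
            c for c in other.positions if other.positions[c].size
        }
        return all(
            np.array_equal(self.chrom_positions(c), other.chrom_positions(c))
            for c in keys
        )

    def __repr__(self) -> str:
        return (
            f"ReadCoordinates({self.sample_id!r}, {self.n_unique:,} unique of "
            f"{self.n_total_reads:,} reads)"
        )


class Locus(NamedTuple):
    locus_id: str
    chrom: str
    start: int
    end: int


# ---------------------------------------------------------------------------
# alignment loading


def load_alignments(
    path: str | os.PathLike,
    layout: GenomeLayout,
    mapq_threshold: int = DEFAULT_MAPQ,
    sample_id: str | None = None,
) -> ReadCoordinates:
    """Load per-read 5' coordinates from SAM/BAM or the tabular dialect.

    SAM/BAM: primary records are counted as reads; mapped primaries as
    aligned; mapped primaries with MAPQ >= ``mapq_threshold`` are retained,
    recorded at their 0-based leftmost aligned base regardless of strand.
    Tabular: every row is a retained read; header directives, if present,
    supply the pre-filter accounting.
    """
    path = str(path)
    if sample_id is None:
        sample_id = os.path.basename(path).rsplit(".", 1)[0]
    if path.endswith((".sam", ".bam", ".cram")):
        return _load_sam(path, layout, mapq_threshold, sample_id)
    return _load_tabular(path, layout, sample_id)


def _load_sam(
    path: str, layout: GenomeLayout, mapq_threshold: int, sample_id: str
) -> ReadCoordinates:
    per_chrom: dict[str, list[int]] = {}
    n_total = n_aligned = 0
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                continue
            n_total += 1
            if rec.is_unmapped:
                continue
            ref = rec.reference_name
            if ref not in layout:
                raise UnknownReferenceError(
                    f"{path}: read {rec.query_name!r} aligned to unknown "
                    f"reference {ref!r}"
                )
            n_aligned += 1
            if rec.mapping_quality < mapq_threshold:
                continue
            per_chrom.setdefault(ref, []).append(rec.reference_start)
    if n_total == 0:
        raise EmptyInputError(f"{path}: no reads")
    if not per_chrom:
        warnings.warn(
            f"{path}: {n_total} reads but none retained at "
            f"MAPQ >= {mapq_threshold}",
            stacklevel=3,
        )
    return ReadCoordinates(
        sample_id, per_chrom, layout, n_total_reads=n_total, n_aligned=n_aligned
    )


def _load_tabular(path: str, layout: GenomeLayout, sample_id: str) -> ReadCoordinates:
    meta: dict[str, str] = {}
    per_chrom: dict[str, list[int]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected chrom<TAB>pos0")
            chrom = parts[0]
            if chrom not in layout:
                raise UnknownReferenceError(
                    f"{path}:{lineno}: unknown chromosome {chrom!r}"
                )
            try:
                pos = int(parts[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: position {parts[1]!r} is not an integer"
                ) from exc
            per_chrom.setdefault(chrom, []).append(pos)
            n_rows += 1
    if n_rows == 0:
        raise EmptyInputError(f"{path}: no read rows")
    return ReadCoordinates(
        meta.get("sample", sample_id),
        per_chrom,
        layout,
        n_total_reads=int(meta["total_reads"]) if "total_reads" in meta else None,
        n_aligned=int(meta["aligned_reads"]) if "aligned_reads" in meta else None,
    )


def write_alignments_tabular(reads: ReadCoordinates, path: str | os.PathLike) -> None:
    """Write the tabular dialect, including the accounting directives."""
    with open(path, "w") as fh:
        fh.write(f"# sample={reads.sample_id}\n")
        fh.write(f"# total_reads={reads.n_total_reads}\n")
        fh.write(f"# aligned_reads={reads.n_aligned}\n")
        for chrom in reads.layout.names:
            for pos in reads.chrom_positions(chrom):
                fh.write(f"{chrom}\t{pos}\n")


# ---------------------------------------------------------------------------
# loci


def load_loci(path: str | os.PathLike, layout: GenomeLayout) -> list[Locus]:
    """Load gene loci from BED (0-based half-open, verbatim) or GFF3
    (1-based closed, converted). Strand is read but ignored; records whose
    interval is empty after conversion are skipped with a warning."""
    path = str(path)
    if path.endswith((".gff", ".gff3", ".gtf")):
        records = _parse_gff(path)
    else:
        records = _parse_bed(path)
    loci: list[Locus] = []
    for lineno, locus_id, chrom, start, end in records:
        if chrom not in layout:
            raise UnknownReferenceError(
                f"{path}:{lineno}: unknown chromosome {chrom!r}"
            )
        if start >= end:
            warnings.warn(
                f"{path}:{lineno}: empty interval for {locus_id!r} "
                f"({start} >= {end}); record skipped",
                stacklevel=2,
            )
            continue
        if start < 0 or end > layout.length(chrom):
            raise ValueError(
                f"{path}:{lineno}: {locus_id!r} [{start},{end}) outside "
                f"{chrom} (length {layout.length(chrom)})"
            )
        loci.append(Locus(locus_id, chrom, start, end))
    return loci


def _parse_bed(path: str):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] else f"{parts[0]}:{start}-{end}"
            yield lineno, name, parts[0], start, end


def _parse_gff(path: str):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: GFF needs 9 columns")
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = (
                attrs.get("ID")
                or attrs.get("Name")
                or attrs.get("gene_id")
                or f"{parts[0]}:{start1}-{end1}"
            )
            # GFF is 1-based closed; internal is 0-based half-open.
            yield lineno, name, parts[0], start1 - 1, end1


# ---------------------------------------------------------------------------
# profile output

PROFILE_COLUMNS = [
    "element_id", "chrom", "start", "end", "raw_count",
    "cn", "lower", "upper", "p_value", "status",
]

NA = "NA"


def write_profile(profile, path: str | os.PathLike, fmt: str = "tsv") -> None:
    """Write a copy-number profile as TSV (lossless, round-trips through
    :func:`read_profile`), SEG (log2(CN/ploidy), CN floored at
    ``SEG_CN_EPSILON``, masked rows omitted) or BED."""
    if fmt == "tsv":
        _write_profile_tsv(profile, path)
    elif fmt == "seg":
        _write_profile_seg(profile, path)
    elif fmt == "bed":
        _write_profile_bed(profile, path)
    else:
        raise ValueError(f"unknown profile format {fmt!r} (tsv, seg or bed)")


def _fmt(v, spec: str = "{:.10g}") -> str:
    return NA if v is None or (isinstance(v, float) and math.isnan(v)) else spec.format(v)


def _write_profile_tsv(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample={profile.sample_id}\n")
        fh.write(f"# reference={profile.reference_id}\n")
        fh.write(f"# mode={profile.mode:.10g}\n")
        ploidies = ",".join(f"{c}:{p:g}" for c, p in profile.ploidy_map.items())
        fh.write(f"# ploidy={ploidies}\n")
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for row in profile.table.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.element_id,
                        row.chrom,
                        str(row.start),
                        str(row.end),
                        str(row.raw_count),
                        _fmt(row.cn),
                        _fmt(row.lower),
                        _fmt(row.upper),
                        _fmt(row.p_value, "{:.6e}"),
                        row.status,
                    ]
                )
                + "\n"
            )


def read_profile(path: str | os.PathLike):
    """Read back a TSV profile written by :func:`write_profile`."""
    from .normalize import CopyNumberProfile

    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(
            fh, sep="\t", na_values=[NA], keep_default_na=False,
            dtype={"element_id": str, "chrom": str, "status": str},
        )
    # sigma is not a column of the TSV but upper = cn + sigma always holds
    table["sigma"] = table["upper"] - table["cn"]
    ploidy_map = {}
    if meta.get("ploidy"):
        for item in meta["ploidy"].split(","):
            chrom, _, p = item.partition(":")
            ploidy_map[chrom] = float(p)
    return CopyNumberProfile(
        table=table,
        sample_id=meta.get("sample", ""),
        reference_id=meta.get("reference", ""),
        mode=float(meta.get("mode", "nan")),
        ploidy_map=ploidy_map,
    )


def _write_profile_seg(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tseg.mean\n")
        for row in profile.table.itertuples(index=False):
            if row.status != "called":
                continue
            ploidy = profile.ploidy_map[row.chrom]
            value = math.log2(max(row.cn, SEG_CN_EPSILON) / ploidy)
            fh.write(
                f"{profile.sample_id}\t{row.chrom}\t{row.start}\t{row.end}"
                f"\t{value:.6g}\n"
            )


def _write_profile_bed(profile, path) -> None:
    with open(path, "w") as fh:
        for row in profile.table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.element_id}"
                f"\t{_fmt(row.cn)}\t{row.status}\n"
            )
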