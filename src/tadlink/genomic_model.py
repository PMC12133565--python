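"""Core genomic data types and readers/writers.

All internal coordinates are 0-based half-open ([start, end)); BED-family
formats are native, GTF is converted at the boundary. Readers are
deterministic (file order preserved) and every reader/writer pair is a
bit-exact round trip on files it produced.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Interval",
    "Peak",
    "GeneModel",
    "TadPartition",
    "FormatError",
    "parse_intervals",
    "write_intervals",
    "parse_gene_models",
    "write_gene_models",
    "parse_fasta",
    "write_fasta",
    "harmonize_chrom_name",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open.

    Attributes
    ----------
    chrom : str
        Chromosome name; a whitespace-free token.
    start, end : int
        0-based inclusive start, exclusive end; ``end > start >= 0``.
    id : str or None
        Optional stable identifier.
    """

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        """Half-open containment test for a single position."""
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        """Strict overlap: at least one shared base (adjacency is not overlap)."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Peak(Interval):
    """An accessibility peak: an Interval plus provenance and optional summit."""

    sample_of_origin: str | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.summit_offset is not None and not (0 <= self.summit_offset < self.length):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside [0, {self.length})"
            )

    @property
    def summit(self) -> int:
        """Absolute summit position; falls back to the midpoint."""
        if self.summit_offset is None:
            return self.midpoint
        return self.start + self.summit_offset


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand, TSS and exon structure.

    The TSS is the first transcribed base: ``start`` on '+', ``end - 1``
    on '-'. Exons must lie within the gene body and be non-overlapping.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad gene body [{self.start}, {self.end})")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for ex in exons:
            if ex.chrom != self.chrom or ex.start < self.start or ex.end > self.end:
                raise FormatError(
                    f"exon [{ex.start},{ex.end}) outside gene {self.gene_id} body"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise FormatError(f"overlapping exons in gene {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def body(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, id=self.gene_id)

    def signed_tss_distance(self, pos: int) -> int:
        """Distance from the TSS in transcription orientation (negative = upstream)."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


class TadPartition:
    """A per-chromosome sorted, disjoint set of TAD intervals.

    Overlapping input TADs are repaired by truncating each at the midpoint
    of their overlap (the repair is recorded in :attr:`repairs`);
    zero-length results are dropped.
    """

    def __init__(self, tads: Iterable[Interval]):
        by_chrom: dict[str, list[Interval]] = {}
        for t in tads:
            by_chrom.setdefault(t.chrom, []).append(t)
        self.repairs: list[str] = []
        self._by_chrom: dict[str, list[Interval]] = {}
        n = 0
        for chrom in sorted(by_chrom):
            repaired = self._repair(sorted(by_chrom[chrom], key=lambda t: (t.start, t.end)))
            self._by_chrom[chrom] = repaired
            n += len(repaired)
        self.n_tads = n

    def _repair(self, tads: list[Interval]) -> list[Interval]:
        out: list[Interval] = []
        for t in tads:
            if out and t.start < out[-1].end:
                prev = out[-1]
                mid = (t.start + min(prev.end, t.end)) // 2
                self.repairs.append(
                    f"overlap between {prev.id or prev.start} and {t.id or t.start} "
                    f"on {t.chrom}: truncated at {mid}"
                )
                if mid > prev.start:
                    out[-1] = Interval(prev.chrom, prev.start, mid, id=prev.id)
                else:
                    out.pop()
                if mid < t.end:
                    t = Interval(t.chrom, mid, t.end, id=t.id)
                else:
                    continue
            out.append(t)
        return out

    def __iter__(self):
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return self.n_tads

    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def find(self, chrom: str, pos: int) -> Interval | None:
        """The unique TAD whose half-open interval contains pos, else None.

        Binary search over the sorted disjoint per-chromosome list.
        """
        tads = self._by_chrom.get(chrom)
        if not tads:
            return None
        lo, hi = 0, len(tads) - 1
        while lo <= hi:
            mid = (lo + hi) // 2
            t = tads[mid]
            if pos < t.start:
                hi = mid - 1
            elif pos >= t.end:
                lo = mid + 1
            else:
                return t
        return None


# ---------------------------------------------------------------------------
# BED-family I/O
# ---------------------------------------------------------------------------

_DIALECT_MIN_COLS = {"bed3": 3, "bed6": 6, "narrowpeak": 10}


def parse_intervals(path: str | Path, dialect: str = "bed3") -> list[Interval]:
    """Parse a BED3/BED6/narrowPeak file into Intervals (Peaks for narrowPeak).

    Coordinates are taken as-is (BED is natively 0-based half-open). For
    narrowPeak, column 10 becomes ``summit_offset`` (-1 means absent).
    Malformed rows raise :class:`FormatError` naming the 1-based line number.
    """
    dialect = dialect.lower()
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    min_cols = _DIALECT_MIN_COLS[dialect]
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            try:
                if dialect == "narrowpeak":
                    summit = int(fields[9])
                    out.append(
                        Peak(
                            chrom,
                            start,
                            end,
                            id=name,
                            summit_offset=None if summit == -1 else summit,
                        )
                    )
                else:
                    out.append(Interval(chrom, start, end, id=name))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(
    path: str | Path, intervals: Sequence[Interval], dialect: str = "bed3"
) -> None:
    """Write intervals in the given BED dialect (inverse of :func:`parse_intervals`)."""
    dialect = dialect.lower()
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.id if iv.id is not None else "."
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\n")
            else:
                summit = getattr(iv, "summit_offset", None)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\t0\t-1\t-1\t"
                    f"{-1 if summit is None else summit}\n"
                )


# ---------------------------------------------------------------------------
# GTF subset I/O (features: gene, exon; attribute: gene_id)
# ---------------------------------------------------------------------------


def _gtf_attr(attr_field: str, key: str) -> str | None:
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key) :].strip().strip('"')
    return None


def parse_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a GTF subset (gene + exon features) into GeneModels.

    GTF is 1-based inclusive; coordinates are converted to 0-based
    half-open at this boundary. A missing ``gene_id`` attribute or an
    exon outside its gene raises :class:`FormatError`.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = fields[:9]
            if feature not in ("gene", "exon"):
                continue
            gene_id = _gtf_attr(attrs, "gene_id")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if feature == "gene":
                if gene_id in genes and "body" in genes[gene_id]:
                    raise FormatError(f"{path}:{lineno}: duplicate gene {gene_id}")
                rec = genes.setdefault(gene_id, {"exons": []})
                rec["body"] = (chrom, strand, start, end)
                if gene_id not in order:
                    order.append(gene_id)
            else:
                rec = genes.setdefault(gene_id, {"exons": []})
                rec["exons"].append((chrom, start, end))
    out: list[GeneModel] = []
    for gid in order:
        rec = genes[gid]
        chrom, strand, start, end = rec["body"]
        exons = tuple(Interval(c, s, e) for c, s, e in rec["exons"])
        for c, s, e in rec["exons"]:
            if c != chrom or s < start or e > end:
                raise FormatError(f"exon [{s},{e}) outside gene {gid}")
        out.append(GeneModel(gid, chrom, strand, start, end, exons))
    return out


def write_gene_models(path: str | Path, genes: Sequence[GeneModel]) -> None:
    """Write GeneModels as a GTF subset (inverse of :func:`parse_gene_models`)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\ttadlink\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\ttadlink\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_VALID_BASES = set("ACGTN")


def parse_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into id -> uppercase sequence over {A,C,G,T,N}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {rec.id}")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(f"sequence {rec.id} has invalid characters {sorted(bad)}")
        out[rec.id] = seq
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def harmonize_chrom_name(name: str, add_prefix: bool = True) -> str:
    """Normalize the 'chr' prefix dialect ('1' <-> 'chr1')."""
    has = name.startswith("chr")
    if add_prefix and not has:
        return "chr" + name
    if not add_prefix and has:
        return name[3:]
    return name
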