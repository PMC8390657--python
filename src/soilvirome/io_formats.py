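"""Readers and writers for the plain-text formats shared by all pipeline stages.

Every module in the package exchanges data through the containers defined
here.  One coordinate convention holds throughout: internal coordinates are
0-based half-open.  GFF3 is written 1-based inclusive and SAM ``POS`` is read
as 1-based; both conversions are applied exactly once, on I/O, and are
involutive (write followed by read restores the internal values).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("soilvirome")

VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

# CIGAR operations that consume read bases / reference bases
_READ_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")
_ALIGNED_OPS = frozenset("M=X")  # read bases aligned to the reference


class ParseError(ValueError):
    """A record could not be parsed; the message names the record."""


class SchemaError(ValueError):
    """A table is missing a required column; the message names it."""


# ---------------------------------------------------------------------------
# sequence records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneInterval:
    """A gene on a contig, 0-based half-open on the forward coordinate system."""

    start: int
    end: int
    strand: str = "+"
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ContigRecord:
    """A nucleotide sequence with optional gene annotations.

    The sequence is stored uppercase over {A, C, G, T, N}; characters outside
    that alphabet are mapped to N on construction (with a logged warning).
    """

    id: str
    sequence: str
    genes: list[GeneInterval] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("contig with empty id")
        seq = self.sequence.upper()
        n_bad = len(_NON_ACGTN.findall(seq))
        if n_bad:
            log.warning(
                "contig %s: %d non-ACGTN characters mapped to N", self.id, n_bad
            )
            seq = _NON_ACGTN.sub("N", seq)
        self.sequence = seq
        if not seq:
            raise ParseError(f"contig {self.id!r} has an empty sequence")
        if self.genes is not None:
            for g in self.genes:
                if g.end > len(seq):
                    raise ValueError(
                        f"contig {self.id}: gene {g.gene_id!r} exceeds contig length"
                    )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read a FASTA file into :class:`ContigRecord` objects.

    Lowercase input is uppercased; non-ACGTN characters become N with a
    warning.  An empty sequence raises :class:`ParseError` naming the record.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ContigRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[ContigRecord], path: str | Path) -> None:
    out = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    for r in out:
        if not r.id:
            raise ParseError("cannot write a record with an empty id")
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (gene intervals only)
# ---------------------------------------------------------------------------

def write_gff(genes: Mapping[str, Sequence[GeneInterval]], path: str | Path,
              source: str = "soilvirome") -> None:
    """Write gene intervals as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id in sorted(genes):
            for g in genes[contig_id]:
                attrs = f"ID={g.gene_id}" if g.gene_id else "."
                fh.write(
                    f"{contig_id}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def read_gff(path: str | Path) -> dict[str, list[GeneInterval]]:
    """Read GFF3 gene lines back into 0-based half-open intervals."""
    genes: dict[str, list[GeneInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns")
            contig_id, _, _, start, end, _, strand, _, attrs = parts
            gene_id = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            genes.setdefault(contig_id, []).append(
                GeneInterval(start=int(start) - 1, end=int(end),
                             strand=strand if strand in "+-" else "+",
                             gene_id=gene_id)
            )
    return genes


# ---------------------------------------------------------------------------
# SAM alignments
# ---------------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=X"


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-contig alignment.

    ``cigar`` is a tuple of (operation, length) pairs; ``contig_start`` is
    0-based.  ``mismatch_count`` is the NM-equivalent edit count within the
    aligned region, or ``None`` when the tag was absent on disk, in which
    case the record is *flagged* and refused by identity computations.
    """

    read_id: str
    contig_id: str
    contig_start: int
    cigar: tuple[tuple[str, int], ...]
    read_length: int
    mismatch_count: int | None

    @property
    def flagged(self) -> bool:
        return self.mismatch_count is None

    @property
    def aligned_read_bases(self) -> int:
        """Read bases aligned to the reference (CIGAR M/=/X)."""
        return sum(n for op, n in self.cigar if op in _ALIGNED_OPS)

    @property
    def aligned_ref_span(self) -> int:
        """Reference bases consumed by the alignment (M/=/X/D/N)."""
        return sum(n for op, n in self.cigar if op in _REF_OPS)

    @property
    def contig_end(self) -> int:
        return self.contig_start + self.aligned_ref_span

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    ops = tuple((op, int(n)) for n, op in _CIGAR_RE.findall(cigar))
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ParseError(f"malformed CIGAR string {cigar!r}")
    return ops


class SamRecords(list):
    """List of mapped primary :class:`AlignmentRecord` with exclusion counts."""

    def __init__(self, records: Iterable[AlignmentRecord] = (),
                 n_unmapped: int = 0, n_secondary: int = 0) -> None:
        super().__init__(records)
        self.n_unmapped = n_unmapped
        self.n_secondary = n_secondary


def read_sam(path: str | Path) -> SamRecords:
    """Read a SAM file, keeping only mapped primary alignments.

    Unmapped and secondary/supplementary records are excluded from the list
    (counted on the returned object) so downstream per-read counting never
    double-counts.  A mapped record without an NM tag is kept but flagged.
    """
    out = SamRecords()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                out.n_unmapped += 1
                continue
            if seg.is_secondary or seg.is_supplementary:
                out.n_secondary += 1
                continue
            cigar = tuple(
                (_CIGAR_OPS[op], length) for op, length in (seg.cigartuples or ())
            )
            nm = seg.get_tag("NM") if seg.has_tag("NM") else None
            read_length = seg.infer_read_length() or sum(
                n for op, n in cigar if op in _READ_OPS
            )
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name or "",
                    contig_id=seg.reference_name or "",
                    contig_start=seg.reference_start,
                    cigar=cigar,
                    read_length=read_length,
                    mismatch_count=int(nm) if nm is not None else None,
                )
            )
    if out.n_unmapped or out.n_secondary:
        log.info(
            "read_sam(%s): excluded %d unmapped, %d secondary/supplementary",
            path, out.n_unmapped, out.n_secondary,
        )
    return out


def write_sam(records: Iterable[AlignmentRecord],
              contig_lengths: Mapping[str, int],
              path: str | Path,
              sequences: Mapping[str, str] | None = None) -> None:
    """Write alignments as SAM with NM tags (POS written 1-based by pysam)."""
    names = sorted(contig_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(contig_lengths[n])} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for rec in records:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = rec.read_id
            seg.flag = 0
            seg.reference_id = names.index(rec.contig_id)
            seg.reference_start = rec.contig_start
            seg.mapping_quality = 60
            seg.cigarstring = rec.cigar_string()
            if sequences is not None and rec.read_id in sequences:
                seg.query_sequence = sequences[rec.read_id]
            if rec.mismatch_count is not None:
                seg.set_tag("NM", int(rec.mismatch_count))
            sam.write(seg)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path,
               required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a TSV with a named header; "NA" becomes a missing value, never 0.

    ``required`` columns are checked and a missing one raises
    :class:`SchemaError` naming it.  Unknown columns are preserved.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
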