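"""Readers and writers for the text formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython, SAM parsing to pysam and
Newick parsing to scikit-bio; this module adds the strict contracts the
pipeline relies on (unique ids, validated alphabets, 0-based half-open
coordinates, mandatory NM tags, deterministic binary resolution of
multifurcating trees).

Coordinate convention: everything downstream of SAM ingestion is 0-based
half-open; SAM's 1-based inclusive coordinates appear nowhere else.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from skbio import TreeNode

NUCLEOTIDE_CODES = set("ACGTURYSWKMBDHVN")
PROTEIN_CODES = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


class FormatError(ValueError):
    """A file violated one of the parsing contracts."""


@dataclass(frozen=True)
class SeqRecord:
    """A sequence with a whitespace-free id; stored uppercase."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read, in 0-based half-open reference coordinates.

    ``aligned_ref_len`` counts reference bases consumed (CIGAR M/=/X/D),
    ``aligned_read_len`` counts read bases aligned (CIGAR M/=/X/I) and
    ``edit_distance`` is the SAM NM tag.
    """

    read_id: str
    contig_id: str
    start: int
    end: int
    aligned_ref_len: int
    aligned_read_len: int
    edit_distance: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) for read {self.read_id}"
            )
        if self.edit_distance < 0:
            raise FormatError(f"negative edit distance for read {self.read_id}")


def _validate_sequence(rec_id: str, seq: str, alphabet: str | None) -> None:
    if not seq:
        raise FormatError(f"record {rec_id!r} has an empty sequence")
    if alphabet is None:
        return
    codes = NUCLEOTIDE_CODES if alphabet == "nucleotide" else PROTEIN_CODES
    bad = set(seq) - codes
    if bad:
        raise FormatError(
            f"record {rec_id!r} contains non-IUPAC {alphabet} characters: "
            f"{sorted(bad)}"
        )


def read_fasta(path: str | Path, alphabet: str | None = "nucleotide") -> list[SeqRecord]:
    """Read FASTA records in file order.

    Wrapped sequence lines are joined; the header is split at the first
    whitespace into id and description.  Duplicate ids, empty sequences
    and (when ``alphabet`` is given) non-IUPAC characters are errors.
    ``alphabet`` is ``"nucleotide"``, ``"protein"`` or ``None`` (skip
    validation).  An empty file yields an empty list.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        _validate_sequence(rec.id, seq, alphabet)
        desc = rec.description[len(rec.id) :].strip()
        records.append(SeqRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{quality_char * len(rec.sequence)}\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(SeqRecord(rec.id, str(rec.seq).upper()))
    return records


def _cigar_lengths(cigartuples: Sequence[tuple[int, int]]) -> tuple[int, int]:
    # pysam ops: 0=M 1=I 2=D 3=N 4=S 5=H 6=P 7== 8=X
    ref = sum(n for op, n in cigartuples if op in (0, 2, 3, 7, 8))
    read = sum(n for op, n in cigartuples if op in (0, 1, 7, 8))
    return ref, read


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read mapped records from a SAM file with @SQ headers.

    Unmapped and secondary/supplementary records are skipped.  A mapped
    record without an NM tag is an error: read identity is undefined
    without it.
    """
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if not aln.has_tag("NM"):
                raise FormatError(f"read {aln.query_name!r} lacks an NM tag")
            ref_len, read_len = _cigar_lengths(aln.cigartuples or [])
            out.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    contig_id=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_start + ref_len,
                    aligned_ref_len=ref_len,
                    aligned_read_len=read_len,
                    edit_distance=int(aln.get_tag("NM")),
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return out


def write_sam(
    path: str | Path,
    references: dict[str, int],
    alignments: Iterable[tuple[str, str, int, str, str, int]],
) -> None:
    """Write a minimal SAM file.

    ``alignments`` yields ``(read_id, contig_id, start0, strand, read_seq,
    edit_distance)`` tuples; reads are written with a full-length match
    CIGAR, which is exact for the substitution-only simulator.
    """
    names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": references[n]} for n in names],
    }
    idx = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for read_id, contig_id, start, strand, seq, nm in alignments:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = read_id
            a.query_sequence = seq
            a.flag = 16 if strand == "-" else 0
            a.reference_id = idx[contig_id]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("NM", nm)
            sam.write(a)


def read_newick(source: str | Path) -> TreeNode:
    """Parse a Newick tree into a binary-resolved rooted representation.

    Multifurcations are split deterministically with zero-length inserted
    edges; branch lengths absent from the input default to 1.0 so that
    downstream Brownian simulations are defined.  Tip labels are kept
    verbatim.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    stack: list[int] = []
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {pos}")
            stack.pop()
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    tree = TreeNode.read(io.StringIO(text), format="newick", convert_underscores=False)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 1.0
    tree.length = None
    tree.bifurcate(insert_length=0.0)
    return tree


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV with a header row; missing required columns are errors."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.rstrip("\n")]
    if not lines:
        raise FormatError(f"{path} has no header row")
    ncol = lines[0].count("\t") + 1
    for i, ln in enumerate(lines[1:], start=2):
        if ln.count("\t") + 1 != ncol:
            raise FormatError(f"{path}: ragged row at line {i}")
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed TSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path} is missing required column(s): {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
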