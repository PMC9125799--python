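"""Readers and writers for the plain-text formats the pipeline consumes.

Everything here is deliberately strict: the discovery pipeline's later stages
reason about *absence* of evidence (no database hit, no reads on a strand), so
silently dropped or misparsed records would bias results.  Formats handled:

* FASTA nucleotide/protein/aligned (via Biopython),
* BLAST/DIAMOND tabular ``outfmt 6`` (12+ columns, e-value in column 11),
* SAM text (flag/qname/rname only -- orientation is the only alignment
  evidence the pipeline uses),
* delimited Ct tables (qPCR quantification cycles; decimal commas tolerated
  because lab exports frequently use them).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Nucleotide alphabet retained on read; anything else becomes ``N``.
VALID_NT = frozenset("ACGTN")


@dataclass(frozen=True)
class Contig:
    """A nucleotide sequence record (assembled contig or genome segment)."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignedRead:
    """Minimal view of one SAM alignment record.

    ``is_reverse`` is only meaningful for mapped reads; ``is_first_in_pair``
    is ``None`` for single-end reads.
    """

    read_id: str
    ref_id: str
    is_mapped: bool
    is_reverse: bool | None
    is_first_in_pair: bool | None


def _clean_seq(record_id: str, raw: str) -> str:
    seq = raw.upper()
    bad = [c for c in set(seq) if c not in VALID_NT]
    if bad:
        n_bad = sum(seq.count(c) for c in bad)
        logger.warning(
            "contig %s: %d non-ACGTN characters (%s) replaced by N",
            record_id, n_bad, ",".join(sorted(bad)),
        )
        seq = "".join(c if c in VALID_NT else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a nucleotide FASTA into a list of :class:`Contig`.

    Sequences are uppercased; characters outside ``{A,C,G,T,N}`` (IUPAC
    ambiguity codes etc.) are replaced by ``N`` with a logged warning.
    Duplicate ids and empty sequences are hard errors.
    """
    path = Path(path)
    seen: set[str] = set()
    out: list[Contig] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: FASTA record with empty id")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(Contig(id=rec.id, seq=_clean_seq(rec.id, seq)))
    return out


def write_fasta(records: Iterable[Contig | tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write ``(id, seq)`` pairs (or Contigs) as wrapped FASTA."""
    seqrecs = []
    for rec in records:
        rid, seq = (rec.id, rec.seq) if isinstance(rec, Contig) else rec
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_protein_fasta(path: str | Path,
                       require_equal_length: bool = False) -> list[tuple[str, str]]:
    """Read a protein (optionally aligned) FASTA as ``(id, seq)`` pairs.

    Gap characters ``-`` are preserved; sequences are uppercased.  With
    ``require_equal_length`` the rows must form a rectangular MSA.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        pairs.append((rec.id, str(rec.seq).upper()))
    if require_equal_length and len({len(s) for _, s in pairs}) > 1:
        raise ValueError(f"{path}: aligned FASTA rows have unequal lengths")
    return pairs


def read_hits_table(path: str | Path, evalue_max: float) -> set[str]:
    """Collect query ids with at least one hit at ``evalue <= evalue_max``.

    Input is BLAST/DIAMOND tabular ``outfmt 6``: tab-separated, >=12 columns,
    e-value in column 11.  Lines with fewer than 12 columns are counted and
    reported as malformed; an unparseable e-value is a hard error naming the
    line.
    """
    path = Path(path)
    hits: set[str] = set()
    n_malformed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                n_malformed += 1
                continue
            try:
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: unparseable e-value {fields[10]!r}"
                ) from exc
            if evalue < 0 or math.isnan(evalue):
                raise ValueError(f"{path}: line {lineno}: invalid e-value {evalue}")
            if evalue <= evalue_max:
                hits.add(fields[0])
    if n_malformed:
        logger.warning("%s: %d malformed lines (<12 columns) skipped",
                       path, n_malformed)
    return hits


# SAM flag bits consumed here.
_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_FIRST = 0x40
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


def read_alignments(path: str | Path) -> Iterator[AlignedRead]:
    """Stream SAM text as :class:`AlignedRead`.

    Header lines are skipped.  Secondary (0x100) and supplementary (0x800)
    records are never yielded; unmapped records (0x4) come out with
    ``is_mapped=False``.  Only flag, read name and reference name are
    consumed.  A record with fewer than 11 tab-separated fields is a hard
    error with its line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("@"):
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: truncated SAM record "
                    f"({len(fields)} fields)")
            try:
                flag = int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer FLAG {fields[1]!r}"
                ) from exc
            if flag & (_FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
                continue
            mapped = not flag & _FLAG_UNMAPPED
            yield AlignedRead(
                read_id=fields[0],
                ref_id=fields[2],
                is_mapped=mapped,
                is_reverse=bool(flag & _FLAG_REVERSE) if mapped else None,
                is_first_in_pair=(bool(flag & _FLAG_FIRST)
                                  if flag & _FLAG_PAIRED else None),
            )


def _sniff_delimiter(header: str) -> str:
    if "\t" in header:
        return "\t"
    if ";" in header:
        return ";"
    return ","


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table (rows = assays/segments, columns = samples).

    Returns a float DataFrame with ``NaN`` for missing (blank) cells.
    Decimal commas ("24,67") are accepted when the cell delimiter is tab or
    semicolon.  Any non-numeric non-blank cell is a hard error naming its
    row and column; Ct values must be positive.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False)
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for row in raw.index:
        for col in raw.columns:
            cell = str(raw.at[row, col]).strip()
            if cell == "":
                out.at[row, col] = float("nan")
                continue
            if sep != ",":
                cell = cell.replace(",", ".")
            try:
                value = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric Ct cell at row {row!r}, "
                    f"column {col!r}: {raw.at[row, col]!r}") from exc
            if value <= 0:
                raise ValueError(
                    f"{path}: non-positive Ct at row {row!r}, column {col!r}")
            out.at[row, col] = value
    return out


def write_ct_table(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a Ct table with blank cells for missing values."""
    table.to_csv(path, sep=sep, na_rep="", float_format="%.2f")


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read a per-library read-count table (rows = segments, cols = libraries)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.fillna(0).astype(float)
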