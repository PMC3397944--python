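"""Readers and writers for every external format the pipeline touches.

Covers FASTA sequence files, SOLiD CSFASTA colorspace files (with dibase
decoding), GFF3 gene models, two-column barcode index tables, and the
tab-separated report files produced by the downstream stages.

Coordinate convention: everything internal is 0-based half-open; 1-based
closed coordinates exist only at the GFF3 boundary.
"""

from __future__ import annotations

import io
import os
from collections import OrderedDict
from dataclasses import dataclass
from typing import IO, Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from gffutils.feature import feature_from_line

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named base-space sequence over {A,C,G,T,N}."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ColorspaceRecord:
    """A SOLiD read: a primer base followed by a string of color calls."""

    id: str
    primer_base: str
    colors: str

    def __post_init__(self) -> None:
        if self.primer_base not in "ACGT":
            raise FormatError(
                f"record {self.id!r}: primer base {self.primer_base!r} not in A/C/G/T"
            )
        if not self.colors:
            raise FormatError(f"record {self.id!r}: empty color string")
        bad = set(self.colors) - set("0123.")
        if bad:
            raise FormatError(f"record {self.id!r}: invalid color calls {sorted(bad)}")


@dataclass
class IndexTable:
    """Ordered mapping sample_id -> barcode index sequence."""

    entries: "OrderedDict[str, str]"
    index_length: int = 6

    def __post_init__(self) -> None:
        self.entries = OrderedDict(self.entries)
        for sample, idx in self.entries.items():
            if len(idx) != self.index_length:
                raise FormatError(
                    f"index for sample {sample!r} has length {len(idx)}, "
                    f"expected {self.index_length}"
                )
        indices = list(self.entries.values())
        if len(set(indices)) != len(indices):
            raise FormatError("index sequences are not pairwise distinct")

    @property
    def samples(self) -> list[str]:
        return list(self.entries)

    def by_index(self) -> dict[str, str]:
        return {idx: sample for sample, idx in self.entries.items()}


@dataclass
class GeneModel:
    """A strand-aware gene interval, 0-based half-open internally."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id!r}: strand must be + or -")


PathOrHandle = Union[str, os.PathLike, IO[str]]


def _as_handle(source: PathOrHandle, mode: str = "r"):
    """Return (handle, needs_close) for a path or an open text handle."""
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode), True
    return source, False


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(source: PathOrHandle) -> list[SequenceRecord]:
    """Parse FASTA text into :class:`SequenceRecord` objects, order preserved."""
    handle, close = _as_handle(source)
    try:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SequenceRecord(rec.id, str(rec.seq), desc))
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord], dest: PathOrHandle) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        bio = [
            _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
            for r in records
        ]
        SeqIO.write(bio, handle, "fasta")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# CSFASTA and dibase colorspace

# Color c maps base b to DIBASE[b][c]: color 0 preserves the base, 1 swaps
# A<->C and G<->T, 2 swaps A<->G and C<->T, 3 swaps A<->T and C<->G.
DIBASE = {
    "A": "ACGT",
    "C": "CATG",
    "G": "GTAC",
    "T": "TGCA",
}
# Inverse: _ENCODE[(prev, cur)] -> color character.
_ENCODE = {
    (b, DIBASE[b][c]): str(c) for b in "ACGT" for c in range(4)
}


def read_csfasta(source: PathOrHandle) -> list[ColorspaceRecord]:
    """Parse SOLiD CSFASTA: '#' comments, '>' headers, primer base + colors."""
    handle, close = _as_handle(source)
    try:
        records: list[ColorspaceRecord] = []
        header: str | None = None
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise FormatError(f"line {lineno}: empty CSFASTA header")
                continue
            if header is None:
                raise FormatError(f"line {lineno}: sequence line before any header")
            if line[0] not in "ACGT":
                raise FormatError(
                    f"line {lineno}: record {header!r} does not start with a "
                    f"primer base (got {line[0]!r})"
                )
            records.append(ColorspaceRecord(header, line[0], line[1:]))
            header = None
        return records
    finally:
        if close:
            handle.close()


def write_csfasta(records: Iterable[ColorspaceRecord], dest: PathOrHandle) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        for r in records:
            handle.write(f">{r.id}\n{r.primer_base}{r.colors}\n")
    finally:
        if close:
            handle.close()


def decode_colorspace(record: ColorspaceRecord) -> SequenceRecord:
    """Decode a colorspace read to base space.

    The primer base seeds the chain but is not emitted. A '.' (missing call)
    decodes to N and, because decoding is sequential, poisons every
    downstream base to N as well.
    """
    out = []
    prev = record.primer_base
    poisoned = False
    for color in record.colors:
        if poisoned or color == ".":
            out.append("N")
            poisoned = True
        else:
            prev = DIBASE[prev][int(color)]
            out.append(prev)
    return SequenceRecord(record.id, "".join(out))


def encode_colorspace(record: SequenceRecord, primer_base: str = "T") -> ColorspaceRecord:
    """Encode a base-space sequence as a colorspace read (inverse of decode).

    Only defined for sequences without N.
    """
    if "N" in record.sequence:
        raise ValueError(f"cannot colorspace-encode {record.id!r}: contains N")
    colors = []
    prev = primer_base
    for base in record.sequence:
        colors.append(_ENCODE[(prev, base)])
        prev = base
    return ColorspaceRecord(record.id, primer_base, "".join(colors))


# ---------------------------------------------------------------------------
# GFF3 gene models

def read_gene_models(source: PathOrHandle) -> list[GeneModel]:
    """Read rows of type 'gene' from GFF3, converting to 0-based half-open."""
    handle, close = _as_handle(source)
    try:
        genes: list[GeneModel] = []
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"line {lineno}: unparseable GFF3 row: {exc}") from exc
            if feat.featuretype != "gene":
                continue
            if feat.end < feat.start:
                raise FormatError(
                    f"line {lineno}: end ({feat.end}) < start ({feat.start})"
                )
            if feat.strand not in "+-":
                raise FormatError(
                    f"line {lineno}: gene strand must be + or -, got {feat.strand!r}"
                )
            gid = (
                feat.attributes.get("ID", [None])[0]
                or feat.attributes.get("Name", [None])[0]
                or f"gene_line{lineno}"
            )
            genes.append(
                GeneModel(gid, feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
        return genes
    finally:
        if close:
            handle.close()


def write_gene_models(genes: Iterable[GeneModel], dest: PathOrHandle) -> None:
    """Write gene models as GFF3 (back to 1-based closed coordinates)."""
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("##gff-version 3\n")
        for g in genes:
            handle.write(
                f"{g.seq_id}\tsagetag\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Index table

def read_index_table(source: PathOrHandle, index_length: int = 6) -> IndexTable:
    """Read a two-column sample_id<TAB>index TSV."""
    handle, close = _as_handle(source)
    try:
        entries: "OrderedDict[str, str]" = OrderedDict()
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"line {lineno}: expected sample_id<TAB>index, got {line!r}"
                )
            sample, idx = parts
            if sample in entries:
                raise FormatError(f"line {lineno}: duplicate sample id {sample!r}")
            entries[sample] = idx.upper()
        return IndexTable(entries, index_length=index_length)
    finally:
        if close:
            handle.close()


def write_index_table(table: IndexTable, dest: PathOrHandle) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        for sample, idx in table.entries.items():
            handle.write(f"{sample}\t{idx}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# TSV reports

def write_report(rows, dest: PathOrHandle) -> None:
    """Write a tab-separated report with a '#'-prefixed header line.

    ``rows`` is a DataFrame or a list of dicts sharing one schema. Tables
    carrying 'tag' and 'total' columns are sorted by descending total with
    lexicographic tag tie-break, so diffs between runs are stable.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = list(rows)
        if rows:
            schema = list(rows[0].keys())
            for i, r in enumerate(rows):
                if list(r.keys()) != schema:
                    raise FormatError(f"row {i} does not share the report schema")
        df = pd.DataFrame(rows)
    if "tag" in df.columns and "total" in df.columns and len(df):
        df = df.sort_values(
            ["total", "tag"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("#" + "\t".join(map(str, df.columns)) + "\n")
        if len(df):
            df.to_csv(handle, sep="\t", header=False, index=False)
    finally:
        if close:
            handle.close()


def read_report(source: PathOrHandle) -> pd.DataFrame:
    handle, close = _as_handle(source)
    try:
        header = handle.readline()
        if not header.startswith("#"):
            raise FormatError("report missing '#'-prefixed header line")
        columns = header[1:].rstrip("\n").split("\t")
        body = handle.read()
        if not body.strip():
            return pd.DataFrame(columns=columns)
        return pd.read_csv(io.StringIO(body), sep="\t", names=columns)
    finally:
        if close:
            handle.close()
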