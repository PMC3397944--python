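"""Exact-match mapping of 26-bp tags to a partitioned reference.

The reference is split into four named partitions — the X chromosome BACs,
the hermaphrodite Y (Yh) BACs, the rest of the nuclear genome, and the
organelle (chloroplast + mitochondrion) genomes. Mapping is perfect-match
only, on both strands, via a k-mer index with k equal to the tag length;
tags one mismatch away from a reference site deliberately do not map.

Each mapped tag gets exactly one of six disjoint categories:
X_specific, Yh_specific, XYh_shared (sex-chromosome-specific tags),
sex_plus_nuclear, sex_plus_organelle (sex hits with extra genomic copies),
or non_SC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .io_formats import SequenceRecord, reverse_complement

PARTITIONS = ("X", "Yh", "other_nuclear", "organelle")
SEX_PARTITIONS = frozenset({"X", "Yh"})

CATEGORIES = (
    "X_specific",
    "Yh_specific",
    "XYh_shared",
    "sex_plus_nuclear",
    "sex_plus_organelle",
    "non_SC",
)
#: the three categories that make up the sex-chromosome-specific tag set
SEX_SPECIFIC_CATEGORIES = ("X_specific", "Yh_specific", "XYh_shared")


class TagHit(NamedTuple):
    """One perfect-match placement of a tag on the reference.

    ``start`` is always the 0-based forward-strand coordinate of the matched
    window; for '-' hits the tag equals the reverse complement of that
    window.
    """

    tag: str
    partition: str
    seq_id: str
    start: int
    strand: str


@dataclass
class SCClassification:
    tag: str
    hits: list[TagHit]
    category: str


@dataclass
class ReferenceSet:
    """Named sequence partitions; ids must be unique across the whole set."""

    partitions: dict[str, list[SequenceRecord]]

    def __post_init__(self) -> None:
        bad = set(self.partitions) - set(PARTITIONS)
        if bad:
            raise ValueError(f"unknown partition names: {sorted(bad)}")
        ids = [r.id for recs in self.partitions.values() for r in recs]
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids are not unique across the reference set")

    def iter_sequences(self) -> Iterable[tuple[str, SequenceRecord]]:
        for name in PARTITIONS:
            for rec in self.partitions.get(name, []):
                yield name, rec

    def get(self, seq_id: str) -> tuple[str, SequenceRecord]:
        for name, rec in self.iter_sequences():
            if rec.id == seq_id:
                return name, rec
        raise KeyError(seq_id)


@dataclass
class TagIndex:
    """k-mer -> placements lookup covering both strands of every sequence."""

    k: int
    entries: dict[str, list[tuple[str, str, int, str]]] = field(default_factory=dict)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries


def build_index(refs: ReferenceSet, k: int = 26) -> TagIndex:
    """Index every k-mer position of every reference sequence, both strands.

    '-' strand entries are keyed by the reverse complement of the forward
    window and store the forward-strand start, so a query hit immediately
    gives the window to excise. Windows containing N are skipped.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    index = TagIndex(k)
    entries = index.entries
    for partition, rec in refs.iter_sequences():
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            entries.setdefault(kmer, []).append((partition, rec.id, i, "+"))
            entries.setdefault(reverse_complement(kmer), []).append(
                (partition, rec.id, i, "-")
            )
    return index


def map_tag(tag: str, index: TagIndex) -> list[TagHit]:
    """All exact-match placements of ``tag``, in deterministic order."""
    if len(tag) != index.k:
        raise ValueError(f"tag length {len(tag)} != index k {index.k}")
    raw = index.entries.get(tag, [])
    hits = {TagHit(tag, *entry) for entry in raw}
    return sorted(hits, key=lambda h: (h.partition, h.seq_id, h.start, h.strand))


def brute_force_scan(tag: str, refs: ReferenceSet) -> list[TagHit]:
    """Naive both-strand substring scan; the independent oracle for map_tag."""
    hits: set[TagHit] = set()
    rc = reverse_complement(tag)
    for partition, rec in refs.iter_sequences():
        seq = rec.sequence
        for query, strand in ((tag, "+"), (rc, "-")):
            pos = seq.find(query)
            while pos >= 0:
                hits.add(TagHit(tag, partition, rec.id, pos, strand))
                pos = seq.find(query, pos + 1)
    return sorted(hits, key=lambda h: (h.partition, h.seq_id, h.start, h.strand))


def classify_tag(hits: list[TagHit]) -> str:
    """Disjoint category from the set of partitions a tag hits.

    No sex-chromosome hit -> non_SC. A sex hit plus any other_nuclear hit ->
    sex_plus_nuclear (nuclear takes precedence over organelle when both
    co-occur). A sex hit plus organelle only -> sex_plus_organelle.
    Sex-only hits split into X_specific / Yh_specific / XYh_shared.
    """
    partitions = {h.partition for h in hits}
    sex = partitions & SEX_PARTITIONS
    if not sex:
        return "non_SC"
    if "other_nuclear" in partitions:
        return "sex_plus_nuclear"
    if "organelle" in partitions:
        return "sex_plus_organelle"
    if sex == {"X"}:
        return "X_specific"
    if sex == {"Yh"}:
        return "Yh_specific"
    return "XYh_shared"


def classify_tags(tags: Iterable[str], index: TagIndex) -> dict[str, SCClassification]:
    """Map and classify a collection of tags."""
    out = {}
    for tag in tags:
        hits = map_tag(tag, index)
        out[tag] = SCClassification(tag, hits, classify_tag(hits))
    return out


def format_hits(hits: list[TagHit]) -> str:
    """Serialize hits for report files: partition:seq:start:strand;..."""
    return ";".join(f"{h.partition}:{h.seq_id}:{h.start}:{h.strand}" for h in hits)
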