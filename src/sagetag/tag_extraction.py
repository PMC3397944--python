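"""Barcode demultiplexing, 26-bp tag extraction, and tag-count matrices.

SuperSAGE reads look like ``<6-base index><CATG><22 variable bases><filler>``.
A read is assigned to a sample only if its leading bases equal one of the
barcode indices exactly and it carries the NlaIII anchor (CATG) downstream
of the index. The tag is the 26-base window starting at the first anchor
occurrence, leading CATG included.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import IndexTable, SequenceRecord

#: reasons a read can be dropped before or during tag extraction
DISCARD_REASONS = ("has_N", "bad_index", "no_anchor", "short_tag", "tag_has_N")


@dataclass
class ReadLayout:
    """Geometry of a SuperSAGE read."""

    index_length: int = 6
    tag_offset: int = 0  # anchor expected at/after index_length + tag_offset
    tag_length: int = 26
    anchor: str = "CATG"

    def __post_init__(self) -> None:
        if self.tag_length < len(self.anchor):
            raise ValueError("tag_length shorter than the anchor")
        if self.index_length < 1:
            raise ValueError("index_length must be >= 1")


@dataclass
class TagProfile:
    """Per-sample tag multiset (the digital expression profile)."""

    sample_id: str
    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def unique(self) -> int:
        return len(self.counts)


@dataclass
class TagMatrix:
    """Tag-by-sample count table with per-row totals."""

    samples: list[str]
    counts: pd.DataFrame  # index: tag, columns: samples, dtype int

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples):
            raise ValueError("count columns do not match the sample order")

    @property
    def total(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def tags(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df.insert(0, "tag", df.index)
        df["total"] = self.total.values
        return df.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TagMatrix":
        samples = [c for c in df.columns if c not in ("tag", "total")]
        counts = df.set_index("tag")[samples].astype(int)
        counts.index.name = None
        return cls(samples, counts)


def demultiplex(
    reads: list[SequenceRecord],
    table: IndexTable,
    layout: ReadLayout | None = None,
) -> tuple[dict[str, list[SequenceRecord]], Counter]:
    """Assign reads to samples by exact barcode match.

    A read goes to sample ``s`` iff its first ``index_length`` bases equal
    the index of ``s`` exactly and the anchor occurs at or after the index.
    Unassigned reads are tallied by reason (has_N / bad_index / no_anchor);
    assigned + discarded always equals the input count.
    """
    layout = layout or ReadLayout()
    by_index = table.by_index()
    assigned: dict[str, list[SequenceRecord]] = {s: [] for s in table.samples}
    discards: Counter = Counter()
    for read in reads:
        seq = read.sequence
        if "N" in seq:
            discards["has_N"] += 1
            continue
        sample = by_index.get(seq[: layout.index_length])
        if sample is None:
            discards["bad_index"] += 1
            continue
        if seq.find(layout.anchor, layout.index_length + layout.tag_offset) < 0:
            discards["no_anchor"] += 1
            continue
        assigned[sample].append(read)
    return assigned, discards


def extract_tag(
    read: SequenceRecord, layout: ReadLayout | None = None
) -> tuple[str | None, str | None]:
    """Extract the anchored tag from an assigned read.

    Returns ``(tag, None)`` on success or ``(None, reason)`` when the read
    is unusable (anchor missing, too few bases left after the anchor, or an
    N inside the tag window). The first anchor occurrence at or after the
    index is used.
    """
    layout = layout or ReadLayout()
    pos = read.sequence.find(layout.anchor, layout.index_length + layout.tag_offset)
    if pos < 0:
        return None, "no_anchor"
    tag = read.sequence[pos : pos + layout.tag_length]
    if len(tag) < layout.tag_length:
        return None, "short_tag"
    if "N" in tag:
        return None, "tag_has_N"
    return tag, None


def build_profile(sample_id: str, tags: list[str]) -> TagProfile:
    """Tally a list of extracted tags into a profile."""
    return TagProfile(sample_id, Counter(tags))


def extract_profile(
    sample_id: str,
    reads: list[SequenceRecord],
    layout: ReadLayout | None = None,
) -> tuple[TagProfile, Counter]:
    """Run extract_tag over a sample's reads and tally failures."""
    tags = []
    reasons: Counter = Counter()
    for read in reads:
        tag, reason = extract_tag(read, layout)
        if tag is None:
            reasons[reason] += 1
        else:
            tags.append(tag)
    return build_profile(sample_id, tags), reasons


def nonsingleton_count(profile: TagProfile, min_count: int = 2) -> int:
    """Number of distinct tags with count >= min_count."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return sum(1 for c in profile.counts.values() if c >= min_count)


def combine_profiles(
    profiles: list[TagProfile], sample_order: list[str] | None = None
) -> TagMatrix:
    """Union per-sample profiles into one tag-by-sample matrix (absent = 0)."""
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample_id among profiles")
    order = sample_order if sample_order is not None else ids
    if set(order) != set(ids):
        raise ValueError("sample_order does not match the profiles")
    by_id = {p.sample_id: p for p in profiles}
    all_tags = sorted(set().union(*(p.counts.keys() for p in profiles))) if profiles else []
    data = {
        s: [by_id[s].counts.get(t, 0) for t in all_tags] for s in order
    }
    counts = pd.DataFrame(data, index=all_tags, dtype=int)
    return TagMatrix(list(order), counts)


def filter_by_total(matrix: TagMatrix, min_total: int = 10) -> TagMatrix:
    """Keep rows whose combined count is strictly greater than min_total."""
    keep = matrix.total > min_total
    return TagMatrix(matrix.samples, matrix.counts.loc[keep])
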