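"""Upstream-window logic, gene association, and X-allele search.

SuperSAGE tags sit near transcript 3' ends, so the gene body lies upstream
(5') of the CATG anchor on the tag's matched strand. This module builds
strand-aware upstream windows, intersects them with gene models (the
"within 2 kb upstream" rule), exports upstream sequence for annotation
hooks, and searches the X partition for allele candidates of Yh-specific
tags by Smith-Waterman local alignment (the in-repo stand-in for a BLASTN
allele search, with a fixed deterministic traceback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .io_formats import GeneModel, SequenceRecord, reverse_complement
from .reference_mapping import ReferenceSet, TagHit

#: default local-alignment scoring, chosen to rank like BLASTN defaults
DEFAULT_SCORING = {"match": 2, "mismatch": -1, "gap_open": -2, "gap_extend": -2}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class UpstreamWindow:
    seq_id: str
    start: int
    end: int
    strand: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")


@dataclass
class AlignmentResult:
    """A local alignment: score, identity over aligned columns, and spans."""

    score: int
    identity: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    target_id: str = ""
    strand: str = "+"
    n_columns: int = 0
    n_matches: int = 0


def upstream_window(
    hit: TagHit, length: int, ref_length: int | None = None
) -> UpstreamWindow:
    """The ``length``-bp window 5' of the tag anchor on the matched strand.

    '+' hits look left of the tag start; '-' hits look right of the tag end
    (their transcript runs leftward). Windows are clipped at sequence ends
    and flagged as truncated.
    """
    if length <= 0:
        raise ValueError("window length must be positive")
    tag_len = len(hit.tag)
    if hit.start < 0 or (ref_length is not None and hit.start + tag_len > ref_length):
        raise ValueError(f"hit at {hit.start} lies outside sequence {hit.seq_id}")
    if hit.strand == "+":
        start = max(0, hit.start - length)
        end = hit.start
        truncated = hit.start - length < 0
    else:
        start = hit.start + tag_len
        end = start + length
        truncated = False
        if ref_length is not None and end > ref_length:
            end = ref_length
            truncated = True
    return UpstreamWindow(hit.seq_id, start, end, hit.strand, truncated)


def genes_within_upstream(
    hit: TagHit,
    genes: list[GeneModel],
    window: int = 2000,
    ref_length: int | None = None,
    stranded: bool = True,
) -> list[str]:
    """Gene ids overlapping the upstream window by at least one base.

    With ``stranded=False`` the window covers both flanks of the tag.
    Results are ordered by proximity of the gene to the tag anchor, ties
    broken by gene id.
    """
    if stranded:
        win = upstream_window(hit, window, ref_length)
        w_start, w_end = win.start, win.end
    else:
        w_start = max(0, hit.start - window)
        w_end = hit.start + len(hit.tag) + window
        if ref_length is not None:
            w_end = min(w_end, ref_length)
    anchor = hit.start if hit.strand == "+" else hit.start + len(hit.tag)
    found = []
    for g in genes:
        if g.seq_id != hit.seq_id:
            continue
        if g.start < w_end and g.end > w_start:
            dist = max(0, anchor - g.end, g.start - anchor)
            found.append((dist, g.gene_id))
    return [gid for _, gid in sorted(found)]


# An empty upstream window is a legitimate (flagged) outcome, but
# SequenceRecord requires a non-empty id only; empty sequences are allowed
# here and marked in the description.
def _make_upstream_record(name: str, seq: str) -> SequenceRecord:
    if seq:
        return SequenceRecord(name, seq)
    rec = SequenceRecord.__new__(SequenceRecord)
    rec.id = name
    rec.sequence = ""
    rec.description = "empty-after-truncation"
    return rec


def extract_upstream(
    hit: TagHit, refs: ReferenceSet, length: int
) -> tuple[SequenceRecord, bool]:
    """Excise the upstream window, oriented 5'->3' toward the anchor.

    '-' strand hits return the reverse complement of the forward window.
    Returns ``(record, truncated)``; a hit flush with the sequence end
    yields an empty-sequence record with the truncation flag set.
    """
    _, rec = refs.get(hit.seq_id)
    win = upstream_window(hit, length, ref_length=len(rec.sequence))
    seq = rec.sequence[win.start : win.end]
    if hit.strand == "-":
        seq = reverse_complement(seq)
    name = f"{hit.tag}|{hit.seq_id}|{win.start}-{win.end}({hit.strand})"
    return _make_upstream_record(name, seq), win.truncated or not seq


@njit(cache=True)
def _sw_fill(q, t, match, mismatch, gap):  # pragma: no cover - numba kernel
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            tj = t[j - 1]
            if qi == 4 or tj == 4:  # N never matches
                s = mismatch
            elif qi == tj:
                s = match
            else:
                s = mismatch
            v = H[i - 1, j - 1] + s
            u = H[i - 1, j] + gap
            if u > v:
                v = u
            w = H[i, j - 1] + gap
            if w > v:
                v = w
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return H, best, bi, bj


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper()
        .translate(str.maketrans("ACGTN", "\x00\x01\x02\x03\x04"))
        .encode("latin1"),
        dtype=np.uint8,
    )


def local_align(
    query: str,
    target: str,
    scoring: dict | None = None,
    target_id: str = "",
    strand: str = "+",
) -> AlignmentResult:
    """Smith-Waterman local alignment with linear gap costs.

    N never matches anything. Traceback is deterministic: among co-optimal
    predecessors, diagonal wins, then the vertical (query-consuming) move,
    then the horizontal one; among co-optimal end cells the first in
    row-major order wins. Identity is matches / aligned columns, gap
    columns included.
    """
    sc = dict(DEFAULT_SCORING)
    if scoring:
        sc.update(scoring)
    if sc["gap_open"] != sc["gap_extend"]:
        raise ValueError("only linear gap costs (gap_open == gap_extend) supported")
    gap = sc["gap_open"]
    match, mismatch = sc["match"], sc["mismatch"]
    if not query or not target:
        return AlignmentResult(0, 0.0, (0, 0), (0, 0), target_id, strand)
    q = _encode(query)
    t = _encode(target)
    H, best, bi, bj = _sw_fill(q, t, match, mismatch, gap)
    if best == 0:
        return AlignmentResult(0, 0.0, (0, 0), (0, 0), target_id, strand)
    i, j = int(bi), int(bj)
    n_cols = 0
    n_matches = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        qi, tj = q[i - 1], t[j - 1]
        s = match if (qi == tj and qi != 4) else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            n_cols += 1
            if qi == tj and qi != 4:
                n_matches += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            n_cols += 1
            i -= 1
        else:
            n_cols += 1
            j -= 1
    return AlignmentResult(
        int(best),
        n_matches / n_cols if n_cols else 0.0,
        (i, int(bi)),
        (j, int(bj)),
        target_id,
        strand,
        n_cols,
        n_matches,
    )


def find_x_allele(
    yh_hit: TagHit,
    refs: ReferenceSet,
    upstream_length: int = 1000,
    min_identity: float = 0.80,
    min_aligned: int = 100,
    scoring: dict | None = None,
) -> list[AlignmentResult]:
    """Search the X partition for an allele of a Yh-specific tag's gene.

    The ~1 kb of genomic sequence upstream of the tag is aligned against
    both strands of every X sequence; alignments with identity strictly
    above ``min_identity`` over at least ``min_aligned`` columns are
    returned in best-score order.
    """
    if yh_hit.partition != "Yh":
        raise ValueError("allele search is defined for Yh-partition hits")
    query_rec, _ = extract_upstream(yh_hit, refs, upstream_length)
    query = query_rec.sequence
    if not query:
        return []
    results = []
    for rec in refs.partitions.get("X", []):
        for target, strand in ((rec.sequence, "+"), (reverse_complement(rec.sequence), "-")):
            res = local_align(query, target, scoring, target_id=rec.id, strand=strand)
            if res.identity > min_identity and res.n_columns >= min_aligned:
                results.append(res)
    results.sort(key=lambda r: (-r.score, r.target_id, r.strand))
    return results
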