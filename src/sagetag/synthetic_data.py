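"""Seeded simulator of the six-sample SuperSAGE study design.

Emulates: a partitioned reference (X / Yh / other nuclear / organelle) with
planted 26-bp CATG-anchored tag sites of every mapping category, gene
models placed inside and outside the 2-kb upstream windows, X-chromosome
allele copies of Yh upstream regions at configurable divergence, and pooled
indexed reads (optionally colorspace-encoded) with Poisson-sampled counts
under per-sex expression patterns plus a controlled fraction of junk reads.

Everything is driven by one integer seed; a fixed seed gives byte-identical
outputs. The ground truth (categories, positions, patterns, allele
identities) is machine-readable so every downstream stage can be verified
end to end without any external data.
"""

from __future__ import annotations

import json
import os
from collections import OrderedDict
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .io_formats import (
    ColorspaceRecord,
    GeneModel,
    IndexTable,
    SequenceRecord,
    encode_colorspace,
    reverse_complement,
    write_fasta,
    write_csfasta,
    write_gene_models,
    write_index_table,
)
from .reference_mapping import ReferenceSet, build_index, map_tag

#: the study's six barcode indices (P1..P6)
DEFAULT_INDEXES = OrderedDict(
    [
        ("P1", "ACACAA"),
        ("P2", "ATAGAG"),
        ("P3", "AGAGTG"),
        ("P4", "AGGCTG"),
        ("P5", "CCGAAG"),
        ("P6", "CGGATG"),
    ]
)

#: sample -> (sex type, stage); males P1/P2, females P3/P4, hermaphrodites P5/P6
DEFAULT_SAMPLE_SEX = {
    "P1": "M",
    "P2": "M",
    "P3": "F",
    "P4": "F",
    "P5": "H",
    "P6": "H",
}

_BASES = np.array(list("ACGT"))

# expression patterns cycled over planted tags, per category; Yh-linked
# transcripts show up in males and hermaphrodites (both carry a Y variant),
# never females, matching the genetics of the system
_PATTERN_CYCLE = {
    "X_specific": ["MFH", "FH", "MH", "H", "MFH"],
    "Yh_specific": ["MH", "H"],
    "XYh_shared": ["MFH"],
    "sex_plus_nuclear": ["MFH"],
    "sex_plus_organelle": ["MFH"],
    "non_SC": ["MFH"],
}

_SLOT_FIRST = 2600
_SLOT_STEP = 2600


class GenerationError(RuntimeError):
    """The simulator could not satisfy its uniqueness/placement contract."""


@dataclass
class SimulationConfig:
    """All dials of the simulator, with the study design as defaults."""

    seed: int = 0
    n_x_specific: int = 10
    n_yh_specific: int = 3
    n_shared: int = 2
    n_multi_nuclear: int = 4
    n_organelle: int = 1
    n_non_sc: int = 5
    partition_lengths: dict = field(
        default_factory=lambda: {
            "X": 46000,
            "Yh": 20000,
            "other_nuclear": 25000,
            "organelle": 6000,
        }
    )
    depth: int = 50000  # expected reads per sample
    read_length: int = 50
    present_mean: float = 20.0  # Poisson mean per present sample
    n_background_tags: int = 200
    junk_fraction: float = 0.05
    allele_mutation_rates: tuple = (0.05, 0.10, 0.30)
    allele_upstream_length: int = 1000
    colorspace: bool = False
    expression_patterns: dict | None = None  # optional label -> pattern override
    max_attempts: int = 5

    def __post_init__(self) -> None:
        for name in (
            "n_x_specific",
            "n_yh_specific",
            "n_shared",
            "n_multi_nuclear",
            "n_organelle",
            "n_non_sc",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class PlantedTag:
    label: str
    tag: str
    category: str
    positions: list  # [(partition, seq_id, start, strand), ...]
    pattern: str
    mean: float


@dataclass
class AllelePair:
    yh_label: str
    yh_seq_id: str
    yh_tag_start: int
    x_seq_id: str
    x_start: int
    mutation_rate: float
    realized_identity: float


@dataclass
class SyntheticTruth:
    """Planted ground truth for end-to-end verification."""

    planted: dict  # label -> PlantedTag
    allele_pairs: list = field(default_factory=list)
    genes: dict = field(default_factory=dict)  # label -> {positive, negative}

    def by_tag(self) -> dict[str, PlantedTag]:
        return {p.tag: p for p in self.planted.values()}

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": {k: asdict(v) for k, v in self.planted.items()},
                "allele_pairs": [asdict(a) for a in self.allele_pairs],
                "genes": self.genes,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        planted = {
            k: PlantedTag(**{**v, "positions": [tuple(p) for p in v["positions"]]})
            for k, v in raw["planted"].items()
        }
        pairs = [AllelePair(**a) for a in raw["allele_pairs"]]
        return cls(planted, pairs, raw.get("genes", {}))


@dataclass
class SimResult:
    config: SimulationConfig
    refs: ReferenceSet
    truth: SyntheticTruth
    genes: list
    reads: list
    background_means: dict  # background tag -> Poisson mean (same all samples)
    index_table: IndexTable


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _novel_tag(rng: np.random.Generator, taken: set[str]) -> str:
    for _ in range(1000):
        tag = "CATG" + _random_seq(rng, 22)
        if tag not in taken and reverse_complement(tag) not in taken:
            taken.add(tag)
            taken.add(reverse_complement(tag))
            return tag
    raise GenerationError("could not draw a novel tag within the retry budget")


def _category_plan(config: SimulationConfig) -> list[tuple[str, str]]:
    """Ordered (label, category) list for all planted tags."""
    plan = []
    for i in range(config.n_x_specific):
        plan.append((f"tagX{i:02d}", "X_specific"))
    for i in range(config.n_yh_specific):
        plan.append((f"tagY{i:02d}", "Yh_specific"))
    for i in range(config.n_shared):
        plan.append((f"tagS{i:02d}", "XYh_shared"))
    for i in range(config.n_multi_nuclear):
        plan.append((f"tagN{i:02d}", "sex_plus_nuclear"))
    for i in range(config.n_organelle):
        plan.append((f"tagO{i:02d}", "sex_plus_organelle"))
    for i in range(config.n_non_sc):
        plan.append((f"tagB{i:02d}", "non_SC"))
    return plan


_SEQ_IDS = {
    "X": "X_bac1",
    "Yh": "Yh_bac1",
    "other_nuclear": "nuc_sc1",
    "organelle": "org_pt1",
}


def generate_reference(
    config: SimulationConfig, attempt: int = 0
) -> tuple[ReferenceSet, SyntheticTruth]:
    """Random background per partition with planted tag sites.

    X-specific tags go only into X, Yh-specific only into Yh, shared tags
    into both, multi-nuclear tags into a sex partition (alternating X/Yh)
    plus other_nuclear, organelle-co-hit tags into a sex partition plus the
    organelle sequence, and non-SC tags into other_nuclear only. Sites are
    spaced so every tag has free upstream room for gene and allele tests.
    """
    rng = np.random.default_rng([config.seed % (2**31), 1, attempt])
    # background
    seqs = {
        part: list(_random_seq(rng, length))
        for part, length in config.partition_lengths.items()
    }
    # slot cursors per partition
    cursor = {part: 0 for part in seqs}
    reserve = {
        part: 0 for part in seqs
    }
    reserve["X"] = config.n_yh_specific * (config.allele_upstream_length + 300)

    def next_slot(part: str) -> int:
        pos = _SLOT_FIRST + cursor[part] * _SLOT_STEP
        cursor[part] += 1
        limit = config.partition_lengths[part] - reserve[part]
        if pos + 26 > limit:
            raise GenerationError(
                f"partition {part!r} too short for its planted tags "
                f"(need past {pos + 26}, have {limit})"
            )
        return pos

    taken: set[str] = set()
    planted: dict[str, PlantedTag] = {}
    pattern_counters: dict[str, int] = {}
    alt_sex = 0  # alternate X / Yh for co-hit categories

    def assign_pattern(label: str, category: str) -> str:
        if config.expression_patterns and label in config.expression_patterns:
            return config.expression_patterns[label]
        cycle = _PATTERN_CYCLE[category]
        i = pattern_counters.get(category, 0)
        pattern_counters[category] = i + 1
        return cycle[i % len(cycle)]

    def plant(part: str, tag: str) -> tuple[str, str, int, str]:
        pos = next_slot(part)
        seqs[part][pos : pos + 26] = list(tag)
        return (part, _SEQ_IDS[part], pos, "+")

    for label, category in _category_plan(config):
        tag = _novel_tag(rng, taken)
        positions = []
        if category == "X_specific":
            positions.append(plant("X", tag))
        elif category == "Yh_specific":
            positions.append(plant("Yh", tag))
        elif category == "XYh_shared":
            positions.append(plant("X", tag))
            positions.append(plant("Yh", tag))
        elif category == "sex_plus_nuclear":
            sex = "X" if alt_sex % 2 == 0 else "Yh"
            alt_sex += 1
            positions.append(plant(sex, tag))
            positions.append(plant("other_nuclear", tag))
        elif category == "sex_plus_organelle":
            sex = "X" if alt_sex % 2 == 0 else "Yh"
            alt_sex += 1
            positions.append(plant(sex, tag))
            positions.append(plant("organelle", tag))
        else:  # non_SC
            positions.append(plant("other_nuclear", tag))
        planted[label] = PlantedTag(
            label,
            tag,
            category,
            positions,
            assign_pattern(label, category),
            config.present_mean,
        )

    refs = ReferenceSet(
        {
            part: [SequenceRecord(_SEQ_IDS[part], "".join(chars))]
            for part, chars in seqs.items()
        }
    )
    return refs, SyntheticTruth(planted)


def plant_allele_pairs(
    config: SimulationConfig,
    refs: ReferenceSet,
    truth: SyntheticTruth,
    attempt: int = 0,
) -> tuple[ReferenceSet, SyntheticTruth]:
    """Copy Yh upstream regions into the X partition at set divergence.

    For each Yh-specific tag, the ``allele_upstream_length`` bases upstream
    of its site are copied into a reserved tail region of X with per-base
    substitution rate taken from ``allele_mutation_rates`` (cycled). The
    realized identity of each copy is recorded in the truth table.
    """
    rng = np.random.default_rng([config.seed % (2**31), 2, attempt])
    yh_tags = [p for p in truth.planted.values() if p.category == "Yh_specific"]
    if not yh_tags:
        return refs, truth
    L = config.allele_upstream_length
    x_rec = refs.partitions["X"][0]
    yh_rec = refs.partitions["Yh"][0]
    x_chars = list(x_rec.sequence)
    x_len = len(x_chars)
    region_start = x_len - config.n_yh_specific * (L + 300)
    rates = config.allele_mutation_rates
    pairs = []
    for i, p in enumerate(yh_tags):
        _, yh_seq_id, start, _ = p.positions[0]
        source = yh_rec.sequence[start - L : start]
        rate = rates[i % len(rates)]
        mutate = rng.random(L) < rate
        copy = list(source)
        for j in np.flatnonzero(mutate):
            choices = [b for b in "ACGT" if b != copy[j]]
            copy[j] = choices[rng.integers(0, 3)]
        x_start = region_start + i * (L + 300) + 150
        x_chars[x_start : x_start + L] = copy
        pairs.append(
            AllelePair(
                p.label,
                yh_seq_id,
                start,
                x_rec.id,
                x_start,
                float(rate),
                1.0 - int(mutate.sum()) / L,
            )
        )
    refs.partitions["X"][0] = SequenceRecord(
        x_rec.id, "".join(x_chars), x_rec.description
    )
    truth.allele_pairs = pairs
    return refs, truth


def verify_truth(refs: ReferenceSet, truth: SyntheticTruth) -> None:
    """Check every planted tag occurs exactly at its recorded positions.

    Rejects references where the random background (or an allele copy)
    accidentally duplicated a planted tag, keeping the truth table exact
    rather than probabilistic.
    """
    index = build_index(refs, 26)
    for p in truth.planted.values():
        hits = map_tag(p.tag, index)
        observed = {(h.partition, h.seq_id, h.start, h.strand) for h in hits}
        expected = {tuple(pos) for pos in p.positions}
        if observed != expected:
            raise GenerationError(
                f"planted tag {p.label} has unexpected placements: "
                f"{sorted(observed - expected)} extra, "
                f"{sorted(expected - observed)} missing"
            )


def generate_gene_models(
    config: SimulationConfig, refs: ReferenceSet, truth: SyntheticTruth
) -> list[GeneModel]:
    """Positive/negative gene placements around sex-specific tag sites.

    For each X- or Yh-specific tag with enough upstream room, one gene is
    placed wholly inside the 2-kb upstream window and one wholly beyond it;
    placements (or skips) are recorded in the truth table.
    """
    genes: list[GeneModel] = []
    for p in truth.planted.values():
        if p.category not in ("X_specific", "Yh_specific"):
            continue
        _, seq_id, pos, _ = p.positions[0]
        entry: dict = {"positive": None, "negative": None}
        if pos - 1500 > 0:
            gid = f"g_{p.label}_pos"
            genes.append(GeneModel(gid, seq_id, pos - 1500, pos - 700, "+"))
            entry["positive"] = gid
        if pos - 2500 > 0:
            gid = f"g_{p.label}_neg"
            genes.append(GeneModel(gid, seq_id, pos - 2500, pos - 2100, "+"))
            entry["negative"] = gid
        truth.genes[p.label] = entry
    return genes


def default_index_table() -> IndexTable:
    return IndexTable(OrderedDict(DEFAULT_INDEXES))


def make_background_tags(
    config: SimulationConfig,
    refs: ReferenceSet,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Non-reference background transcriptome tags with Zipf-like means.

    These fill each sample to the configured depth; none of them (nor their
    reverse complements) occurs in the reference, so they classify non_SC
    with zero hits.
    """
    rng = rng or np.random.default_rng([config.seed % (2**31), 4])
    index = build_index(refs, 26)
    taken = set(truth.by_tag())
    tags = []
    while len(tags) < config.n_background_tags:
        tag = "CATG" + _random_seq(rng, 22)
        if tag in taken or tag in index or reverse_complement(tag) in index:
            continue
        taken.add(tag)
        tags.append(tag)
    # mean expected planted load per sample (averaged over sex types)
    planted_load = np.mean(
        [
            sum(
                p.mean
                for p in truth.planted.values()
                if DEFAULT_SAMPLE_SEX[s] in p.pattern
            )
            for s in DEFAULT_INDEXES
        ]
    )
    remaining = max(0.0, config.depth * (1 - config.junk_fraction) - planted_load)
    weights = 1.0 / np.arange(1, len(tags) + 1)
    weights /= weights.sum()
    return {t: float(remaining * w) for t, w in zip(tags, weights)}


def draw_tag_counts(
    truth: SyntheticTruth,
    background_means: dict[str, float],
    sample: str,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Poisson-sample per-tag read counts for one sample."""
    sex = DEFAULT_SAMPLE_SEX[sample]
    counts: dict[str, int] = {}
    for p in truth.planted.values():
        if sex in p.pattern:
            c = int(rng.poisson(p.mean))
            if c:
                counts[p.tag] = c
    for tag, mean in background_means.items():
        c = int(rng.poisson(mean))
        if c:
            counts[tag] = c
    return counts


def _junk_reads(
    config: SimulationConfig,
    index_table: IndexTable,
    sample: str,
    rng: np.random.Generator,
    start_id: int,
) -> list[SequenceRecord]:
    """Reads exercising every discard reason of the demultiplexer."""
    n_junk = int(round(config.depth * config.junk_fraction))
    per = n_junk // 4
    counts = {
        "bad_index": per + n_junk - 4 * per,
        "no_anchor": per,
        "short_tag": per,
        "has_N": per,
    }
    idx = index_table.entries[sample]
    known = set(index_table.entries.values())
    reads = []
    rid = start_id
    fill = config.read_length - 32
    for _ in range(counts["bad_index"]):
        while True:
            bad = _random_seq(rng, 6)
            if bad not in known:
                break
        reads.append(
            SequenceRecord(f"j{rid}", bad + "CATG" + _random_seq(rng, 22 + fill))
        )
        rid += 1
    for _ in range(counts["no_anchor"]):
        body = "".join(np.array(list("ACG"))[rng.integers(0, 3, config.read_length - 6)])
        reads.append(SequenceRecord(f"j{rid}", idx + body))
        rid += 1
    for _ in range(counts["short_tag"]):
        reads.append(SequenceRecord(f"j{rid}", idx + "CATG" + _random_seq(rng, 10)))
        rid += 1
    for _ in range(counts["has_N"]):
        tail = list(_random_seq(rng, 22 + fill))
        tail[int(rng.integers(0, len(tail)))] = "N"
        reads.append(SequenceRecord(f"j{rid}", idx + "CATG" + "".join(tail)))
        rid += 1
    return reads


def generate_reads(
    config: SimulationConfig,
    truth: SyntheticTruth,
    index_table: IndexTable | None = None,
    background_means: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> list:
    """One pooled lane of indexed reads across all six samples.

    Each planted tag whose pattern includes a sample's sex type is emitted
    Poisson(mean) times for that sample; junk reads cover the bad_index /
    no_anchor / short_tag / has_N discard reasons. Reads are shuffled, and
    colorspace-encoded when configured.
    """
    index_table = index_table or default_index_table()
    background_means = background_means or {}
    rng = rng or np.random.default_rng([config.seed % (2**31), 3])
    reads: list[SequenceRecord] = []
    rid = 0
    fill = config.read_length - 32
    for sample, idx in index_table.entries.items():
        counts = draw_tag_counts(truth, background_means, sample, rng)
        for tag, c in sorted(counts.items()):
            for _ in range(c):
                filler = _random_seq(rng, fill) if fill > 0 else ""
                reads.append(SequenceRecord(f"r{rid}", idx + tag + filler))
                rid += 1
        reads.extend(_junk_reads(config, index_table, sample, rng, rid))
        rid = len(reads)
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    if config.colorspace:
        cs = []
        for r in reads:
            if "N" in r.sequence:
                # encode around the N by emitting a missing call at its site
                prefix = r.sequence.split("N")[0]
                enc = encode_colorspace(SequenceRecord(r.id, prefix), "T")
                pad = "." * (len(r.sequence) - len(prefix))
                cs.append(ColorspaceRecord(r.id, "T", enc.colors + pad))
            else:
                cs.append(encode_colorspace(r, "T"))
        return cs
    return reads


def simulate(config: SimulationConfig) -> SimResult:
    """Run the full generator with verification and retry."""
    last_err: Exception | None = None
    for attempt in range(config.max_attempts):
        try:
            refs, truth = generate_reference(config, attempt)
            refs, truth = plant_allele_pairs(config, refs, truth, attempt)
            verify_truth(refs, truth)
            break
        except GenerationError as exc:
            last_err = exc
    else:
        raise GenerationError(f"generation failed after retries: {last_err}")
    genes = generate_gene_models(config, refs, truth)
    index_table = default_index_table()
    background = make_background_tags(config, refs, truth)
    reads = generate_reads(config, truth, index_table, background)
    return SimResult(config, refs, truth, genes, reads, background, index_table)


def write_simulation(sim: SimResult, outdir: str) -> dict:
    """Write lanes, references, manifest, gene models, index and truth.

    Returns a ready-to-run pipeline configuration dict (also written as
    ``pipeline.yaml``) whose paths point at the emitted files.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest = {}
    for part, recs in sim.refs.partitions.items():
        path = os.path.join(outdir, f"{part}.fasta")
        write_fasta(recs, path)
        manifest[part] = [f"{part}.fasta"]
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)
    write_gene_models(sim.genes, os.path.join(outdir, "genes.gff3"))
    write_index_table(sim.index_table, os.path.join(outdir, "index.tsv"))
    if sim.config.colorspace:
        lane = "lane.csfasta"
        write_csfasta(sim.reads, os.path.join(outdir, lane))
    else:
        lane = "lane.fasta"
        write_fasta(sim.reads, os.path.join(outdir, lane))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(sim.truth.to_json())
    pipeline_cfg = {
        "reads": [lane],
        "reference_manifest": "manifest.yaml",
        "gene_models": "genes.gff3",
        "index_table": "index.tsv",
        "output_dir": "run",
        "colorspace": sim.config.colorspace,
        "seed": sim.config.seed,
    }
    with open(os.path.join(outdir, "pipeline.yaml"), "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh)
    return pipeline_cfg
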