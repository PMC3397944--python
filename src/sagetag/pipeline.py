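"""End-to-end orchestration: decode, demultiplex, extract, map, classify,
associate, allele-search, expression-call, and report.

Every stage persists its output as plain TSV inside the run directory so
any stage can be inspected or re-run; a JSON summary carries the per-stage
tallies and the category identities, and the run fails loudly if those
identities break.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import yaml

from . import io_formats as iof
from .annotation_link import extract_upstream, find_x_allele, genes_within_upstream
from .expression_analysis import (
    DEFAULT_DESIGN,
    SexDesign,
    category_tally,
    select_sex_dependent,
    x_activity_ratios,
)
from .reference_mapping import (
    ReferenceSet,
    PARTITIONS,
    build_index,
    classify_tags,
    format_hits,
)
from .tag_extraction import (
    ReadLayout,
    combine_profiles,
    demultiplex,
    extract_profile,
    filter_by_total,
    nonsingleton_count,
)


class PipelineError(RuntimeError):
    """A configuration or input problem detected before/while running."""


def _write_rows(rows: list[dict], columns: list[str], path: str) -> None:
    """Write a report, falling back to a header-only file when empty."""
    import pandas as pd

    if rows:
        iof.write_report(rows, path)
    else:
        iof.write_report(pd.DataFrame(columns=columns), path)


@dataclass
class PipelineConfig:
    """Paths, cutoffs and flags for one pipeline run.

    The defaults are the study's cutoffs: tags kept when their combined
    count exceeds 10, genes associated within 2 kb upstream, allele search
    over ~1 kb upstream at >80% identity.
    """

    reads: list[str] = field(default_factory=list)
    reference_manifest: str = ""
    gene_models: str | None = None
    index_table: str = ""
    output_dir: str = "run"
    min_total: int = 10
    window: int = 2000
    upstream_allele: int = 1000
    min_identity: float = 0.80
    min_aligned: int = 100
    t_present: int = 5
    t_absent: int = 0
    nonsingleton_min: int = 2
    colorspace: bool = False
    unstranded_window: bool = False
    cpm_mode: bool = False
    seed: int = 0
    design: dict | None = None  # sample -> [sex, stage]; None = study design

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        cfg.reads = [resolve(p) for p in cfg.reads]
        cfg.reference_manifest = resolve(cfg.reference_manifest)
        if cfg.gene_models:
            cfg.gene_models = resolve(cfg.gene_models)
        cfg.index_table = resolve(cfg.index_table)
        cfg.output_dir = resolve(cfg.output_dir)
        return cfg

    def sex_design(self) -> SexDesign:
        if self.design is None:
            return DEFAULT_DESIGN
        return SexDesign({s: tuple(v) for s, v in self.design.items()})


def load_reference_manifest(path: str) -> ReferenceSet:
    """Read a YAML manifest mapping partition name -> FASTA path(s)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise PipelineError(f"reference manifest {path!r} is not a mapping")
    missing = [p for p in ("X", "Yh") if p not in raw]
    if missing:
        raise PipelineError(
            f"reference manifest {path!r} is missing partition(s): {missing}"
        )
    base = os.path.dirname(os.path.abspath(path))
    partitions = {}
    for name, paths in raw.items():
        if name not in PARTITIONS:
            raise PipelineError(f"unknown reference partition {name!r}")
        if isinstance(paths, str):
            paths = [paths]
        records = []
        for p in paths:
            full = p if os.path.isabs(p) else os.path.join(base, p)
            if not os.path.exists(full):
                raise PipelineError(f"reference FASTA not found: {full}")
            records.extend(iof.read_fasta(full))
        partitions[name] = records
    return ReferenceSet(partitions)


def _check_inputs(config: PipelineConfig) -> None:
    paths = list(config.reads) + [config.reference_manifest, config.index_table]
    if config.gene_models:
        paths.append(config.gene_models)
    for p in paths:
        if not p or not os.path.exists(p):
            raise PipelineError(f"input path does not exist: {p!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and persist) the run summary."""
    _check_inputs(config)
    os.makedirs(config.output_dir, exist_ok=True)
    log = logging.getLogger("sagetag")
    handler = logging.FileHandler(os.path.join(config.output_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, log)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, log: logging.Logger) -> dict:
    out = config.output_dir
    layout = ReadLayout()
    table = iof.read_index_table(config.index_table)
    design = config.sex_design()

    # --- decode + pool reads
    reads = []
    for path in config.reads:
        if config.colorspace:
            reads.extend(iof.decode_colorspace(r) for r in iof.read_csfasta(path))
        else:
            reads.extend(iof.read_fasta(path))
    log.info("loaded %d reads from %d lane file(s)", len(reads), len(config.reads))

    # --- demultiplex + extract
    assigned, discards = demultiplex(reads, table, layout)
    profiles = []
    extract_tally = {}
    sample_stats = []
    for sample in table.samples:
        profile, reasons = extract_profile(sample, assigned[sample], layout)
        profiles.append(profile)
        extract_tally[sample] = dict(reasons)
        sample_stats.append(
            {
                "sample": sample,
                "assigned_reads": len(assigned[sample]),
                "total_tags": profile.total,
                "unique_tags": profile.unique,
                "nonsingleton_tags": nonsingleton_count(
                    profile, config.nonsingleton_min
                ),
            }
        )
        iof.write_report(
            [{"tag": t, "count": c} for t, c in profile.counts.items()],
            os.path.join(out, f"profile_{sample}.tsv"),
        )
    n_assigned = sum(len(v) for v in assigned.values())
    if n_assigned + sum(discards.values()) != len(reads):
        raise PipelineError("read conservation violated in demultiplex")
    log.info("assigned %d reads; discards: %s", n_assigned, dict(discards))

    # --- combine + filter
    matrix = combine_profiles(profiles, table.samples)
    iof.write_report(matrix.to_frame(), os.path.join(out, "tag_matrix.tsv"))
    filtered = filter_by_total(matrix, config.min_total)
    iof.write_report(filtered.to_frame(), os.path.join(out, "tag_matrix_filtered.tsv"))
    log.info("tag matrix: %d tags, %d past the >%d filter",
             len(matrix), len(filtered), config.min_total)

    # --- map + classify
    refs = load_reference_manifest(config.reference_manifest)
    index = build_index(refs, layout.tag_length)
    classes = classify_tags(filtered.tags, index)
    tally = category_tally(classes)  # raises ConsistencyError on violation
    class_frame = filtered.to_frame()
    class_frame["category"] = [classes[t].category for t in class_frame["tag"]]
    class_frame["hits"] = [format_hits(classes[t].hits) for t in class_frame["tag"]]
    iof.write_report(class_frame, os.path.join(out, "classification.tsv"))
    log.info("category tally: %s", tally)

    sex_specific = {
        t: c
        for t, c in classes.items()
        if c.category in ("X_specific", "Yh_specific", "XYh_shared")
    }

    # --- gene association + upstream export
    gene_rows = []
    upstream_records = []
    genes = iof.read_gene_models(config.gene_models) if config.gene_models else []
    for tag, cls in sorted(sex_specific.items()):
        for hit in cls.hits:
            _, rec = refs.get(hit.seq_id)
            gids = genes_within_upstream(
                hit,
                genes,
                config.window,
                ref_length=len(rec.sequence),
                stranded=not config.unstranded_window,
            )
            gene_rows.append(
                {
                    "tag": tag,
                    "seq_id": hit.seq_id,
                    "start": hit.start,
                    "strand": hit.strand,
                    "genes": ",".join(gids),
                }
            )
            up_rec, _ = extract_upstream(hit, refs, config.window)
            if up_rec.sequence:
                upstream_records.append(up_rec)
    _write_rows(
        gene_rows,
        ["tag", "seq_id", "start", "strand", "genes"],
        os.path.join(out, "gene_association.tsv"),
    )
    iof.write_fasta(upstream_records, os.path.join(out, "upstream_windows.fasta"))

    # --- allele search for Yh-specific tags
    allele_rows = []
    for tag, cls in sorted(sex_specific.items()):
        if cls.category != "Yh_specific":
            continue
        yh_hits = [h for h in cls.hits if h.partition == "Yh"]
        for res in find_x_allele(
            yh_hits[0],
            refs,
            config.upstream_allele,
            config.min_identity,
            config.min_aligned,
        ):
            allele_rows.append(
                {
                    "tag": tag,
                    "target_id": res.target_id,
                    "strand": res.strand,
                    "score": res.score,
                    "identity": round(res.identity, 4),
                    "query_span": f"{res.query_span[0]}-{res.query_span[1]}",
                    "target_span": f"{res.target_span[0]}-{res.target_span[1]}",
                }
            )
    _write_rows(
        allele_rows,
        ["tag", "target_id", "strand", "score", "identity",
         "query_span", "target_span"],
        os.path.join(out, "allele_search.tsv"),
    )

    # --- sex-dependent expression
    calls = select_sex_dependent(
        filtered, design, classes, config.t_present, config.t_absent, config.cpm_mode
    )
    call_rows = []
    for call in calls:
        row = {"tag": call.tag, "category": classes[call.tag].category}
        for s in filtered.samples:
            row[s] = int(filtered.counts.loc[call.tag, s])
        row.update({f"call_{x}": call.per_sex[x] for x in ("M", "F", "H")})
        row["pattern"] = call.pattern
        row["total"] = int(filtered.total.loc[call.tag])
        call_rows.append(row)
    _write_rows(
        call_rows, ["tag", "category", "pattern"], os.path.join(out, "sex_dependent.tsv")
    )

    # --- X-activity ratios (denominator = all tags analyzed per sample)
    x_tags = {t for t, c in classes.items() if c.category == "X_specific"}
    sample_totals = {p.sample_id: p.total for p in profiles}
    ratios = x_activity_ratios(filtered, x_tags, sample_totals)
    iof.write_report(
        [
            {"sample": s, "x_specific_count": int(
                filtered.counts.loc[list(x_tags & set(filtered.tags)), s].sum()
            ), "total_tags": sample_totals[s], "ratio_percent": round(r, 4)}
            for s, r in ratios.items()
        ],
        os.path.join(out, "x_activity.tsv"),
    )

    summary = {
        "reads_in": len(reads),
        "reads_assigned": n_assigned,
        "discards": dict(discards),
        "extraction_tally": extract_tally,
        "samples": sample_stats,
        "n_tags": len(matrix),
        "n_tags_filtered": len(filtered),
        "category_tally": tally,
        "n_sex_dependent": len(calls),
        "sex_dependent_patterns": {c.tag: c.pattern for c in calls},
        "x_activity_percent": {s: round(r, 4) for s, r in ratios.items()},
        "n_allele_hits": len(allele_rows),
        "allele_tags_found": sorted({r["tag"] for r in allele_rows}),
    }
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
    log.info("run complete: %d SC tags, %d sex-dependent",
             tally["SC_total"], len(calls))
    return summary


REQUIRED_ARTIFACTS = (
    "summary.json",
    "tag_matrix.tsv",
    "tag_matrix_filtered.tsv",
    "classification.tsv",
    "sex_dependent.tsv",
    "x_activity.tsv",
)


def summarize(run_dir: str) -> str:
    """Human-readable summary of a completed run directory."""
    missing = [a for a in REQUIRED_ARTIFACTS if not os.path.exists(os.path.join(run_dir, a))]
    if missing:
        raise PipelineError(f"incomplete run dir {run_dir!r}; missing: {missing}")
    with open(os.path.join(run_dir, "summary.json")) as fh:
        s = json.load(fh)
    lines = ["sample\tassigned\ttotal_tags\tunique_tags\tnonsingleton"]
    for row in s["samples"]:
        lines.append(
            f"{row['sample']}\t{row['assigned_reads']}\t{row['total_tags']}"
            f"\t{row['unique_tags']}\t{row['nonsingleton_tags']}"
        )
    lines.append("")
    lines.append("category\tcount")
    for cat in ("X_specific", "Yh_specific", "XYh_shared",
                "sex_plus_nuclear", "sex_plus_organelle", "non_SC",
                "sex_specific_total", "SC_total"):
        lines.append(f"{cat}\t{s['category_tally'][cat]}")
    lines.append("")
    lines.append(f"sex-dependent tags\t{s['n_sex_dependent']}")
    lines.append("")
    lines.append("sample\tX-activity %")
    for sample, r in s["x_activity_percent"].items():
        lines.append(f"{sample}\t{r}")
    return "\n".join(lines)
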