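"""End-to-end orchestration: simulate -> process -> variants -> classify -> stats.

``analyze_pairs`` is the core per-sample path used both by the CLI (from
FASTQ files on disk) and by in-memory simulation studies; ``run_pipeline``
drives a full multi-sample run from a structured config and writes every
intermediate table plus a reproducible JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .demo import DEMO_LOCI, MIN_OVERLAP, STUDY_GROUPS
from .hdr_classification import (
    SampleSummary,
    VariantCall,
    aggregate_groups,
    classify_variant,
    summaries_frame,
    summarize_sample,
)
from .locus_model import (
    EditSpec,
    TargetLocus,
    build_expected_alleles,
    locus_from_config,
)
from .read_processing import (
    ProcessParams,
    ReadPair,
    demultiplex,
    process_pairs,
    read_fastq_pairs,
    write_fastq_pairs,
)
from .synthetic_data import (
    CohortGroupSpec,
    ReadSimConfig,
    SimulatedSample,
    cohort_truth_table,
    simulate_cohort,
)
from .variant_calling import call_variants

log = logging.getLogger("hdrpipe")


@dataclass(frozen=True)
class SampleResult:
    sample_id: str
    group: str
    ledger: dict
    calls: tuple[VariantCall, ...]
    summary: SampleSummary | None  # None when no variant reaches support
    flagged: str = ""


def analyze_pairs(
    pairs: list[ReadPair],
    locus: TargetLocus,
    edit: EditSpec,
    params: ProcessParams,
    sample_id: str = "",
    group: str = "",
    anchor_k: int = 10,
    max_n_diff: int = 5,
    min_reads: int = 100,
) -> SampleResult:
    """Run one sample's read pairs through the whole analysis."""
    processed, ledger = process_pairs(pairs, locus, params)
    result = call_variants(processed, max_n_diff=max_n_diff, min_reads=min_reads)
    ledger["variants_retained"] = len(result.retained)
    ledger["variants_dropped_support"] = result.dropped_variants
    ledger["reads_retained"] = result.denominator
    ledger["reads_dropped_support"] = result.dropped_reads
    if result.no_callable_variants:
        return SampleResult(sample_id, group, ledger, (), None,
                            flagged="no callable variants")
    expected = build_expected_alleles(locus, edit, anchor_k)
    calls = tuple(classify_variant(v, expected) for v in result.retained)
    summary = summarize_sample(list(calls), result.denominator, sample_id, group)
    return SampleResult(sample_id, group, ledger, calls, summary)


def analyze_cohort(
    samples: list[SimulatedSample],
    locus: TargetLocus,
    edit: EditSpec,
    params: ProcessParams,
    **kwargs,
) -> list[SampleResult]:
    return [
        analyze_pairs(s.pairs, locus, edit, params, s.sample_id, s.group, **kwargs)
        for s in samples
    ]


# ---------------------------------------------------------------------------
# file-driven runs


@dataclass
class RunConfig:
    """One structured run description (normally loaded from YAML).

    ``loci`` holds locus/edit config mappings (see locus_model); the
    sample sheet TSV has columns sample_id, fastq_r1, fastq_r2, gene,
    group.  Per-locus overrides (e.g. min_overlap) live under
    ``locus_params``.
    """

    loci: list[dict]
    sample_sheet: str
    output_dir: str
    locus_params: dict = field(default_factory=dict)
    process: dict = field(default_factory=dict)
    anchor_k: int = 10
    max_n_diff: int = 5
    min_reads: int = 100
    seed: int = 0
    base_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.setdefault("base_dir", str(path.parent))
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _params_for(locus_name: str, cfg: RunConfig) -> ProcessParams:
    overrides = dict(cfg.process)
    overrides.update(cfg.locus_params.get(locus_name, {}))
    return ProcessParams(**overrides)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a full run; returns (and writes) the report dictionary."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = Path(cfg.base_dir)
    loci: dict[str, tuple[TargetLocus, EditSpec]] = {}
    for locus_cfg in cfg.loci:
        locus, edit = locus_from_config(locus_cfg, base_dir=base)
        loci[locus.name] = (locus, edit)

    sheet = pd.read_csv(base / cfg.sample_sheet, sep="\t")
    required = {"sample_id", "fastq_r1", "fastq_r2", "gene", "group"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")

    # several locus entries may share one amplicon/primer pair (same gene,
    # different intended edit); demultiplex on distinct primer pairs only
    rep_of: dict[str, str] = {}
    rep_loci: list[TargetLocus] = []
    seen_primers: dict[tuple[str, str], str] = {}
    for name, (locus, _) in loci.items():
        key = (locus.fwd_primer, locus.rev_primer)
        if key not in seen_primers:
            seen_primers[key] = name
            rep_loci.append(locus)
        rep_of[name] = seen_primers[key]

    results: list[SampleResult] = []
    all_calls_rows = []
    for row in sheet.itertuples(index=False):
        pairs = read_fastq_pairs(base / row.fastq_r1, base / row.fastq_r2)
        assigned, demux_counts = demultiplex(pairs, rep_loci)
        locus, edit = loci[row.gene]
        params = _params_for(row.gene, cfg)
        res = analyze_pairs(
            assigned[rep_of[row.gene]], locus, edit, params,
            sample_id=row.sample_id, group=row.group,
            anchor_k=cfg.anchor_k, max_n_diff=cfg.max_n_diff,
            min_reads=cfg.min_reads)
        res.ledger.update({f"demux_{k}": v for k, v in demux_counts.items()})
        results.append(res)
        for call in res.calls:
            all_calls_rows.append({
                "sample_id": row.sample_id, "group": row.group,
                "sequence": call.variant.sequence,
                "read_count": call.variant.read_count,
                "label": call.label,
                "perfect_5p": call.perfect_5p, "perfect_3p": call.perfect_3p,
            })
        if res.flagged:
            log.warning("sample %s flagged: %s", row.sample_id, res.flagged)

    summaries = [r.summary for r in results if r.summary is not None]
    sum_df = summaries_frame(summaries)
    sum_df.to_csv(out / "sample_summaries.tsv", sep="\t", index=False)
    pd.DataFrame(all_calls_rows).to_csv(out / "variant_calls.tsv", sep="\t", index=False)
    groups_df = aggregate_groups(summaries) if summaries else pd.DataFrame()
    groups_df.to_csv(out / "group_aggregates.tsv", sep="\t", index=False)
    ledger_df = pd.DataFrame(
        [{"sample_id": r.sample_id, **r.ledger} for r in results])
    ledger_df.to_csv(out / "read_accounting.tsv", sep="\t", index=False)

    report = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "n_samples": len(results),
        "flagged_samples": {r.sample_id: r.flagged for r in results if r.flagged},
        "group_aggregates": groups_df.to_dict(orient="records"),
        "read_accounting": ledger_df.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# demo fixtures


def make_demo_fixtures(
    out_dir: str | Path,
    seed: int = 0,
    n_per_group: int = 3,
    n_read_pairs: int = 1500,
) -> Path:
    """Write a small two-gene synthetic cohort (FASTQ + sample sheet +
    run config) mirroring the demo group structure, sized for quick runs.

    The variant support threshold in the generated config is scaled to the
    reduced read depth (1% of depth) so the demo behaves like a full-depth
    run; full-scale analyses keep the standard 100-read support filter.
    """
    out = Path(out_dir)
    (out / "fastq").mkdir(parents=True, exist_ok=True)
    cfg = ReadSimConfig(n_read_pairs=n_read_pairs)
    sheet_rows = []
    used_keys: list[str] = []
    for cond in STUDY_GROUPS[:3]:  # one KI group per gene + one SNR group
        locus_fn, edit_fn = DEMO_LOCI[cond.locus_key]
        locus, edit = locus_fn(), edit_fn()
        if cond.locus_key not in used_keys:
            used_keys.append(cond.locus_key)
        spec = CohortGroupSpec(
            label=cond.label, n_individuals=n_per_group,
            mean_perfect=cond.mean_perfect, mean_erroneous=cond.mean_erroneous,
            mean_nhej=cond.mean_nhej, indel_bias_5p=cond.indel_bias_5p)
        samples = simulate_cohort(locus, edit, [spec], cfg, seed=seed, stratified=True)
        for s in samples:
            r1 = out / "fastq" / f"{s.sample_id}_R1.fastq"
            r2 = out / "fastq" / f"{s.sample_id}_R2.fastq"
            write_fastq_pairs(s.pairs, r1, r2)
            sheet_rows.append({
                "sample_id": s.sample_id,
                "fastq_r1": str(r1.relative_to(out)),
                "fastq_r2": str(r2.relative_to(out)),
                "gene": cond.locus_key,
                "group": cond.label,
            })
        truth = cohort_truth_table(samples)
        truth.to_csv(out / f"truth_{cond.label}.tsv", sep="\t", index=False)
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)

    loci_cfg = []
    for key in used_keys:
        locus_fn, edit_fn = DEMO_LOCI[key]
        locus, edit = locus_fn(), edit_fn()
        entry = {
            "name": key,
            "amplicon": locus.amplicon,
            "fwd_primer": locus.fwd_primer,
            "rev_primer": locus.rev_primer,
            "window": {"start": locus.window[0], "end": locus.window[1]},
            "guide": {
                "protospacer": locus.guide.protospacer,
                "pam": locus.guide.pam,
                "strand": locus.guide.strand,
                "start": locus.guide.start,
            },
        }
        if edit.kind == "insertion":
            entry["edit"] = {"kind": "insertion", "insert": edit.insert}
        else:
            entry["edit"] = {
                "kind": "substitution",
                "substitutions": [[p, b] for p, b in edit.substitutions],
            }
        loci_cfg.append(entry)
    run_cfg = {
        "loci": loci_cfg,
        "sample_sheet": "sample_sheet.tsv",
        "output_dir": str(out / "results"),
        "locus_params": {
            key: {"min_overlap": MIN_OVERLAP[DEMO_LOCI[key][0]().name]}
            for key in used_keys
        },
        "min_reads": max(5, n_read_pairs // 100),
        "seed": seed,
    }
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=False)
    return out / "run_config.yaml"
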