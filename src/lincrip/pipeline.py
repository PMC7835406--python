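"""End-to-end orchestration of the identification screen.

``run_identify`` chains candidate selection, the expression cascade, the
dual-strategy enrichment classifier, isoform deduplication, EST
categorization and location classification, and writes the calls table, the
final transcript set (TSV + BED12), the funnel report and a JSON run report.
``run_simulate`` materializes a ground-truthed synthetic dataset and
``run_evaluate`` scores a finished run against its truth table.

Output files contain no timestamps, so re-running on identical inputs
reproduces byte-identical tables; every count in the run report can be
recomputed from the emitted tables by an independent reader.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import (
    LocationClass,
    TranscriptCatalog,
    classify_location,
    read_gtf,
    write_bed,
)
from .enrichment import (
    DedupPolicy,
    classify_all,
    deduplicate,
    est_category_counts,
    read_est_table,
    strategy_subtotals,
)
from .filters import (
    ThresholdConfig,
    apply_expression_cascade,
    funnel_report,
    read_cpc_table,
    read_expression_table,
    select_novel_candidates,
)
from .simulate import (
    SimParams,
    evaluate_recovery,
    simulate_dataset,
    write_dataset,
)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_identify",
           "run_simulate", "run_evaluate"]

logger = logging.getLogger("lincrip")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Paths and policies for one identification run."""

    novel_gtf: Path
    reference_gtf: Path
    expression_tsv: Path
    cpc_tsv: Path
    est_tsv: Path | None
    out_dir: Path
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    dedup: DedupPolicy = field(default_factory=DedupPolicy)

    def __post_init__(self) -> None:
        for name in ("novel_gtf", "reference_gtf", "expression_tsv",
                     "cpc_tsv", "est_tsv", "out_dir"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))

    def validate(self) -> None:
        required = {
            "novel_gtf": self.novel_gtf,
            "reference_gtf": self.reference_gtf,
            "expression_tsv": self.expression_tsv,
            "cpc_tsv": self.cpc_tsv,
        }
        if self.est_tsv is not None:
            required["est_tsv"] = self.est_tsv
        for name, path in required.items():
            if not path.is_file():
                raise PipelineError("config", f"{name} not found: {path}")


@dataclass
class RunReport:
    """Machine-readable summary of one identification run."""

    version: str
    funnel: list[dict]
    strategy_counts: list[dict]
    n_bound: int
    n_non_bound: int
    n_final: int
    n_dedup_groups: int
    est_categories: dict[str, int] | None
    location_counts: dict[str, int]
    intergenic_pct: float
    thresholds: dict
    dedup_policy: dict
    input_checksums: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_identify(cfg: RunConfig) -> RunReport:
    """Execute the full screen; write outputs under ``cfg.out_dir``.

    On any stage failure the partially written outputs of this run are
    removed and a :class:`PipelineError` naming the stage is raised.
    """
    cfg.validate()
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        try:
            novel = read_gtf(cfg.novel_gtf, source="novel")
            reference = read_gtf(cfg.reference_gtf, source="reference")
            expr = read_expression_table(cfg.expression_tsv)
            cpc = read_cpc_table(cfg.cpc_tsv)
            est = read_est_table(cfg.est_tsv) if cfg.est_tsv else None
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc

        try:
            candidates = select_novel_candidates(
                novel, reference, cfg.thresholds
            )
        except Exception as exc:
            raise PipelineError("candidate_selection", str(exc)) from exc
        logger.info("candidate_selection: %d of %d novel transcripts kept",
                    len(candidates), len(novel))

        try:
            funnel = apply_expression_cascade(
                candidates, expr, cpc, cfg.thresholds
            )
        except Exception as exc:
            raise PipelineError("expression_cascade", str(exc)) from exc

        survivors = funnel.surviving()
        expr_idx = expr.set_index("transcript_id", drop=False)
        try:
            bound, non_bound, calls = classify_all(
                expr_idx.loc[sorted(survivors)].reset_index(drop=True),
                cfg.thresholds,
            )
        except Exception as exc:
            raise PipelineError("enrichment", str(exc)) from exc
        logger.info("enrichment: %d bound, %d non-bound",
                    len(bound), len(non_bound))

        try:
            bound_records = [novel[tid] for tid in sorted(bound)]
            final_ids = deduplicate(bound_records, expr, cfg.dedup)
            from .enrichment import dedup_groups  # count, for the report
            n_groups = len(dedup_groups(bound_records, cfg.dedup))
        except Exception as exc:
            raise PipelineError("deduplication", str(exc)) from exc

        final_records = [novel[tid] for tid in sorted(final_ids)]
        location_counts = {"intergenic": 0, "genic_overlap": 0}
        for rec in final_records:
            loc = classify_location(rec, reference)
            location_counts[loc.value] += 1
        n_final = len(final_records)
        intergenic_pct = (
            100.0 * location_counts["intergenic"] / n_final if n_final else 0.0
        )

        est_counts = None
        if est is not None and n_final:
            est_final = est[est["transcript_id"].isin(final_ids)]
            est_counts = est_category_counts(est_final)
        elif est is not None:
            est_counts = est_category_counts(est.iloc[0:0])

        # outputs
        calls_path = out / "calls.tsv"
        calls.to_csv(calls_path, sep="\t", index=False)
        written.append(calls_path)

        final_catalog = TranscriptCatalog.from_records(final_records)
        final_bed = out / "final_lincrnas.bed"
        write_bed(final_catalog, final_bed)
        written.append(final_bed)

        final_tsv = out / "final_lincrnas.tsv"
        final_df = pd.DataFrame(
            {
                "transcript_id": [r.transcript_id for r in final_records],
                "chrom": [r.chrom for r in final_records],
                "span_start": [r.span.start for r in final_records],
                "span_end": [r.span.end for r in final_records],
                "strand": [r.strand for r in final_records],
                "spliced_length": [r.spliced_length for r in final_records],
                "location": [
                    classify_location(r, reference).value
                    for r in final_records
                ],
            }
        )
        final_df.to_csv(final_tsv, sep="\t", index=False)
        written.append(final_tsv)

        funnel_tsv = out / "funnel.tsv"
        funnel_report(funnel).to_csv(funnel_tsv, sep="\t", index=False)
        written.append(funnel_tsv)

        report = RunReport(
            version=__version__,
            funnel=funnel_report(funnel).to_dict(orient="records"),
            strategy_counts=strategy_subtotals(calls).to_dict(
                orient="records"
            ),
            n_bound=len(bound),
            n_non_bound=len(non_bound),
            n_final=n_final,
            n_dedup_groups=n_groups,
            est_categories=est_counts,
            location_counts=location_counts,
            intergenic_pct=intergenic_pct,
            thresholds=asdict(cfg.thresholds),
            dedup_policy=asdict(cfg.dedup),
            input_checksums={
                "novel_gtf": _sha256(cfg.novel_gtf),
                "reference_gtf": _sha256(cfg.reference_gtf),
                "expression_tsv": _sha256(cfg.expression_tsv),
                "cpc_tsv": _sha256(cfg.cpc_tsv),
                **(
                    {"est_tsv": _sha256(cfg.est_tsv)}
                    if cfg.est_tsv
                    else {}
                ),
            },
        )
        report_path = out / "report.json"
        report_path.write_text(report.to_json())
        written.append(report_path)
        return report
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def run_simulate(params: SimParams, out_dir: str | Path) -> dict:
    """Generate and write a synthetic dataset; returns the manifest."""
    dataset = simulate_dataset(params)
    return write_dataset(dataset, out_dir)


def run_evaluate(
    calls_tsv: str | Path,
    truth_tsv: str | Path,
    funnel_tsv: str | Path,
    out_path: str | Path | None = None,
) -> dict:
    """Score a finished run against its truth table; optionally write JSON."""
    calls = pd.read_csv(calls_tsv, sep="\t")
    truth = pd.read_csv(truth_tsv, sep="\t")
    funnel_df = pd.read_csv(funnel_tsv, sep="\t")
    # rebuild a funnel whose final stage carries the surviving ids: the calls
    # table lists exactly the cascade survivors
    from .filters import FilterFunnel

    funnel = FilterFunnel()
    funnel.append("survivors", frozenset(calls["transcript_id"]))
    summary = evaluate_recovery(calls, truth, funnel).to_dict()
    summary["funnel_counts"] = funnel_df.to_dict(orient="records")
    if out_path is not None:
        Path(out_path).write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return summary
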