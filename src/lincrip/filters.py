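"""The lincRNA candidate filter cascade with per-stage accounting.

Candidate selection takes the novel transcripts of an assembly that are
long enough (spliced length >= 200 bp by default) and intergenic with at
least 1 kb of clearance from every annotated transcript. The expression
cascade then applies, in a fixed order, a detection floor on the input
lincRNA library, a detection requirement in the RIP pulldown, a
coding-potential cutoff, and a final expression floor. Each stage records
its surviving transcript set so the screen is auditable as a funnel.

Boundary semantics are deliberately exact: FPKM floors are strict
(value > threshold), while the coding-potential cutoff, the length minimum
and the neighbor gap are inclusive. No epsilon is applied — the thresholds
are round numbers and an epsilon would be a second, undocumented threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .catalog import (
    LocationClass,
    NO_NEIGHBOR,
    TranscriptCatalog,
    classify_location,
    neighbor_distance,
    transcript_length,
)

__all__ = [
    "ThresholdConfig",
    "FilterFunnel",
    "FilterValidationError",
    "EXPRESSION_COLUMNS",
    "CPC_COLUMNS",
    "read_expression_table",
    "read_cpc_table",
    "select_novel_candidates",
    "apply_expression_cascade",
    "funnel_report",
]

EXPRESSION_COLUMNS = ("transcript_id", "lincRNA_FPKM", "EZH2_FPKM", "IgG_FPKM")
CPC_COLUMNS = ("transcript_id", "cpc_score")


class FilterValidationError(ValueError):
    """Inputs to a filter stage violate its contract."""


@dataclass(frozen=True)
class ThresholdConfig:
    """All screening constants in one place.

    min_length
        Minimum spliced transcript length in bp (inclusive).
    min_neighbor_gap
        Minimum bases strictly between a candidate's span and the nearest
        annotated transcript span (inclusive); chromosomes with no annotated
        transcript pass trivially.
    detect_fpkm
        Detection floor on the input lincRNA library FPKM (strict >).
    min_linc_fpkm
        Final expression floor on the input library FPKM (strict >).
    min_ezh2_fpkm
        Detection floor on the RIP pulldown FPKM (strict >); the default 0
        just requires the transcript to appear in the pulldown at all.
    max_cpc
        Coding-potential cutoff (inclusive <=); negative scores mean
        predicted noncoding.
    pseudo_count
        FPKM added to numerator and denominator of the enrichment ratio.
    min_ratio
        log2 enrichment at or above which a transcript is called bound
        (inclusive >=).
    """

    min_length: int = 200
    min_neighbor_gap: int = 1000
    detect_fpkm: float = 0.1
    min_linc_fpkm: float = 1.0
    min_ezh2_fpkm: float = 0.0
    max_cpc: float = -1.0
    pseudo_count: float = 2.0
    min_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise FilterValidationError("min_length must be >= 1")
        if self.min_neighbor_gap < 0:
            raise FilterValidationError("min_neighbor_gap must be >= 0")
        if self.pseudo_count <= 0:
            raise FilterValidationError("pseudo_count must be > 0")
        if self.detect_fpkm > self.min_linc_fpkm:
            raise FilterValidationError(
                "detect_fpkm must not exceed min_linc_fpkm"
            )


@dataclass
class FilterFunnel:
    """Ordered filter stages with their surviving transcript-id sets.

    Each appended stage must be a subset of the previous one; violating
    monotonicity raises immediately rather than producing a silently
    inconsistent report.
    """

    stages: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def append(self, name: str, surviving: set[str] | frozenset[str]) -> None:
        surviving = frozenset(surviving)
        if self.stages:
            prev = self.stages[-1][1]
            if not surviving <= prev:
                extra = sorted(surviving - prev)[:5]
                raise FilterValidationError(
                    f"funnel stage {name!r} is not a subset of the previous "
                    f"stage (e.g. {extra})"
                )
        self.stages.append((name, surviving))

    @property
    def stage_names(self) -> list[str]:
        return [name for name, _ in self.stages]

    @property
    def counts(self) -> list[int]:
        return [len(ids) for _, ids in self.stages]

    def surviving(self, name: str | None = None) -> frozenset[str]:
        """Survivors of the named stage (default: the last stage)."""
        if not self.stages:
            return frozenset()
        if name is None:
            return self.stages[-1][1]
        for stage_name, ids in self.stages:
            if stage_name == name:
                return ids
        raise KeyError(name)


def select_novel_candidates(
    novel: TranscriptCatalog,
    reference: TranscriptCatalog,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> set[str]:
    """Novel transcripts that are long enough, intergenic, and isolated.

    Keeps ids whose spliced length is >= ``cfg.min_length``, whose span
    overlaps no reference transcript span, and whose gap to the nearest
    reference span is >= ``cfg.min_neighbor_gap`` (no neighbor on the
    chromosome counts as an infinite gap).
    """
    shared = novel.transcript_ids & reference.transcript_ids
    if shared:
        raise FilterValidationError(
            "transcript ids shared between novel and reference catalogs: "
            f"{sorted(shared)[:5]}"
        )
    kept: set[str] = set()
    for rec in novel:
        if transcript_length(rec) < cfg.min_length:
            continue
        if classify_location(rec, reference) is not LocationClass.INTERGENIC:
            continue
        gap = neighbor_distance(rec, reference)
        if gap != NO_NEIGHBOR and gap < cfg.min_neighbor_gap:
            continue
        kept.add(rec.transcript_id)
    return kept


def apply_expression_cascade(
    candidates: set[str] | frozenset[str],
    expr: pd.DataFrame,
    cpc: pd.DataFrame,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> FilterFunnel:
    """Run the four expression/coding-potential stages over the candidates.

    Stage order is fixed: (1) ``detected`` — input library FPKM above the
    detection floor; (2) ``rip_detected`` — pulldown FPKM above its floor;
    (3) ``noncoding`` — coding-potential score at or below the cutoff;
    (4) ``expressed`` — input library FPKM above the final floor. Each stage
    intersects the previous stage's survivors, so per-stage counts describe
    one ordered funnel; the final set equals the unordered conjunction.

    Candidates missing from ``expr`` are a hard error. Candidates missing a
    coding-potential score fail the ``noncoding`` stage (a missing score
    signals an upstream failure; dropping is the conservative action).
    """
    _require_columns(expr, EXPRESSION_COLUMNS, "expression")
    _require_columns(cpc, CPC_COLUMNS, "coding-potential")
    candidates = frozenset(candidates)
    expr = expr.set_index("transcript_id", drop=False)
    if expr.index.has_duplicates:
        dups = sorted(expr.index[expr.index.duplicated()])[:5]
        raise FilterValidationError(
            f"duplicate transcript ids in expression table: {dups}"
        )
    missing = candidates - set(expr.index)
    if missing:
        raise FilterValidationError(
            "candidate ids absent from the expression table: "
            f"{sorted(missing)[:10]} ({len(missing)} total)"
        )
    cpc_scores = cpc.set_index("transcript_id")["cpc_score"]

    funnel = FilterFunnel()
    funnel.append("candidates", candidates)

    sub = expr.loc[sorted(candidates)]
    detected = frozenset(sub.index[sub["lincRNA_FPKM"] > cfg.detect_fpkm])
    funnel.append("detected", detected)

    sub = sub.loc[sorted(detected)]
    rip = frozenset(sub.index[sub["EZH2_FPKM"] > cfg.min_ezh2_fpkm])
    funnel.append("rip_detected", rip)

    scored = cpc_scores.reindex(sorted(rip))
    n_unscored = int(scored.isna().sum())
    if n_unscored:
        warnings.warn(
            f"{n_unscored} candidate(s) lack a coding-potential score and "
            "fail the noncoding stage",
            stacklevel=2,
        )
    noncoding = frozenset(scored.index[scored <= cfg.max_cpc])
    funnel.append("noncoding", noncoding)

    sub = expr.loc[sorted(noncoding)]
    expressed = frozenset(sub.index[sub["lincRNA_FPKM"] > cfg.min_linc_fpkm])
    funnel.append("expressed", expressed)
    return funnel


def funnel_report(funnel: FilterFunnel) -> pd.DataFrame:
    """One row per stage: name, survivor count, retention vs previous stage."""
    rows = []
    prev: int | None = None
    for name, ids in funnel.stages:
        n = len(ids)
        retention = 100.0 if prev in (None, 0) else 100.0 * n / prev
        if prev == 0:
            retention = 100.0 if n == 0 else float("nan")
        rows.append({"stage": name, "count": n, "retained_pct": retention})
        prev = n
    return pd.DataFrame(rows, columns=["stage", "count", "retained_pct"])


def write_funnel_report(
    funnel: FilterFunnel, tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> pd.DataFrame:
    report = funnel_report(funnel)
    if tsv_path is not None:
        report.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = report.to_dict(orient="records")
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    return report


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read the three-dataset FPKM table (TSV with a header)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EXPRESSION_COLUMNS, f"expression table {path}")
    bad = df[list(EXPRESSION_COLUMNS[1:])]
    if bad.isna().any().any() or (bad < 0).any().any():
        raise FilterValidationError(
            f"{path}: FPKM values must be finite and non-negative"
        )
    return df


def read_cpc_table(path: str | Path) -> pd.DataFrame:
    """Read the coding-potential score table (TSV with a header)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CPC_COLUMNS, f"coding-potential table {path}")
    return df


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FilterValidationError(f"{what} lacks required columns {missing}")
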