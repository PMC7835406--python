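"""Dual-strategy RIP enrichment calls, deduplication, and evidence summaries.

A transcript that survived the candidate cascade is scored by exactly one of
two pseudo-counted log2 ratios, selected by whether the IgG control library
detected it:

* IgG_FPKM > 0  ->  ``igg_ratio``:    log2((EZH2_FPKM + p) / (IgG_FPKM + p))
* IgG_FPKM == 0 ->  ``input_ratio``:  log2((EZH2_FPKM + p) / (lincRNA_FPKM + p))

with pseudo-count p (default 2 FPKM). A ratio at or above the threshold
(default 1, i.e. two-fold over background) calls the transcript bound. The
IgG branch tests exact equality with 0.0: FPKM tables report hard zeros for
transcripts the control library never observed, and the zero branch exists
precisely for those dropouts.

The bound set is then collapsed to one representative per overlapping-isoform
group, cross-species EST evidence is summarized over the eight subsets of
{pig, mouse, human}, and a classical pooled two-sample t-test is provided for
the expression-level group contrasts.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import TranscriptRecord
from .filters import ThresholdConfig, _require_columns

__all__ = [
    "Strategy",
    "EnrichmentCall",
    "EstCategory",
    "DedupPolicy",
    "EnrichmentValidationError",
    "enrichment_ratio",
    "classify_all",
    "deduplicate",
    "categorize_est",
    "est_category_counts",
    "compare_groups",
    "TTestResult",
    "EST_COLUMNS",
    "read_est_table",
]

EST_COLUMNS = ("transcript_id", "pig", "mouse", "human")


class EnrichmentValidationError(ValueError):
    pass


class Strategy(enum.Enum):
    """Which denominator the enrichment ratio used."""

    IGG_RATIO = "igg_ratio"      # EZH2 over the IgG control library
    INPUT_RATIO = "input_ratio"  # EZH2 over the input lincRNA library


@dataclass(frozen=True)
class EnrichmentCall:
    transcript_id: str
    strategy: Strategy
    ratio: float
    bound: bool


class EstCategory(enum.Enum):
    """The eight subsets of {pig, mouse, human} EST evidence."""

    ALL_THREE = "all_three"
    NONE = "none"
    PIG_ONLY = "pig_only"
    MOUSE_ONLY = "mouse_only"
    HUMAN_ONLY = "human_only"
    PIG_MOUSE = "pig_mouse"
    PIG_HUMAN = "pig_human"
    MOUSE_HUMAN = "mouse_human"


_EST_MAP = {
    (True, True, True): EstCategory.ALL_THREE,
    (False, False, False): EstCategory.NONE,
    (True, False, False): EstCategory.PIG_ONLY,
    (False, True, False): EstCategory.MOUSE_ONLY,
    (False, False, True): EstCategory.HUMAN_ONLY,
    (True, True, False): EstCategory.PIG_MOUSE,
    (True, False, True): EstCategory.PIG_HUMAN,
    (False, True, True): EstCategory.MOUSE_HUMAN,
}


@dataclass(frozen=True)
class DedupPolicy:
    """How overlapping bound isoforms collapse to one representative.

    Transcripts whose exonic regions overlap (on the same strand when
    ``strand_aware``) are grouped transitively; the representative is the
    group member with the highest input-library FPKM (``max_lincRNA_FPKM``)
    or, if configured, the lexicographically smallest id. Ties under the
    FPKM rule break lexicographically so the policy is total.
    """

    strand_aware: bool = True
    tie_break: str = "max_lincRNA_FPKM"

    def __post_init__(self) -> None:
        if self.tie_break not in ("max_lincRNA_FPKM", "lexicographic_id"):
            raise EnrichmentValidationError(
                f"unknown tie_break {self.tie_break!r}"
            )


def enrichment_ratio(
    transcript_id: str,
    linc_fpkm: float,
    ezh2_fpkm: float,
    igg_fpkm: float,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> EnrichmentCall:
    """Score one transcript with the strategy its IgG value selects."""
    for name, v in (
        ("lincRNA_FPKM", linc_fpkm),
        ("EZH2_FPKM", ezh2_fpkm),
        ("IgG_FPKM", igg_fpkm),
    ):
        if not math.isfinite(v) or v < 0:
            raise EnrichmentValidationError(
                f"{transcript_id}: {name} must be finite and >= 0, got {v}"
            )
    p = cfg.pseudo_count
    if igg_fpkm > 0:
        strategy = Strategy.IGG_RATIO
        ratio = math.log2((ezh2_fpkm + p) / (igg_fpkm + p))
    else:
        strategy = Strategy.INPUT_RATIO
        ratio = math.log2((ezh2_fpkm + p) / (linc_fpkm + p))
    return EnrichmentCall(
        transcript_id=transcript_id,
        strategy=strategy,
        ratio=ratio,
        bound=ratio >= cfg.min_ratio,
    )


def classify_all(
    expr: pd.DataFrame, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[frozenset[str], frozenset[str], pd.DataFrame]:
    """Call every record in ``expr``; return (bound, non_bound, calls table).

    The calls table has columns transcript_id, strategy, ratio, bound; the
    bound and non-bound id sets partition the input. Vectorized, but
    row-for-row identical to :func:`enrichment_ratio`.
    """
    _require_columns(expr, ("transcript_id", "lincRNA_FPKM", "EZH2_FPKM",
                            "IgG_FPKM"), "expression")
    fpkm = expr[["lincRNA_FPKM", "EZH2_FPKM", "IgG_FPKM"]].to_numpy(float)
    if not np.isfinite(fpkm).all() or (fpkm < 0).any():
        raise EnrichmentValidationError(
            "FPKM values must be finite and non-negative"
        )
    linc, ezh2, igg = fpkm.T
    p = cfg.pseudo_count
    zero_igg = igg == 0.0
    denom = np.where(zero_igg, linc, igg)
    ratio = np.log2((ezh2 + p) / (denom + p))
    bound = ratio >= cfg.min_ratio
    calls = pd.DataFrame(
        {
            "transcript_id": expr["transcript_id"].to_numpy(),
            "strategy": np.where(
                zero_igg, Strategy.INPUT_RATIO.value, Strategy.IGG_RATIO.value
            ),
            "ratio": ratio,
            "bound": bound,
        }
    )
    bound_ids = frozenset(calls.loc[calls["bound"], "transcript_id"])
    non_bound_ids = frozenset(calls.loc[~calls["bound"], "transcript_id"])
    return bound_ids, non_bound_ids, calls


def strategy_subtotals(calls: pd.DataFrame) -> pd.DataFrame:
    """Bound / non-bound counts per strategy, conserving the total."""
    out = (
        calls.groupby(["strategy", "bound"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["strategy", "bound"], ignore_index=True)
    )
    return out


# ---------------------------------------------------------------------------
# deduplication


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def dedup_groups(
    transcripts: Sequence[TranscriptRecord], policy: DedupPolicy = DedupPolicy()
) -> list[list[TranscriptRecord]]:
    """Transitive groups of transcripts with overlapping exonic regions.

    A single sweep over exons sorted by start unions transcripts whose exons
    intersect on the same chromosome (and strand, when the policy is
    strand-aware); transitivity comes from the union-find closure.
    """
    uf = _UnionFind(len(transcripts))
    exons: list[tuple[str, str, int, int, int]] = []
    for idx, rec in enumerate(transcripts):
        strand = rec.strand if policy.strand_aware else "."
        for e in rec.exons:
            exons.append((e.chrom, strand, e.start, e.end, idx))
    exons.sort()
    # sweep within each (chrom, strand) bucket: an exon overlaps a prior one
    # iff its start precedes the running maximum end
    active_key: tuple[str, str] | None = None
    active: list[tuple[int, int]] = []  # (end, idx) not yet closed
    for chrom, strand, start, end, idx in exons:
        key = (chrom, strand)
        if key != active_key:
            active_key, active = key, []
        active = [(aend, aidx) for aend, aidx in active if aend > start]
        for _aend, aidx in active:
            uf.union(aidx, idx)
        active.append((end, idx))
    groups: dict[int, list[TranscriptRecord]] = {}
    for idx, rec in enumerate(transcripts):
        groups.setdefault(uf.find(idx), []).append(rec)
    return [sorted(g, key=lambda r: r.transcript_id) for g in groups.values()]


def deduplicate(
    bound: Iterable[TranscriptRecord],
    expr: pd.DataFrame | None = None,
    policy: DedupPolicy = DedupPolicy(),
) -> set[str]:
    """Collapse overlapping bound isoforms to one representative each.

    Returns the representative transcript ids. Idempotent and independent of
    input order. With the ``max_lincRNA_FPKM`` tie-break the expression
    table is required and every transcript must appear in it.
    """
    transcripts = sorted(bound, key=lambda r: r.transcript_id)
    if policy.tie_break == "max_lincRNA_FPKM":
        if expr is None:
            raise EnrichmentValidationError(
                "max_lincRNA_FPKM tie-break needs an expression table"
            )
        fpkm = expr.set_index("transcript_id")["lincRNA_FPKM"]
        missing = [t.transcript_id for t in transcripts
                   if t.transcript_id not in fpkm.index]
        if missing:
            raise EnrichmentValidationError(
                f"transcripts lack expression for deduplication: {missing[:5]}"
            )

    representatives: set[str] = set()
    for group in dedup_groups(transcripts, policy):
        if policy.tie_break == "max_lincRNA_FPKM":
            # highest input FPKM wins; lexicographic id settles exact ties
            rep = max(
                group,
                key=lambda r: (fpkm[r.transcript_id], _NegStr(r.transcript_id)),
            )
        else:
            rep = min(group, key=lambda r: r.transcript_id)
        representatives.add(rep.transcript_id)
    return representatives


class _NegStr(str):
    """Orders strings in reverse, so max() prefers the smaller id on ties."""

    def __lt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)


# ---------------------------------------------------------------------------
# EST evidence


def categorize_est(pig: bool, mouse: bool, human: bool) -> EstCategory:
    """Map a cross-species EST-hit triple to its canonical category."""
    return _EST_MAP[(bool(pig), bool(mouse), bool(human))]


def est_category_counts(est: pd.DataFrame) -> dict[str, int]:
    """Counts per EST category; the eight counts sum to the record count."""
    _require_columns(est, EST_COLUMNS, "EST evidence")
    counts = {cat.value: 0 for cat in EstCategory}
    for pig, mouse, human in est[["pig", "mouse", "human"]].itertuples(
        index=False
    ):
        counts[categorize_est(pig, mouse, human).value] += 1
    return counts


def read_est_table(path: str) -> pd.DataFrame:
    """TSV with header transcript_id, pig, mouse, human (0/1 flags)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EST_COLUMNS, f"EST table {path}")
    for col in ("pig", "mouse", "human"):
        df[col] = df[col].astype(bool)
    return df


# ---------------------------------------------------------------------------
# group comparison


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float


def compare_groups(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sample Student's t-test between expression-level groups.

    The default is the classical pooled equal-variance form with
    df = n_a + n_b - 2; ``welch=True`` switches to the unequal-variance
    form. Two groups with zero pooled variance and equal means compare as
    t = 0, p = 1 rather than 0/0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EnrichmentValidationError(
            "each group needs at least two observations"
        )
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise EnrichmentValidationError("group values must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = float(a.size + b.size - 2)
        return TTestResult(statistic=0.0, pvalue=1.0, df=df)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        df=float(res.df),
    )
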