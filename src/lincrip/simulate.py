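"""Seeded simulator for a RIP-seq lincRNA screen with planted ground truth.

The generator emits exactly the files the identification pipeline consumes —
a reference annotation GTF, a novel-transcript GTF, the three-dataset FPKM
table (input lincRNA library, RIP pulldown, IgG control), a coding-potential
score table and cross-species EST flags — plus a truth table recording, for
every novel transcript, whether it was planted noncoding, whether it was
planted protein-bound, and the multiplicative enrichment factor used.

Statistical model
-----------------
* Input-library abundance is log-normal: lincRNA_FPKM ~ LogNormal(mu, sigma).
* The IgG control is scaled-down input with multiplicative log-normal noise,
  set to exactly 0 with probability ``igg_dropout_prob`` — the dropout regime
  that forces the classifier onto its input-ratio strategy.
* The RIP pulldown of a bound transcript is the background level times a
  log-normal enrichment factor (median ``enrichment_factor_mean``); an
  unbound transcript's pulldown sits at background with noise.
* Coding-potential scores are a two-component (bimodal) Gaussian mixture
  selected by the planted noncoding label.
* EST hits are independent Bernoulli per species.

Planted class counts (noncoding, bound, geometry violators) are exact —
sampled without replacement, not Bernoulli — so tests can assert counts
without tolerance. One master seed drives per-field child generators spawned
from a ``numpy`` SeedSequence in a fixed order, so adding a new sampled
field appends a stream without perturbing earlier ones; identical parameters
give byte-identical output files.

Geometry violators exercise every candidate filter: ``too_short``
transcripts sit in valid intergenic slots but with spliced length below the
length cutoff, ``too_close`` transcripts are intergenic but under 1 kb from
the nearest gene, and ``genic`` transcripts overlap a reference gene.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    GenomicInterval,
    TranscriptCatalog,
    TranscriptRecord,
    write_gtf,
)
from .filters import FilterFunnel

__all__ = [
    "SimParams",
    "SimConfigError",
    "SimulatedDataset",
    "RecoverySummary",
    "simulate_dataset",
    "write_dataset",
    "evaluate_recovery",
    "PLACEMENT_CATEGORIES",
]

PLACEMENT_CATEGORIES = ("valid", "too_short", "too_close", "genic")


class SimConfigError(ValueError):
    """Simulation parameters are inconsistent or geometrically infeasible."""


@dataclass(frozen=True)
class SimParams:
    """All knobs of the simulator, with the screen's regime as defaults.

    The defaults emulate the study conditions the pipeline was built for:
    several hundred novel transcripts against a sparse reference annotation;
    right-skewed input expression with a median near 1 FPKM so the detection
    and expression floors both bite; an IgG control at a quarter of input
    abundance with a high dropout rate (most transcripts are never seen in
    the control library, as is typical for IgG pulldowns); a bound minority
    with median 16-fold enrichment over background; and a clearly bimodal
    coding-potential score distribution.
    """

    seed: int = 0
    # geometry
    n_chrom: int = 5
    chrom_length: int = 3_000_000
    n_reference_genes: int = 120
    n_novel: int = 400
    frac_too_short: float = 0.05
    frac_too_close: float = 0.05
    frac_genic: float = 0.05
    gene_span_range: tuple[int, int] = (2_000, 8_000)
    min_exons: int = 1
    max_exons: int = 3
    exon_length_range: tuple[int, int] = (200, 800)
    intron_length_range: tuple[int, int] = (200, 2_000)
    short_length_range: tuple[int, int] = (50, 199)
    clearance: int = 1_000  # minimum planted intergenic gap for valid slots
    extra_gap_max: int = 2_000
    # planted labels
    frac_noncoding: float = 0.7
    frac_bound_of_noncoding: float = 0.35
    # expression model
    expr_log_mean: float = 0.5
    expr_log_sd: float = 1.2
    enrichment_factor_mean: float = 16.0
    enrichment_factor_sd: float = 0.5
    igg_background_factor: float = 0.25
    igg_dropout_prob: float = 0.85
    background_noise_sd: float = 0.25
    # coding potential (two Gaussian components)
    cpc_noncoding_mean: float = -2.5
    cpc_noncoding_sd: float = 0.8
    cpc_coding_mean: float = 1.5
    cpc_coding_sd: float = 1.0
    # EST evidence: per-species hit probabilities (pig, mouse, human)
    est_probs: tuple[float, float, float] = (0.55, 0.15, 0.15)

    def __post_init__(self) -> None:
        fracs = {
            "frac_too_short": self.frac_too_short,
            "frac_too_close": self.frac_too_close,
            "frac_genic": self.frac_genic,
            "frac_noncoding": self.frac_noncoding,
            "frac_bound_of_noncoding": self.frac_bound_of_noncoding,
            "igg_dropout_prob": self.igg_dropout_prob,
            **{f"est_probs[{i}]": p for i, p in enumerate(self.est_probs)},
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {value}")
        if self.frac_too_short + self.frac_too_close + self.frac_genic > 1:
            raise SimConfigError("violator fractions must sum to <= 1")
        for name in ("expr_log_sd", "enrichment_factor_sd",
                     "background_noise_sd", "cpc_noncoding_sd",
                     "cpc_coding_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.enrichment_factor_mean <= 0:
            raise SimConfigError("enrichment_factor_mean must be > 0")
        if self.igg_background_factor <= 0:
            raise SimConfigError("igg_background_factor must be > 0")
        if self.n_chrom < 1 or self.chrom_length < 10 * self.clearance:
            raise SimConfigError("genome too small for the configured layout")
        if self.min_exons < 1 or self.max_exons < self.min_exons:
            raise SimConfigError("need 1 <= min_exons <= max_exons")


@dataclass
class SimulatedDataset:
    """Everything :func:`simulate_dataset` produced, in memory."""

    params: SimParams
    reference: TranscriptCatalog
    novel: TranscriptCatalog
    expression: pd.DataFrame
    cpc: pd.DataFrame
    est: pd.DataFrame
    truth: pd.DataFrame


@dataclass
class _NovelSpec:
    index: int
    category: str
    exon_lengths: list[int]
    intron_lengths: list[int]

    @property
    def span_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


def simulate_dataset(params: SimParams) -> SimulatedDataset:
    """Generate one fully ground-truthed screen dataset.

    Raises :class:`SimConfigError` before producing anything if the
    configured features cannot be placed on the configured genome.
    """
    streams = np.random.SeedSequence(params.seed).spawn(7)
    rng_geom, rng_labels, rng_expr, rng_enrich, rng_igg, rng_cpc, rng_est = (
        np.random.default_rng(s) for s in streams
    )

    n = params.n_novel
    n_short = int(round(params.frac_too_short * n))
    n_close = int(round(params.frac_too_close * n))
    n_genic = int(round(params.frac_genic * n))
    n_valid = n - n_short - n_close - n_genic
    if n_valid < 0:
        raise SimConfigError("violator fractions leave no valid transcripts")
    if (n_close or n_genic) and params.n_reference_genes == 0:
        raise SimConfigError(
            "too_close/genic violators require at least one reference gene"
        )

    categories = np.array(
        ["valid"] * n_valid + ["too_short"] * n_short
        + ["too_close"] * n_close + ["genic"] * n_genic
    )
    rng_geom.shuffle(categories)

    specs = [
        _NovelSpec(i, cat, *_exon_structure(cat, params, rng_geom))
        for i, cat in enumerate(categories)
    ]

    reference, novel = _place_features(specs, params, rng_geom)

    # planted labels: exact counts, sampled without replacement
    n_noncoding = int(round(params.frac_noncoding * n))
    n_bound = int(round(params.frac_bound_of_noncoding * n_noncoding))
    noncoding_idx = rng_labels.choice(n, size=n_noncoding, replace=False)
    is_noncoding = np.zeros(n, dtype=bool)
    is_noncoding[noncoding_idx] = True
    bound_idx = rng_labels.choice(
        np.flatnonzero(is_noncoding), size=n_bound, replace=False
    )
    is_bound = np.zeros(n, dtype=bool)
    is_bound[bound_idx] = True

    # expression model
    linc = rng_expr.lognormal(params.expr_log_mean, params.expr_log_sd, n)
    background = params.igg_background_factor * linc
    factor = np.ones(n)
    factor[is_bound] = rng_enrich.lognormal(
        np.log(params.enrichment_factor_mean),
        params.enrichment_factor_sd,
        n_bound,
    )
    ezh2_noise = _lognoise(rng_enrich, params.background_noise_sd, n)
    ezh2 = np.where(
        is_bound, factor * background, background * ezh2_noise
    )
    igg_noise = _lognoise(rng_igg, params.background_noise_sd, n)
    igg = background * igg_noise
    dropped = rng_igg.random(n) < params.igg_dropout_prob
    igg[dropped] = 0.0

    cpc_scores = np.where(
        is_noncoding,
        rng_cpc.normal(params.cpc_noncoding_mean, params.cpc_noncoding_sd, n),
        rng_cpc.normal(params.cpc_coding_mean, params.cpc_coding_sd, n),
    )

    est_flags = rng_est.random((n, 3)) < np.asarray(params.est_probs)

    # the novel catalog preserves spec-index order, matching the label arrays
    ids = [rec.transcript_id for rec in novel]

    expression = pd.DataFrame(
        {
            "transcript_id": ids,
            "lincRNA_FPKM": linc,
            "EZH2_FPKM": ezh2,
            "IgG_FPKM": igg,
        }
    )
    cpc = pd.DataFrame({"transcript_id": ids, "cpc_score": cpc_scores})
    est = pd.DataFrame(
        {
            "transcript_id": ids,
            "pig": est_flags[:, 0].astype(int),
            "mouse": est_flags[:, 1].astype(int),
            "human": est_flags[:, 2].astype(int),
        }
    )
    truth = pd.DataFrame(
        {
            "transcript_id": ids,
            "placement": categories,
            "is_noncoding": is_noncoding,
            "is_bound": is_bound,
            "true_enrichment_factor": factor,
        }
    )
    return SimulatedDataset(
        params=params,
        reference=reference,
        novel=novel,
        expression=expression,
        cpc=cpc,
        est=est,
        truth=truth,
    )


def _lognoise(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.ones(n)
    return rng.lognormal(0.0, sd, n)


def _exon_structure(
    category: str, params: SimParams, rng: np.random.Generator
) -> tuple[list[int], list[int]]:
    """Sample (exon_lengths, intron_lengths) for one novel transcript."""
    if category == "too_short":
        lo, hi = params.short_length_range
        return [int(rng.integers(lo, hi + 1))], []
    n_exons = int(rng.integers(params.min_exons, params.max_exons + 1))
    elo, ehi = params.exon_length_range
    ilo, ihi = params.intron_length_range
    exons = [int(rng.integers(elo, ehi + 1)) for _ in range(n_exons)]
    introns = [int(rng.integers(ilo, ihi + 1)) for _ in range(n_exons - 1)]
    return exons, introns


def _build_transcript(
    tid: str, gid: str, chrom: str, strand: str, start: int, spec: _NovelSpec,
    source: str,
) -> TranscriptRecord:
    exons = []
    pos = start
    for i, elen in enumerate(spec.exon_lengths):
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < len(spec.intron_lengths):
            pos += spec.intron_lengths[i]
    return TranscriptRecord(
        transcript_id=tid, gene_id=gid, exons=tuple(exons), source=source
    )


def _place_features(
    specs: list[_NovelSpec], params: SimParams, rng: np.random.Generator
) -> tuple[TranscriptCatalog, TranscriptCatalog]:
    """Lay genes and novel transcripts left-to-right along chromosomes.

    Each chromosome alternates reference genes with at most one novel
    transcript per inter-gene slot; a novel transcript's left gap encodes
    its placement category, and the cursor then advances far enough that the
    next gene honors every already-placed transcript's category.
    """
    n_chrom = params.n_chrom
    gene_bins: list[int] = [
        params.n_reference_genes // n_chrom
        + (1 if c < params.n_reference_genes % n_chrom else 0)
        for c in range(n_chrom)
    ]
    novel_bins: list[list[_NovelSpec]] = [[] for _ in range(n_chrom)]
    chroms_with_genes = [c for c in range(n_chrom) if gene_bins[c] > 0]
    vi = ai = 0
    for spec in specs:
        # violators anchored to a gene must land where genes exist
        if spec.category in ("too_close", "genic"):
            c = chroms_with_genes[vi % len(chroms_with_genes)]
            vi += 1
        else:
            c = ai % n_chrom
            ai += 1
        novel_bins[c].append(spec)

    reference = TranscriptCatalog(genome_tag="simulated")
    placed_novels: list[tuple[_NovelSpec, TranscriptRecord]] = []
    gene_counter = 0
    limit = params.chrom_length - params.clearance
    for c in range(n_chrom):
        chrom = f"chrS{c + 1}"
        cursor = params.clearance
        genes_left = gene_bins[c]
        queue = list(novel_bins[c])
        last_gene: tuple[int, int] | None = None  # (start, end)
        while genes_left or queue:
            if genes_left:
                g_len = int(
                    rng.integers(
                        params.gene_span_range[0], params.gene_span_range[1] + 1
                    )
                )
                g_start, g_end = cursor, cursor + g_len
                if g_end > limit:
                    raise SimConfigError(
                        f"{chrom}: reference gene at {g_start} exceeds "
                        f"chromosome length {params.chrom_length}"
                    )
                gene_counter += 1
                strand = "+" if rng.random() < 0.5 else "-"
                reference.add(
                    TranscriptRecord(
                        transcript_id=f"REFT_{gene_counter:05d}",
                        gene_id=f"REFG_{gene_counter:05d}",
                        exons=(GenomicInterval(chrom, g_start, g_end, strand),),
                        source="reference",
                    )
                )
                last_gene = (g_start, g_end)
                genes_left -= 1
                cursor = g_end
            if queue:
                spec = queue.pop(0)
                span = spec.span_length
                if spec.category == "genic":
                    if last_gene is None:
                        raise SimConfigError(
                            f"{chrom}: genic violator needs a preceding gene"
                        )
                    overlap = int(
                        rng.integers(1, min(last_gene[1] - last_gene[0], span))
                    )
                    start = last_gene[1] - overlap
                elif spec.category == "too_close":
                    if last_gene is None:
                        raise SimConfigError(
                            f"{chrom}: too_close violator needs a preceding "
                            "gene"
                        )
                    gap = int(rng.integers(1, params.clearance))
                    start = last_gene[1] + gap
                else:  # valid or too_short: >= clearance from everything
                    gap = params.clearance + int(
                        rng.integers(0, params.extra_gap_max + 1)
                    )
                    start = cursor + gap
                end = start + span
                if end > limit:
                    raise SimConfigError(
                        f"{chrom}: novel transcript at {start} exceeds "
                        f"chromosome length {params.chrom_length}"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                rec = _build_transcript(
                    tid=f"TCONS_SIM_{spec.index:07d}",
                    gid=f"XLOC_SIM_{spec.index:07d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    spec=spec,
                    source="novel",
                )
                placed_novels.append((spec, rec))
                cursor = (
                    max(cursor, end)
                    + params.clearance
                    + int(rng.integers(0, params.extra_gap_max + 1))
                )
            elif genes_left:
                cursor += params.clearance + int(
                    rng.integers(0, params.extra_gap_max + 1)
                )

    placed_novels.sort(key=lambda pair: pair[0].index)
    novel = TranscriptCatalog(genome_tag="simulated")
    for _spec, rec in placed_novels:
        novel.add(rec)
    return reference, novel


# ---------------------------------------------------------------------------
# file output


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict:
    """Write the six dataset files plus a manifest with checksums.

    Returns the manifest dict. Identical parameters (including the seed)
    yield byte-identical files, hence identical checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_gtf": outdir / "reference.gtf",
        "novel_gtf": outdir / "novel.gtf",
        "expression_tsv": outdir / "expression.tsv",
        "cpc_tsv": outdir / "cpc.tsv",
        "est_tsv": outdir / "est.tsv",
        "truth_tsv": outdir / "truth.tsv",
    }
    write_gtf(dataset.reference, paths["reference_gtf"])
    write_gtf(dataset.novel, paths["novel_gtf"])
    dataset.expression.to_csv(paths["expression_tsv"], sep="\t", index=False)
    dataset.cpc.to_csv(paths["cpc_tsv"], sep="\t", index=False)
    dataset.est.to_csv(paths["est_tsv"], sep="\t", index=False)
    dataset.truth.to_csv(paths["truth_tsv"], sep="\t", index=False)
    manifest = {
        "params": asdict(dataset.params),
        "files": {
            key: {
                "path": p.name,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for key, p in paths.items()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass(frozen=True)
class RecoverySummary:
    """Confusion summary of bound-calls against the planted truth.

    Rates are computed among cascade survivors — the only transcripts the
    classifier ever sees — while ``end_to_end_sensitivity`` charges the
    pipeline for planted-bound transcripts lost in the cascade as well.
    """

    n_survivors: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    n_true_bound_total: int
    end_to_end_sensitivity: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_recovery(
    calls: pd.DataFrame, truth: pd.DataFrame, funnel: FilterFunnel
) -> RecoverySummary:
    """Score bound-calls against planted labels among cascade survivors."""
    call_ids = set(calls["transcript_id"])
    truth_ids = set(truth["transcript_id"])
    unknown = call_ids - truth_ids
    if unknown:
        raise ValueError(
            f"calls contain ids absent from the truth table: "
            f"{sorted(unknown)[:5]}"
        )
    survivors = funnel.surviving()
    if not survivors <= call_ids:
        raise ValueError("funnel survivors missing from the calls table")
    merged = calls.set_index("transcript_id").join(
        truth.set_index("transcript_id")[["is_bound"]], how="inner"
    )
    merged = merged.loc[sorted(survivors)]
    called = merged["bound"].to_numpy(bool)
    actual = merged["is_bound"].to_numpy(bool)
    tp = int((called & actual).sum())
    fp = int((called & ~actual).sum())
    tn = int((~called & ~actual).sum())
    fn = int((~called & actual).sum())
    n_true_bound_total = int(truth["is_bound"].sum())
    return RecoverySummary(
        n_survivors=len(merged),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        precision=_rate(tp, tp + fp),
        n_true_bound_total=n_true_bound_total,
        end_to_end_sensitivity=_rate(tp, n_true_bound_total),
    )


def _rate(num: int, denom: int) -> float:
    return float("nan") if denom == 0 else num / denom
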