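# Methods

## The screening model

The pipeline identifies lincRNAs enriched in a protein pulldown from three
FPKM measurements per transcript: the input RNA library (`lincRNA_FPKM`),
the antibody pulldown (`EZH2_FPKM`), and a nonspecific IgG control
(`IgG_FPKM`). It makes no distributional assumptions about expression; the
screen is a deterministic threshold cascade followed by a pseudo-counted
ratio classifier.

**Candidate geometry.** A novel transcript qualifies as a lincRNA candidate
if its spliced length (sum of exon lengths, not genomic span) is at least
`min_length` (default 200 bp) and it is intergenic with clearance: its
genomic span overlaps no annotated transcript span, and the number of bases
strictly between its span and the nearest annotated span is at least
`min_neighbor_gap` (default 1000). Both geometric comparisons are
strand-agnostic and consider annotated transcripts of every biotype — the
conservative reading of "intergenic". A transcript alone on its chromosome
trivially satisfies the gap rule. Internally all coordinates are 0-based
half-open; GTF I/O converts from 1-based inclusive in exactly one module so
off-by-one behavior is auditable, and round-trip preservation of every exon
boundary is tested.

**Expression cascade.** Four stages in a fixed order, each intersecting the
previous survivors: input detection (`lincRNA_FPKM > 0.1`), pulldown
detection (`EZH2_FPKM > 0`), noncoding (`cpc_score ≤ −1`; coding-potential
scores are an input, negative means predicted noncoding), and the
expression floor (`lincRNA_FPKM > 1`). FPKM floors are strict and the
score/length/gap cutoffs inclusive; comparisons are exact floating-point
against the configured thresholds — an epsilon would act as a second,
undocumented threshold. The ordered funnel is reported per stage; the final
set equals the unordered conjunction of the predicates, which is tested.
Transcripts missing a coding-potential score are dropped at the noncoding
stage with a warning: a missing score signals an upstream failure, and
dropping is the conservative action.

**Enrichment classifier.** Each cascade survivor is scored by exactly one
of two log2 ratios with pseudo-count `p = 2` FPKM, selected by whether the
IgG library detected it: `log2((EZH2+p)/(IgG+p))` when `IgG_FPKM > 0`, else
`log2((EZH2+p)/(lincRNA+p))`. The branch tests exact equality with zero
because FPKM tables report hard zeros for undetected transcripts; the
zero-IgG regime is common enough in IgG controls that the strategy split is
itself a reported result. A ratio ≥ `min_ratio` (default 1, i.e. two-fold)
calls the transcript bound; the boundary is inclusive. The pseudo-count
bounds the classifier: a transcript undetected in the pulldown has a ratio
of at most 0 and can never be called bound, and under the input-ratio
strategy a transcript of input abundance `L` is called bound only when
`EZH2_FPKM ≥ 2·L + 2`, so weak binders of weakly expressed transcripts are
deliberately unreachable.

**Deduplication.** The bound set is collapsed to one representative per
group of transcripts whose exonic regions overlap transitively (same
strand by default — antisense overlap is a different transcript). The
representative is the member with the highest input FPKM, ties broken
lexicographically by id, so the policy is total, idempotent and
order-invariant; grouping is a single sweep over start-sorted exons with a
union-find closure, tested against an O(n²) transitive-closure oracle.
This operationalizes an otherwise manual "remove redundant isoforms" step;
other definitions of redundancy (locus-level, cross-run) would give
different final counts.

**Evidence summaries.** Cross-species EST hits are consumed as boolean
flags per species and summarized over the eight subsets of
{pig, mouse, human}; counts conserve by construction. Location of the final
set is re-classified against the supplied annotation; because candidates
were already required to be intergenic, the intergenic percentage is 100%
when the same annotation is reused, and below that only if a different
(e.g. newer or broader) annotation is supplied — the API deliberately
accepts any catalog for this step.

**Group comparison.** `compare_groups` is the classical pooled
equal-variance two-sample Student's t with `df = n_a + n_b − 2`
(`scipy.stats.ttest_ind`); Welch's form is available behind a flag. The
degenerate zero-variance/equal-means case returns t = 0, p = 1 rather than
0/0. The pipeline applies no multiple-testing correction: the screen is
threshold-based, not p-value-based, and group contrasts are descriptive.

## The simulator

`simulate_dataset` emulates the statistical structure the classifier
assumes, not raw reads: no fragment- or length-bias, no alignment or
assembly noise, and coding potential and EST evidence are drawn directly
rather than computed from sequence. Passing tests therefore validate the
screen's logic and its behavior across regimes — they do not validate
upstream quantification of real data.

Model and defaults (one global seed; per-field child generators are
spawned from a `numpy.random.SeedSequence` in a fixed documented order, so
adding a sampled field never perturbs earlier ones):

- **Genome/geometry**: 5 chromosomes × 3 Mb; 120 single-exon reference
  genes of 2–8 kb; 400 novel transcripts of 1–3 exons (exons 200–800 bp,
  introns 0.2–2 kb), laid left-to-right with ≥1 kb planted clearance.
  Planted placement classes are exact counts: 85% valid, 5% spliced length
  50–199 bp (fails only the length rule), 5% intergenic but 1–999 bp from
  a gene (fails only the gap rule), 5% overlapping a gene (fails only the
  location rule). Infeasible layouts raise before any output is written.
- **Labels**: exactly `round(0.7·n)` noncoding, of which exactly
  `round(0.35·…)` bound — sampled without replacement so tests assert
  counts exactly; bound ⊆ noncoding.
- **Expression**: `lincRNA_FPKM ~ LogNormal(μ=0.5, σ=1.2)` (median
  ≈1.6 FPKM, right-skewed, so both FPKM floors bite realistically). The
  background pulldown level is `0.25 × lincRNA_FPKM`; IgG is background
  with multiplicative LogNormal(0, 0.25) noise, zeroed with probability
  0.85 — matching the observed dominance of the zero-IgG branch in typical
  IgG controls, where roughly six of seven classified transcripts carry an
  IgG zero. A bound transcript's pulldown is background times an
  enrichment factor ~ LogNormal(ln 16, 0.5); an unbound transcript's is
  background times noise. The median factor of 16 makes the bound class
  detectable but not trivially so: under the input-ratio strategy a factor
  f calls a transcript of abundance L bound only when `f ≥ 8 + 8/L`, so
  factors near the background-to-input ratio are invisible by design.
- **Coding potential**: Normal(−2.5, 0.8) for noncoding, Normal(+1.5, 1.0)
  for coding — clearly bimodal with ≈97% of noncoding transcripts below
  the −1 cutoff.
- **EST flags**: independent Bernoulli per species at (0.55, 0.15, 0.15),
  giving the pig-heavy, many-none category profile typical of a
  pig-centric catalog.

The *separable regime* (factor 64, zero factor variance, zero dropout,
zero background noise) is the analytic sanity point: every bound cascade
survivor's ratio is `log2((64·B+2)/(B+2)) > 1` for any background level B
reached by survivors, and every unbound survivor's ratio is exactly 0, so
sensitivity and specificity must both be 1.0 among survivors — this is
asserted, as is the end-to-end propagation of the inclusive ratio boundary
(triples constructed so the ratio is exactly 1 must all be called bound).

`evaluate_recovery` reports sensitivity/specificity/precision among
cascade survivors (the only transcripts the classifier sees) and an
end-to-end sensitivity that also charges cascade losses.

## Quantification utilities

`ddct_fold_change` implements 2^−ΔΔCt with a fixed amplification
efficiency of 2: ΔCt per sample, group-mean ΔΔCt, fold = 2^−ΔΔCt, plus
per-replicate folds for dispersion. `chip_fold_enrichment` is
2^(Ct_control − Ct_IP) against the IgG mock pulldown; the percent-input
convention is provided separately (`chip_percent_input`, default 1%
input, Ct adjusted by log2 of the dilution). Both are exactly linear in Ct
differences on the log2 scale and invariant under per-plate constant Ct
shifts; both identities are tested to machine precision.
Efficiency-corrected (Pfaffl) quantification is out of scope.

## Numerical and design notes

- Exact set semantics everywhere: stage survivors are id sets, compared by
  equality against an independent naive re-implementation on randomized
  datasets; counts are derived from the sets, never tracked separately.
- The funnel raises on any non-subset stage rather than reporting an
  inconsistent cascade.
- Validation sizes: randomized-equivalence tests use catalogs of 80–200
  novel transcripts across 50 seeds and tables of up to 1,000 records —
  set equality is size-independent, and these sizes keep the suite quick;
  Monte-Carlo calibration of the t-test uses 10,000 null draws of 10 vs 10.
- Determinism: identical parameters (including seed) give byte-identical
  output files (checksummed in a manifest); pipeline outputs contain no
  timestamps, so re-runs are byte-identical too.
- Known limitations: FPKM is taken as given (no uncertainty model), the
  enrichment call has no significance statistic attached (as in
  threshold-based screens generally), deduplication is one documented
  policy among several defensible ones, and the simulator's independence
  assumptions (expression vs. coding potential vs. EST evidence) are
  stronger than real catalogs warrant.
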