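"""Independent brute-force re-implementations used as test oracles.

Everything here is written for obviousness, not speed: per-base position
sets, O(n*m) pairwise scans, and explicit transitive closures. These
functions deliberately share no code with the package internals they check.
"""

from __future__ import annotations

import math


def naive_spliced_length(exons) -> int:
    """Count exonic base positions one by one."""
    covered = set()
    for e in exons:
        covered.update(range(e.start, e.end))
    return len(covered)


def naive_neighbor_distance(t, annotation):
    """Exhaustive pairwise scan over all annotated spans; None = no neighbor."""
    span = t.span
    best = None
    for other in annotation:
        o = other.span
        if o.chrom != span.chrom:
            continue
        if o.start < span.end and span.start < o.end:
            gap = 0
        elif o.start >= span.end:
            gap = o.start - span.end
        else:
            gap = span.start - o.end
        best = gap if best is None else min(best, gap)
    return best


def naive_is_intergenic(t, annotation) -> bool:
    span = t.span
    for other in annotation:
        o = other.span
        if o.chrom == span.chrom and o.start < span.end and span.start < o.end:
            return False
    return True


def naive_select_candidates(novel, reference, cfg):
    """Conjunction of the three candidate predicates, checked independently."""
    kept = set()
    for rec in novel:
        long_enough = naive_spliced_length(rec.exons) >= cfg.min_length
        intergenic = naive_is_intergenic(rec, reference)
        gap = naive_neighbor_distance(rec, reference)
        isolated = gap is None or gap >= cfg.min_neighbor_gap
        if long_enough and intergenic and isolated:
            kept.add(rec.transcript_id)
    return kept


def naive_cascade_sets(candidates, expr_df, cpc_df, cfg):
    """Recompute every cascade stage with plain dict lookups."""
    expr = {
        row.transcript_id: (row.lincRNA_FPKM, row.EZH2_FPKM, row.IgG_FPKM)
        for row in expr_df.itertuples(index=False)
    }
    cpc = {
        row.transcript_id: row.cpc_score
        for row in cpc_df.itertuples(index=False)
    }
    stage0 = set(candidates)
    stage1 = {t for t in stage0 if expr[t][0] > cfg.detect_fpkm}
    stage2 = {t for t in stage1 if expr[t][1] > cfg.min_ezh2_fpkm}
    stage3 = {t for t in stage2 if t in cpc and cpc[t] <= cfg.max_cpc}
    stage4 = {t for t in stage3 if expr[t][0] > cfg.min_linc_fpkm}
    return [stage0, stage1, stage2, stage3, stage4]


def naive_call(linc, ezh2, igg, cfg):
    """One enrichment call computed with scalar math."""
    p = cfg.pseudo_count
    if igg == 0.0:
        strategy = "input_ratio"
        ratio = math.log2((ezh2 + p) / (linc + p))
    else:
        strategy = "igg_ratio"
        ratio = math.log2((ezh2 + p) / (igg + p))
    return strategy, ratio, ratio >= cfg.min_ratio


def naive_dedup_groups(transcripts, strand_aware=True):
    """Transitive closure of pairwise exonic overlap, by repeated merging."""

    def overlap(a, b):
        if a.chrom != b.chrom:
            return False
        if strand_aware and a.strand != b.strand:
            return False
        for ea in a.exons:
            for eb in b.exons:
                if ea.start < eb.end and eb.start < ea.end:
                    return True
        return False

    groups = [{t.transcript_id} for t in transcripts]
    by_id = {t.transcript_id: t for t in transcripts}
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    overlap(by_id[a], by_id[b])
                    for a in groups[i]
                    for b in groups[j]
                ):
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(g) for g in groups}


def naive_pooled_t(a, b):
    """Closed-form pooled-variance two-sample t statistic and df."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2
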