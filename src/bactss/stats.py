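"""Riboswitch readthrough ratios, functional-category enrichment,
transcription-initiation nucleotide statistics, and per-gene depth summaries.

The readthrough ratio is the mean whole-transcriptome coverage of a
cis-regulatory element's 5'-UTR divided by the mean coverage of the
downstream ORF: ratios far above 1 indicate premature transcription
termination at the element (termination-like), ratios near 1 indicate
readthrough into the ORF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genomics_io import CisElementPrediction, GeneFeature, Genome, StrandedProfile


@dataclass
class ReadthroughResult:
    element: CisElementPrediction
    tss_found: bool
    tss_position: int | None
    utr_mean_depth: float
    orf_mean_depth: float
    ratio: float
    verdict: str  # termination-like / readthrough-like
    flags: set = field(default_factory=set)


def readthrough_ratio(element: CisElementPrediction, downstream_gene: GeneFeature,
                      profile: StrandedProfile, tss_records=(),
                      verdict_threshold: float = 10.0,
                      eps: float = 1e-9) -> ReadthroughResult:
    """Coverage ratio of a cis-element's 5'-UTR over its downstream ORF.

    The UTR region runs from the gene's assigned TSS (when one exists) or
    else from the element start, to the base before the gene start,
    strand-aware.  Verdict is termination-like iff ratio >= threshold.
    """
    gid = downstream_gene.gene_id
    tss_pos = None
    for r in tss_records:
        if gid in (r.gene_by_category.get("sTSS"), r.gene_by_category.get("pTSS")):
            if tss_pos is None or r.read_start_count > tss_pos[1]:
                tss_pos = (r.position, r.read_start_count)
    tss_found = tss_pos is not None

    strand = downstream_gene.strand
    if strand == "+":
        utr_start = tss_pos[0] if tss_found else element.start
        utr_end = downstream_gene.start
    else:
        utr_start = downstream_gene.end
        utr_end = (tss_pos[0] + 1) if tss_found else element.end
    if utr_end <= utr_start:
        raise ValueError(
            f"zero-length UTR region for element {element.name!r}")

    depth = np.asarray(profile.depth, dtype=float)
    utr_mean = float(depth[utr_start:utr_end].mean())
    orf_mean = float(depth[downstream_gene.start:downstream_gene.end].mean())
    ratio = utr_mean / max(orf_mean, eps)
    flags = set()
    if orf_mean <= eps:
        flags.add("orf depth ~ 0")
    if not tss_found and 0.5 <= ratio <= 2.0:
        flags.add("no TSS, readthrough-like coverage")
    verdict = ("termination-like" if ratio >= verdict_threshold
               else "readthrough-like")
    return ReadthroughResult(
        element=element, tss_found=tss_found,
        tss_position=tss_pos[0] if tss_found else None,
        utr_mean_depth=utr_mean, orf_mean_depth=orf_mean,
        ratio=ratio, verdict=verdict, flags=flags)


@dataclass
class EnrichmentResult:
    category: str
    subset_with: int
    subset_without: int
    rest_with: int
    rest_without: int
    odds_ratio: float
    p_value: float
    bh_q: float | None = None


def fisher_enrichment(genes_in_subset, all_genes, categories: dict,
                      alternative: str = "two-sided") -> list[EnrichmentResult]:
    """Fisher's exact test per functional category.

    ``categories`` maps gene id to a category label (genes may be absent =
    uncategorised).  Raw p-values are reported together with a
    Benjamini-Hochberg adjusted column.
    """
    all_genes = list(dict.fromkeys(all_genes))
    if not all_genes:
        raise ValueError("empty gene universe")
    subset = set(genes_in_subset)
    if not subset <= set(all_genes):
        raise ValueError("subset must be contained in the gene universe")
    labels = sorted({categories[g] for g in all_genes if g in categories})
    results = []
    for cat in labels:
        with_cat = {g for g in all_genes if categories.get(g) == cat}
        a = len(subset & with_cat)
        b = len(subset) - a
        c = len(with_cat) - a
        d = len(all_genes) - a - b - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
        results.append(EnrichmentResult(
            category=cat, subset_with=a, subset_without=b,
            rest_with=c, rest_without=d,
            odds_ratio=float(odds), p_value=float(p)))
    # Benjamini-Hochberg
    m = len(results)
    order = sorted(range(m), key=lambda i: results[i].p_value)
    qs = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        q = min(prev, results[i].p_value * m / rank)
        qs[i] = q
        prev = q
    for r, q in zip(results, qs):
        r.bh_q = q
    return results


@dataclass
class CategoryInitiation:
    category: str
    n: int
    freqs: dict          # stratum -> {position(-1/+1/+2) -> {base -> freq}}
    mean_read_starts: dict  # stratum -> mean read-start count
    decile_size: int
    deciles_skipped: bool = False


@dataclass
class InitiationStats:
    per_category: dict  # category -> CategoryInitiation


_GROUPS = ("sTSS-group", "pTSS", "iTSS", "asTSS")


def _group_of(record) -> str | None:
    cats = record.categories
    if "sTSS" in cats or record.relabeled_sTSS:
        return "sTSS-group"
    if "pTSS" in cats:
        return "pTSS"
    if "iTSS" in cats:
        return "iTSS"
    if "asTSS" in cats:
        return "asTSS"
    return None


def _base_freqs(records, slot: int) -> dict:
    counts = {b: 0 for b in "ACGT"}
    for r in records:
        b = r.context[slot]
        if b in counts:
            counts[b] += 1
    total = sum(counts.values())
    if total == 0:
        return {b: 0.0 for b in "ACGT"}
    return {b: c / total for b, c in counts.items()}


def initiation_stats(tss_records, genome: Genome,
                     primary_only: bool = False) -> InitiationStats:
    """Nucleotide frequencies at -1/+1/+2 per TSS category, with coverage
    strata.

    Each classified TSS is counted once, in the highest-priority group
    sTSS-group (sTSS, revised, or nTSS folded in) > pTSS > iTSS > asTSS.
    Strata are all TSSs plus the top and bottom decile (ceil(n/10), ties
    broken by genome position) by read-start count; categories with fewer
    than 10 members skip the decile strata and are flagged.
    """
    from .classify import annotate_context

    records = [r for r in tss_records if not r.feature_class]
    if primary_only:
        records = [r for r in records
                   if "primary" in r.rank.values() or not r.rank]
    if any(r.context == ("N", "N", "N") for r in records):
        annotate_context(records, genome)

    per_category = {}
    for group in _GROUPS:
        members = [r for r in records if _group_of(r) == group]
        n = len(members)
        k = math.ceil(n / 10)
        strata = {"all": members}
        skipped = n < 10
        if not skipped:
            by_count = sorted(members,
                              key=lambda r: (-r.read_start_count, r.position))
            strata["top_decile"] = by_count[:k]
            strata["bottom_decile"] = by_count[-k:]
        freqs, means = {}, {}
        for name, rs in strata.items():
            freqs[name] = {pos: _base_freqs(rs, slot)
                           for slot, pos in enumerate((-1, 1, 2))}
            means[name] = (float(np.mean([r.read_start_count for r in rs]))
                           if rs else float("nan"))
        per_category[group] = CategoryInitiation(
            category=group, n=n, freqs=freqs, mean_read_starts=means,
            decile_size=k, deciles_skipped=skipped)
    return InitiationStats(per_category=per_category)


def gene_mean_depth(features, profiles) -> pd.DataFrame:
    """Arithmetic mean of same-strand whole-transcriptome depth over each
    gene body (a simple expression summary)."""
    prof = {(p.replicon_id, p.strand): p for p in profiles}
    rows = []
    for f in features:
        p = prof.get((f.replicon_id, f.strand))
        mean = float(np.asarray(p.depth[f.start:f.end]).mean()) if p is not None \
            and f.end > f.start else 0.0
        rows.append({"gene_id": f.gene_id, "replicon": f.replicon_id,
                     "strand": f.strand, "mean_depth": mean})
    return pd.DataFrame(rows, columns=["gene_id", "replicon", "strand",
                                       "mean_depth"])
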