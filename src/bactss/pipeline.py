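"""End-to-end orchestration of the primary-transcriptome analysis.

Stage order: barcode filter (optional) -> TSS detection -> curation ->
classification and start-codon revision -> ranking -> 5'-UTR/leaderless ->
promoter and RBS motif discovery -> operons/sub-operons -> antisense and
novel transcripts -> statistics.  ``run_analysis`` works on in-memory
objects; ``run_pipeline`` adds file I/O around it; ``simulate_and_score``
generates a synthetic dataset, runs the analysis, and scores recovery
against the planted truth.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import genomics_io as gio
from .genomics_io import CisElementPrediction, Genome
from .detect import DetectionConfig, detect_tss, curate_tss, filter_barcoded_reads
from .classify import (
    ClassificationConfig, build_tss_records, rank_primary_secondary,
    compute_utr_and_leaderless, annotate_context,
)
from .motifs import PromoterConfig, RBSConfig, find_promoters, purine_profile, find_rbs
from .transcripts import (
    OperonConfig, AntisenseConfig, join_operons, derive_suboperons,
    call_antisense_transcript, find_novel_transcripts,
)
from .stats import (
    readthrough_ratio, fisher_enrichment, initiation_stats, gene_mean_depth,
)
from .simulate import SyntheticConfig, generate_dataset, truth_scorer

log = logging.getLogger("bactss")


@dataclass
class PipelineConfig:
    """Paths plus per-stage parameter blocks; the single global seed fans out
    to per-stage seeds by fixed derivation."""

    genome_path: str = ""
    annotation_path: str = ""
    depth_fwd: str = ""
    depth_rev: str = ""
    starts_fwd: str = ""
    starts_rev: str = ""
    reads_path: str | None = None
    spanning_counts_path: str | None = None
    cis_elements_path: str | None = None
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    promoter: PromoterConfig = field(default_factory=PromoterConfig)
    rbs: RBSConfig = field(default_factory=RBSConfig)
    operon: OperonConfig = field(default_factory=OperonConfig)
    antisense: AntisenseConfig = field(default_factory=AntisenseConfig)
    min_orf_aa: int = 25
    # long-UTR band (nt) for the functional-category enrichment test
    enrichment_utr_band: tuple = (100, 300)


@dataclass
class PipelineResult:
    candidates: list = field(default_factory=list)
    removed: list = field(default_factory=list)
    tss_records: list = field(default_factory=list)
    revised_starts: list = field(default_factory=list)
    utr_histogram: dict = field(default_factory=dict)
    promoter_calls: list = field(default_factory=list)
    promoter_summary: dict = field(default_factory=dict)
    motif_models: dict = field(default_factory=dict)
    purine_fractions: list = field(default_factory=list)
    rbs_calls: list = field(default_factory=list)
    rbs_summary: dict = field(default_factory=dict)
    monocistronic: list = field(default_factory=list)
    operons: list = field(default_factory=list)
    suboperons: list = field(default_factory=list)
    antisense_transcripts: list = field(default_factory=list)
    intragenic_transcripts: list = field(default_factory=list)
    novel_transcripts: list = field(default_factory=list)
    readthrough: list = field(default_factory=list)
    enrichment: list = field(default_factory=list)
    initiation: object = None
    gene_depth: object = None
    n_reads_kept: int = 0
    n_reads_discarded: int = 0
    manifest: dict = field(default_factory=dict)


def _stage_seed(seed: int, stage: int) -> int:
    return (seed * 1000003 + stage * 7919) % (2 ** 31 - 1)


def _detected_utr_intervals(records, features):
    """Genomic 5'-UTR intervals of genes with an sTSS/pTSS, for the
    antisense-to-UTR extension."""
    feat_by_id = {f.gene_id: f for f in features}
    utrs = {}
    for r in records:
        for cat in ("sTSS", "pTSS"):
            gid = r.gene_by_category.get(cat)
            if gid is None:
                continue
            f = feat_by_id[gid]
            if r.strand == "+":
                iv = (r.position, f.start)
            else:
                iv = (f.end, r.position + 1)
            if iv[1] <= iv[0]:
                continue
            prev = utrs.get(gid)
            if prev is None or (iv[1] - iv[0]) > (prev[1] - prev[0]):
                utrs[gid] = (iv[0], iv[1], f.strand, f.replicon_id)
    return utrs


def _add_utr_antisense(records, utr_intervals):
    for r in records:
        if r.feature_class:
            continue
        for gid, (s, e, strand, rid) in utr_intervals.items():
            if rid == r.replicon_id and strand != r.strand and s <= r.position < e:
                if "asTSS" not in r.categories:
                    r.categories.add("asTSS")
                    r.gene_by_category["asTSS"] = gid
                    if "nTSS" in r.categories:
                        r.categories.discard("nTSS")
                        r.relabeled_sTSS = False
    return records


def run_analysis(genome: Genome, features, profiles, spanning_counts=None,
                 reads=None, cis_elements=None, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run every analysis stage on in-memory inputs."""
    cfg = config or PipelineConfig()
    res = PipelineResult()
    profiles = list(profiles)
    prof_by_key = {(p.replicon_id, p.strand): p for p in profiles}

    # 1. barcode filter (reported; detection consumes the profiles directly)
    if reads is not None:
        kept, discarded = filter_barcoded_reads(reads, cfg.detection.barcode)
        res.n_reads_kept, res.n_reads_discarded = len(kept), discarded
        log.info("barcode filter: kept %d, discarded %d", len(kept), discarded)

    # 2. detection + curation
    verified = []
    for p in profiles:
        cands = detect_tss(p, cfg.detection)
        res.candidates.extend(cands)
        ok, removed = curate_tss(cands, p, cfg.detection)
        verified.extend(ok)
        res.removed.extend(removed)
    verified.sort(key=lambda c: (c.replicon_id, c.position, c.strand))
    log.info("detected %d candidates, %d verified", len(res.candidates),
             len(verified))

    # 3-5. classification, revision, ranking, UTRs
    records, revised = build_tss_records(verified, features, genome,
                                         cfg.classification)
    res.revised_starts = revised
    classified = [r for r in records if not r.feature_class]
    rank_primary_secondary(classified, features)
    _, res.utr_histogram = compute_utr_and_leaderless(
        classified, features, cfg.classification, revised)
    utr_intervals = _detected_utr_intervals(classified, features)
    if cfg.classification.as_utr_extension:
        _add_utr_antisense(classified, utr_intervals)
    annotate_context(records, genome)
    res.tss_records = records

    # 6. promoter motifs over primary sense TSSs with UTR < 300 nt
    promoter_input = [
        r for r in classified
        if "sTSS" in r.categories
        and r.rank.get(r.gene_by_category.get("sTSS")) == "primary"
        and r.utr_length is not None and r.utr_length < 300
    ]
    if len(promoter_input) >= 2:
        calls, m10, m35, summary = find_promoters(
            promoter_input, genome, cfg.promoter, seed=_stage_seed(cfg.seed, 1))
        res.promoter_calls = calls
        res.promoter_summary = summary
        res.motif_models["minus10"] = m10
        res.motif_models["minus35"] = m35

    # 7. RBS: one 20-nt window per gene with a >=20-nt 5'-UTR
    feat_by_id = {f.gene_id: f for f in features}
    windows, codons = [], []
    seen_genes = set()
    for r in classified:
        gid = r.gene_by_category.get("sTSS") or r.gene_by_category.get("pTSS")
        if gid is None or gid in seen_genes:
            continue
        if r.utr_length is None or r.utr_length < cfg.rbs.utr_min_nt:
            continue
        f = feat_by_id[gid]
        s = f.start_codon_pos()
        if f.strand == "+":
            if s - cfg.rbs.window_nt < 0:
                continue
            win = genome.fetch(f.replicon_id, s - cfg.rbs.window_nt, s)
            codon = genome.fetch(f.replicon_id, s, s + 3)
        else:
            if s + 1 + cfg.rbs.window_nt > genome[f.replicon_id].length:
                continue
            win = genome.fetch(f.replicon_id, s + 1, s + 1 + cfg.rbs.window_nt, "-")
            codon = genome.fetch(f.replicon_id, s - 2, s + 1, "-")
        windows.append(win)
        codons.append(codon)
        seen_genes.add(gid)
    rbs_model = None
    if len(windows) >= 2:
        fractions, mask = purine_profile(windows, cfg.rbs)
        res.purine_fractions = list(fractions)
        extracted = [w for w, m in zip(windows, mask) if m]
        ext_codons = [c for c, m in zip(codons, mask) if m]
        if len(extracted) >= 2:
            rbs_model, rbs_calls, rbs_summary = find_rbs(
                extracted, ext_codons, cfg.rbs, seed=_stage_seed(cfg.seed, 2))
            res.motif_models["rbs"] = rbs_model
            res.rbs_calls = rbs_calls
            res.rbs_summary = rbs_summary

    # 8. operons and sub-operons
    res.gene_depth = gene_mean_depth(features, profiles)
    expressed = set(res.gene_depth.loc[
        res.gene_depth.mean_depth >= cfg.operon.min_expression_depth, "gene_id"])
    res.monocistronic, res.operons = join_operons(
        features, spanning_counts or {}, cfg.operon, expressed)
    for op in res.operons:
        res.suboperons.extend(derive_suboperons(op, classified))

    # 9. antisense, intragenic, novel transcripts
    for r in classified:
        if "asTSS" in r.categories:
            p = prof_by_key.get((r.replicon_id, r.strand))
            call = call_antisense_transcript(r, p, cfg.antisense)
            if call is not None:
                res.antisense_transcripts.append(call)
        elif r.categories == {"iTSS"}:
            p = prof_by_key.get((r.replicon_id, r.strand))
            call = call_antisense_transcript(r, p, cfg.antisense,
                                             kind="intragenic")
            if call is not None:
                res.intragenic_transcripts.append(call)
    for (rid, strand), p in prof_by_key.items():
        pure_n = [r for r in classified
                  if r.categories == {"nTSS"} and r.replicon_id == rid
                  and r.strand == strand]
        if pure_n:
            res.novel_transcripts.extend(find_novel_transcripts(
                pure_n, p, genome, rbs_model, cfg.antisense, cfg.min_orf_aa))

    # 10. statistics
    res.initiation = initiation_stats(classified, genome)
    if cis_elements:
        for e in cis_elements:
            f = feat_by_id.get(e.downstream_gene_id)
            p = prof_by_key.get((e.replicon_id, f.strand)) if f else None
            if f is None or p is None:
                continue
            res.readthrough.append(readthrough_ratio(
                e, f, p, [r for r in classified if r.replicon_id == e.replicon_id]))
    lo, hi = cfg.enrichment_utr_band
    cat_map = {f.gene_id: f.functional_category for f in features
               if f.feature_type == "CDS" and f.functional_category}
    long_utr_genes = {
        r.gene_by_category.get("sTSS") or r.gene_by_category.get("pTSS")
        for r in classified
        if r.utr_length is not None and lo <= r.utr_length <= hi}
    long_utr_genes.discard(None)
    universe = [f.gene_id for f in features if f.feature_type == "CDS"]
    if cat_map and long_utr_genes:
        res.enrichment = fisher_enrichment(
            long_utr_genes & set(universe), universe, cat_map)

    res.manifest = _build_manifest(cfg, res)
    return res


def _category_counts(records) -> dict:
    counts: dict[str, int] = {}
    classified = [r for r in records if not r.feature_class]
    for r in classified:
        for c in sorted(r.categories):
            counts[c] = counts.get(c, 0) + 1
    counts["total_verified"] = len(records)
    counts["structural_rna"] = sum(1 for r in records if r.feature_class)
    counts["classified"] = len(classified)
    counts["leaderless"] = sum(1 for r in classified if r.leaderless)
    counts["primary"] = sum(
        1 for r in classified if "primary" in r.rank.values())
    counts["secondary"] = sum(
        list(r.rank.values()).count("secondary") for r in classified)
    return counts


def _build_manifest(cfg: PipelineConfig, res: PipelineResult) -> dict:
    return {
        "seed": cfg.seed,
        "parameters": {
            "detection": asdict(cfg.detection),
            "classification": asdict(cfg.classification),
            "promoter": asdict(cfg.promoter),
            "rbs": asdict(cfg.rbs),
            "operon": asdict(cfg.operon),
            "antisense": asdict(cfg.antisense),
            "min_orf_aa": cfg.min_orf_aa,
            "increase_signal": cfg.detection.increase_signal,
            "rbs_spacer_anchor": "motif 3' end to start codon",
            "minus10_spacer_anchor": "motif 3' end to +1 site",
        },
        "counts": {
            "candidates": len(res.candidates),
            "removed_by_curation": len(res.removed),
            "reads_kept": res.n_reads_kept,
            "reads_discarded": res.n_reads_discarded,
            "tss": _category_counts(res.tss_records),
            "revised_starts": len(res.revised_starts),
            "monocistronic": len(res.monocistronic),
            "operons": len(res.operons),
            "operon_genes": sum(len(o.gene_ids) for o in res.operons),
            "suboperons": len(res.suboperons),
            "antisense_transcripts": len(res.antisense_transcripts),
            "intragenic_transcripts": len(res.intragenic_transcripts),
            "novel_transcripts": len(res.novel_transcripts),
            "novel_with_orf": sum(
                1 for t in res.novel_transcripts if t.orf is not None),
        },
        "promoter_summary": res.promoter_summary,
        "rbs_summary": res.rbs_summary,
    }


# ---------------------------------------------------------------------------
# file-level entry points
# ---------------------------------------------------------------------------

def _read_spanning_counts(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {(a, b): int(c)
            for a, b, c in zip(df["gene_a"], df["gene_b"], df["count"])}


def _read_cis_elements(path) -> list[CisElementPrediction]:
    df = pd.read_csv(path, sep="\t")
    return [CisElementPrediction(
        name=row.name_, rfam_accession=row.rfam_accession,
        replicon_id=row.replicon, start=int(row.start) - 1, end=int(row.end),
        strand=row.strand, downstream_gene_id=row.downstream_gene)
        for row in df.rename(columns={"name": "name_"}).itertuples()]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Load inputs from files, run the analysis, write tables + manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    for attr in ("genome_path", "annotation_path", "depth_fwd", "depth_rev",
                 "starts_fwd", "starts_rev"):
        path = getattr(config, attr)
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"{attr}: {path!r} does not exist")

    genome = gio.read_genome(config.genome_path)
    features = gio.read_annotation(config.annotation_path, genome)
    profiles = gio.read_stranded_bedgraph(
        config.depth_fwd, config.depth_rev, config.starts_fwd,
        config.starts_rev, genome)
    reads = None
    if config.reads_path:
        from Bio import SeqIO
        reads = list(SeqIO.parse(config.reads_path, "fastq"))
    spanning = (_read_spanning_counts(config.spanning_counts_path)
                if config.spanning_counts_path else None)
    elements = (_read_cis_elements(config.cis_elements_path)
                if config.cis_elements_path else None)

    result = run_analysis(genome, features, profiles, spanning_counts=spanning,
                          reads=reads, cis_elements=elements, config=config)

    os.makedirs(config.out_dir, exist_ok=True)
    gio.write_tables(result, config.out_dir)
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)
    return result


def simulate_and_score(synth_config: SyntheticConfig | None = None,
                       pipeline_config: PipelineConfig | None = None,
                       tolerance_nt: int = 0):
    """Generate a synthetic dataset, run the pipeline, score recovery.

    Returns (RecoveryReport, PipelineResult, SyntheticDataset).
    """
    ds = generate_dataset(synth_config)
    cfg = pipeline_config or PipelineConfig(seed=ds.config.seed)
    result = run_analysis(
        ds.genome, ds.features, ds.profiles,
        spanning_counts=ds.spanning_counts, reads=ds.reads,
        cis_elements=ds.cis_elements, config=cfg)
    report = truth_scorer(result, ds.truth, tolerance_nt)
    return report, result, ds
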