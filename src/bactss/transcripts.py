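"""Operon/sub-operon inference and antisense/novel transcript calling.

Adjacent same-strand genes are joined into an operon when at least 10 reads
span the pair in sense orientation; a TSS assigned to an internal operon gene
defines a sub-operon consisting of that gene and all downstream genes of the
parent.  Antisense and novel transcripts are called by extending coverage
downstream from the TSS while the per-position depth stays at or above a
floor, with an extra start-coverage requirement for long, well-covered
transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomics_io import GeneFeature, Genome, StrandedProfile
from .classify import START_CODONS, STOP_CODONS


@dataclass
class OperonConfig:
    min_spanning_reads: int = 10
    # mean gene-body depth at or above which a gene counts as expressed for
    # the mono/polycistronic census
    min_expression_depth: float = 5.0

    def __post_init__(self):
        if self.min_spanning_reads < 1:
            raise ValueError("min_spanning_reads must be >= 1")


@dataclass
class Operon:
    operon_id: str
    replicon_id: str
    strand: str
    gene_ids: list[str]           # transcription order
    spanning_counts: list[int]    # between consecutive genes, same order
    primary_tss: int | None = None


@dataclass
class SubOperon:
    parent_operon_id: str
    first_gene_id: str
    gene_ids: list[str]           # contiguous suffix of the parent, transcription order
    tss_position: int = -1
    tss_read_starts: int = 0


@dataclass
class AntisenseConfig:
    min_pos_coverage: float = 15.0
    min_length_nt: int = 20
    long_length_nt: int = 500
    long_mean_cov: float = 40.0
    long_start_cutoff: float = 80.0

    def __post_init__(self):
        for v in (self.min_pos_coverage, self.min_length_nt,
                  self.long_length_nt, self.long_mean_cov,
                  self.long_start_cutoff):
            if v <= 0:
                raise ValueError("antisense thresholds must be positive")


@dataclass
class OrfCall:
    start: int  # 0-based half-open genomic interval including the stop codon
    end: int
    start_codon: str
    length_aa: int  # codons before the stop


@dataclass
class NovelTranscript:
    replicon_id: str
    tss_positions: list[int]
    start: int  # 0-based half-open, start < end
    end: int
    strand: str
    kind: str  # intergenic / antisense / intragenic
    orf: OrfCall | None = None
    rbs_found: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _spanning_count(counts: dict, a: str, b: str) -> int:
    return counts.get((a, b), counts.get((b, a), 0))


def join_operons(features: list[GeneFeature], spanning_counts: dict,
                 config: OperonConfig | None = None,
                 expressed_genes: set | None = None):
    """Join annotation-adjacent same-strand genes into operons.

    ``spanning_counts`` maps (gene_id, gene_id) pairs (either order) to the
    number of sense-orientation spanning reads.  Adjacency is in genome
    coordinate order; an intervening opposite-strand gene breaks adjacency,
    and opposite-strand neighbours are never joined.  Returns
    (monocistronic gene ids, operons): every expressed gene not in an operon
    is monocistronic (all genes count as expressed when ``expressed_genes``
    is None).
    """
    config = config or OperonConfig()
    cds = sorted((f for f in features if f.feature_type == "CDS"),
                 key=lambda f: (f.replicon_id, f.start))
    operons: list[Operon] = []
    in_operon: set[str] = set()
    run: list[GeneFeature] = []
    run_counts: list[int] = []

    def flush():
        nonlocal run, run_counts
        if len(run) > 1:
            genes = [f.gene_id for f in run]
            counts = list(run_counts)
            if run[0].strand == "-":
                genes = genes[::-1]
                counts = counts[::-1]
            operons.append(Operon(
                operon_id=f"operon_{len(operons) + 1:04d}",
                replicon_id=run[0].replicon_id, strand=run[0].strand,
                gene_ids=genes, spanning_counts=counts))
            in_operon.update(genes)
        run, run_counts = [], []

    prev: GeneFeature | None = None
    for f in cds:
        joined = (
            prev is not None
            and prev.replicon_id == f.replicon_id
            and prev.strand == f.strand
            and _spanning_count(spanning_counts, prev.gene_id, f.gene_id)
            >= config.min_spanning_reads
        )
        if joined:
            if not run:
                run = [prev]
                run_counts = []
            run.append(f)
            run_counts.append(_spanning_count(spanning_counts, prev.gene_id,
                                              f.gene_id))
        else:
            flush()
        prev = f
    flush()

    all_ids = [f.gene_id for f in cds]
    expressed = set(all_ids) if expressed_genes is None else set(expressed_genes)
    monocistronic = [g for g in all_ids if g in expressed and g not in in_operon]
    return monocistronic, operons


def derive_suboperons(operon: Operon, tss_records) -> list[SubOperon]:
    """Sub-operons of one operon from gene-assigned TSSs.

    A TSS assigned (sTSS/pTSS) to the operon's first gene becomes the
    operon's primary TSS; a TSS assigned to gene k > 1 defines the sub-operon
    (gene k .. last gene).  Multiple TSSs on the same internal gene collapse
    to one sub-operon keeping the strongest TSS.
    """
    index = {g: i for i, g in enumerate(operon.gene_ids)}
    best_by_gene: dict[str, tuple] = {}  # gene -> (read_starts, position)
    for r in tss_records:
        for cat in ("sTSS", "pTSS"):
            gid = r.gene_by_category.get(cat)
            if gid in index:
                cur = best_by_gene.get(gid)
                cand = (r.read_start_count, r.position)
                if cur is None or cand[0] > cur[0] or \
                        (cand[0] == cur[0] and cand[1] < cur[1]):
                    best_by_gene[gid] = cand
    subs = []
    for gid, (count, pos) in sorted(best_by_gene.items(),
                                    key=lambda kv: index[kv[0]]):
        k = index[gid]
        if k == 0:
            operon.primary_tss = pos
        else:
            subs.append(SubOperon(
                parent_operon_id=operon.operon_id, first_gene_id=gid,
                gene_ids=list(operon.gene_ids[k:]), tss_position=pos,
                tss_read_starts=count))
    return subs


# ---------------------------------------------------------------------------
# coverage-extension transcript calls
# ---------------------------------------------------------------------------

def _extend_downstream(pos: int, strand: str, depth: np.ndarray,
                       floor: float) -> int:
    """Number of consecutive positions from ``pos`` (inclusive, strand-aware
    downstream) with depth >= floor."""
    n = len(depth)
    length = 0
    if strand == "+":
        i = pos
        while i < n and depth[i] >= floor:
            length += 1
            i += 1
    else:
        i = pos
        while i >= 0 and depth[i] >= floor:
            length += 1
            i -= 1
    return length


def call_antisense_transcript(as_tss, profile: StrandedProfile,
                              config: AntisenseConfig | None = None,
                              kind: str = "antisense") -> NovelTranscript | None:
    """Extend coverage downstream from an antisense TSS into a transcript.

    Extension continues while per-position depth stays >= 15 and must reach
    at least 20 nt.  A transcript longer than 500 nt with mean depth > 40
    additionally requires depth >= 80 at the TSS position.
    """
    config = config or AntisenseConfig()
    depth = np.asarray(profile.depth, dtype=float)
    p, strand = as_tss.position, as_tss.strand
    length = _extend_downstream(p, strand, depth, config.min_pos_coverage)
    if length < config.min_length_nt:
        return None
    if strand == "+":
        start, end = p, p + length
    else:
        start, end = p - length + 1, p + 1
    mean_cov = float(depth[start:end].mean())
    if length > config.long_length_nt and mean_cov > config.long_mean_cov:
        if depth[p] < config.long_start_cutoff:
            return None
    return NovelTranscript(
        replicon_id=profile.replicon_id, tss_positions=[p], start=start,
        end=end, strand=strand, kind=kind)


def _scan_orfs(seq: str, min_orf_aa: int):
    """All complete ORFs (start codon .. in-frame stop) in the given sense
    sequence; coordinates are half-open within ``seq`` and include the stop."""
    orfs = []
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            codon = seq[i:i + 3]
            if codon in START_CODONS:
                j = i + 3
                while j + 3 <= n:
                    c2 = seq[j:j + 3]
                    if c2 in STOP_CODONS:
                        aa = (j - i) // 3
                        if aa >= min_orf_aa:
                            orfs.append((i, j + 3, codon, aa))
                        break
                    j += 3
            i += 3
    return orfs


def find_novel_transcripts(n_tss_list, profile: StrandedProfile,
                           genome: Genome, rbs_model=None,
                           config: AntisenseConfig | None = None,
                           min_orf_aa: int = 25) -> list[NovelTranscript]:
    """Novel intergenic transcripts from nTSSs.

    Transcript extents use the same coverage-extension rule as antisense
    calls; nTSSs with overlapping extents merge into one transcript carrying
    alternative TSSs.  Within each transcript all three frames are scanned
    for ORFs (ATG/GTG/TTG/CTG start, in-frame stop, >= min_orf_aa codons);
    the longest is reported, with an RBS search 3-14 nt upstream of its
    start.
    """
    from .classify import _rbs_match

    config = config or AntisenseConfig()
    raw = []
    for t in n_tss_list:
        call = call_antisense_transcript(t, profile, config, kind="intergenic")
        if call is not None:
            raw.append(call)
    raw.sort(key=lambda c: (c.strand, c.start))

    merged: list[NovelTranscript] = []
    for c in raw:
        if merged and merged[-1].strand == c.strand and c.start < merged[-1].end:
            m = merged[-1]
            m.start = min(m.start, c.start)
            m.end = max(m.end, c.end)
            m.tss_positions = sorted(set(m.tss_positions + c.tss_positions))
        else:
            merged.append(c)

    for m in merged:
        seq = genome.fetch(m.replicon_id, m.start, m.end, m.strand)
        orfs = _scan_orfs(seq, min_orf_aa)
        if orfs:
            i, j, codon, aa = max(orfs, key=lambda o: (o[3], -o[0]))
            if m.strand == "+":
                g_start, g_end = m.start + i, m.start + j
                orf_start_pos = g_start
            else:
                g_start, g_end = m.end - j, m.end - i
                orf_start_pos = g_end - 1
            m.orf = OrfCall(start=g_start, end=g_end, start_codon=codon,
                            length_aa=aa)
            m.rbs_found = _rbs_match(genome, m.replicon_id, orf_start_pos,
                                     m.strand, rbs_model)
    return merged
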