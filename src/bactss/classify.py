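"""TSS classification, start-codon revision, ranking, and 5'-UTR analysis.

Categories (a TSS may belong to several):

* ``sTSS``  — sense TSS, 0-300 nt upstream of the nearest downstream
  same-strand ORF start (UTR length = distance; 0 means the TSS sits on the
  first start-codon base).
* ``nsTSS`` — a sense TSS inside an ORF at most 200 nt downstream of its
  annotated start; routed to start-codon revision and re-labelled sTSS (or
  iTSS when no alternative in-frame start codon exists downstream).
* ``pTSS``  — putative TSS, more than 300 and at most 600 nt upstream of the
  nearest downstream same-strand ORF start.
* ``iTSS``  — intragenic: inside a same-strand ORF more than 200 nt
  downstream of its start, unless within 300 nt of the ORF end while
  simultaneously being sTSS of the next gene.
* ``asTSS`` — inside an opposite-strand ORF (optionally its detected 5'-UTR).
* ``nTSS``  — intergenic and none of the above; treated as sTSS-like in
  downstream statistics via ``relabeled_sTSS``.

Boundary semantics: the sTSS window is [0, 300] inclusive, pTSS is
(300, 600], iTSS requires distance into the ORF > 200, leaderless requires
UTR <= 3 nt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genomics_io import GeneFeature, Genome, revcomp

START_CODONS = ("ATG", "GTG", "TTG", "CTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class ClassificationConfig:
    s_max_nt: int = 300
    ns_downstream_max_nt: int = 200
    p_min_nt: int = 300   # exclusive
    p_max_nt: int = 600   # inclusive
    i_min_into_orf_nt: int = 200  # exclusive
    i_near_end_nt: int = 300
    leaderless_max_nt: int = 3
    as_utr_extension: bool = True

    def __post_init__(self):
        if self.s_max_nt >= self.p_max_nt:
            raise ValueError("sTSS window must end before the pTSS window")


@dataclass
class TSSRecord:
    replicon_id: str
    position: int  # 0-based +1 site
    strand: str
    read_start_count: int
    categories: set[str] = field(default_factory=set)
    gene_by_category: dict[str, str] = field(default_factory=dict)
    rank: dict[str, str] = field(default_factory=dict)  # gene_id -> primary/secondary
    utr_length: int | None = None
    leaderless: bool = False
    context: tuple[str, str, str] = ("N", "N", "N")  # bases at -1, +1, +2
    relabeled_sTSS: bool = False  # nTSS folded into the sTSS group for stats
    feature_class: str = ""  # "rRNA"/"tRNA" tag; such TSSs skip classification
    curation_flags: set[str] = field(default_factory=set)


@dataclass
class RevisedStart:
    gene_id: str
    replicon_id: str
    strand: str
    old_start: int  # 0-based genome position of the first start-codon base
    new_start: int
    shortening_aa: int
    new_utr_nt: int
    rbs_found: bool
    new_cds_start: int  # revised CDS as half-open genomic interval
    new_cds_end: int


# ---------------------------------------------------------------------------
# geometry helpers (0-based, strand-aware)
# ---------------------------------------------------------------------------

def _downstream_distance(pos: int, strand: str, feature: GeneFeature) -> int:
    """Transcribed-nucleotide distance from the +1 site to the first base of
    the feature's start codon; >= 0 when the start is downstream of the TSS."""
    s = feature.start_codon_pos()
    return s - pos if strand == "+" else pos - s


def _contains(pos: int, feature: GeneFeature) -> bool:
    return feature.start <= pos < feature.end


def _distance_into_orf(pos: int, feature: GeneFeature) -> int:
    return pos - feature.start if feature.strand == "+" else (feature.end - 1) - pos


def _distance_to_orf_end(pos: int, feature: GeneFeature) -> int:
    e = feature.stop_side_pos()
    return e - pos if feature.strand == "+" else pos - e


def classify_tss(tss, features: list[GeneFeature], detected_utrs=None,
                 config: ClassificationConfig | None = None) -> set[tuple]:
    """Assign categories to a single TSS.

    ``tss`` needs ``position``, ``strand`` and ``replicon_id`` attributes.
    ``features`` is the annotation (only CDS features take part in
    classification).  ``detected_utrs`` optionally maps gene_id to a genomic
    (start, end, strand, replicon_id) 5'-UTR interval used for the
    antisense-to-UTR extension.  Returns a set of (category, gene_id) pairs;
    the nTSS entry carries gene_id None.
    """
    config = config or ClassificationConfig()
    pos, strand, rid = tss.position, tss.strand, tss.replicon_id
    cds = [f for f in features
           if f.replicon_id == rid and f.feature_type == "CDS"]
    out: set[tuple] = set()

    # nearest downstream same-strand ORF start
    same = [f for f in cds if f.strand == strand]
    downstream = [(d, f) for f in same
                  if 0 <= (d := _downstream_distance(pos, strand, f))]
    s_gene = None
    if downstream:
        d, f = min(downstream, key=lambda df: (df[0], df[1].gene_id))
        if d <= config.s_max_nt:
            s_gene = f
            out.add(("sTSS", f.gene_id))
        elif d <= config.p_max_nt:
            out.add(("pTSS", f.gene_id))

    # inside a same-strand ORF (a TSS exactly on the start-codon base is the
    # annotated start: sTSS with UTR 0, not a revision case)
    for f in same:
        if not _contains(pos, f):
            continue
        d_in = _distance_into_orf(pos, f)
        if d_in == 0:
            continue
        if d_in <= config.ns_downstream_max_nt:
            out.add(("nsTSS", f.gene_id))
        else:
            near_end = _distance_to_orf_end(pos, f) <= config.i_near_end_nt
            s_of_next = s_gene is not None and s_gene.gene_id != f.gene_id
            if not (near_end and s_of_next):
                out.add(("iTSS", f.gene_id))

    # antisense to an opposite-strand ORF (or its detected 5'-UTR)
    for f in cds:
        if f.strand != strand and _contains(pos, f):
            out.add(("asTSS", f.gene_id))
    if config.as_utr_extension and detected_utrs:
        for gid, (u_start, u_end, u_strand, u_rid) in detected_utrs.items():
            if u_rid == rid and u_strand != strand and u_start <= pos < u_end:
                out.add(("asTSS", gid))

    if not out:
        out.add(("nTSS", None))
    return out


def revise_start_codon(tss, gene: GeneFeature, genome: Genome, rbs_model=None,
                       rbs_spacer=(3, 14)) -> RevisedStart | None:
    """Revise an annotated translation start for an intragenic sense TSS.

    Scans downstream of the TSS for the first codon in-frame with the
    annotated stop that is one of ATG/GTG/TTG/CTG.  Returns a RevisedStart
    (with an RBS search result 3-14 nt upstream of the new start), or None
    when no alternative in-frame start codon exists, in which case the
    caller re-labels the TSS as iTSS.
    """
    if gene.feature_type != "CDS":
        raise ValueError(f"start revision requires a CDS, got {gene.feature_type}")
    pos, strand = tss.position, tss.strand
    rep_seq = genome[gene.replicon_id].sequence
    old_start = gene.start_codon_pos()
    d_in = _distance_into_orf(pos, gene)
    if d_in < 0:
        raise ValueError("TSS is not downstream of the annotated start")

    # offsets (in nt from the old start, along transcription) of candidate codons
    first_k = math.ceil(d_in / 3)
    n_codons = gene.length // 3
    new_offset = None
    for k in range(first_k, n_codons - 1):  # exclude the stop codon itself
        if strand == "+":
            codon = rep_seq[gene.start + 3 * k: gene.start + 3 * k + 3]
        else:
            codon = revcomp(rep_seq[gene.end - 3 * k - 3: gene.end - 3 * k])
        if codon in START_CODONS:
            new_offset = 3 * k
            break
    if new_offset is None:
        return None

    if strand == "+":
        new_start = gene.start + new_offset
        new_cds = (new_start, gene.end)
    else:
        new_start = gene.end - 1 - new_offset
        new_cds = (gene.start, new_start + 1)

    rbs_found = _rbs_match(genome, gene.replicon_id, new_start, strand,
                           rbs_model, rbs_spacer)
    new_utr = new_offset - d_in
    return RevisedStart(
        gene_id=gene.gene_id, replicon_id=gene.replicon_id, strand=strand,
        old_start=old_start, new_start=new_start,
        shortening_aa=new_offset // 3, new_utr_nt=new_utr,
        rbs_found=rbs_found, new_cds_start=new_cds[0], new_cds_end=new_cds[1])


def _rbs_match(genome: Genome, replicon_id: str, start_pos: int, strand: str,
               rbs_model=None, spacer=(3, 14), width: int | None = None) -> bool:
    """True iff an RBS-like motif ends ``spacer`` nt upstream of the start
    codon.  With a MotifModel, an occurrence is a positive log-odds window;
    without one, >= 4/5 agreement with the canonical Shine-Dalgarno AGGAG."""
    consensus = "AGGAG"
    w = width or (rbs_model.width if rbs_model is not None else len(consensus))
    lo, hi = spacer
    rep = genome[replicon_id]
    for gap in range(lo, hi + 1):
        if strand == "+":
            s = start_pos - gap - w
            if s < 0:
                continue
            window = rep.sequence[s: s + w]
        else:
            s = start_pos + 1 + gap
            if s + w > rep.length:
                continue
            window = revcomp(rep.sequence[s: s + w])
        if rbs_model is not None:
            if rbs_model.log_odds(window) > 0:
                return True
        else:
            if sum(a == b for a, b in zip(window, consensus)) >= 4:
                return True
    return False


# ---------------------------------------------------------------------------
# record assembly over a verified candidate list
# ---------------------------------------------------------------------------

def _tagged_structural_rna(pos, strand, rid, features, window=300):
    for f in features:
        if (f.replicon_id == rid and f.strand == strand
                and f.feature_type in ("rRNA", "tRNA", "other")):
            d = _downstream_distance(pos, strand, f)
            if _contains(pos, f) or 0 <= d <= window:
                return f.feature_type
    return ""


def build_tss_records(candidates, features, genome: Genome,
                      config: ClassificationConfig | None = None,
                      rbs_model=None, detected_utrs=None):
    """Classify verified candidates into TSSRecords.

    Applies categories, routes nsTSS through start-codon revision, and tags
    TSSs of structural RNAs (rRNA/tRNA/other), which are excluded from
    classification.  Returns (records, revised_starts).
    """
    config = config or ClassificationConfig()
    records, revised = [], []
    feat_by_id = {f.gene_id: f for f in features}
    for c in candidates:
        rec = TSSRecord(
            replicon_id=c.replicon_id, position=c.position, strand=c.strand,
            read_start_count=c.read_start_count,
            curation_flags=set(getattr(c, "curation_flags", set())))
        tag = _tagged_structural_rna(c.position, c.strand, c.replicon_id, features)
        if tag:
            rec.feature_class = tag
            records.append(rec)
            continue
        for cat, gid in classify_tss(rec, features, detected_utrs, config):
            rec.categories.add(cat)
            if gid is not None:
                rec.gene_by_category[cat] = gid
        if "nsTSS" in rec.categories:
            gid = rec.gene_by_category.pop("nsTSS")
            rec.categories.discard("nsTSS")
            rv = revise_start_codon(rec, feat_by_id[gid], genome, rbs_model)
            if rv is None:
                rec.categories.add("iTSS")
                rec.gene_by_category["iTSS"] = gid
            else:
                rec.categories.add("sTSS")
                rec.gene_by_category["sTSS"] = gid
                revised.append(rv)
        if rec.categories == {"nTSS"}:
            rec.relabeled_sTSS = True
        records.append(rec)
    return records, revised


def rank_primary_secondary(records, features):
    """Per-gene primary/secondary ranking over sTSS/pTSS assignments.

    The TSS with the highest read-start count is primary; ties go to the TSS
    closest to the start codon, then to the smaller coordinate.  Records are
    mutated in place and returned.
    """
    feat_by_id = {f.gene_id: f for f in features}
    by_gene: dict[str, list[TSSRecord]] = {}
    for r in records:
        for cat in ("sTSS", "pTSS"):
            gid = r.gene_by_category.get(cat)
            if gid is not None:
                by_gene.setdefault(gid, []).append(r)
    for gid, group in by_gene.items():
        f = feat_by_id[gid]
        group = sorted(
            group,
            key=lambda r: (-r.read_start_count,
                           abs(_downstream_distance(r.position, r.strand, f)),
                           r.position))
        group[0].rank[gid] = "primary"
        for r in group[1:]:
            r.rank[gid] = "secondary"
    return records


def compute_utr_and_leaderless(records, features, config=None, revised_starts=None):
    """Fill in UTR lengths and leaderless flags; return (records, histogram).

    UTR length is the distance from the +1 site to the first base of the
    start codon (0 = TSS on the start codon); a transcript is leaderless iff
    its UTR is <= 3 nt.  The histogram counts primary+secondary TSSs in 5-nt
    bins keyed by bin start (0, 5, 10, ...).
    """
    config = config or ClassificationConfig()
    feat_by_id = {f.gene_id: f for f in features}
    new_start = {r.gene_id: r.new_start for r in (revised_starts or [])}
    hist: dict[int, int] = {}
    for r in records:
        gid = r.gene_by_category.get("sTSS") or r.gene_by_category.get("pTSS")
        if gid is None:
            continue
        f = feat_by_id[gid]
        s = new_start.get(gid, f.start_codon_pos())
        d = s - r.position if r.strand == "+" else r.position - s
        r.utr_length = int(d)
        r.leaderless = d <= config.leaderless_max_nt
        if r.rank.get(gid) in ("primary", "secondary"):
            b = 5 * (d // 5)
            hist[b] = hist.get(b, 0) + 1
    return records, hist


def annotate_context(records, genome: Genome):
    """Fill in the -1/+1/+2 bases around each TSS, strand-aware."""
    comp = str.maketrans("ACGTN", "TGCAN")
    for r in records:
        seq = genome[r.replicon_id].sequence
        n = len(seq)

        def base(i):
            return seq[i] if 0 <= i < n else "N"

        p = r.position
        if r.strand == "+":
            r.context = (base(p - 1), base(p), base(p + 1))
        else:
            r.context = (base(p + 1).translate(comp),
                         base(p).translate(comp),
                         base(p - 1).translate(comp))
    return records
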