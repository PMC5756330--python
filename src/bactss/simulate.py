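"""Synthetic dRNA-seq dataset generator with planted ground truth.

Builds a toy multi-gene genome with annotated CDS features, plants TSSs of
every category (sense, putative, intragenic, antisense, intergenic, start
revisions and leaderless starts), promoter and RBS motifs at the canonical
spacings, operons with spanning-read counts straddling the joining threshold,
sub-operon internal TSSs, antisense and novel intergenic transcripts,
riboswitch-like coverage profiles, barcode-flagged false-positive reads, and
Poisson background read-start noise.  Everything planted is recorded in a
SyntheticTruth object so every downstream stage can be scored.

Placement uses generous clearances so that each planted TSS derives exactly
its intended category from the final annotation; the generator re-derives
categories from coordinates with its own geometry code (independent of the
classification module) and refuses to emit an inconsistent dataset.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genomics_io import (
    Genome, Replicon, GeneFeature, StrandedProfile, CisElementPrediction,
    revcomp, write_gff3, write_bedgraph,
)

_NONSTOP_CODONS = [a + b + c
                   for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in ("TAA", "TAG", "TGA")]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults give one 100-kb replicon with 80 genes and 50 planted TSSs of
    read-start strength 40 over Poisson(0.2) background — a desk-scale
    dataset that exercises every pipeline threshold.
    """

    seed: int = 1
    n_replicons: int = 1
    replicon_length: int = 100_000
    n_genes: int = 80
    # (run length, spanning-read count) per operon run; counts straddle the
    # joining threshold of 10
    operon_spec: tuple = ((3, 25), (2, 15), (4, 12), (2, 8), (3, 5))
    # (category, how many, read-start strength)
    tss_spec: tuple = (
        ("sTSS", 28, 40), ("pTSS", 5, 40), ("iTSS", 5, 40),
        ("asTSS", 5, 40), ("nTSS", 3, 40), ("leaderless", 2, 40),
        ("nsTSS", 2, 40),
    )
    minus10_consensus: str = "TATAAT"
    minus35_consensus: str = "TTGACA"
    rbs_consensus: str = "AGGAG"
    motif_plant_rate: float = 0.9
    noise_lambda: float = 0.2
    barcode: str = "TACCCTAG"
    fp_read_fraction: float = 0.6
    n_reads: int = 1000
    read_length: int = 35
    # (extension length nt, mean coverage) cycled over planted antisense TSSs
    antisense_spec: tuple = ((150, 30), (150, 30), (600, 50), (150, 30),
                             (150, 30))
    # (UTR coverage, ORF coverage) per riboswitch-like locus; the last is a
    # readthrough locus without a TSS
    riboswitch_spec: tuple = ((6000, 60), (2000, 33), (1500, 75), (1300, 50),
                              (40, 40))
    transcript_depth: float = 50.0
    # processed-end false-positive read-start spikes (no downstream coverage)
    fp_spike_count: int = 3
    fp_spike_strength: int = 50

    def __post_init__(self):
        for frac in (self.motif_plant_rate, self.fp_read_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        for _, n, strength in self.tss_spec:
            if strength < 0:
                raise ValueError("TSS strengths must be >= 0")
        for s in (self.minus10_consensus, self.minus35_consensus,
                  self.rbs_consensus):
            if set(s) - set("ACGT"):
                raise ValueError("consensus strings must be over ACGT")


@dataclass
class PlantedTSS:
    replicon_id: str
    position: int  # 0-based +1 site
    strand: str
    category: str  # sTSS / pTSS / iTSS / asTSS / nTSS / nsTSS / leaderless
    strength: int
    gene_id: str | None = None
    utr: int | None = None


@dataclass
class SyntheticTruth:
    planted_tss: list = field(default_factory=list)
    planted_operons: list = field(default_factory=list)   # expected gene lists
    planted_operon_runs: list = field(default_factory=list)  # (genes, count)
    planted_suboperon_tss: list = field(default_factory=list)  # (first_gene, suffix)
    planted_antisense: list = field(default_factory=list)  # (start, end, strand)
    planted_novel: list = field(default_factory=list)      # dicts
    planted_revisions: list = field(default_factory=list)  # dicts
    planted_motif_offsets: dict = field(default_factory=dict)
    planted_leaderless: list = field(default_factory=list)
    riboswitch_truth: list = field(default_factory=list)   # (name, verdict)
    barcode_read_ids: set = field(default_factory=set)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: Genome
    features: list
    profiles: list
    reads: list
    spanning_counts: dict
    cis_elements: list
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# independent geometry check (deliberately separate from the classifier)
# ---------------------------------------------------------------------------

def _derive_categories(pos, strand, rid, features,
                       s_max=300, ns_max=200, p_max=600, i_near_end=300):
    cds = [f for f in features if f.replicon_id == rid
           and f.feature_type == "CDS"]
    cats = set()
    dists = []
    for f in cds:
        anchor = f.start if f.strand == "+" else f.end - 1
        d = anchor - pos if strand == "+" else pos - anchor
        if f.strand == strand and d >= 0:
            dists.append(d)
    s_hit = False
    if dists:
        d = min(dists)
        if d <= s_max:
            cats.add("sTSS")
            s_hit = True
        elif d <= p_max:
            cats.add("pTSS")
    for f in cds:
        inside = f.start <= pos < f.end
        if not inside:
            continue
        if f.strand != strand:
            cats.add("asTSS")
            continue
        d_in = pos - f.start if strand == "+" else (f.end - 1) - pos
        if d_in == 0:
            continue  # the annotated start itself; covered by sTSS
        if d_in <= ns_max:
            cats.add("nsTSS")
        else:
            d_end = (f.end - 1) - pos if strand == "+" else pos - f.start
            if not (d_end <= i_near_end and s_hit):
                cats.add("iTSS")
    return cats or {"nTSS"}


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

class _Layout:
    """Mutable genome under construction."""

    def __init__(self, rng, length, rid):
        self.rng = rng
        self.rid = rid
        self.seq = list("".join(rng.choice(list("ACGT"), size=length)))
        self.length = length

    def write(self, pos, text, strand="+"):
        if strand == "-":
            text = revcomp(text)
            pos = pos - len(text) + 1
        if pos < 0 or pos + len(text) > self.length:
            raise ValueError("sequence write out of range")
        self.seq[pos:pos + len(text)] = list(text)


def _random_cds(rng, length):
    n_codons = length // 3
    body = "".join(rng.choice(_NONSTOP_CODONS, size=n_codons - 2))
    return "ATG" + body + "TAA"


def _plant_promoter(layout, rng, cfg, tss_pos, strand, truth_entry):
    """Write -10 (and -35) boxes upstream of a TSS, strand-aware."""
    spacer10 = int(rng.integers(3, 12))
    m10 = cfg.minus10_consensus
    if strand == "+":
        end10 = tss_pos - spacer10          # exclusive end of the -10
        layout.write(end10 - len(m10), m10)
        gap = int(rng.integers(16, 24))
        end35 = end10 - len(m10) - gap
        layout.write(end35 - len(cfg.minus35_consensus), cfg.minus35_consensus)
    else:
        start10 = tss_pos + spacer10        # -10 occupies upstream = higher coords
        layout.write(start10 + len(m10), m10, strand="-")
        gap = int(rng.integers(16, 24))
        start35 = start10 + len(m10) + gap
        layout.write(start35 + len(cfg.minus35_consensus),
                     cfg.minus35_consensus, strand="-")
    truth_entry["minus10_spacer"] = spacer10
    truth_entry["minus35_gap"] = gap


def _plant_rbs(layout, rng, cfg, start_pos, strand, spacer=None):
    """Write the RBS consensus ending ``spacer`` nt upstream of a start codon."""
    spacer = int(rng.integers(5, 12)) if spacer is None else spacer
    rbs = cfg.rbs_consensus
    if strand == "+":
        layout.write(start_pos - spacer - len(rbs), rbs)
    else:
        layout.write(start_pos + spacer + len(rbs), rbs, strand="-")
    return spacer


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic dataset; deterministic for a fixed seed."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    rid = "chr1"
    L = cfg.replicon_length
    layout = _Layout(rng, L, rid)
    truth = SyntheticTruth()

    spec = {cat: (n, strength) for cat, n, strength in cfg.tss_spec}
    n_riboswitch = len(cfg.riboswitch_spec)
    n_term = n_riboswitch - 1  # last locus is the readthrough control

    # ------------------------------------------------------------------ units
    # Each unit is one transcription unit: an operon run or a single gene.
    units = []
    for i, (run_len, count) in enumerate(cfg.operon_spec):
        units.append({"kind": "operon", "n": run_len, "count": count})
    n_operon_genes = sum(u["n"] for u in units)
    n_singles = cfg.n_genes - n_operon_genes
    if n_singles < 0:
        raise ValueError("operon_spec uses more genes than n_genes")

    single_roles = (
        ["riboswitch"] * n_term + ["riboswitch_rt"]
        + ["pTSS"] * spec.get("pTSS", (0, 0))[0]
        + ["iTSS"] * spec.get("iTSS", (0, 0))[0]
        + ["asTSS"] * spec.get("asTSS", (0, 0))[0]
        + ["leaderless"] * spec.get("leaderless", (0, 0))[0]
        + ["nsTSS"] * spec.get("nsTSS", (0, 0))[0]
    )
    n_plain_s = spec.get("sTSS", (0, 0))[0] - len(cfg.operon_spec) - 2 - n_term
    if n_plain_s < 0:
        raise ValueError("tss_spec plants fewer sTSSs than the layout needs")
    # two of the plain sense genes receive a second TSS (secondary ranking)
    n_dual = 2 if n_plain_s >= 4 else 0
    single_roles += ["sTSS"] * (n_plain_s - n_dual)
    if len(single_roles) > n_singles:
        raise ValueError("replicon too short for requested genes/roles")
    single_roles += ["silent"] * (n_singles - len(single_roles))
    for role in single_roles:
        units.append({"kind": "single", "role": role})

    # interleave deterministically so roles are spread along the replicon
    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    # intergenic zones for novel transcripts: the first carries two
    # alternative TSSs of one transcript (with a planted ORF), the others one
    # TSS each (putative ncRNAs)
    n_n = spec.get("nTSS", (0, 0))[0]
    zone_plan = ([(1500, 2)] + [(1100, 1)] * (n_n - 2)) if n_n >= 2 \
        else [(1100, 1)] * n_n
    step = max(1, len(units) // (len(zone_plan) + 1))
    for zi, (width, n_tss) in enumerate(zone_plan):
        units.insert(min(len(units), (zi + 1) * step + zi),
                     {"kind": "nzone", "width": width, "n_tss": n_tss})

    def gene_length(role):
        if role in ("iTSS",):
            return 840
        if role in ("nsTSS",):
            return 750
        if role == "asTSS":
            return 0  # set later (long host for the long antisense call)
        return int(rng.integers(150, 300)) * 3

    # ---------------------------------------------------------------- layout
    features: list[GeneFeature] = []
    gene_no = 0
    cursor = int(rng.integers(400, 600))
    as_hosts, i_hosts, ns_hosts, p_targets, s_targets = [], [], [], [], []
    leaderless_targets, ribo_targets, ribo_rt_target = [], [], None
    operon_units = []
    nzones = []
    as_count = 0

    for u in units:
        if u["kind"] == "nzone":
            pre = int(rng.integers(700, 800))
            zone = (cursor + pre, cursor + pre + u["width"])
            nzones.append({"span": zone, "n_tss": u["n_tss"]})
            cursor = zone[1]
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        role = u.get("role", "operon")
        pre = int(rng.integers(330, 420))
        if role == "pTSS":
            # a distal TSS needs a long clear run upstream of the gene start;
            # keeping these targets on '+' puts that run in this unit's own
            # preceding gap
            strand = "+"
            pre = int(rng.integers(650, 750))
        if u["kind"] == "operon":
            genes = []
            for k in range(u["n"]):
                glen = int(rng.integers(150, 260)) * 3
                start = cursor + (pre if k == 0 else int(rng.integers(60, 150)))
                gene_no += 1
                f = GeneFeature(
                    gene_id=f"g{gene_no:03d}", replicon_id=rid,
                    start=start, end=start + glen, strand=strand,
                    feature_type="CDS", functional_category="")
                layout.write(f.start_codon_pos(), _random_cds(rng, glen),
                             strand=strand)
                features.append(f)
                genes.append(f)
                cursor = f.end
            operon_units.append({"genes": genes, "count": u["count"],
                                 "strand": strand})
        else:
            if role == "asTSS":
                ext_len, _ = cfg.antisense_spec[as_count % len(cfg.antisense_spec)]
                glen = 1290 if ext_len > 500 else 960
                as_count += 1
            else:
                glen = gene_length(role)
            start = cursor + pre
            gene_no += 1
            f = GeneFeature(gene_id=f"g{gene_no:03d}", replicon_id=rid,
                            start=start, end=start + glen, strand=strand,
                            feature_type="CDS", functional_category="")
            layout.write(f.start_codon_pos(), _random_cds(rng, glen),
                         strand=strand)
            features.append(f)
            cursor = f.end
            if role == "asTSS":
                as_hosts.append(f)
            elif role == "iTSS":
                i_hosts.append(f)
            elif role == "nsTSS":
                ns_hosts.append(f)
            elif role == "pTSS":
                p_targets.append(f)
            elif role == "sTSS":
                s_targets.append(f)
            elif role == "leaderless":
                leaderless_targets.append(f)
            elif role == "riboswitch":
                ribo_targets.append(f)
            elif role == "riboswitch_rt":
                ribo_rt_target = f
    cursor += 600
    if cursor > L:
        raise ValueError(
            f"replicon too short for requested genes/operons ({cursor} > {L})")

    # functional categories for the enrichment test: 5 roles, deterministic
    roles = ["transport", "energy metabolism", "DNA metabolism",
             "translation", "hypothetical"]
    for i, f in enumerate(features):
        f.functional_category = roles[i % len(roles)]

    # ------------------------------------------------------------- profiles
    depth = {s: np.zeros(L, dtype=np.int64) for s in "+-"}
    read_starts = {
        s: rng.poisson(cfg.noise_lambda, size=L).astype(np.int64)
        for s in "+-"
    }

    def plant_depth(strand, start, end, level):
        depth[strand][max(0, start):min(L, end)] = int(level)

    def upstream_gap_ok(f, offset):
        """TSS ``offset`` nt upstream of gene start stays intergenic."""
        p = f.start - offset if f.strand == "+" else f.end - 1 + offset
        return all(not (g.start - 46 <= p < g.end + 46)
                   for g in features if g is not f)

    def tss_upstream(f, offset):
        return f.start - offset if f.strand == "+" else f.end - 1 + offset

    planted_positions = set()

    def add_tss(pos, strand, category, strength, gene_id=None, utr=None,
                plant_promoter=True):
        read_starts[strand][pos] += strength
        entry = {}
        if plant_promoter and rng.random() < cfg.motif_plant_rate:
            _plant_promoter(layout, rng, cfg, pos, strand, entry)
        truth.planted_motif_offsets[f"{strand}{pos}"] = entry
        truth.planted_tss.append(PlantedTSS(
            replicon_id=rid, position=pos, strand=strand, category=category,
            strength=strength, gene_id=gene_id, utr=utr))
        planted_positions.add((pos, strand))

    s_strength = spec.get("sTSS", (0, 40))[1]

    def plant_sense_unit(f_first, unit_end, offset, category="sTSS",
                         strength=None, with_rbs=True, depth_level=None):
        """TSS ``offset`` nt upstream of f_first + transcript plateau."""
        strength = s_strength if strength is None else strength
        pos = tss_upstream(f_first, offset)
        strand = f_first.strand
        if strand == "+":
            plant_depth("+", pos, unit_end, depth_level or cfg.transcript_depth)
        else:
            plant_depth("-", unit_end, pos + 1, depth_level or cfg.transcript_depth)
        if with_rbs and offset >= 20 and rng.random() < cfg.motif_plant_rate:
            _plant_rbs(layout, rng, cfg, f_first.start_codon_pos(), strand)
        add_tss(pos, strand, category, strength, gene_id=f_first.gene_id,
                utr=offset)
        return pos

    # operons: TSS on the first gene; internal TSSs on two of the joined runs
    spanning_counts = {}
    for op in operon_units:
        genes = op["genes"] if op["strand"] == "+" else op["genes"][::-1]
        for a, b in zip(op["genes"], op["genes"][1:]):  # genomic order
            spanning_counts[(a.gene_id, b.gene_id)] = op["count"]
        first = genes[0]
        unit_end = (op["genes"][-1].end if op["strand"] == "+"
                    else op["genes"][0].start)
        off = int(rng.integers(40, 120))
        while not upstream_gap_ok(first, off):
            off -= 5
        plant_sense_unit(first, unit_end, off)
        truth.planted_operon_runs.append(
            ([g.gene_id for g in genes], op["count"]))
        if op["count"] >= 10:
            truth.planted_operons.append([g.gene_id for g in genes])

    joined = [op for op in operon_units if op["count"] >= 10]
    for op, internal_idx in zip(joined[:2], (1, 2)):
        genes = op["genes"] if op["strand"] == "+" else op["genes"][::-1]
        if internal_idx >= len(genes):
            internal_idx = len(genes) - 1
        g = genes[internal_idx]
        gap_prev = (g.start - genes[internal_idx - 1].end if op["strand"] == "+"
                    else genes[internal_idx - 1].start - g.end)
        off = min(int(rng.integers(20, 50)), gap_prev - 15)
        pos = tss_upstream(g, off)
        add_tss(pos, g.strand, "sTSS", s_strength, gene_id=g.gene_id, utr=off)
        truth.planted_suboperon_tss.append(
            (g.gene_id, [x.gene_id for x in genes[internal_idx:]]))

    # plain sense targets; the first two genes carry a second (secondary)
    # TSS farther upstream to exercise primary/secondary ranking
    for i, f in enumerate(s_targets):
        off = int(rng.integers(25, 140))
        while not upstream_gap_ok(f, off) and off > 10:
            off -= 10
        plant_sense_unit(f, f.end if f.strand == "+" else f.start, off)
        if i < n_dual:
            off2 = off + int(rng.integers(40, 80))
            while not upstream_gap_ok(f, off2) and off2 > off + 20:
                off2 -= 10
            plant_sense_unit(f, f.end if f.strand == "+" else f.start, off2,
                             with_rbs=False)

    # leaderless (UTR 1-3 nt; a TSS on the start-codon base itself would be
    # the annotated start, not a distinct planting)
    for f in leaderless_targets:
        off = int(rng.integers(1, 4))
        plant_sense_unit(f, f.end if f.strand == "+" else f.start, off,
                         category="leaderless",
                         strength=spec.get("leaderless", (0, 40))[1],
                         with_rbs=False)
        truth.planted_leaderless.append(f.gene_id)

    # putative (distal) TSSs
    for f in p_targets:
        off = int(rng.integers(330, 560))
        while not upstream_gap_ok(f, off) and off > 310:
            off -= 10
        plant_sense_unit(f, f.end if f.strand == "+" else f.start, off,
                         category="pTSS",
                         strength=spec.get("pTSS", (0, 40))[1], with_rbs=False)

    # riboswitch-like loci (termination-like, with TSS)
    cis_elements = []
    names = ("FMN", "glycine", "SAM-II", "TPP", "readthrough-control")
    for i, f in enumerate(ribo_targets):
        utr_cov, orf_cov = cfg.riboswitch_spec[i]
        off = 200
        while not upstream_gap_ok(f, off) and off > 150:
            off -= 10
        pos = tss_upstream(f, off)
        if f.strand == "+":
            plant_depth("+", pos, f.start, utr_cov)
            plant_depth("+", f.start, f.end, orf_cov)
            elem = CisElementPrediction(
                name=names[i], rfam_accession=f"RFSYN{i:02d}",
                replicon_id=rid, start=pos + 20, end=f.start - 20,
                strand="+", downstream_gene_id=f.gene_id)
        else:
            plant_depth("-", f.end, pos + 1, utr_cov)
            plant_depth("-", f.start, f.end, orf_cov)
            elem = CisElementPrediction(
                name=names[i], rfam_accession=f"RFSYN{i:02d}",
                replicon_id=rid, start=f.end + 20, end=pos - 20 + 1,
                strand="-", downstream_gene_id=f.gene_id)
        cis_elements.append(elem)
        if rng.random() < cfg.motif_plant_rate:
            _plant_rbs(layout, rng, cfg, f.start_codon_pos(), f.strand)
        add_tss(pos, f.strand, "sTSS", s_strength, gene_id=f.gene_id, utr=off)
        truth.riboswitch_truth.append((names[i], "termination-like"))

    # readthrough control locus: similar coverage over element and ORF, no TSS
    if ribo_rt_target is not None:
        f = ribo_rt_target
        utr_cov, orf_cov = cfg.riboswitch_spec[-1]
        if f.strand == "+":
            plant_depth("+", f.start - 200, f.end, orf_cov)
            elem = CisElementPrediction(
                name=names[-1], rfam_accession=f"RFSYN{n_riboswitch - 1:02d}",
                replicon_id=rid, start=f.start - 150, end=f.start - 30,
                strand="+", downstream_gene_id=f.gene_id)
        else:
            plant_depth("-", f.start, f.end + 200, orf_cov)
            elem = CisElementPrediction(
                name=names[-1], rfam_accession=f"RFSYN{n_riboswitch - 1:02d}",
                replicon_id=rid, start=f.end + 30, end=f.end + 150,
                strand="-", downstream_gene_id=f.gene_id)
        cis_elements.append(elem)
        truth.riboswitch_truth.append((names[-1], "readthrough-like"))

    # intragenic TSSs
    for f in i_hosts:
        d_in = int(rng.integers(210, f.length - 320))
        pos = f.start + d_in if f.strand == "+" else f.end - 1 - d_in
        plant_depth(f.strand, f.start, f.end, cfg.transcript_depth)
        add_tss(pos, f.strand, "iTSS", spec.get("iTSS", (0, 40))[1],
                gene_id=f.gene_id, plant_promoter=False)

    # start-revision (nsTSS) hosts
    for f in ns_hosts:
        d_in = int(rng.integers(60, 180))
        d_in -= d_in % 3  # keep the arithmetic simple: TSS on a codon boundary
        new_off = d_in + 3 * int(rng.integers(5, 13))
        utr = new_off - d_in
        # rewrite interior codons so the planted ATG is the first in-frame
        # start downstream of the TSS (GCA repeats carry no start codon in
        # any frame)
        interior = "GCA" * (new_off // 3 - 1)
        if f.strand == "+":
            layout.write(f.start + 3, interior)
            layout.write(f.start + new_off, "ATG")
            new_start = f.start + new_off
        else:
            layout.write(f.end - 4, interior, strand="-")
            layout.write(f.end - 1 - new_off, "ATG", strand="-")
            new_start = f.end - 1 - new_off
        spacer = _plant_rbs(layout, rng, cfg, new_start, f.strand,
                            spacer=int(rng.integers(4, 11)))
        pos = f.start + d_in if f.strand == "+" else f.end - 1 - d_in
        plant_depth(f.strand, f.start, f.end, cfg.transcript_depth)
        add_tss(pos, f.strand, "nsTSS", spec.get("nsTSS", (0, 40))[1],
                gene_id=f.gene_id, plant_promoter=False)
        truth.planted_revisions.append({
            "gene_id": f.gene_id, "tss": pos, "new_start": new_start,
            "new_utr_nt": utr, "shortening_aa": new_off // 3,
            "rbs_spacer": spacer,
        })

    # antisense TSSs and transcripts
    as_strength = spec.get("asTSS", (0, 40))[1]
    for i, host in enumerate(as_hosts):
        ext_len, cov = cfg.antisense_spec[i % len(cfg.antisense_spec)]
        strand = "-" if host.strand == "+" else "+"
        if host.strand == "+":
            pos = host.start + 620 + ext_len - 150 if ext_len > 500 \
                else host.start + 620
            pos = min(pos, host.end - 60)
            lo, hi = pos - ext_len + 1, pos + 1
        else:
            pos = host.end - 621 - (ext_len - 150) if ext_len > 500 \
                else host.end - 621
            pos = max(pos, host.start + 59)
            lo, hi = pos, pos + ext_len
        plant_depth(strand, lo, hi, cov)
        long_call = ext_len > 500 and cov > 40
        if long_call:
            # long high-coverage antisense transcripts need depth >= 80 at
            # the TSS
            if strand == "+":
                depth[strand][lo:lo + 10] = 85
            else:
                depth[strand][hi - 10:hi] = 85
        plant_depth(host.strand, host.start, host.end, cfg.transcript_depth)
        add_tss(pos, strand, "asTSS", as_strength, gene_id=host.gene_id,
                plant_promoter=False)
        truth.planted_antisense.append((lo, hi, strand))

    # novel intergenic transcripts
    n_strength = spec.get("nTSS", (0, 40))[1]
    for zi, zone in enumerate(nzones):
        z0, z1 = zone["span"]
        base = z0 + 100
        ext = 330 if zone["n_tss"] == 2 else 300
        # keep the transcript region free of start codons except planted ORFs
        region = "".join(rng.choice(list("ACT"), size=ext + 40))
        layout.write(base, region)
        plant_depth("+", base, base + ext, 30)
        tss_positions = [base] if zone["n_tss"] == 1 else [base, base + 30]
        for p in tss_positions:
            add_tss(p, "+", "nTSS", n_strength, plant_promoter=True)
        orf = None
        if zone["n_tss"] == 2:
            # RBS + ATG + 25 x GCA + stop, padded with in-frame stops
            orf_start = base + 60
            block = ("AGGAG" + "ACCACAA" + "ATG" + "GCA" * 25 + "TAA"
                     + "TAATAA")
            layout.write(orf_start - 12, block)
            orf = {"start": orf_start, "end": orf_start + 81,
                   "start_codon": "ATG", "length_aa": 26}
        truth.planted_novel.append({
            "tss_positions": tss_positions, "start": base, "end": base + ext,
            "strand": "+", "orf": orf,
        })

    # processed-end false-positive read-start spikes in silent gaps
    spikes = 0
    attempt = 0
    while spikes < cfg.fp_spike_count and attempt < 1000:
        attempt += 1
        p = int(rng.integers(200, L - 200))
        near_gene = any(f.start - 700 <= p < f.end + 700 for f in features)
        near_zone = any(z["span"][0] - 700 <= p < z["span"][1] + 700
                        for z in nzones)
        if near_gene or near_zone or (p, "+") in planted_positions:
            continue
        read_starts["+"][p] += cfg.fp_spike_strength
        spikes += 1

    # ----------------------------------------------------- verify geometry
    problems = []
    for t in truth.planted_tss:
        intended = "sTSS" if t.category == "leaderless" else t.category
        derived = _derive_categories(t.position, t.strand, rid, features)
        if derived != {intended}:
            problems.append((t, sorted(derived)))
    if problems:
        raise RuntimeError(
            f"planted TSS geometry inconsistent with intent: {problems[:5]}")

    # -------------------------------------------------------------- genome
    genome = Genome()
    genome.add(Replicon(id=rid, sequence="".join(layout.seq)))
    profiles = [
        StrandedProfile(replicon_id=rid, strand=s, depth=depth[s],
                        read_starts=read_starts[s])
        for s in "+-"
    ]

    # --------------------------------------------------------------- reads
    reads = []
    tss_list = truth.planted_tss
    for i in range(cfg.n_reads):
        read_id = f"read_{i:05d}"
        if rng.random() < cfg.fp_read_fraction:
            p = int(rng.integers(0, L - cfg.read_length))
            seq = cfg.barcode + "".join(layout.seq[p:p + cfg.read_length])
            truth.barcode_read_ids.add(read_id)
        else:
            t = tss_list[int(rng.integers(len(tss_list)))]
            if t.strand == "+":
                seq = "".join(layout.seq[t.position:t.position + cfg.read_length])
            else:
                seq = revcomp("".join(
                    layout.seq[max(0, t.position - cfg.read_length + 1):
                               t.position + 1]))
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        reads.append(rec)

    return SyntheticDataset(
        config=cfg, genome=genome, features=features, profiles=profiles,
        reads=reads, spanning_counts=spanning_counts,
        cis_elements=cis_elements, truth=truth)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir) -> dict:
    """Write the dataset in the same dialects the readers consume."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    fasta = os.path.join(out_dir, "genome.fasta")
    SeqIO.write([SeqRecord(Seq(r.sequence), id=r.id, description="")
                 for r in ds.genome], fasta, "fasta")
    paths["genome"] = fasta

    gff = os.path.join(out_dir, "annotation.gff3")
    write_gff3(ds.features, gff, source="synthetic")
    paths["annotation"] = gff

    by_strand = {"+": "fwd", "-": "rev"}
    for p in ds.profiles:
        tag = by_strand[p.strand]
        for name, arr in (("depth", p.depth), ("starts", p.read_starts)):
            path = os.path.join(out_dir, f"{name}_{tag}.bedgraph")
            mode = "a" if os.path.exists(path) and paths.get(f"{name}_{tag}") \
                else "w"
            if mode == "w":
                write_bedgraph(arr, p.replicon_id, path)
            else:
                tmp = path + ".part"
                write_bedgraph(arr, p.replicon_id, tmp)
                with open(path, "a") as out, open(tmp) as src:
                    out.write(src.read())
                os.remove(tmp)
            paths[f"{name}_{tag}"] = path

    fastq = os.path.join(out_dir, "reads.fastq")
    SeqIO.write(ds.reads, fastq, "fastq")
    paths["reads"] = fastq

    span = os.path.join(out_dir, "spanning_counts.tsv")
    with open(span, "w") as fh:
        fh.write("gene_a\tgene_b\tcount\n")
        for (a, b), c in sorted(ds.spanning_counts.items()):
            fh.write(f"{a}\t{b}\t{c}\n")
    paths["spanning_counts"] = span

    elems = os.path.join(out_dir, "cis_elements.tsv")
    with open(elems, "w") as fh:
        fh.write("name\trfam_accession\treplicon\tstart\tend\tstrand"
                 "\tdownstream_gene\n")
        for e in ds.cis_elements:
            fh.write(f"{e.name}\t{e.rfam_accession}\t{e.replicon_id}"
                     f"\t{e.start + 1}\t{e.end}\t{e.strand}"
                     f"\t{e.downstream_gene_id}\n")
    paths["cis_elements"] = elems

    truth_path = os.path.join(out_dir, "truth.json")
    t = ds.truth
    payload = {
        "planted_tss": [asdict(x) for x in t.planted_tss],
        "planted_operons": t.planted_operons,
        "planted_operon_runs": t.planted_operon_runs,
        "planted_suboperon_tss": t.planted_suboperon_tss,
        "planted_antisense": t.planted_antisense,
        "planted_novel": t.planted_novel,
        "planted_revisions": t.planted_revisions,
        "planted_motif_offsets": t.planted_motif_offsets,
        "planted_leaderless": t.planted_leaderless,
        "riboswitch_truth": t.riboswitch_truth,
        "barcode_read_ids": sorted(t.barcode_read_ids),
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class ClassScore:
    n_planted: int
    n_called: int
    n_matched: int
    sensitivity: float
    precision: float
    zero_calls: bool = False


@dataclass
class RecoveryReport:
    per_class: dict

    def __getitem__(self, k):
        return self.per_class[k]


def _greedy_match(planted, called, tolerance):
    """One-to-one greedy matching by distance between (pos, strand) pairs."""
    pairs = []
    for i, (pp, ps) in enumerate(planted):
        for j, (cp, cs) in enumerate(called):
            if ps == cs and abs(pp - cp) <= tolerance:
                pairs.append((abs(pp - cp), i, j))
    pairs.sort()
    used_p, used_c = set(), set()
    for _, i, j in pairs:
        if i not in used_p and j not in used_c:
            used_p.add(i)
            used_c.add(j)
    return len(used_p)


def _score(n_planted, n_called, n_matched) -> ClassScore:
    sens = n_matched / n_planted if n_planted else 1.0
    if n_called == 0:
        return ClassScore(n_planted, 0, n_matched, sens, 1.0, zero_calls=True)
    return ClassScore(n_planted, n_called, n_matched, sens,
                      n_matched / n_called)


def truth_scorer(called, truth: SyntheticTruth,
                 tolerance_nt: int = 0) -> RecoveryReport:
    """Score pipeline outputs against planted truth, per element class.

    ``called`` is a PipelineResult (or anything exposing tss_records,
    operons, suboperons, antisense_transcripts, novel_transcripts).  A called
    TSS matches a planted TSS if |delta position| <= tolerance_nt and strands
    are equal, matched greedily one-to-one by distance.  With zero calls the
    precision is reported as 1.0 and flagged.
    """
    per = {}

    planted_tss = [(t.position, t.strand) for t in truth.planted_tss]
    called_tss = [(r.position, r.strand) for r in called.tss_records]
    m = _greedy_match(planted_tss, called_tss, tolerance_nt)
    per["tss"] = _score(len(planted_tss), len(called_tss), m)

    p_ops = {tuple(g) for g in truth.planted_operons}
    c_ops = {tuple(o.gene_ids) for o in called.operons}
    per["operons"] = _score(len(p_ops), len(c_ops), len(p_ops & c_ops))

    p_sub = {(g, tuple(suffix)) for g, suffix in truth.planted_suboperon_tss}
    c_sub = {(s.first_gene_id, tuple(s.gene_ids)) for s in called.suboperons}
    per["suboperons"] = _score(len(p_sub), len(c_sub), len(p_sub & c_sub))

    p_as = [((s + e) // 2, st) for s, e, st in truth.planted_antisense]
    ants = list(called.antisense_transcripts)
    c_as = [((t.start + t.end) // 2, t.strand) for t in ants]
    m = 0
    used = set()
    for s, e, st in truth.planted_antisense:
        for j, t in enumerate(ants):
            if (j not in used and t.strand == st
                    and abs(t.start - s) <= tolerance_nt
                    and abs(t.end - e) <= tolerance_nt):
                used.add(j)
                m += 1
                break
    per["antisense"] = _score(len(truth.planted_antisense), len(ants), m)

    novels = list(called.novel_transcripts)
    m = 0
    used = set()
    for p in truth.planted_novel:
        for j, t in enumerate(novels):
            if (j not in used and t.strand == p["strand"]
                    and abs(t.start - p["start"]) <= tolerance_nt
                    and abs(t.end - p["end"]) <= tolerance_nt):
                used.add(j)
                m += 1
                break
    per["novel"] = _score(len(truth.planted_novel), len(novels), m)

    return RecoveryReport(per_class=per)
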