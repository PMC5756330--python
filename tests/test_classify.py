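"""Category boundaries, start-codon revision, ranking, UTR/leaderless."""

import pytest

from bactss.classify import (
    ClassificationConfig, TSSRecord, build_tss_records, classify_tss,
    compute_utr_and_leaderless, rank_primary_secondary, revise_start_codon,
)
from bactss.genomics_io import GeneFeature, Genome, Replicon, revcomp


def tss(position, strand="+", rid="chr1", count=50):
    return TSSRecord(replicon_id=rid, position=position, strand=strand,
                     read_start_count=count)


def gene(gid, start, end, strand="+", ftype="CDS"):
    return GeneFeature(gene_id=gid, replicon_id="chr1", start=start, end=end,
                       strand=strand, feature_type=ftype)


@pytest.fixture()
def config():
    return ClassificationConfig()


class TestCategoryBoundaries:
    """The sTSS window is [0, 300], pTSS (300, 600], nsTSS (0, 200] into the
    ORF, iTSS > 200 into the ORF."""

    @pytest.mark.parametrize("distance,expected", [
        (120, "sTSS"),   # well inside the sense window
        (300, "sTSS"),   # inclusive upper bound
        (301, "pTSS"),   # first distal position
        (450, "pTSS"),
        (600, "pTSS"),   # inclusive distal bound
        (601, "nTSS"),   # beyond assignment range
        (0, "sTSS"),     # TSS on the start-codon base
    ])
    def test_upstream_distance_plus_strand(self, distance, expected, config):
        g = gene("g1", 2000, 2900)
        cats = classify_tss(tss(2000 - distance), [g], None, config)
        assert cats == {(expected, "g1" if expected != "nTSS" else None)}

    @pytest.mark.parametrize("distance,expected", [
        (300, "sTSS"), (301, "pTSS"), (600, "pTSS"), (601, "nTSS")])
    def test_upstream_distance_minus_strand(self, distance, expected, config):
        g = gene("g1", 2000, 2900, strand="-")
        cats = classify_tss(tss(2899 + distance, strand="-"), [g], None, config)
        assert cats == {(expected, "g1" if expected != "nTSS" else None)}

    @pytest.mark.parametrize("d_in,expected", [
        (1, "nsTSS"), (200, "nsTSS"), (201, "iTSS"), (250, "iTSS")])
    def test_inside_orf_downstream_distance(self, d_in, expected, config):
        g = gene("g1", 2000, 3000)  # 1000 nt, far from the end at d_in <= 250
        cats = classify_tss(tss(2000 + d_in), [g], None, config)
        assert cats == {(expected, "g1")}

    def test_itss_near_end_exception(self, config):
        # TSS 250 nt before g1's end, also 150 nt upstream of g2: sTSS of g2
        # and the iTSS label on g1 is dropped
        g1 = gene("g1", 1000, 2000)
        g2 = gene("g2", 2100, 2800)
        cats = classify_tss(tss(1950), [g1, g2], None, config)
        assert cats == {("sTSS", "g2")}

    def test_itss_near_end_without_next_gene_stays_itss(self, config):
        g1 = gene("g1", 1000, 2000)
        cats = classify_tss(tss(1950), [g1], None, config)
        assert cats == {("iTSS", "g1")}

    def test_antisense_inside_opposite_orf(self, config):
        g = gene("g1", 1000, 2000, strand="-")
        cats = classify_tss(tss(1500, strand="+"), [g], None, config)
        assert cats == {("asTSS", "g1")}

    def test_dual_antisense_and_sense(self, config):
        # inside an opposite-strand ORF and 150 nt upstream of a same-strand
        # gene: both labels are kept
        g_a = gene("g_a", 1000, 2000, strand="-")
        g_b = gene("g_b", 2100, 2800, strand="+")
        cats = classify_tss(tss(1950, strand="+"), [g_a, g_b], None, config)
        assert cats == {("asTSS", "g_a"), ("sTSS", "g_b")}

    def test_antisense_to_detected_utr(self, config):
        g = gene("g1", 1000, 2000, strand="-")
        utrs = {"g1": (2000, 2120, "-", "chr1")}
        cats = classify_tss(tss(2050, strand="+"), [g], utrs, config)
        assert ("asTSS", "g1") in cats
        cats_off = classify_tss(
            tss(2050, strand="+"), [g], utrs,
            ClassificationConfig(as_utr_extension=False))
        assert ("asTSS", "g1") not in cats_off

    def test_empty_annotation_gives_ntss(self, config):
        assert classify_tss(tss(100), [], None, config) == {("nTSS", None)}

    def test_non_cds_features_ignored(self, config):
        g = gene("r1", 2000, 2900, ftype="rRNA")
        assert classify_tss(tss(1900), [g], None, config) == {("nTSS", None)}


def _revision_genome(d_tss=150, d_new=180, with_rbs=True, length=600,
                     stop_after=None):
    """A '+' CDS at 100 whose first in-frame start downstream of the TSS sits
    at +d_new, with GGC filler (no start codons in any frame, not RBS-like)
    in between."""
    n_codons = length // 3
    codons = ["GGC"] * n_codons
    codons[0] = "ATG"
    codons[-1] = "TAA"
    if d_new is not None:
        codons[d_new // 3] = "ATG"
    seq = "C" * 100 + "".join(codons) + "C" * 100
    if with_rbs and d_new is not None:
        rbs_end = 100 + d_new - 8  # spacer 8 nt upstream of the new start
        seq = seq[:rbs_end - 5] + "AGGAG" + seq[rbs_end:]
    g = Genome()
    g.add(Replicon(id="chr1", sequence=seq))
    return g, gene("g1", 100, 100 + length)


class TestStartRevision:
    def test_example_arithmetic(self):
        genome, g = _revision_genome(d_tss=150, d_new=180)
        rv = revise_start_codon(tss(100 + 150), g, genome)
        assert rv.shortening_aa == 60
        assert rv.new_utr_nt == 30
        assert rv.rbs_found is True
        assert rv.new_start == 100 + 180

    def test_no_downstream_start_returns_none(self):
        genome, g = _revision_genome(d_tss=150, d_new=None)
        assert revise_start_codon(tss(250), g, genome) is None

    def test_no_upper_bound_on_shortening(self):
        # a 74-aa shortening (the kind of large revision real data shows)
        genome, g = _revision_genome(d_tss=150, d_new=222)
        rv = revise_start_codon(tss(250), g, genome)
        assert rv.shortening_aa == 74

    def test_rbs_absence_recorded(self):
        genome, g = _revision_genome(d_tss=150, d_new=180, with_rbs=False)
        rv = revise_start_codon(tss(250), g, genome)
        assert rv is not None and rv.rbs_found is False

    def test_minus_strand_mirror(self):
        genome, g = _revision_genome(d_tss=150, d_new=180)
        seq = genome["chr1"].sequence
        flipped = Genome()
        flipped.add(Replicon(id="chr1", sequence=revcomp(seq)))
        n = len(seq)
        g_rev = gene("g1", n - g.end, n - g.start, strand="-")
        rv = revise_start_codon(tss(n - 1 - 250, strand="-"), g_rev, flipped)
        assert rv.shortening_aa == 60 and rv.new_utr_nt == 30

    def test_non_cds_rejected(self):
        genome, g = _revision_genome()
        g.feature_type = "rRNA"
        with pytest.raises(ValueError):
            revise_start_codon(tss(250), g, genome)


class TestRanking:
    def test_highest_read_starts_wins(self):
        g = gene("g1", 1000, 1900)
        a = tss(900, count=150)
        b = tss(850, count=30)
        for r in (a, b):
            r.categories.add("sTSS")
            r.gene_by_category["sTSS"] = "g1"
        rank_primary_secondary([a, b], [g])
        assert a.rank["g1"] == "primary" and b.rank["g1"] == "secondary"

    def test_tie_broken_toward_start_codon(self):
        g = gene("g1", 1000, 1900)
        a = tss(1000 - 120, count=40)
        b = tss(1000 - 60, count=40)
        for r in (a, b):
            r.categories.add("sTSS")
            r.gene_by_category["sTSS"] = "g1"
        rank_primary_secondary([a, b], [g])
        assert b.rank["g1"] == "primary"

    def test_single_tss_is_primary(self):
        g = gene("g1", 1000, 1900)
        a = tss(900, count=40)
        a.categories.add("sTSS")
        a.gene_by_category["sTSS"] = "g1"
        rank_primary_secondary([a], [g])
        assert a.rank["g1"] == "primary"


class TestUtrAndLeaderless:
    @pytest.mark.parametrize("utr,leaderless", [(0, True), (3, True),
                                                (4, False), (33, False)])
    def test_leaderless_boundary(self, utr, leaderless):
        g = gene("g1", 1000, 1900)
        r = tss(1000 - utr)
        r.categories.add("sTSS")
        r.gene_by_category["sTSS"] = "g1"
        r.rank["g1"] = "primary"
        compute_utr_and_leaderless([r], [g])
        assert r.utr_length == utr and r.leaderless is leaderless

    def test_histogram_bins(self):
        g = gene("g1", 1000, 1900)
        records = []
        for utr in (2, 12, 14, 33):
            r = tss(1000 - utr)
            r.categories.add("sTSS")
            r.gene_by_category["sTSS"] = "g1"
            r.rank["g1"] = "secondary"
            records.append(r)
        _, hist = compute_utr_and_leaderless(records, [g])
        assert hist == {0: 1, 10: 2, 30: 1}


class TestOnSyntheticTruth:
    def test_planted_categories_reproduced_exactly(self, dataset):
        """Geometry oracle: classification recovers every planted label."""
        cfg = ClassificationConfig()
        for t in dataset.truth.planted_tss:
            expected = "sTSS" if t.category == "leaderless" else t.category
            cats = classify_tss(tss(t.position, t.strand), dataset.features,
                                None, cfg)
            assert {c for c, _ in cats} == {expected}, t

    def test_exhaustiveness_and_exclusivity(self, pipeline_run):
        _, result = pipeline_run
        for r in result.tss_records:
            if r.feature_class:
                continue
            assert r.categories, r
            for gid in set(r.gene_by_category.values()):
                cats_of_gene = {c for c, g in r.gene_by_category.items()
                                if g == gid}
                assert not {"sTSS", "iTSS"} <= cats_of_gene

    def test_primary_secondary_count_conservation(self, pipeline_run):
        _, result = pipeline_run
        by_gene = {}
        for r in result.tss_records:
            for cat in ("sTSS", "pTSS"):
                gid = r.gene_by_category.get(cat)
                if gid is not None:
                    by_gene.setdefault(gid, []).append(r)
        for gid, group in by_gene.items():
            ranks = [r.rank.get(gid) for r in group]
            assert ranks.count("primary") == 1
            assert ranks.count("secondary") == len(group) - 1

    def test_planted_revisions_recovered(self, dataset, pipeline_run):
        _, result = pipeline_run
        got = {r.gene_id: r for r in result.revised_starts}
        for planted in dataset.truth.planted_revisions:
            rv = got[planted["gene_id"]]
            assert rv.new_start == planted["new_start"]
            assert rv.shortening_aa == planted["shortening_aa"]
            assert rv.new_utr_nt == planted["new_utr_nt"]
            assert rv.rbs_found

    def test_planted_leaderless_flagged(self, dataset, pipeline_run):
        _, result = pipeline_run
        flagged = {r.gene_by_category.get("sTSS")
                   for r in result.tss_records if r.leaderless}
        assert set(dataset.truth.planted_leaderless) <= flagged
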