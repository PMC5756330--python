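"""EM motif discovery: recovery, monotonicity, brute-force oracle, promoter
and RBS geometry."""

import itertools

import numpy as np
import pytest

from bactss.classify import TSSRecord
from bactss.genomics_io import Genome, Replicon, revcomp
from bactss.motifs import (
    MotifModel, PromoterConfig, RBSConfig, consensus_string, em_motif,
    find_promoters, find_rbs, purine_profile,
)

BASES = "ACGT"


def _consensus_matches(consensus, target):
    return sum(a.upper() == b.upper() for a, b in zip(consensus, target))


def plant(rng, n, length, motif, rate=1.0, offsets=None):
    seqs = []
    for _ in range(n):
        s = list(rng.choice(list(BASES), size=length))
        if rng.random() < rate:
            o = int(rng.integers(0, length - len(motif) + 1)) \
                if offsets is None else int(rng.choice(offsets))
            s[o:o + len(motif)] = list(motif)
        seqs.append("".join(s))
    return seqs


class TestEmMotif:
    def test_planted_hexamer_recovered(self):
        rng = np.random.default_rng(7)
        seqs = plant(rng, 20, 50, "TATAAT")
        model = em_motif(seqs, 6, seed=7)
        assert _consensus_matches(model.consensus, "TATAAT") >= 5

    def test_log_likelihood_monotone(self):
        rng = np.random.default_rng(11)
        seqs = plant(rng, 15, 40, "TTGACA", rate=0.8)
        model = em_motif(seqs, 6, seed=11)
        diffs = np.diff(model.ll_history)
        assert (diffs >= -1e-8).all()
        assert len(model.ll_history) >= 2

    def test_sequence_shorter_than_width_rejected(self):
        with pytest.raises(ValueError):
            em_motif(["ACGTACGT", "ACGTA", "ACGTACGT"], 6)

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            em_motif(["ACGTACGT"], 4)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        seqs = plant(rng, 10, 30, "AGGAG")
        m1 = em_motif(seqs, 5, seed=5)
        m2 = em_motif(seqs, 5, seed=5)
        assert np.array_equal(m1.pwm, m2.pwm)
        assert m1.per_sequence == m2.per_sequence

    def test_pwm_rows_normalised(self):
        rng = np.random.default_rng(1)
        seqs = plant(rng, 10, 30, "AGGAG")
        model = em_motif(seqs, 5, seed=1)
        assert np.allclose(model.pwm.sum(axis=1), 1.0, atol=1e-9)
        assert np.isclose(model.background.sum(), 1.0)

    def test_brute_force_assignment_oracle(self):
        """The converged EM objective is at least the best objective over all
        hard single-offset assignments evaluated at their MAP PWM."""
        rng = np.random.default_rng(2)
        seqs = plant(rng, 4, 10, "ACGT")
        width, pc = 4, 0.25
        model = em_motif(seqs, width, seed=2, n_restarts=20, tol=1e-10,
                         max_iter=500)
        bg = model.background
        enc = [[BASES.index(b) for b in s] for s in seqs]
        n_off = len(seqs[0]) - width + 1
        log_bg = np.log(bg)
        bg_term = sum(log_bg[b] for e in enc for b in e)

        def objective(pwm, gamma=model.gamma):
            total = pc * float(np.log(pwm).sum()) + bg_term
            for e in enc:
                ratios = [
                    np.prod([pwm[j, e[o + j]] / bg[e[o + j]]
                             for j in range(width)])
                    for o in range(n_off)]
                total += np.log((1 - gamma) + gamma / n_off * sum(ratios))
            return total

        best = -np.inf
        for assign in itertools.product(range(n_off), repeat=len(seqs)):
            counts = np.full((width, 4), pc)
            for e, o in zip(enc, assign):
                for j in range(width):
                    counts[j, e[o + j]] += 1
            pwm = counts / counts.sum(axis=1, keepdims=True)
            best = max(best, objective(pwm))
        assert model.log_likelihood >= best - 1e-6

    def test_shuffled_input_control(self):
        """Column-shuffled sequences lose the motif signal: the planted
        consensus is no longer recovered and the mean best-window log-odds
        under the planted model drops by a clear margin."""
        rng = np.random.default_rng(13)
        seqs = plant(rng, 40, 30, "TATAAT", rate=1.0)  # random offsets
        model = em_motif(seqs, 6, seed=13)
        frac_planted = model.occurrence_count() / len(seqs)
        cols = np.array([list(s) for s in seqs])
        for j in range(cols.shape[1]):
            rng.shuffle(cols[:, j])
        shuffled = ["".join(row) for row in cols]
        m2 = em_motif(shuffled, 6, seed=13)

        def strong_fraction(m, windows):
            # fraction of sequences whose called window matches TATAAT well
            n = 0
            for w, (off, post) in zip(windows, m.per_sequence):
                if off is None or post < 0.5:
                    continue
                site = w[off:off + 6]
                if sum(a == b for a, b in zip(site, "TATAAT")) >= 5:
                    n += 1
            return n / len(windows)

        assert strong_fraction(model, seqs) - strong_fraction(m2, shuffled) \
            >= 0.3

    def test_n_bases_score_at_background(self):
        model = em_motif(["ACGTAC", "ACGTAC", "ACGTAC"], 4, seed=0)
        assert model.log_odds("NNNN") == 0.0


class TestConsensusString:
    @pytest.mark.parametrize("column,expected", [
        ([0.9, 0.05, 0.03, 0.02], "A"),
        ([0.2, 0.1, 0.2, 0.5], "t"),
        ([0.25, 0.25, 0.25, 0.25], "n"),
        ([0.05, 0.7, 0.15, 0.1], "C"),
        ([0.39, 0.31, 0.2, 0.1], "n"),
        ([0.4, 0.3, 0.2, 0.1], "a"),
    ])
    def test_casing_thresholds(self, column, expected):
        assert consensus_string(np.array([column])) == expected


def _records_with_windows(genome_seq, positions, strand="+"):
    g = Genome()
    g.add(Replicon(id="chr1", sequence=genome_seq))
    recs = [TSSRecord(replicon_id="chr1", position=p, strand=strand,
                      read_start_count=50) for p in positions]
    return g, recs


class TestPromoters:
    def test_planted_spacers_recovered(self):
        """-10 boxes ending 7 nt before the +1 and -35 boxes 18 nt further
        upstream are called with their planted spacers."""
        rng = np.random.default_rng(4)
        windows = []
        for _ in range(30):
            w = list(rng.choice(list(BASES), size=50))
            # -10 at spacer 7 -> offset 50-6-7 = 37; -35 gap 18 -> offset 13
            w[37:43] = list("TATAAT")
            w[13:19] = list("TTGACA")
            windows.append("".join(w))
        seq = "".join(windows)
        positions = [50 * (i + 1) for i in range(30)]
        g, recs = _records_with_windows(seq, positions)
        calls, m10, m35, summary = find_promoters(recs, g, seed=4)
        with10 = [c for c in calls if c.has_minus10]
        assert len(with10) / len(calls) >= 0.9
        assert {c.minus10_spacer for c in with10} == {7}
        with35 = [c for c in calls if c.has_minus35]
        assert len(with35) / len(calls) >= 0.8
        assert {c.minus35_spacer for c in with35} == {18}
        assert _consensus_matches(m10.consensus, "TATAAT") >= 5

    def test_partial_plant_fraction(self):
        """With the -10 planted in 90% of 200 windows the detected fraction
        lands near the plant rate."""
        rng = np.random.default_rng(3)
        windows = []
        for i in range(200):
            w = list(rng.choice(list(BASES), size=50))
            if rng.random() < 0.9:
                off = int(rng.integers(33, 42))
                w[off:off + 6] = list("TATAAT")
            windows.append("".join(w))
        seq = "".join(windows)
        g, recs = _records_with_windows(seq, [50 * (i + 1) for i in range(200)])
        calls, m10, _, summary = find_promoters(recs, g, seed=3)
        assert 0.85 <= summary["fraction_minus10"] <= 0.95

    def test_truncated_windows_skipped(self):
        g, recs = _records_with_windows("ACGT" * 30, [10, 60])
        calls, *_ = find_promoters(recs, g, seed=0)
        assert [c.tss_index for c in calls] == [1]

    def test_minus_strand_windows_are_transcript_sense(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list(BASES), size=300))
        g, recs = _records_with_windows(seq, [100, 200], strand="-")
        calls, *_ = find_promoters(recs, g, seed=0)
        for c in calls:
            expected = revcomp(seq[c.position + 1: c.position + 51])
            assert c.window == expected


class TestPurineProfile:
    def test_all_purine_windows(self):
        fracs, mask = purine_profile(["A" * 20, "G" * 20])
        assert np.allclose(fracs, 1.0)
        assert mask.all()

    def test_all_pyrimidine_windows(self):
        fracs, mask = purine_profile(["C" * 20, "T" * 20])
        assert np.allclose(fracs, 0.0)
        assert not mask.any()

    def test_planted_rbs_positions_enriched(self):
        rng = np.random.default_rng(5)
        windows = []
        for _ in range(100):
            w = list(rng.choice(list(BASES), size=20))
            if rng.random() < 0.8:
                w[8:13] = list("AGGAG")  # positions -12..-8
            windows.append("".join(w))
        fracs, mask = purine_profile(windows)
        assert (fracs[8:13] > 0.55).all()

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            purine_profile(["A" * 19])

    def test_extraction_uses_minus15_minus6_band(self):
        # purines only outside the assessed band -> not extracted
        w = "GGGGG" + "CTCTCTCTCT" + "GGGGG"
        _, mask = purine_profile([w, w])
        assert not mask.any()


class TestFindRbs:
    def _windows(self, rng, n, spacer):
        # pyrimidine background so no accidental second AGGAG site exists
        out = []
        for _ in range(n):
            w = list(rng.choice(list("CT"), size=20))
            off = 20 - 5 - spacer
            w[off:off + 5] = list("AGGAG")
            out.append("".join(w))
        return out

    def test_spacer_eight_called(self):
        rng = np.random.default_rng(9)
        windows = self._windows(rng, 30, spacer=8)
        model, calls, summary = find_rbs(windows, ["ATG"] * 30, seed=9)
        assert _consensus_matches(model.consensus, "AGGAG") >= 4
        spacers = {c.spacer for c in calls}
        assert spacers == {8}
        assert summary["spacer_mean"] == pytest.approx(8.0)

    def test_spacer_below_three_not_called_there(self):
        """A motif ending 2 nt before the start codon is outside the legal
        spacer window, so no occurrence is reported at that offset."""
        rng = np.random.default_rng(10)
        windows = self._windows(rng, 25, spacer=8) \
            + self._windows(rng, 5, spacer=2)
        model, calls, _ = find_rbs(windows, ["ATG"] * 30, seed=10)
        assert all(3 <= c.spacer <= 14 for c in calls)
        assert not any(c.spacer == 2 for c in calls)

    def test_start_codon_usage_tabulated(self):
        rng = np.random.default_rng(11)
        windows = self._windows(rng, 10, spacer=7)
        codons = ["ATG"] * 7 + ["GTG"] * 2 + ["TTG"]
        _, _, summary = find_rbs(windows, codons, seed=11)
        assert summary["start_codon_usage"] == {"ATG": 7, "GTG": 2, "TTG": 1}
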