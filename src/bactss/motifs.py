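"""Fixed-width motif discovery by expectation maximization (ZOOPS model).

The promoter search mirrors sigma-70 geometry: a -10 hexamer whose 3' end
lies 3-11 nt upstream of the +1 site, and a -35 hexamer separated from the
-10 by a 16-23 nt spacer.  The RBS search first extracts purine-rich 20-nt
windows upstream of start codons, then fits a width-5 motif whose 3' end
must lie 3-14 nt upstream of the start codon.

The EM uses a zero-or-one-occurrence-per-sequence (ZOOPS) likelihood with a
uniform offset prior over the legal spacer window; positional constraints are
expressed as per-sequence sets of allowed offsets.  The log-likelihood is
non-decreasing across iterations by construction and is asserted so.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genomics_io import Genome, revcomp

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGT"


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.int8)


@dataclass
class MotifModel:
    """A position weight matrix with background and per-sequence occurrences.

    ``pwm`` is width x 4 (columns A, C, G, T); each row sums to 1.
    ``per_sequence`` holds (best offset or None, occurrence posterior) per
    input sequence.  N bases score at background probability (odds ratio 1).
    """

    width: int
    pwm: np.ndarray
    background: np.ndarray
    pseudocount: float
    per_sequence: list = field(default_factory=list)
    consensus: str = ""
    log_likelihood: float = float("-inf")
    ll_history: list = field(default_factory=list)
    gamma: float = 0.5

    def log_odds(self, window: str) -> float:
        """Log-odds (nat) of a width-length window versus background."""
        if len(window) != self.width:
            raise ValueError(f"window must have length {self.width}")
        enc = _encode(window)
        total = 0.0
        for j, b in enumerate(enc):
            if b < 4:
                total += np.log(self.pwm[j, b] / self.background[b])
        return float(total)

    def occurrence_count(self, threshold: float = 0.5) -> int:
        return sum(1 for off, post in self.per_sequence
                   if off is not None and post >= threshold)


def consensus_string(pwm: np.ndarray, upper_threshold: float = 0.7,
                     lower_threshold: float = 0.4) -> str:
    """IUPAC-free consensus with conservation casing: uppercase when the top
    base frequency reaches ``upper_threshold``, lowercase when it reaches
    ``lower_threshold``, 'n' otherwise."""
    out = []
    for row in np.asarray(pwm):
        b = int(np.argmax(row))
        f = row[b]
        if f >= upper_threshold:
            out.append(_BASES[b])
        elif f >= lower_threshold:
            out.append(_BASES[b].lower())
        else:
            out.append("n")
    return "".join(out)


def _normalise_offsets(sequences, width, allowed_offsets):
    n = len(sequences)
    if allowed_offsets is None:
        return [np.arange(len(s) - width + 1) for s in sequences]
    if isinstance(allowed_offsets, tuple) and len(allowed_offsets) == 2 \
            and all(isinstance(x, (int, np.integer)) for x in allowed_offsets):
        lo, hi = allowed_offsets
        return [np.arange(max(0, lo), min(len(s) - width, hi) + 1)
                for s in sequences]
    if len(allowed_offsets) != n:
        raise ValueError("allowed_offsets must match the number of sequences")
    out = []
    for s, offs in zip(sequences, allowed_offsets):
        offs = np.asarray(sorted(set(int(o) for o in offs)), dtype=int)
        if len(offs) and (offs[0] < 0 or offs[-1] > len(s) - width):
            raise ValueError("allowed offset outside sequence")
        out.append(offs)
    return out


def em_motif(sequences, width: int, background=None, seed: int = 0,
             n_restarts: int = 15, max_iter: int = 200, tol: float = 1e-6,
             allowed_offsets=None, pseudocount: float = 0.25,
             gamma_init: float = 0.5) -> MotifModel:
    """ZOOPS EM for one fixed-width motif.

    Each sequence contributes zero or one occurrence at an allowed offset
    (uniform prior over its allowed offsets; occurrence prior ``gamma`` is
    re-estimated).  The best of ``n_restarts`` seeded runs is returned.
    The reported log-likelihood includes the Dirichlet pseudocount prior on
    the PWM (a MAP objective), which is what EM makes non-decreasing.

    Raises ValueError for fewer than two sequences or any sequence shorter
    than ``width``.
    """
    sequences = [str(s).upper() for s in sequences]
    if len(sequences) < 2:
        raise ValueError("EM motif discovery requires at least 2 sequences")
    for i, s in enumerate(sequences):
        if len(s) < width:
            raise ValueError(f"sequence {i} shorter than motif width {width}")
    enc = [_encode(s) for s in sequences]
    offsets = _normalise_offsets(sequences, width, allowed_offsets)

    if background is None:
        counts = np.zeros(4)
        for e in enc:
            for b in range(4):
                counts[b] += int((e == b).sum())
        background = (counts + 1.0) / (counts.sum() + 4.0)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()

    # per-sequence matrix of motif-window base indices for every allowed offset
    windows = []
    for e, offs in zip(enc, offsets):
        if len(offs):
            windows.append(np.stack([e[o:o + width] for o in offs]))
        else:
            windows.append(np.zeros((0, width), dtype=np.int8))

    def run(rng):
        # seed the PWM from one random k-mer
        candidates = [(i, o) for i, offs in enumerate(offsets) for o in offs]
        i0, o0 = candidates[rng.integers(len(candidates))]
        pwm = np.tile(background, (width, 1)) * 0.4
        for j in range(width):
            b = enc[i0][o0 + j]
            if b < 4:
                pwm[j, b] += 0.6
            else:
                pwm[j] += 0.6 / 4
        pwm /= pwm.sum(axis=1, keepdims=True)
        gamma = gamma_init

        ll_history = []
        z_all = None
        prev_ll = -np.inf
        for _ in range(max_iter):
            # E-step
            ll = 0.0
            z_all = []
            counts = np.full((width, 4), pseudocount)
            gamma_num = gamma_den = 0.0
            for e, offs, win in zip(enc, offsets, windows):
                # constant background term
                for b in range(4):
                    ll += np.log(background[b]) * int((e == b).sum())
                if len(offs) == 0:
                    z_all.append(np.zeros(0))
                    continue
                # odds ratio of each candidate window vs background
                ratio = np.ones(len(offs))
                for j in range(width):
                    col = win[:, j]
                    valid = col < 4
                    ratio[valid] *= pwm[j, col[valid]] / background[col[valid]]
                prior = gamma / len(offs)
                denom = (1.0 - gamma) + prior * ratio.sum()
                ll += np.log(denom)
                z = prior * ratio / denom
                z_all.append(z)
                gamma_num += z.sum()
                gamma_den += 1.0
                # M-step accumulation
                for j in range(width):
                    col = win[:, j]
                    np.add.at(counts[j], col[col < 4], z[col < 4])
            # Dirichlet pseudocount prior term: the M-step maximizes this
            # penalized objective, which is therefore monotone
            ll += pseudocount * float(np.log(pwm).sum())
            ll_history.append(ll)
            assert ll >= prev_ll - 1e-8, "EM log-likelihood decreased"
            converged = ll - prev_ll < tol and np.isfinite(prev_ll)
            prev_ll = ll
            if converged:
                break
            pwm = counts / counts.sum(axis=1, keepdims=True)
            if gamma_den > 0:
                gamma = float(np.clip(gamma_num / gamma_den, 1e-3, 1 - 1e-3))
        return pwm, gamma, ll_history, z_all

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng((seed + 1) * 100003 + r)
        pwm, gamma, ll_history, z_all = run(rng)
        if best is None or ll_history[-1] > best[2][-1]:
            best = (pwm, gamma, ll_history, z_all)
    pwm, gamma, ll_history, z_all = best

    per_sequence = []
    for offs, z in zip(offsets, z_all):
        if len(offs) == 0:
            per_sequence.append((None, 0.0))
        else:
            per_sequence.append((int(offs[np.argmax(z)]), float(z.sum())))

    return MotifModel(
        width=width, pwm=pwm, background=background, pseudocount=pseudocount,
        per_sequence=per_sequence, consensus=consensus_string(pwm),
        log_likelihood=float(ll_history[-1]), ll_history=ll_history,
        gamma=gamma)


# ---------------------------------------------------------------------------
# promoter search
# ---------------------------------------------------------------------------

@dataclass
class PromoterConfig:
    upstream_window_nt: int = 50
    minus10_width: int = 6
    minus10_spacer_to_tss: tuple = (3, 11)
    minus35_width: int = 6
    spacer_10_35: tuple = (16, 23)
    posterior_threshold: float = 0.5
    n_restarts: int = 15
    max_iter: int = 200

    def __post_init__(self):
        need = (self.minus10_spacer_to_tss[1] + self.minus10_width
                + self.spacer_10_35[0] + self.minus35_width)
        if need > self.upstream_window_nt:
            raise ValueError("motif geometry does not fit the upstream window")


@dataclass
class PromoterCall:
    tss_index: int
    position: int
    strand: str
    window: str
    has_minus10: bool = False
    minus10_offset: int | None = None
    minus10_spacer: int | None = None
    minus10_seq: str = ""
    minus10_posterior: float = 0.0
    has_minus35: bool = False
    minus35_offset: int | None = None
    minus35_spacer: int | None = None
    minus35_seq: str = ""
    minus35_posterior: float = 0.0


def extract_upstream_windows(tss_records, genome: Genome, length: int):
    """(index, window) pairs of strand-aware upstream sequence for each TSS;
    windows truncated by the replicon edge are skipped."""
    out = []
    for i, r in enumerate(tss_records):
        seq = genome[r.replicon_id].sequence
        p = r.position
        if r.strand == "+":
            if p - length < 0:
                continue
            out.append((i, seq[p - length: p]))
        else:
            if p + 1 + length > len(seq):
                continue
            out.append((i, revcomp(seq[p + 1: p + 1 + length])))
    return out


def find_promoters(tss_records, genome: Genome,
                   config: PromoterConfig | None = None, seed: int = 0):
    """Search -10 and -35 promoter motifs upstream of TSSs.

    Returns (calls, minus10_model, minus35_model, summary); summary holds
    the fraction of analyzable TSSs with each motif.  The -35 is searched
    only in sequences that received a -10, with the spacer constrained to
    16-23 nt between the -35 3' end and the -10 5' end.
    """
    config = config or PromoterConfig()
    W = config.upstream_window_nt
    idx_win = extract_upstream_windows(tss_records, genome, W)
    calls = [PromoterCall(tss_index=i, position=tss_records[i].position,
                          strand=tss_records[i].strand, window=w)
             for i, w in idx_win]
    if len(calls) < 2:
        return calls, None, None, {"n_windows": len(calls),
                                   "fraction_minus10": 0.0,
                                   "fraction_minus35": 0.0}
    seqs = [c.window for c in calls]
    w10 = config.minus10_width
    lo_s, hi_s = config.minus10_spacer_to_tss
    m10 = em_motif(
        seqs, w10, seed=seed, n_restarts=config.n_restarts,
        max_iter=config.max_iter,
        allowed_offsets=(W - w10 - hi_s, W - w10 - lo_s))
    for c, (off, post) in zip(calls, m10.per_sequence):
        if off is not None and post >= config.posterior_threshold:
            c.has_minus10 = True
            c.minus10_offset = off
            c.minus10_spacer = W - off - w10
            c.minus10_seq = c.window[off: off + w10]
            c.minus10_posterior = post

    with10 = [c for c in calls if c.has_minus10]
    m35 = None
    if len(with10) >= 2:
        w35 = config.minus35_width
        lo_g, hi_g = config.spacer_10_35
        seqs35 = [c.window for c in with10]
        allowed = []
        for c in with10:
            o10 = c.minus10_offset
            allowed.append(range(max(0, o10 - hi_g - w35),
                                 max(0, o10 - lo_g - w35) + 1)
                           if o10 - lo_g - w35 >= 0 else [])
        m35 = em_motif(seqs35, w35, seed=seed + 1,
                       n_restarts=config.n_restarts, max_iter=config.max_iter,
                       allowed_offsets=allowed)
        for c, (off, post) in zip(with10, m35.per_sequence):
            if off is not None and post >= config.posterior_threshold:
                gap = c.minus10_offset - (off + w35)
                if lo_g <= gap <= hi_g:
                    c.has_minus35 = True
                    c.minus35_offset = off
                    c.minus35_spacer = gap
                    c.minus35_seq = c.window[off: off + w35]
                    c.minus35_posterior = post

    n = len(calls)
    summary = {
        "n_windows": n,
        "fraction_minus10": sum(c.has_minus10 for c in calls) / n,
        "fraction_minus35": sum(c.has_minus35 for c in calls) / n,
    }
    return calls, m10, m35, summary


# ---------------------------------------------------------------------------
# ribosome binding sites
# ---------------------------------------------------------------------------

@dataclass
class RBSConfig:
    utr_min_nt: int = 20
    window_nt: int = 20
    purine_threshold: float = 0.55
    rbs_width: int = 5
    spacer_to_start: tuple = (3, 14)
    # purine accumulation is assessed over this sub-window relative to the
    # start codon (positions -15..-6)
    purine_window: tuple = (-15, -6)
    posterior_threshold: float = 0.5
    n_restarts: int = 15
    max_iter: int = 200

    def __post_init__(self):
        if not (0 < self.purine_threshold < 1):
            raise ValueError("purine_threshold must be in (0, 1)")


@dataclass
class RBSCall:
    window_index: int
    seq: str
    offset: int
    spacer: int
    posterior: float


def purine_profile(utr_windows, config: RBSConfig | None = None):
    """Per-position purine (A+G) fraction over 20-nt windows upstream of
    start codons, plus the mask of purine-rich sequences.

    Position index 0 is -20, index 19 is -1 relative to the start codon.
    A sequence is extracted iff its mean purine fraction over positions
    -15..-6 exceeds the threshold.
    """
    config = config or RBSConfig()
    W = config.window_nt
    for i, w in enumerate(utr_windows):
        if len(w) != W:
            raise ValueError(f"window {i} is not exactly {W} nt")
    mat = np.array([[b in "AG" for b in w.upper()] for w in utr_windows],
                   dtype=float)
    fractions = mat.mean(axis=0) if len(mat) else np.zeros(W)
    lo, hi = config.purine_window  # e.g. (-15, -6)
    i0, i1 = W + lo, W + hi + 1
    mask = (mat[:, i0:i1].mean(axis=1) > config.purine_threshold
            if len(mat) else np.zeros(0, dtype=bool))
    return fractions, mask


def find_rbs(extracted_windows, start_codons, config: RBSConfig | None = None,
             seed: int = 0):
    """Width-5 EM motif over purine-rich UTR windows.

    An occurrence is legal iff the motif 3' end lies 3-14 nt upstream of the
    start codon.  Returns (model, calls, summary) where summary carries the
    spacer mean/SD and the start-codon usage over the analyzed genes.
    """
    config = config or RBSConfig()
    W, w = config.window_nt, config.rbs_width
    lo_s, hi_s = config.spacer_to_start
    windows = [str(x).upper() for x in extracted_windows]
    model = em_motif(windows, w, seed=seed, n_restarts=config.n_restarts,
                     max_iter=config.max_iter,
                     allowed_offsets=(W - w - hi_s, W - w - lo_s))
    calls = []
    for i, (off, post) in enumerate(model.per_sequence):
        if off is not None and post >= config.posterior_threshold:
            spacer = W - off - w
            calls.append(RBSCall(window_index=i, seq=windows[i][off: off + w],
                                 offset=off, spacer=spacer, posterior=post))
    spacers = np.array([c.spacer for c in calls], dtype=float)
    summary = {
        "n_windows": len(windows),
        "n_with_rbs": len(calls),
        "fraction_with_rbs": len(calls) / len(windows) if windows else 0.0,
        "spacer_mean": float(spacers.mean()) if len(spacers) else float("nan"),
        "spacer_sd": float(spacers.std(ddof=1)) if len(spacers) > 1 else 0.0,
        "start_codon_usage": dict(Counter(s.upper() for s in start_codons)),
    }
    return model, calls, summary
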