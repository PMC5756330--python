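"""TSS detection from primary-library read-start profiles.

A position is a candidate TSS when its read-start count reaches a minimum
(default 20) and rises by a minimum percentage (default 250%) over its
strand-aware upstream neighbour.  Two deterministic curation rules replace
the manual inspection step of the original protocol: a candidate must be the
read-start local maximum within a small window, and must be supported by
whole-transcriptome coverage immediately downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomics_io import StrandedProfile


@dataclass
class CurationConfig:
    local_max_window_nt: int = 3
    downstream_window_nt: int = 20
    min_downstream_depth: float = 5.0
    enabled: bool = True


@dataclass
class DetectionConfig:
    min_increase_percent: float = 250.0
    min_read_starts: int = 20
    assignment_window_nt: int = 600
    barcode: str = "TACCCTAG"
    # which signal the percent-increase rule is applied to; the read-start
    # signal is the default, coverage depth is available as an alternative
    increase_signal: str = "read_starts"
    curation: CurationConfig = field(default_factory=CurationConfig)

    def __post_init__(self):
        if self.min_increase_percent <= 0 or self.min_read_starts <= 0:
            raise ValueError("detection thresholds must be positive")


@dataclass
class CandidateTSS:
    replicon_id: str
    position: int  # 0-based position of the +1 base
    strand: str
    read_start_count: int
    local_increase_percent: float
    curation_flags: set[str] = field(default_factory=set)


def filter_barcoded_reads(reads, barcode: str):
    """Split a read stream into (kept, n_discarded).

    A read is discarded iff its 5' end begins with the exact barcode
    (case-insensitive, no mismatches).  Reads may be Bio.SeqRecord objects or
    plain strings.
    """
    if not barcode:
        raise ValueError("barcode must be non-empty")
    bc = barcode.upper()
    kept, n_discarded = [], 0
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else str(read)
        if seq.upper().startswith(bc):
            n_discarded += 1
        else:
            kept.append(read)
    return kept, n_discarded


def detect_tss(profile: StrandedProfile, config: DetectionConfig) -> list[CandidateTSS]:
    """Candidate TSS positions from a stranded read-start profile.

    Position p qualifies iff read_starts[p] >= min_read_starts and
    100 * (signal[p] - signal[q]) / max(signal[q], 1) >= min_increase_percent,
    where q is the strand-aware upstream neighbour (p-1 on '+', p+1 on '-').
    Positions at the replicon edge take an upstream count of 0.
    """
    rs = np.asarray(profile.read_starts, dtype=np.float64)
    sig = rs if config.increase_signal == "read_starts" \
        else np.asarray(profile.depth, dtype=np.float64)
    n = len(rs)
    if n == 0:
        return []
    up = np.empty(n, dtype=np.float64)
    if profile.strand == "+":
        up[1:] = sig[:-1]
        up[0] = 0.0
    else:
        up[:-1] = sig[1:]
        up[-1] = 0.0
    increase = 100.0 * (sig - up) / np.maximum(up, 1.0)
    mask = (rs >= config.min_read_starts) & (increase >= config.min_increase_percent)
    return [
        CandidateTSS(
            replicon_id=profile.replicon_id,
            position=int(p),
            strand=profile.strand,
            read_start_count=int(profile.read_starts[p]),
            local_increase_percent=float(increase[p]),
        )
        for p in np.flatnonzero(mask)
    ]


def curate_tss(candidates: list[CandidateTSS], profile: StrandedProfile,
               config: DetectionConfig):
    """Automated surrogate for manual TSS curation.

    Removes candidates that are not the read-start local maximum within
    +/- w nt (the maximum is kept; exact ties keep the smaller coordinate),
    and candidates with insufficient mean whole-transcriptome depth over the
    next d nt downstream.  Returns (verified, removed) where removed pairs
    each candidate with a reason string.
    """
    cur = config.curation
    if not cur.enabled:
        return list(candidates), []
    rs = profile.read_starts
    depth = profile.depth
    n = len(rs)
    w = cur.local_max_window_nt
    d = cur.downstream_window_nt
    cand_pos = {c.position for c in candidates}

    verified, removed = [], []
    for c in candidates:
        p = c.position
        lo, hi = max(0, p - w), min(n, p + w + 1)
        window = rs[lo:hi]
        peak = window.max()
        is_max = rs[p] >= peak
        if is_max and rs[p] == peak:
            # tie among candidates: keep the smaller coordinate
            for j in range(lo, p):
                if rs[j] == peak and j in cand_pos:
                    is_max = False
                    break
        if not is_max:
            c.curation_flags.add("not local maximum")
            removed.append((c, "not local maximum"))
            continue
        if profile.strand == "+":
            ds = depth[p:min(n, p + d)]
        else:
            ds = depth[max(0, p - d + 1):p + 1]
        mean_depth = float(ds.mean()) if len(ds) else 0.0
        if mean_depth < cur.min_downstream_depth:
            c.curation_flags.add("no downstream transcript")
            removed.append((c, "no downstream transcript"))
            continue
        verified.append(c)
    return verified, removed
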