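"""PWM scanning and hypergeometric motif enrichment.

A deliberately simple motif stage: score fixed-length windows of interval
sequences against a position weight matrix (log-odds vs. a uniform
background, both strands), call an interval motif-positive when any window
clears a fraction of the maximum attainable score, and test foreground
vs. background interval sets with an upper-tail hypergeometric. Suited to
synthetic uniform-composition genomes; the background interval set is always
supplied explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError
from .intervals import IntervalSet

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PositionWeightMatrix:
    """A motif as 4 x L base counts with log-odds scoring.

    Counts get a pseudocount (default 0.5 per cell) and are converted to
    per-position probabilities; scores are log2(p / background) summed over
    positions, with a uniform 0.25 background by default.
    """

    name: str
    counts: np.ndarray  # 4 x L, rows A/C/G/T
    pseudocount: float = 0.5
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ConfigError("PWM counts must be a 4 x L matrix")
        if self.counts.shape[1] < 4:
            raise ConfigError("PWM length must be >= 4")
        if np.any(self.counts < 0):
            raise ConfigError("PWM counts must be non-negative")
        if np.any(self.counts.sum(axis=0) == 0) and self.pseudocount <= 0:
            raise ConfigError("a PWM position has all-zero counts")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")
        probs = self.counts + self.pseudocount
        probs = probs / probs.sum(axis=0, keepdims=True)
        bg = np.asarray(self.background, dtype=float).reshape(4, 1)
        self.log_odds = np.log2(probs / bg)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @classmethod
    def from_sequences(cls, name: str, seqs: Sequence[str], **kw) -> "PositionWeightMatrix":
        """Build a count matrix from aligned equal-length sequences."""
        if not seqs:
            raise ConfigError("need at least one sequence")
        length = len(seqs[0])
        counts = np.zeros((4, length))
        for s in seqs:
            if len(s) != length:
                raise ConfigError("sequences must be equal length")
            for j, base in enumerate(s.upper()):
                counts[_BASE_INDEX[base], j] += 1
        return cls(name, counts, **kw)

    @classmethod
    def read_tsv(cls, path, name: str = "", **kw) -> "PositionWeightMatrix":
        """Read a 4-row TSV of A/C/G/T counts (optional row labels)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                fields = line.split()
                if not fields:
                    continue
                if fields[0].upper() in _BASE_INDEX:
                    fields = fields[1:]
                rows.append([float(x) for x in fields])
        if len(rows) != 4:
            raise DataError(f"PWM TSV must have 4 rows, got {len(rows)}")
        return cls(name or "motif", np.array(rows), **kw)


@dataclass
class EnrichmentResult:
    motif: str
    n_fg_hit: int
    n_fg: int
    n_bg_hit: int
    n_bg: int
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)

    def as_dict(self) -> dict:
        return {
            "motif": self.motif,
            "n_fg_hit": self.n_fg_hit,
            "n_fg": self.n_fg,
            "n_bg_hit": self.n_bg_hit,
            "n_bg": self.n_bg,
            "p_value": self.p_value,
            "neg_log10_p": self.neg_log10_p,
        }


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _window_scores(seq: str, pwm: PositionWeightMatrix) -> np.ndarray:
    """Score every forward-strand window; windows with N score -inf."""
    L = pwm.length
    n_win = len(seq) - L + 1
    if n_win <= 0:
        return np.empty(0)
    codes = np.full(len(seq), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for j in range(L):
        c = codes[j : j + n_win]
        ok = c >= 0
        valid &= ok
        scores += np.where(ok, pwm.log_odds[np.clip(c, 0, 3), j], 0.0)
    scores[~valid] = -np.inf
    return scores


def scan(sequence: str, pwm: PositionWeightMatrix, threshold_fraction: float = 0.8) -> list[int]:
    """Find motif hits on both strands.

    Returns 0-based forward-strand start positions of windows whose score on
    either strand reaches ``threshold_fraction`` of the PWM's maximum
    attainable log-odds score. Windows containing N never hit. A sequence
    shorter than the motif yields no hits.
    """
    if not 0 < threshold_fraction <= 1:
        raise ConfigError("threshold_fraction must be in (0, 1]")
    seq = sequence.upper()
    if any(c not in "ACGTN" for c in seq):
        raise DataError("sequence must be over the alphabet {A,C,G,T,N}")
    L = pwm.length
    if len(seq) < L:
        return []
    threshold = threshold_fraction * pwm.max_score
    fwd = _window_scores(seq, pwm)
    rev = _window_scores(reverse_complement(seq), pwm)[::-1]  # align to fwd starts
    hits = np.flatnonzero((fwd >= threshold) | (rev >= threshold))
    return [int(h) for h in hits]


def interval_has_motif(
    iv, genome: Mapping[str, str], pwm: PositionWeightMatrix, threshold_fraction: float = 0.8
) -> bool:
    if iv.chrom not in genome:
        raise DataError(f"interval {iv} on unknown chromosome {iv.chrom!r}")
    seq = genome[iv.chrom]
    if iv.end > len(seq):
        raise DataError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} outside genome "
            f"(chromosome length {len(seq)})"
        )
    return len(scan(seq[iv.start : iv.end], pwm, threshold_fraction)) > 0


def enrich(
    fg: IntervalSet,
    bg: IntervalSet,
    genome: Mapping[str, str],
    pwm: PositionWeightMatrix,
    threshold_fraction: float = 0.8,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of motif-positive intervals.

    The foreground's hit count is compared with drawing ``n_fg`` intervals
    from the pooled foreground + background population:
    p = P(X >= n_fg_hit), X ~ Hypergeom(N = n_fg + n_bg, K = total hits).
    """
    if len(fg) == 0 or len(bg) == 0:
        raise DataError("foreground and background must both be non-empty")
    fg_hits = sum(interval_has_motif(iv, genome, pwm, threshold_fraction) for iv in fg)
    bg_hits = sum(interval_has_motif(iv, genome, pwm, threshold_fraction) for iv in bg)
    n_fg, n_bg = len(fg), len(bg)
    pop, successes = n_fg + n_bg, fg_hits + bg_hits
    p = float(stats.hypergeom.sf(fg_hits - 1, pop, successes, n_fg))
    p = min(max(p, 5e-324), 1.0)
    return EnrichmentResult(pwm.name, fg_hits, n_fg, bg_hits, n_bg, p)
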