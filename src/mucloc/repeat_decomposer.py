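"""Tandem-repeat analysis of mucin PTS exons.

Dot-plot self comparison, autocorrelation period detection, decomposition
of a repeat array into fixed-period units, perfect/imperfect unit
classification against the array consensus, and position-frequency
matrices suitable for sequence-logo rendering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DotPlot", "RepeatUnit", "RepeatDecomposition", "ExpansionReport",
    "dotplot", "detect_period", "decompose_array", "compare_repeat_expansion",
]


@dataclass
class DotPlot:
    word: int
    len_a: int
    len_b: int
    matches: list[tuple[int, int]]   # (i, j): a[i:i+word] == b[j:j+word]


@dataclass(frozen=True)
class RepeatUnit:
    start: int
    end: int
    seq: str
    identity: float        # percent identity to the final consensus
    perfect: bool


@dataclass
class RepeatDecomposition:
    period: int
    units: list[RepeatUnit]
    n_perfect: int
    n_imperfect: int
    consensus: str
    pfm: np.ndarray              # shape (period, len(alphabet)); columns sum to 1
    alphabet: str
    lead_flank: str
    trail_flank: str

    def reconstruct(self) -> str:
        return self.lead_flank + "".join(u.seq for u in self.units) + self.trail_flank

    @property
    def imperfect_residues(self) -> int:
        return sum(u.end - u.start for u in self.units if not u.perfect)


@dataclass
class ExpansionReport:
    unit_count_delta: int
    perfect_count_delta: int
    imperfect_length_delta: int


def dotplot(seq_a: str, seq_b: str, word: int) -> DotPlot:
    """All exact word matches between two sequences (forward orientation)."""
    if word < 3:
        raise ValueError("word must be >= 3")
    if word > min(len(seq_a), len(seq_b)):
        raise ValueError("word longer than the shortest sequence")
    index: dict[str, list[int]] = {}
    for j in range(len(seq_b) - word + 1):
        index.setdefault(seq_b[j:j + word], []).append(j)
    matches = []
    for i in range(len(seq_a) - word + 1):
        for j in index.get(seq_a[i:i + word], ()):
            matches.append((i, j))
    return DotPlot(word, len(seq_a), len(seq_b), matches)


def detect_period(seq: str, min_p: int = 2, max_p: int | None = None) -> int | None:
    """Dominant repeat period by lag autocorrelation.

    A(p) is the fraction of positions i with seq[i] == seq[i+p]. Candidates
    are lags scoring >= 95% of the best A; the smallest candidate is
    returned so that harmonics at 2p, 3p, ... are suppressed. Returns None
    when even the best lag agrees at fewer than half of the positions.
    """
    n = len(seq)
    if max_p is None:
        max_p = n // 2
    if not (2 <= min_p <= max_p <= n // 2):
        raise ValueError(f"need 2 <= min_p <= max_p <= len(seq)/2, "
                         f"got ({min_p}, {max_p}) for length {n}")
    x = np.frombuffer(seq.encode(), dtype=np.uint8)
    scores = np.empty(max_p - min_p + 1)
    for k, p in enumerate(range(min_p, max_p + 1)):
        scores[k] = np.mean(x[:-p] == x[p:])
    best = float(scores.max())
    if best < 0.5:
        return None
    candidates = np.flatnonzero(scores >= 0.95 * best)
    return int(candidates[0]) + min_p


def _majority_consensus(units: list[str], period: int) -> str:
    out = []
    for col in range(period):
        counts = Counter(u[col] for u in units)
        top = max(counts.values())
        out.append(min(c for c, v in counts.items() if v == top))
    return "".join(out)


def _pct_identity(a: str, b: str) -> float:
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def decompose_array(seq: str, period: int,
                    perfect_min_identity: float = 70.0) -> RepeatDecomposition:
    """Cut a repeat array into consecutive period-length units.

    The cutting phase is chosen in two passes: a provisional majority
    consensus is built from the phase-0 cut, then the phase maximizing the
    number of units with identity >= ``perfect_min_identity`` to that
    provisional consensus wins (smallest phase on ties). A unit is perfect
    iff it meets that identity bar; the final consensus and the
    position-frequency matrix are built from the perfect units, and
    per-unit identities are reported against the final consensus.
    """
    if period < 2 or period > len(seq):
        raise ValueError("invalid period")
    if len(seq) // period < 2:
        raise ValueError("not a tandem array (fewer than 2 complete units)")

    def cut(phase: int) -> list[str]:
        n_units = (len(seq) - phase) // period
        return [seq[phase + i * period: phase + (i + 1) * period]
                for i in range(n_units)]

    provisional = _majority_consensus(cut(0), period)
    best_phase, best_count = 0, -1
    for phase in range(period):
        units = cut(phase)
        if len(units) < 2:
            continue
        count = sum(_pct_identity(u, provisional) >= perfect_min_identity
                    for u in units)
        if count > best_count:
            best_phase, best_count = phase, count

    phase = best_phase
    unit_seqs = cut(phase)
    flags = [_pct_identity(u, provisional) >= perfect_min_identity
             for u in unit_seqs]
    perfect_units = [u for u, f in zip(unit_seqs, flags) if f]
    consensus = (_majority_consensus(perfect_units, period)
                 if perfect_units else provisional)

    alphabet = "".join(sorted(set("".join(unit_seqs)) | set(consensus)))
    letter_idx = {c: i for i, c in enumerate(alphabet)}
    pfm_source = perfect_units if perfect_units else unit_seqs
    pfm = np.zeros((period, len(alphabet)))
    for u in pfm_source:
        for col, c in enumerate(u):
            pfm[col, letter_idx[c]] += 1
    pfm /= pfm.sum(axis=1, keepdims=True)

    units = []
    for i, (u, f) in enumerate(zip(unit_seqs, flags)):
        start = phase + i * period
        units.append(RepeatUnit(start, start + period, u,
                                round(_pct_identity(u, consensus), 10), f))
    n_perfect = sum(flags)
    return RepeatDecomposition(
        period, units, n_perfect, len(units) - n_perfect, consensus,
        pfm, alphabet, seq[:phase], seq[phase + len(unit_seqs) * period:])


def compare_repeat_expansion(decomp_a: RepeatDecomposition,
                             decomp_b: RepeatDecomposition) -> ExpansionReport:
    """Differences (b minus a) in unit count, perfect count, and total
    residues held in imperfect units."""
    if decomp_a.period != decomp_b.period:
        raise ValueError("decompositions have different periods")
    return ExpansionReport(
        unit_count_delta=len(decomp_b.units) - len(decomp_a.units),
        perfect_count_delta=decomp_b.n_perfect - decomp_a.n_perfect,
        imperfect_length_delta=(decomp_b.imperfect_residues
                                - decomp_a.imperfect_residues),
    )
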