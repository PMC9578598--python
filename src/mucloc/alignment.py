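"""Thin pairwise-alignment layer over Bio.Align.PairwiseAligner.

Default nucleotide scoring: match +1, mismatch -1, gap open -2, gap
extend -1. Protein local alignments use BLOSUM62 with open -11 / extend -1.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class AlignmentResult:
    identity: float        # percent, matches / alignment columns * 100
    columns: int           # aligned columns incl. gap columns
    score: float
    target_start: int      # footprint on the first ("target") sequence
    target_end: int
    query_start: int
    query_end: int
    alignment: object      # Bio.Align.Alignment


def _make_aligner(mode: str, protein: bool, match: float, mismatch: float,
                  open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    if protein:
        al.substitution_matrix = _BLOSUM62
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
    else:
        al.match_score = match
        al.mismatch_score = mismatch
        al.open_gap_score = open_gap
        al.extend_gap_score = extend_gap
    return al


def pairwise_align(target: str, query: str, mode: str = "global", *,
                   protein: bool = False, match: float = 1.0,
                   mismatch: float = -1.0, open_gap: float = -2.0,
                   extend_gap: float = -1.0) -> AlignmentResult:
    """Align two sequences and report percent identity over alignment columns."""
    if not target or not query:
        raise ValueError("cannot align empty sequence")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    aligner = _make_aligner(mode, protein, match, mismatch, open_gap, extend_gap)
    aln = aligner.align(target, query)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    tblocks, qblocks = aln.aligned
    if len(tblocks):
        t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
        q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    else:  # degenerate: no aligned letters
        t0 = t1 = q0 = q1 = 0
    return AlignmentResult(identity, int(columns), float(aln.score),
                           t0, t1, q0, q1, aln)
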