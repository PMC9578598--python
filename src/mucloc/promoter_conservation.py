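"""Promoter extraction, cross-species alignment, PWM scanning, and
conserved transcription-factor binding-site calls.

The analysis asks whether motif hits found upstream of a reference gene are
present, at the homologous position, upstream of its orthologs: promoters
are aligned pairwise to the reference, motif hits are projected through the
alignment column maps, and a reference hit counts as conserved when every
other species shows a same-motif hit overlapping at least half of its
footprint in reference coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .alignment import pairwise_align
from .io_core import Contig, GeneModel, revcomp

__all__ = [
    "PositionFrequencyMatrix", "MotifHit", "ConservedSite", "PromoterAlignment",
    "extract_upstream", "align_to_reference", "parse_jaspar", "pwm_scan",
    "conserved_sites",
]

_BASE_ORDER = "ACGT"
_BASE_IDX = {c: i for i, c in enumerate(_BASE_ORDER)}


@dataclass
class PositionFrequencyMatrix:
    motif_id: str
    name: str
    counts: np.ndarray     # shape (positions, 4), column order A,C,G,T

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be positions x 4")
        if self.counts.shape[0] < 4:
            raise ValueError(f"motif {self.motif_id}: fewer than 4 positions")
        if (self.counts < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative entries")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASE_ORDER[i] for i in self.counts.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int
    end: int
    strand: str
    score: float           # summed log2 odds
    rel_score: float       # (score - min achievable) / (max - min)


@dataclass
class ConservedSite:
    motif_id: str
    reference_hit: MotifHit
    species_hits: dict[str, MotifHit]


@dataclass
class PromoterAlignment:
    species: str
    identity: float
    column_map: np.ndarray   # species position -> reference position, -1 for gaps


def extract_upstream(contig: Contig, gene: GeneModel, n_bp: int = 1000) -> str:
    """The n_bp bases 5' of the transcription start, on the gene's strand.

    Minus-strand genes yield the reverse complement of the downstream
    flank. Truncated with a warning at the contig edge; an edge-abutting
    gene with zero available bases is an error.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    if gene.strand == "+":
        tss = gene.genomic_start
        lo = max(0, tss - n_bp)
        seq = contig.seq[lo:tss]
    else:
        tss = gene.genomic_end
        hi = min(len(contig), tss + n_bp)
        seq = revcomp(contig.seq[tss:hi])
    if not seq:
        raise ValueError(f"gene {gene.gene_id}: no upstream sequence available")
    if len(seq) < n_bp:
        warnings.warn(f"gene {gene.gene_id}: promoter truncated to {len(seq)} bp "
                      f"at contig edge")
    return seq


def align_to_reference(promoters: dict[str, str], reference_species: str
                       ) -> dict[str, PromoterAlignment]:
    """Global alignment of each species' promoter against the reference,
    with a column map from species to reference coordinates."""
    if reference_species not in promoters:
        raise ValueError(f"reference species {reference_species!r} missing")
    if len(promoters) < 2:
        raise ValueError("need at least 2 species")
    ref = promoters[reference_species]
    out: dict[str, PromoterAlignment] = {}
    for sp, seq in promoters.items():
        if sp == reference_species:
            cm = np.arange(len(ref))
            out[sp] = PromoterAlignment(sp, 100.0, cm)
            continue
        res = pairwise_align(ref, seq, "global")
        cm = np.full(len(seq), -1, dtype=int)
        tblocks, qblocks = res.alignment.aligned
        for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
            cm[q0:q1] = np.arange(t0, t1)
        out[sp] = PromoterAlignment(sp, round(res.identity, 10), cm)
    return out


def parse_jaspar(stream) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR PFM text (">ID name" header + bracketed A/C/G/T rows)."""
    text = stream if isinstance(stream, str) else stream.read()
    motifs = []
    cur_header = None
    rows: dict[str, list[float]] = {}

    def flush():
        if cur_header is None:
            return
        missing = [b for b in _BASE_ORDER if b not in rows]
        if missing:
            raise ValueError(f"motif {cur_header[0]}: missing rows {missing}")
        lens = {len(rows[b]) for b in _BASE_ORDER}
        if len(lens) != 1:
            raise ValueError(f"motif {cur_header[0]}: ragged rows")
        counts = np.array([rows[b] for b in _BASE_ORDER]).T
        motifs.append(PositionFrequencyMatrix(cur_header[0], cur_header[1], counts))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            cur_header = (parts[0], parts[1] if len(parts) > 1 else "")
            rows = {}
        else:
            if cur_header is None:
                raise ValueError("matrix row before any JASPAR header")
            label = line[0].upper()
            if label not in _BASE_IDX:
                raise ValueError(f"unexpected row label {label!r}")
            body = line[1:].replace("[", " ").replace("]", " ")
            rows[label] = [float(v) for v in body.split()]
    flush()
    if not motifs:
        raise ValueError("no JASPAR motifs found")
    return motifs


def _log_odds(pfm: PositionFrequencyMatrix, background: np.ndarray) -> np.ndarray:
    """Per position/base log2 odds with pseudocount 0.5 on counts."""
    totals = pfm.counts.sum(axis=1, keepdims=True)
    return np.log2((pfm.counts + 0.5 * background)
                   / ((totals + 0.5) * background))


def pwm_scan(seq: str, pfm: PositionFrequencyMatrix,
             min_rel_score: float = 0.8,
             background=None) -> list[MotifHit]:
    """Both-strand log-odds scan; hits at relative score >= threshold.

    The relative score rescales each window's summed log odds between the
    minimum and maximum achievable under the matrix, so 1.0 marks a
    consensus match. Windows containing non-ACGT characters are skipped.
    """
    if not 0.0 < min_rel_score <= 1.0:
        raise ValueError("min_rel_score must be in (0, 1]")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    seq = seq.upper()
    m = len(pfm)
    if len(seq) < m:
        return []
    lom = _log_odds(pfm, background)
    lo_rc = lom[::-1, ::-1]     # reverse positions, complement base columns
    smin, smax = {}, {}
    for strand, mat in (("+", lom), ("-", lo_rc)):
        smin[strand] = mat.min(axis=1).sum()
        smax[strand] = mat.max(axis=1).sum()
    codes = np.full(len(seq), -1, dtype=int)
    for b, i in _BASE_IDX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    hits = []
    for i in range(len(seq) - m + 1):
        window = codes[i:i + m]
        if (window < 0).any():
            continue
        for strand, mat in (("+", lom), ("-", lo_rc)):
            score = float(mat[np.arange(m), window].sum())
            denom = smax[strand] - smin[strand]
            rel = (score - smin[strand]) / denom if denom else 1.0
            if rel >= min_rel_score - 1e-12:
                hits.append(MotifHit(pfm.motif_id, i, i + m, strand,
                                     score, min(rel, 1.0)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def conserved_sites(per_species_hits: dict[str, list[MotifHit]],
                    alignments: dict[str, PromoterAlignment],
                    reference_species: str,
                    min_overlap: float = 0.5) -> list[ConservedSite]:
    """Reference hits whose footprint is matched in every other species.

    A species supports a reference hit when it has a same-motif hit whose
    footprint, projected to reference coordinates through the alignment
    column map, overlaps at least ``min_overlap`` of the reference hit's
    footprint.
    """
    for sp in per_species_hits:
        if sp not in alignments:
            raise ValueError(f"species {sp!r} has hits but no alignment")
    if reference_species not in per_species_hits:
        raise ValueError(f"no hits provided for reference {reference_species!r}")
    out = []
    others = [sp for sp in per_species_hits if sp != reference_species]
    for ref_hit in per_species_hits[reference_species]:
        footprint = set(range(ref_hit.start, ref_hit.end))
        need = math.ceil(min_overlap * len(footprint))
        support: dict[str, MotifHit] = {}
        for sp in others:
            cm = alignments[sp].column_map
            for hit in per_species_hits[sp]:
                if hit.motif_id != ref_hit.motif_id:
                    continue
                mapped = {int(cm[p]) for p in range(hit.start, hit.end)
                          if 0 <= p < len(cm) and cm[p] >= 0}
                if len(mapped & footprint) >= need:
                    support[sp] = hit
                    break
            if sp not in support:
                break
        if len(support) == len(others):
            out.append(ConservedSite(ref_hit.motif_id, ref_hit, support))
    return out
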