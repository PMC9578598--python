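"""Criteria-based detection of membrane-mucin genes in a genomic interval.

A candidate mucin gene must satisfy, inside the interval bounded by two
flanking marker anchors:

1. an ATG-initiated open reading frame;
2. a long PTS-rich (proline/threonine/serine) segment in its translation;
3. a SEA-domain-like region downstream of the PTS segment;
4. non-PTS flanking sequence sufficiently distinct (< 95% identity) from
   neighbouring candidates, otherwise the candidates are merged as likely
   assembly duplicates.

Transmembrane segment and Class-I PDZ-binding motif detection annotate
candidates but do not gate them.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .alignment import pairwise_align
from .constants import KYTE_DOOLITTLE, SEA_REFERENCE_SYNTHETIC
from .io_core import Contig, GeneModel, Interval, revcomp, translate

__all__ = [
    "MarkerAnchor", "PtsSegment", "SeaHit", "MucinCandidate", "ClusterMetrics",
    "ConservationPoint", "ScanParams",
    "region_identity", "locate_marker", "find_orfs", "pts_scan", "detect_sea",
    "detect_cterm_features", "call_mucin_genes", "cluster_metrics",
    "conservation_vs_time",
]

PTS_RESIDUES = frozenset("PTS")


@dataclass(frozen=True)
class MarkerAnchor:
    marker_id: str
    interval: Interval
    identity: float


@dataclass(frozen=True)
class PtsSegment:
    start: int      # residue offsets on the protein, half-open
    end: int
    fraction: float  # overall P/T/S fraction of the segment

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SeaHit:
    ref_id: str
    start: int      # residue offsets on the scanned protein
    end: int
    identity: float
    score: float


@dataclass
class MucinCandidate:
    gene_id: str
    model: GeneModel
    protein: str
    pts_segment: PtsSegment          # residue coords on the protein
    pts_exon: Interval               # genomic nucleotide coords
    sea_hit: SeaHit
    tm_segment: tuple[int, int] | None   # residue coords, downstream of PTS
    pdz: bool
    start_codon_pos: int
    merged_ids: list[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.model.genomic_start

    @property
    def end(self) -> int:
        return self.model.genomic_end


@dataclass
class ClusterMetrics:
    span_kbp: float
    intergenic_bp: list[int]
    gene_order: list[str]


@dataclass(frozen=True)
class ConservationPoint:
    species_pair: str
    region: str
    identity: float
    divergence_time: float


@dataclass
class ScanParams:
    """Tunable thresholds for candidate gene calling."""

    min_pts_nt: int = 1000          # minimum PTS segment length, nucleotides
    pts_window: int = 100           # residues
    pts_min_frac: float = 0.4
    orf_min_len: int = 900          # nt; candidate ORFs must at least hold the PTS
    sea_refs: tuple = (("SEA_ref", SEA_REFERENCE_SYNTHETIC),)
    sea_min_identity: float = 30.0
    sea_min_len: int = 80
    merge_identity: float = 95.0    # criterion 4: non-PTS identity merge rule


def region_identity(seq_a: str, seq_b: str, mode: str = "global", *,
                    protein: bool = False, **scores) -> tuple[float, int]:
    """Percent identity and aligned-column count between two regions.

    Arguments are ordered canonically before aligning so the measure is
    exactly symmetric even when co-optimal alignments differ in identity.
    """
    if (len(seq_b), seq_b) < (len(seq_a), seq_a):
        seq_a, seq_b = seq_b, seq_a
    res = pairwise_align(seq_a, seq_b, mode, protein=protein, **scores)
    return round(res.identity, 10), res.columns


def locate_marker(contig: Contig, marker_seq: str, marker_id: str = "marker",
                  min_identity: float = 80.0, k: int = 15) -> MarkerAnchor:
    """Best placement of a flanking marker gene by k-mer seeding plus
    bounded Smith-Waterman refinement. Ties break to the leftmost start."""
    marker_seq = marker_seq.upper()
    if len(marker_seq) < 30:
        raise ValueError("marker sequence shorter than 30 bp")
    index: dict[str, list[int]] = {}
    seq = contig.seq
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    diagonals: set[int] = set()
    for j in range(0, len(marker_seq) - k + 1):
        for pos in index.get(marker_seq[j:j + k], ()):
            diagonals.add(pos - j)
    if not diagonals:
        raise ValueError(f"marker {marker_id!r} not found (no seed hits)")
    # cluster nearby diagonals so one refinement covers small indel shifts
    reps: list[int] = []
    for d in sorted(diagonals):
        if not reps or d - reps[-1] > 20:
            reps.append(d)
    pad = 30
    best: tuple[float, int, Interval] | None = None
    for d in reps:
        lo = max(0, d - pad)
        hi = min(len(seq), d + len(marker_seq) + pad)
        res = pairwise_align(seq[lo:hi], marker_seq, "local")
        iv = Interval(contig.id, lo + res.target_start, lo + res.target_end)
        key = (-res.identity, iv.start)
        if best is None or key < (-best[0], best[2].start):
            best = (res.identity, d, iv)
    identity, _, iv = best
    if identity < min_identity:
        raise ValueError(
            f"marker {marker_id!r} not found (best identity {identity:.1f} "
            f"< {min_identity})")
    return MarkerAnchor(marker_id, iv, round(identity, 10))


def find_orfs(seq: str, min_len_nt: int = 300) -> list[tuple[int, int, int, str]]:
    """All ATG-initiated ORFs ending at the first in-frame stop, both strands.

    Returns (start, end, frame, strand) tuples in forward-contig
    coordinates, 0-based half-open including the stop codon, sorted by start.
    """
    if min_len_nt < 30 or min_len_nt % 3:
        raise ValueError("min_len_nt must be >= 30 and a multiple of 3")
    seq = seq.upper()
    n = len(seq)
    out = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        stops_by_frame = {0: [], 1: [], 2: []}
        for i in range(n - 2):
            if s[i:i + 3] in ("TAA", "TAG", "TGA"):
                stops_by_frame[i % 3].append(i)
        for i in range(n - 2):
            if s[i:i + 3] != "ATG":
                continue
            stops = stops_by_frame[i % 3]
            j = bisect.bisect_left(stops, i)
            if j == len(stops):
                continue  # runs off the end without a stop
            end = stops[j] + 3
            if end - i < min_len_nt:
                continue
            if strand == "+":
                out.append((i, end, i % 3, "+"))
            else:
                out.append((n - end, n - i, i % 3, "-"))
    out.sort()
    return out


def pts_scan(protein: str, window: int = 100, min_frac: float = 0.4) -> list[PtsSegment]:
    """Sliding-window P/T/S composition scan.

    Maximal runs of qualifying windows are merged; each segment spans from
    the first qualifying window's start to the last one's end.
    """
    if window < 10:
        raise ValueError("window must be >= 10")
    if not 0.0 < min_frac <= 1.0:
        raise ValueError("min_frac must be in (0, 1]")
    n = len(protein)
    if n < window:
        return []
    x = np.frombuffer(protein.encode(), dtype=np.uint8)
    is_pts = (x == ord("P")) | (x == ord("T")) | (x == ord("S"))
    csum = np.concatenate([[0], np.cumsum(is_pts)])
    frac = (csum[window:] - csum[:-window]) / window
    ok = np.flatnonzero(frac >= min_frac)
    segments = []
    if ok.size:
        breaks = np.flatnonzero(np.diff(ok) > 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [ok.size - 1]])
        for rs, re in zip(run_starts, run_ends):
            a, b = int(ok[rs]), int(ok[re]) + window
            overall = float((csum[b] - csum[a]) / (b - a))
            segments.append(PtsSegment(a, b, overall))
    return segments


def detect_sea(protein: str, sea_refs=None, min_identity: float = 30.0,
               min_len: int = 80) -> SeaHit | None:
    """Best local BLOSUM62 alignment of any SEA reference against a protein."""
    if sea_refs is None:
        sea_refs = (("SEA_ref", SEA_REFERENCE_SYNTHETIC),)
    sea_refs = list(sea_refs)
    if not sea_refs:
        raise ValueError("empty SEA reference set")
    best: SeaHit | None = None
    for ref_id, ref_seq in sea_refs:
        res = pairwise_align(protein, ref_seq, "local", protein=True)
        if res.columns >= min_len and res.identity >= min_identity:
            hit = SeaHit(ref_id, res.target_start, res.target_end,
                         round(res.identity, 10), res.score)
            if (best is None or hit.score > best.score
                    or (hit.score == best.score and hit.start < best.start)):
                best = hit
    return best


def detect_cterm_features(protein: str, tm_window: int = 19,
                          tm_threshold: float = 1.6):
    """Transmembrane segment (Kyte-Doolittle) and Class-I PDZ-binding motif.

    TM = the window of ``tm_window`` residues with maximal mean hydropathy,
    reported when that mean is >= ``tm_threshold`` (leftmost on ties).
    PDZ Class I = C-terminal [S/T]-X-Phi with Phi in {L,I,V,F,M}.
    """
    tm = None
    n = len(protein)
    if n >= tm_window:
        vals = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in protein])
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        means = (csum[tm_window:] - csum[:-tm_window]) / tm_window
        i = int(np.argmax(means))  # argmax returns the leftmost maximum
        if means[i] >= tm_threshold:
            tm = (i, i + tm_window)
    pdz = (n >= 3 and protein[-3] in "ST" and protein[-1] in "LIVFM")
    return tm, pdz


def _refine_pts_bounds(protein: str, seg: PtsSegment, window: int,
                       theta: float) -> tuple[int, int]:
    """Sharpen window-resolution segment bounds to residue resolution.

    Finds the maximal-scoring subarray (score per residue: +1-theta for
    P/T/S, -theta otherwise) within the segment extended by one window on
    each side; ties break leftmost.
    """
    lo = max(0, seg.start - window)
    hi = min(len(protein), seg.end + window)
    best_sum = cur_sum = -1e18
    best = (seg.start, seg.end)
    cur_start = lo
    for i in range(lo, hi):
        s = (1.0 if protein[i] in PTS_RESIDUES else 0.0) - theta
        if cur_sum <= 0:
            cur_sum, cur_start = s, i
        else:
            cur_sum += s
        if cur_sum > best_sum + 1e-12:
            best_sum = cur_sum
            best = (cur_start, i + 1)
    return best


def call_mucin_genes(contig: Contig, anchors: tuple[MarkerAnchor, MarkerAnchor],
                     params: ScanParams | None = None) -> list[MucinCandidate]:
    """Scan the inter-anchor interval for genes meeting the mucin criteria."""
    if params is None:
        params = ScanParams()
    a5, a3 = anchors
    if a5 is None or a3 is None:
        raise ValueError("both flanking anchors are required")
    lo, hi = a5.interval.end, a3.interval.start
    region = contig.seq[lo:hi]
    if len(region) < params.orf_min_len:
        return []
    orfs = find_orfs(region, params.orf_min_len)
    # nested ORFs from internal ATGs share a stop: keep the longest per stop
    by_stop: dict[tuple[str, int], tuple] = {}
    for start, end, frame, strand in orfs:
        key = (strand, end if strand == "+" else start)
        cur = by_stop.get(key)
        if cur is None or (end - start) > (cur[1] - cur[0]):
            by_stop[key] = (start, end, frame, strand)

    candidates: list[MucinCandidate] = []
    for start, end, _frame, strand in sorted(by_stop.values()):
        orf_nt = region[start:end] if strand == "+" else revcomp(region[start:end])
        protein = translate(orf_nt)
        if protein.endswith("*"):
            protein = protein[:-1]
        segments = pts_scan(protein, params.pts_window, params.pts_min_frac)
        if not segments:
            continue
        seg0 = max(segments, key=lambda s: (s.length, -s.start))
        rs, re_ = _refine_pts_bounds(protein, seg0, params.pts_window,
                                     params.pts_min_frac)
        if 3 * (re_ - rs) < params.min_pts_nt:
            continue
        frac = sum(c in PTS_RESIDUES for c in protein[rs:re_]) / (re_ - rs)
        seg = PtsSegment(rs, re_, frac)
        downstream = protein[seg.end:]
        if not downstream:
            continue
        sea = detect_sea(downstream, params.sea_refs, params.sea_min_identity,
                         params.sea_min_len)
        if sea is None:
            continue
        sea = SeaHit(sea.ref_id, sea.start + seg.end, sea.end + seg.end,
                     sea.identity, sea.score)
        tm, pdz = detect_cterm_features(downstream)
        if tm is not None:
            tm = (tm[0] + seg.end, tm[1] + seg.end)

        gstart, gend = lo + start, lo + end
        if strand == "+":
            pts_g = Interval(contig.id, gstart + 3 * seg.start,
                             gstart + 3 * seg.end, "+")
            bounds = [(gstart, pts_g.start, "N-term"),
                      (pts_g.start, pts_g.end, "PTS"),
                      (pts_g.end, gend, "C-term")]
            start_codon = gstart
        else:
            pts_g = Interval(contig.id, gend - 3 * seg.end,
                             gend - 3 * seg.start, "-")
            bounds = [(pts_g.end, gend, "N-term"),
                      (pts_g.start, pts_g.end, "PTS"),
                      (gstart, pts_g.start, "C-term")]
            start_codon = gend - 3
        exons, roles = [], []
        for s_, e_, role in bounds:
            if e_ > s_:
                exons.append(Interval(contig.id, s_, e_, strand))
                roles.append(role)
        gid = f"{contig.id}_cand{len(candidates) + 1}"
        model = GeneModel(gid, exons, strand, roles)
        candidates.append(MucinCandidate(gid, model, protein, seg, pts_g, sea,
                                         tm, pdz, start_codon))

    candidates.sort(key=lambda c: c.start)
    # criterion 4: adjacent candidates whose non-PTS portions are near
    # identical are assembly duplicates of one gene -> merge
    merged: list[MucinCandidate] = []
    for cand in candidates:
        if merged:
            prev = merged[-1]
            ia, _ = region_identity(_non_pts_seq(contig, prev),
                                    _non_pts_seq(contig, cand), "global")
            if ia >= params.merge_identity:
                prev.merged_ids.append(cand.gene_id)
                continue
        merged.append(cand)
    return merged


def _non_pts_seq(contig: Contig, cand: MucinCandidate) -> str:
    parts = [contig.seq[e.start:e.end]
             for e, r in zip(sorted(cand.model.exons, key=lambda e: e.start),
                             _roles_sorted(cand.model))
             if r != "PTS"]
    return "".join(parts)


def _roles_sorted(model: GeneModel) -> list[str]:
    order = sorted(range(len(model.exons)), key=lambda i: model.exons[i].start)
    return [model.exon_roles[i] for i in order]


def cluster_metrics(candidates) -> ClusterMetrics:
    """Cluster span (kbp, 1 decimal), intergenic distances, and gene order."""
    if not candidates:
        raise ValueError("no candidates")
    cands = sorted(candidates, key=lambda c: _gstart(c))
    span = round((_gend(cands[-1]) - _gstart(cands[0])) / 1000.0, 1)
    intergenic = [int(_gstart(b) - _gend(a)) for a, b in zip(cands, cands[1:])]
    order = [getattr(c, "gene_id", None) or c.model.gene_id for c in cands]
    return ClusterMetrics(span, intergenic, order)


def _gstart(c):
    return c.genomic_start if isinstance(c, GeneModel) else c.start


def _gend(c):
    return c.genomic_end if isinstance(c, GeneModel) else c.end


def conservation_vs_time(pairs, times: dict[str, float]):
    """Percent identity per region against divergence time, with OLS slopes.

    ``pairs`` is an iterable of (species_pair, region, seq_a, seq_b).
    Returns (points sorted by time, {region: slope or None}); slope units
    are percentage points per Myr.
    """
    points: list[ConservationPoint] = []
    for species_pair, region, seq_a, seq_b in pairs:
        if species_pair not in times:
            raise ValueError(f"missing divergence time for {species_pair!r}")
        ident, _ = region_identity(seq_a, seq_b, "global")
        points.append(ConservationPoint(species_pair, region, ident,
                                        float(times[species_pair])))
    points.sort(key=lambda p: (p.divergence_time, p.species_pair))
    slopes: dict[str, float | None] = {}
    for region in {p.region for p in points}:
        sub = [p for p in points if p.region == region]
        if len(sub) < 2:
            slopes[region] = None
        else:
            t = np.array([p.divergence_time for p in sub])
            y = np.array([p.identity for p in sub])
            slopes[region] = float(np.polyfit(t, y, 1)[0])
    return points, slopes
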