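"""Paralog-aware RNA-seq quantification.

Near-identical paralogs (e.g. a 93%-identical gene pair) defeat naive
counting: most reads map equally well to both copies. This module builds
unique k-mer masks over a transcript set, places reads by exact-seed +
full-read Hamming verification, classifies them as unique / shared /
unassigned, and converts counts to RPK over the discriminating (uniquely
maskable) sequence and to TPM.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UniquenessMask", "ReadPlacement", "unique_kmer_mask", "place_reads",
    "quantify", "qc_filter", "parse_sam", "aggregate_samples",
]


@dataclass
class UniquenessMask:
    transcript_id: str
    k: int
    mask: np.ndarray     # bool, one entry per transcript position

    @property
    def unique_length(self) -> int:
        return int(self.mask.sum())


@dataclass
class ReadPlacement:
    read_id: str
    placements: list[tuple[int, int, int]]   # (transcript idx, position, mismatches)
    cls: str                                 # unique | shared | unassigned
    best_mm: int | None


def unique_kmer_mask(transcripts: list[tuple[str, str]], k: int = 31
                     ) -> list[UniquenessMask]:
    """Mark positions covered by at least one k-mer that occurs exactly once
    across the whole transcript set (multiplicity counted over all copies)."""
    if k < 11:
        raise ValueError("k must be >= 11")
    if len(transcripts) < 2:
        raise ValueError("need at least 2 transcripts")
    counts: Counter = Counter()
    for _, seq in transcripts:
        for i in range(len(seq) - k + 1):
            counts[seq[i:i + k]] += 1
    masks = []
    for tid, seq in transcripts:
        mask = np.zeros(len(seq), dtype=bool)
        if len(seq) < k:
            warnings.warn(f"transcript {tid} shorter than k={k}; mask all-false")
        else:
            for i in range(len(seq) - k + 1):
                if counts[seq[i:i + k]] == 1:
                    mask[i:i + k] = True
        masks.append(UniquenessMask(tid, k, mask))
    return masks


def _hamming(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def place_reads(reads, transcripts: list[tuple[str, str]], max_mm: int = 2,
                k_seed: int = 21) -> list[ReadPlacement]:
    """Seed-and-verify read placement with per-read classification.

    Each read contributes ``max_mm + 1`` non-overlapping exact seeds
    (pigeonhole: any placement with <= max_mm mismatches leaves at least one
    seed error-free, so the search is exhaustive over qualifying
    placements). Seed length shrinks for short reads to keep that
    guarantee. A read is *unique* when exactly one transcript attains the
    minimum mismatch count, *shared* when two or more tie, *unassigned*
    when no placement has <= max_mm mismatches.
    """
    seqs = [seq for _, seq in transcripts]
    indexes: dict[int, list[dict[str, list[int]]]] = {}

    def index_for(k: int) -> list[dict[str, list[int]]]:
        if k not in indexes:
            idx = []
            for seq in seqs:
                d: dict[str, list[int]] = {}
                for i in range(len(seq) - k + 1):
                    d.setdefault(seq[i:i + k], []).append(i)
                idx.append(d)
            indexes[k] = idx
        return indexes[k]

    out = []
    for read in reads:
        rid, rseq = (read.id, read.seq) if hasattr(read, "seq") else read
        L = len(rseq)
        k = max(1, min(k_seed, L // (max_mm + 1)))
        idx = index_for(k)
        best_by_t: dict[int, tuple[int, int]] = {}   # t -> (mm, pos)
        for t, seq in enumerate(seqs):
            if L > len(seq):
                continue
            cands: set[int] = set()
            for j in range(max_mm + 1):
                o = j * k
                if o + k > L:
                    break
                for p in idx[t].get(rseq[o:o + k], ()):
                    p0 = p - o
                    if 0 <= p0 <= len(seq) - L:
                        cands.add(p0)
            for p0 in sorted(cands):
                mm = _hamming(rseq, seq[p0:p0 + L], max_mm)
                if mm <= max_mm:
                    cur = best_by_t.get(t)
                    if cur is None or (mm, p0) < cur:
                        best_by_t[t] = (mm, p0)
        if not best_by_t:
            out.append(ReadPlacement(rid, [], "unassigned", None))
            continue
        best_mm = min(mm for mm, _ in best_by_t.values())
        placements = [(t, pos, mm) for t, (mm, pos) in sorted(best_by_t.items())]
        n_best = sum(1 for mm, _ in best_by_t.values() if mm == best_mm)
        cls = "unique" if n_best == 1 else "shared"
        out.append(ReadPlacement(rid, placements, cls, best_mm))
    return out


def quantify(placements: list[ReadPlacement], transcripts: list[tuple[str, str]],
             masks: list[UniquenessMask]) -> pd.DataFrame:
    """Expression table: unique/shared counts, unique-region RPK, and TPM.

    RPK divides unique-read counts by the uniquely maskable length (the
    discriminating sequence) in kb. Shared reads are apportioned to their
    tied transcripts proportionally to per-transcript unique-read rates
    (equal shares when all tied transcripts lack unique reads); TPM then
    normalizes effective counts by full transcript length to sum to 1e6.
    """
    n = len(transcripts)
    ids = [tid for tid, _ in transcripts]
    lengths = np.array([len(seq) for _, seq in transcripts], dtype=float)
    unique_len = np.array([m.unique_length for m in masks], dtype=float)
    unique_count = np.zeros(n)
    shared_count = np.zeros(n)
    shared_sets: list[tuple[int, ...]] = []
    for pl in placements:
        if pl.cls == "unique":
            t = next(t for t, _, mm in pl.placements if mm == pl.best_mm)
            unique_count[t] += 1
        elif pl.cls == "shared":
            tied = tuple(t for t, _, mm in pl.placements if mm == pl.best_mm)
            shared_sets.append(tied)
            for t in tied:
                shared_count[t] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        rpk = np.where(unique_len > 0, unique_count / (unique_len / 1000.0), 0.0)
    effective = unique_count.copy()
    for tied in shared_sets:
        rates = np.array([rpk[t] for t in tied])
        if rates.sum() > 0:
            shares = rates / rates.sum()
        else:
            shares = np.full(len(tied), 1.0 / len(tied))
        for t, s in zip(tied, shares):
            effective[t] += s
    dens = effective / lengths
    total = dens.sum()
    if total == 0:
        warnings.warn("no assignable reads: all TPM set to 0")
        tpm = np.zeros(n)
    else:
        tpm = 1e6 * dens / total
    return pd.DataFrame({
        "unique_count": unique_count.astype(int),
        "shared_count": shared_count.astype(int),
        "effective_count": effective,
        "unique_length": unique_len.astype(int),
        "rpk": rpk,
        "tpm": tpm,
    }, index=pd.Index(ids, name="gene"))


def qc_filter(reads, min_mean_quality: float = 20.0, max_n_frac: float = 0.1):
    """Drop reads with mean Phred below threshold or excess N content."""
    kept, n_qual, n_n = [], 0, 0
    for r in reads:
        if np.mean(r.quals) < min_mean_quality:
            n_qual += 1
        elif r.seq.count("N") / len(r.seq) > max_n_frac:
            n_n += 1
        else:
            kept.append(r)
    report = {"in": len(reads) if hasattr(reads, "__len__") else n_qual + n_n + len(kept),
              "out": len(kept), "dropped_quality": n_qual, "dropped_n": n_n}
    return kept, report


def parse_sam(stream, transcripts: list[tuple[str, str]], max_mm: int = 2
              ) -> list[ReadPlacement]:
    """Minimal SAM text import (mandatory columns + NM tag) as an alternative
    entry point for placements from an external aligner."""
    text = stream if isinstance(stream, str) else stream.read()
    tindex = {tid: i for i, (tid, _) in enumerate(transcripts)}
    by_read: dict[str, list[tuple[int, int, int]]] = {}
    order: list[str] = []
    for line in text.splitlines():
        if not line or line.startswith("@"):
            continue
        cols = line.split("\t")
        if len(cols) < 11:
            raise ValueError("SAM line with fewer than 11 mandatory columns")
        qname, flag, rname, pos = cols[0], int(cols[1]), cols[2], int(cols[3])
        if qname not in by_read:
            by_read[qname] = []
            order.append(qname)
        if flag & 4 or rname == "*" or rname not in tindex:
            continue
        nm = 0
        for tag in cols[11:]:
            if tag.startswith("NM:i:"):
                nm = int(tag[5:])
        by_read[qname].append((tindex[rname], pos - 1, nm))
    out = []
    for rid in order:
        pls = [p for p in by_read[rid] if p[2] <= max_mm]
        best_by_t: dict[int, tuple[int, int]] = {}
        for t, pos, mm in pls:
            cur = best_by_t.get(t)
            if cur is None or (mm, pos) < cur:
                best_by_t[t] = (mm, pos)
        if not best_by_t:
            out.append(ReadPlacement(rid, [], "unassigned", None))
            continue
        best_mm = min(mm for mm, _ in best_by_t.values())
        placements = [(t, pos, mm) for t, (mm, pos) in sorted(best_by_t.items())]
        n_best = sum(1 for mm, _ in best_by_t.values() if mm == best_mm)
        out.append(ReadPlacement(rid, placements,
                                 "unique" if n_best == 1 else "shared", best_mm))
    return out


def aggregate_samples(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- SD of per-sample expression tables (group summary only)."""
    stacked = pd.concat(tables, names=["sample"])
    g = stacked.groupby(level="gene", sort=False)
    mean = g.mean(numeric_only=True).add_suffix("_mean")
    sd = g.std(numeric_only=True, ddof=1).add_suffix("_sd")
    return mean.join(sd)
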