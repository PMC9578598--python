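"""Synthetic mucin-cluster genomes, diverged paralogs, and simulated reads.

Every pipeline stage is testable without downloads: the generator plants a
cluster of mucin-like genes (ATG-initiated N-terminal exon, one PTS exon
back-translated from a repeat unit, a C-terminal exon carrying a SEA-like
segment, a hydrophobic transmembrane stretch and a Class-I PDZ terminus)
between two random marker genes, and records complete ground truth.

All randomness flows through explicitly seeded ``numpy`` generators; no
global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import MUC3_REPEAT_UNIT, PREFERRED_CODON, SEA_REFERENCE_SYNTHETIC, STOP_CODONS
from .io_core import (Contig, FastqRead, GeneModel, Interval, write_fasta,
                      write_fastq, write_gff)

__all__ = [
    "ClusterSpec", "Truth", "backtranslate", "build_cluster_genome",
    "mutate_sequence", "mutate_coding_sequence", "add_noise",
    "simulate_reads", "write_dataset",
]

BASES = "ACGT"
# residues with low P/T/S and hydropathy, used for filler protein stretches
_FILLER_AA = "ADEGKLNQRVWY"
# stop codons in each of the three frames immediately upstream of each
# planted ATG, so no upstream ATG can extend the gene's reading frame
_ORF_GUARD = "TAAATAAATAA"


def backtranslate(protein: str) -> str:
    """Protein -> CDS using one fixed (most-used human) codon per residue."""
    try:
        return "".join(PREFERRED_CODON[c] for c in protein)
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc.args[0]!r}") from None


@dataclass
class ClusterSpec:
    """Layout and divergence parameters of a synthetic mucin cluster.

    The first two genes form the designated paralog pair: gene 2's
    non-PTS exons are derived from gene 1's at ``paralog_identity``.
    """

    n_genes: int = 3
    repeat_unit: str = MUC3_REPEAT_UNIT
    repeat_counts: list[int] | None = None
    paralog_identity: float = 0.93
    intergenic_lengths: list[int] | None = None
    marker_lengths: tuple[int, int] = (2000, 2000)
    nterm_len_aa: int = 150
    seed: int = 0

    def __post_init__(self):
        if len(self.repeat_unit) < 2:
            raise ValueError("repeat_unit must be >= 2 residues")
        if not 0.5 <= self.paralog_identity <= 1.0:
            raise ValueError("paralog_identity must be in [0.5, 1.0]")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.repeat_counts is None:
            base = [30, 45, 25, 35]
            self.repeat_counts = [base[i % 4] for i in range(self.n_genes)]
        if len(self.repeat_counts) != self.n_genes:
            raise ValueError("repeat_counts length must equal n_genes")
        if any(c < 2 for c in self.repeat_counts):
            raise ValueError("repeat counts must be >= 2")
        if self.intergenic_lengths is None:
            base = [10939, 2469, 5000]
            self.intergenic_lengths = [base[i % 3] for i in range(self.n_genes - 1)]
        if len(self.intergenic_lengths) != self.n_genes - 1:
            raise ValueError("need n_genes - 1 intergenic lengths")
        if any(l <= len(_ORF_GUARD) for l in self.intergenic_lengths):
            raise ValueError("intergenic lengths must exceed the ORF guard (11 bp)")
        if any(l <= 0 for l in self.marker_lengths):
            raise ValueError("marker lengths must be > 0")


@dataclass
class Truth:
    """Ground truth recorded by the generator / read simulator."""

    contig_id: str
    gene_models: list[GeneModel] = field(default_factory=list)
    repeat_counts: list[int] = field(default_factory=list)
    marker_intervals: dict[str, Interval] = field(default_factory=dict)
    intergenic_lengths: list[int] = field(default_factory=list)
    abundances: list[float] | None = None
    read_origins: dict[str, tuple[int, int]] = field(default_factory=dict)

    def pts_exon(self, gene_index: int) -> Interval:
        model = self.gene_models[gene_index]
        return model.exons[model.exon_roles.index("PTS")]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_FILLER_AA))[rng.integers(0, len(_FILLER_AA), n)])


def _gene_proteins(spec: ClusterSpec, rng: np.random.Generator,
                   repeat_count: int) -> tuple[str, str, str]:
    nterm = "M" + _random_protein(rng, spec.nterm_len_aa - 1)
    pts = spec.repeat_unit * repeat_count
    cterm = (SEA_REFERENCE_SYNTHETIC + _random_protein(rng, 20)
             + "L" * 19 + _random_protein(rng, 8) + "TSL")
    return nterm, pts, cterm


def mutate_sequence(seq: str, sub_rate: float, indel_rate: float = 0.0,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> str:
    """Per-position substitutions (uniform over the 3 alternatives) and
    single-base indels (50/50 insertion/deletion)."""
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for c in seq:
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:
                out.append(BASES[rng.integers(0, 4)])  # insertion before c
                out.append(c)
            # else: deletion, emit nothing
            continue
        if sub_rate and rng.random() < sub_rate and c in BASES:
            alts = BASES.replace(c, "")
            c = alts[rng.integers(0, 3)]
        out.append(c)
    return "".join(out)


def mutate_coding_sequence(seq: str, sub_rate: float,
                           rng: np.random.Generator) -> str:
    """Substitution-only mutation of a CDS that preserves its reading frame.

    Codons that a substitution would turn into a stop are reverted, and the
    initial ATG is kept intact — a crude stand-in for purifying selection
    against nonsense changes, so planted genes stay one open reading frame
    at any divergence level.
    """
    mut = list(mutate_sequence(seq, sub_rate, 0.0, rng=rng))
    mut[0:3] = seq[0:3]
    for i in range(0, len(mut) - 2, 3):
        if "".join(mut[i:i + 3]) in STOP_CODONS:
            mut[i:i + 3] = seq[i:i + 3]
    return "".join(mut)


def build_cluster_genome(spec: ClusterSpec) -> tuple[Contig, Truth]:
    """Assemble marker5 + genes/gaps + marker3 and record ground truth."""
    rng = np.random.default_rng(spec.seed)
    contig_id = "synthetic_cluster"
    truth = Truth(contig_id, repeat_counts=list(spec.repeat_counts),
                  intergenic_lengths=list(spec.intergenic_lengths))

    # build gene part sequences first (paralog pair shares non-PTS parts)
    parts: list[tuple[str, str, str]] = []   # (nterm_nt, pts_nt, cterm_nt+stop)
    n1 = p1 = c1 = None
    for gi in range(spec.n_genes):
        if gi == 1 and spec.n_genes >= 2:
            sub = 1.0 - spec.paralog_identity
            nterm_nt = mutate_coding_sequence(n1, sub, rng)
            cterm_nt = mutate_coding_sequence(c1, sub, rng)
            pts_nt = backtranslate(spec.repeat_unit * spec.repeat_counts[1])
        else:
            nterm, pts, cterm = _gene_proteins(spec, rng, spec.repeat_counts[gi])
            nterm_nt = backtranslate(nterm)
            pts_nt = backtranslate(pts)
            cterm_nt = backtranslate(cterm)
            if gi == 0:
                n1, c1 = nterm_nt, cterm_nt
        parts.append((nterm_nt, pts_nt, cterm_nt + "TAA"))

    pieces: list[str] = []
    pos = 0

    def emit(s: str) -> int:
        nonlocal pos
        pieces.append(s)
        start = pos
        pos += len(s)
        return start

    m5_start = emit(_random_seq(rng, spec.marker_lengths[0]))
    truth.marker_intervals["marker5"] = Interval(contig_id, m5_start, pos)
    emit(_random_seq(rng, 49) + _ORF_GUARD)   # pad between marker and gene 1

    for gi, (nterm_nt, pts_nt, cterm_nt) in enumerate(parts):
        g_start = pos
        n_iv = Interval(contig_id, g_start, emit(nterm_nt) + len(nterm_nt))
        p_iv = Interval(contig_id, pos, emit(pts_nt) + len(pts_nt))
        c_iv = Interval(contig_id, pos, emit(cterm_nt) + len(cterm_nt))
        truth.gene_models.append(GeneModel(
            f"gene{gi + 1}", [n_iv, p_iv, c_iv], "+",
            ["N-term", "PTS", "C-term"]))
        if gi < spec.n_genes - 1:
            gap = spec.intergenic_lengths[gi]
            emit(_random_seq(rng, gap - len(_ORF_GUARD)) + _ORF_GUARD)

    m3_start = emit(_random_seq(rng, spec.marker_lengths[1]))
    truth.marker_intervals["marker3"] = Interval(contig_id, m3_start, pos)
    return Contig(contig_id, "".join(pieces)), truth


def add_noise(contig: Contig, truth: Truth, sub_rate: float,
              seed: int = 0) -> Contig:
    """Apply substitution noise across a synthetic cluster.

    Gene bodies are mutated frame-aware (no nonsense changes, start codons
    kept) while intergenic/marker sequence is mutated freely, so the planted
    genes remain detectable open reading frames at any noise level.
    """
    rng = np.random.default_rng(seed)
    genic = sorted((m.genomic_start, m.genomic_end) for m in truth.gene_models)
    out, prev = [], 0
    for gs, ge in genic:
        out.append(mutate_sequence(contig.seq[prev:gs], sub_rate, 0.0, rng=rng))
        out.append(mutate_coding_sequence(contig.seq[gs:ge], sub_rate, rng))
        prev = ge
    out.append(mutate_sequence(contig.seq[prev:], sub_rate, 0.0, rng=rng))
    return Contig(contig.id, "".join(out))


def simulate_reads(transcripts: list[tuple[str, str]], abundances: list[float],
                   n_reads: int, read_len: int = 100, err_rate: float = 0.01,
                   seed: int = 0) -> tuple[list[FastqRead], Truth]:
    """Uniform-coverage single-end reads at planted molar abundances.

    Read origins are drawn with probability proportional to
    abundance x transcript length (molar abundance times the number of
    start positions a molecule offers); start positions are uniform and
    per-base substitution errors occur at ``err_rate``. Qualities encode
    the simulated error rate as a constant Phred score.
    """
    if abs(sum(abundances) - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    if len(abundances) != len(transcripts):
        raise ValueError("abundances/transcripts length mismatch")
    lengths = [len(seq) for _, seq in transcripts]
    if read_len > min(lengths):
        raise ValueError("read_len exceeds the shortest transcript")
    rng = np.random.default_rng(seed)
    w = np.array([a * l for a, l in zip(abundances, lengths)], dtype=float)
    w /= w.sum()
    phred = min(40, int(round(-10 * np.log10(err_rate)))) if err_rate > 0 else 40
    truth = Truth("reads", abundances=list(abundances))
    reads = []
    choices = rng.choice(len(transcripts), size=n_reads, p=w)
    for k in range(n_reads):
        t = int(choices[k])
        start = int(rng.integers(0, lengths[t] - read_len + 1))
        seq = transcripts[t][1][start:start + read_len]
        if err_rate:
            seq = mutate_sequence(seq, err_rate, 0.0, rng=rng)
        rid = f"read{k}"
        reads.append(FastqRead(rid, seq, tuple([phred] * read_len)))
        truth.read_origins[rid] = (t, start)
    return reads, truth


def write_dataset(outdir, contig: Contig, truth: Truth,
                  reads: list[FastqRead] | None = None) -> dict[str, Path]:
    """Write genome FASTA, truth GFF3, transcript FASTA, reads FASTQ, and a
    tab-separated truth table; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    with open(outdir / "genome.fa", "w") as fh:
        write_fasta([contig], fh)
    paths["genome"] = outdir / "genome.fa"
    with open(outdir / "genes.gff3", "w") as fh:
        write_gff(truth.gene_models, fh)
    paths["gff"] = outdir / "genes.gff3"
    tx = [(m.gene_id, m.spliced_sequence(contig)) for m in truth.gene_models]
    with open(outdir / "transcripts.fa", "w") as fh:
        write_fasta(tx, fh)
    paths["transcripts"] = outdir / "transcripts.fa"
    if reads is not None:
        with open(outdir / "reads.fq", "w") as fh:
            write_fastq(reads, fh)
        paths["reads"] = outdir / "reads.fq"
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("gene_id\tstart\tend\tstrand\trepeat_count\n")
        for m, rc in zip(truth.gene_models, truth.repeat_counts):
            fh.write(f"{m.gene_id}\t{m.genomic_start}\t{m.genomic_end}"
                     f"\t{m.strand}\t{rc}\n")
    paths["truth"] = outdir / "truth.tsv"
    return paths
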