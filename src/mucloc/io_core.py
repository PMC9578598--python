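"""Sequence and annotation I/O plus elementary sequence operations.

Conventions used throughout the package:

* internal coordinates are 0-based, half-open; GFF3 (1-based, inclusive)
  is converted at the parse/write boundary;
* minus-strand gene sequences are materialized as reverse complements
  before any feature scan, so protein-level positions always refer to the
  spliced, stranded transcript;
* input sequences are upper-cased on parse.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

from .constants import IUPAC_COMPLEMENT

__all__ = [
    "Contig", "Interval", "GeneModel", "FastqRead",
    "parse_fasta", "write_fasta", "parse_fastq",
    "parse_gff", "write_gff", "revcomp", "translate",
]


def _as_text(stream) -> str:
    if isinstance(stream, str):
        return stream
    return stream.read()


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"contig {self.id!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Exon intervals of one gene, ordered 5'->3' on the gene strand.

    ``exon_roles`` tags each exon as one of ``N-term``, ``PTS``, ``C-term``
    or ``other``; at most one exon may be tagged ``PTS``.
    """

    gene_id: str
    exons: list[Interval]
    strand: str
    exon_roles: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        if not self.exon_roles:
            self.exon_roles = ["other"] * len(self.exons)
        if len(self.exon_roles) != len(self.exons):
            raise ValueError(f"gene {self.gene_id}: roles/exons length mismatch")
        if self.exon_roles.count("PTS") > 1:
            raise ValueError(f"gene {self.gene_id}: more than one PTS exon")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expect:
            raise ValueError(f"gene {self.gene_id}: exons not ordered 5'->3'")

    @property
    def transcript_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def genomic_start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def genomic_end(self) -> int:
        return max(e.end for e in self.exons)

    def spliced_sequence(self, contig: Contig) -> str:
        """Spliced transcript sequence, 5'->3' on the gene strand."""
        parts = [contig.seq[e.start:e.end] for e in sorted(self.exons, key=lambda e: e.start)]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class FastqRead:
    id: str
    seq: str
    quals: tuple[int, ...]  # Phred scores, one per base

    def __post_init__(self):
        if len(self.seq) != len(self.quals):
            raise ValueError(f"read {self.id}: seq/qual length mismatch")


def parse_fasta(stream) -> list[Contig]:
    """Parse FASTA text into contigs (whitespace stripped, upper-cased)."""
    text = _as_text(stream)
    stripped = text.strip()
    if not stripped:
        raise ValueError("empty FASTA stream")
    if not stripped.startswith(">"):
        raise ValueError("sequence data before first FASTA header")
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    return [Contig(r.id, str(r.seq)) for r in records]


def write_fasta(contigs, handle, width: int = 60) -> None:
    """Write contigs (or (id, seq) pairs) as FASTA, 60-column wrapped."""
    for c in contigs:
        cid, seq = (c.id, c.seq) if hasattr(c, "seq") else c
        handle.write(f">{cid}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i:i + width] + "\n")


def parse_fastq(stream) -> list[FastqRead]:
    text = _as_text(stream)
    reads = []
    for rec in SeqIO.parse(io.StringIO(text), "fastq"):
        reads.append(FastqRead(rec.id, str(rec.seq).upper(),
                               tuple(rec.letter_annotations["phred_quality"])))
    return reads


def write_fastq(reads, handle) -> None:
    for r in reads:
        qual = "".join(chr(q + 33) for q in r.quals)
        handle.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are complemented class-wise."""
    seq = seq.upper()
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from None


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code; stops render as '*'."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return str(Seq(cds).translate())


# --- GFF3 ------------------------------------------------------------------

def parse_gff(stream, contigs: list[Contig]) -> list[GeneModel]:
    """Parse GFF3 exon features into gene models.

    Exons are grouped by their ``Parent`` (or ``ID``) attribute; 1-based
    inclusive coordinates become 0-based half-open; minus-strand exon lists
    are reversed to 5'->3'. An ``exon_role`` attribute, when present, is
    carried into :class:`GeneModel.exon_roles`.
    """
    text = _as_text(stream)
    by_contig = {c.id: c for c in contigs}
    genes: dict[str, dict] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"GFF line {lineno}: expected 9 columns, got {len(cols)}")
        seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
        if ftype.lower() != "exon":
            continue
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        gid = attr.get("Parent") or attr.get("gene_id") or attr.get("ID")
        if gid is None:
            raise ValueError(f"GFF line {lineno}: exon without Parent/ID")
        iv = Interval(seqid, int(start) - 1, int(end), strand)
        contig = by_contig.get(seqid)
        if contig is not None and iv.end > len(contig):
            raise ValueError(f"GFF line {lineno}: exon beyond contig {seqid} bounds")
        rec = genes.setdefault(gid, {"strand": strand, "contig": seqid, "exons": []})
        rec["exons"].append((iv, attr.get("exon_role", "other")))

    models = []
    for gid, rec in genes.items():
        pairs = sorted(rec["exons"], key=lambda p: p[0].start)
        if rec["strand"] == "-":
            pairs = pairs[::-1]
        models.append(GeneModel(gid, [p[0] for p in pairs], rec["strand"],
                                [p[1] for p in pairs]))
    models.sort(key=lambda m: m.genomic_start)
    return models


def write_gff(models: list[GeneModel], handle, source: str = "mucloc") -> None:
    handle.write("##gff-version 3\n")
    for m in models:
        for iv, role in zip(m.exons, m.exon_roles):
            attrs = f"Parent={m.gene_id};exon_role={role}"
            handle.write("\t".join([
                iv.contig_id, source, "exon", str(iv.start + 1), str(iv.end),
                ".", m.strand, ".", attrs]) + "\n")
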