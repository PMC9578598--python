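"""In-silico PCR and restriction-digest discrimination of near-identical
transcripts.

The discriminating assay this models: gene-specific primer pairs amplify a
cDNA segment from each of two paralogous transcripts; a restriction site
present in only one paralog's amplicon splits it into two fragments, so the
fragment pattern identifies which paralog a template came from.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import (IUPAC_SETS, MUC3A_FWD, MUC3A_REV, MUC3B_FWD, MUC3B_REV)
from .io_core import Interval, revcomp

__all__ = [
    "Primer", "Enzyme", "PrimerSite", "AmpliconPrediction", "PSTI",
    "MUC3A_PRIMERS", "MUC3B_PRIMERS",
    "primer_pair_mismatch", "find_primer_sites", "predict_amplicon",
    "digest", "discriminate",
]


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str     # 5'->3', IUPAC codes allowed

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) < 15:
            raise ValueError(f"primer {self.name}: shorter than 15 nt")
        bad = set(self.seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"primer {self.name}: non-IUPAC characters {sorted(bad)}")


@dataclass(frozen=True)
class Enzyme:
    name: str
    site: str          # IUPAC recognition sequence
    cut_offset: int    # top-strand cut position within the site

    def __post_init__(self):
        object.__setattr__(self, "site", self.site.upper())
        if not 0 < self.cut_offset < len(self.site):
            raise ValueError(f"enzyme {self.name}: cut offset outside site")


PSTI = Enzyme("PstI", "CTGCAG", 5)

# Built-in paralog-specific RT-qPCR primer pairs (exon 3 fwd / exon 8 rev).
MUC3A_PRIMERS = (Primer("MUC3A_fwd", MUC3A_FWD), Primer("MUC3A_rev", MUC3A_REV))
MUC3B_PRIMERS = (Primer("MUC3B_fwd", MUC3B_FWD), Primer("MUC3B_rev", MUC3B_REV))


@dataclass(frozen=True)
class PrimerSite:
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class AmpliconPrediction:
    template_id: str
    fwd_site: PrimerSite
    rev_site: PrimerSite
    interval: Interval
    length: int
    sequence: str
    fragments: list[int] | None = None


def primer_pair_mismatch(primer_a, primer_b) -> float:
    """Position-wise percent mismatch between two equal-length primers."""
    a = primer_a.seq if isinstance(primer_a, Primer) else primer_a.upper()
    b = primer_b.seq if isinstance(primer_b, Primer) else primer_b.upper()
    if len(a) != len(b):
        raise ValueError("primers have unequal lengths")
    mm = sum(x != y for x, y in zip(a, b))
    return round(100.0 * mm / len(a), 1)


def _iupac_match(query_char: str, template_base: str) -> bool:
    # template N sits in no IUPAC class: assembly gaps never satisfy a query
    return template_base in IUPAC_SETS[query_char]


def _scan(template: str, query: str, max_mm: int, strand: str,
          check_3prime: int | None) -> list[PrimerSite]:
    L = len(query)
    sites = []
    for i in range(len(template) - L + 1):
        window = template[i:i + L]
        mm = sum(not _iupac_match(q, t) for q, t in zip(query, window))
        if mm > max_mm:
            continue
        if check_3prime is not None and not _iupac_match(query[check_3prime],
                                                         window[check_3prime]):
            continue
        sites.append(PrimerSite(i, i + L, strand, mm))
    return sites


def find_primer_sites(template: str, primer: Primer, max_mm: int = 3,
                      require_3prime_match: bool = True) -> list[PrimerSite]:
    """All primer binding sites on both strands within a mismatch budget.

    IUPAC classes in the primer match their base sets; with
    ``require_3prime_match`` (default, reflecting polymerase extension
    chemistry) the primer's 3'-terminal base must match exactly.
    """
    template = template.upper()
    if len(template) < len(primer.seq):
        return []
    fwd_3p = len(primer.seq) - 1 if require_3prime_match else None
    sites = _scan(template, primer.seq, max_mm, "+", fwd_3p)
    # minus-strand binding: the primer anneals to the reverse complement,
    # i.e. its reverse complement appears on the template's plus strand;
    # the primer's 3' end is then the leftmost base of the window
    rc = revcomp(primer.seq)
    rev_3p = 0 if require_3prime_match else None
    sites += _scan(template, rc, max_mm, "-", rev_3p)
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicon(template: str, fwd: Primer, rev: Primer,
                     max_mm: int = 3, max_len: int = 5000,
                     enzyme: Enzyme | None = None,
                     template_id: str = "template",
                     require_3prime_match: bool = True) -> AmpliconPrediction | None:
    """Leftmost forward site + nearest downstream reverse site -> amplicon.

    The amplicon spans from the forward site's start to the reverse site's
    end, inclusive of both primers. Returns None when no compatible site
    pair exists within ``max_len``.
    """
    template = template.upper()
    fsites = [s for s in find_primer_sites(template, fwd, max_mm,
                                           require_3prime_match)
              if s.strand == "+"]
    rsites = [s for s in find_primer_sites(template, rev, max_mm,
                                           require_3prime_match)
              if s.strand == "-"]
    if not fsites or not rsites:
        return None
    f = fsites[0]
    down = [r for r in rsites if r.start >= f.end and r.end - f.start <= max_len]
    if not down:
        return None
    r = min(down, key=lambda s: s.end)
    seq = template[f.start:r.end]
    pred = AmpliconPrediction(template_id, f, r,
                              Interval(template_id, f.start, r.end),
                              len(seq), seq)
    if enzyme is not None:
        pred.fragments = digest(seq, enzyme)
    return pred


def digest(seq: str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths after cutting every non-overlapping site occurrence
    (leftmost-first scan); an uncut sequence yields one full-length fragment."""
    seq = seq.upper()
    site, off = enzyme.site, enzyme.cut_offset
    cuts = []
    i = 0
    while i <= len(seq) - len(site):
        window = seq[i:i + len(site)]
        if all(_iupac_match(q, t) for q, t in zip(site, window)):
            cuts.append(i + off)
            i += len(site)
        else:
            i += 1
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def discriminate(fragments: list[int], signatures: dict[str, list[int]],
                 tol_bp: int = 5) -> str:
    """Match an observed fragment multiset against expected patterns.

    A label matches when its expected pattern has the same fragment count
    and each sorted fragment agrees within ``tol_bp``. Zero or multiple
    matching labels -> ``"inconclusive"``.
    """
    if not signatures:
        raise ValueError("empty signature set")
    obs = sorted(fragments)
    hits = []
    for label, expected in signatures.items():
        exp = sorted(expected)
        if len(exp) == len(obs) and all(abs(o - e) <= tol_bp
                                        for o, e in zip(obs, exp)):
            hits.append(label)
    return hits[0] if len(hits) == 1 else "inconclusive"
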