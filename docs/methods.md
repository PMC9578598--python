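# Methods

`mucloc` implements the computational workflow for discovering and
characterizing clustered membrane-mucin genes: criteria-based gene
detection in a genomic interval, tandem-repeat decomposition of PTS/VNTR
exons, paralog-aware expression quantification, in-silico PCR with
restriction discrimination, and promoter/TFBS conservation analysis. This
note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## Coordinate and sequence conventions

Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) is converted at the I/O boundary. Minus-strand genes are
materialized as reverse complements before any feature scan, so all
protein-level positions refer to the spliced, stranded transcript. In
exact sequence comparisons `N` matches nothing (an assembly gap is never
evidence); in degenerate queries (primer and restriction-site scanning)
IUPAC classes in the *query* match their base sets, while a template `N`
still matches no class.

## Mucin gene criteria (cluster_scanner)

A candidate gene inside the interval between two located flanking marker
anchors must have:

1. an ATG-initiated open reading frame ending at its first in-frame stop
   (both strands scanned; nested ORFs sharing a stop collapse to the
   longest);
2. a PTS segment: a sliding-window proline/threonine/serine composition
   scan (window 100 residues, threshold 0.4) whose merged qualifying run,
   after boundary refinement, spans at least 1,000 nt. Window merging has
   window-level resolution, so segment bounds are sharpened by a
   maximal-scoring-subarray pass (per-residue score `1{P/T/S} − 0.4`,
   searched one window beyond each coarse bound, leftmost on ties). On
   arrays built from the 17-residue consensus unit this recovers exon
   bounds to within one codon, because the unit's first residue (I) is
   not P/T/S;
3. a SEA-domain-like region downstream of the PTS segment: best local
   BLOSUM62 alignment (gap open −11 / extend −1) of any reference
   sequence, accepted at ≥ 30% identity over ≥ 80 columns. The shipped
   default reference is a synthetic SEA-like segment (it is planted by the
   generator; it is not a curated domain sequence) — users analysing real
   genomes should supply real SEA references;
4. distinct flanking sequence: adjacent candidates whose non-PTS portions
   align at ≥ 95% global identity are treated as duplicate copies of one
   gene and merged. The 95% bar separates genuinely paralogous pairs
   (~87–93% region identity) from assembly duplicates.

Transmembrane detection (maximal 19-residue Kyte–Doolittle window, mean
≥ 1.6, leftmost on ties) and the Class-I PDZ-binding motif
([S/T]-X-Φ, Φ ∈ {L,I,V,F,M}, at the C-terminus) annotate candidates but do
not gate them.

Pairwise alignment is delegated to `Bio.Align.PairwiseAligner` with
match +1 / mismatch −1 / gap open −2 / extend −1 for nucleotide and
BLOSUM62 (−11/−1) for protein, all configurable. `region_identity` orders
its arguments canonically before aligning: co-optimal alignments can
differ in identity, and canonical ordering makes the measure exactly
symmetric. Marker anchoring seeds with 15-mers, clusters seed diagonals,
and refines each by bounded local alignment; ties prefer the leftmost
start, and anchors below 80% identity raise an error.

## Tandem-repeat decomposition (repeat_decomposer)

Period detection uses lag autocorrelation: `A(p)` is the fraction of
positions where `seq[i] == seq[i+p]`. Lags scoring within 95% of the best
form the candidate set and the smallest wins, suppressing harmonics at 2p,
3p; if even the best lag agrees at under half of positions there is no
repeat. A random 20-letter protein has expected `A ≈ 0.05`, so the 0.5
floor is conservative.

Decomposition cuts the array into consecutive period-length windows. The
phase is chosen in two passes: a provisional majority consensus from the
phase-0 cut, then the phase maximizing the number of units at ≥ 70%
identity to that consensus (smallest phase on ties). A unit is *perfect*
iff it meets the 70% bar at exact unit length — strict 100% identity would
contradict the within-unit variation visible in repeat logos, and the
published perfect/imperfect counts depend on this undefined rule, so the
threshold is explicit and configurable. The final consensus is the
column-wise majority over perfect units (ties break to the
lexicographically smallest residue), the position-frequency matrix is
built from the perfect units (columns sum to 1), and the
flanks-plus-units concatenation reconstructs the input exactly, by
construction. Classification uses the provisional consensus; reported
per-unit identities use the final one.

Dot plots are exact word-hash matches (word ≥ 3), not suffix structures:
inputs are desk-scale and the output semantics are identical.

## Paralog-aware quantification (paralog_expression)

Uniqueness masks mark transcript positions covered by at least one k-mer
(default k = 31) occurring exactly once across the whole transcript set.
Read placement is exact-seed-and-verify: each read contributes
`max_mm + 1` non-overlapping seeds (default seed length 21, shrunk for
short reads), so by pigeonhole any placement within the mismatch budget
(default 2) retains one error-free seed — the search is provably
equivalent to the brute-force Hamming scan the tests compare it against.
A read is *unique* when exactly one transcript attains the minimum
mismatch count, *shared* on ties, *unassigned* otherwise; the three
classes partition every read set.

RPK divides unique-read counts by uniquely-maskable length in kb — the
discriminating region, not the whole transcript — because only that
sequence can evidence one paralog over another. Shared reads are
apportioned to their tied transcripts proportionally to unique-read rates
(equal shares when no tied transcript has unique reads); this minimal
estimator is isolated in one function for replacement by EM-style
approaches. TPM normalizes effective counts by full transcript length to
sum to 10^6; the effective-length convention is plain transcript length.
Multi-sample aggregation reports mean ± SD only — inferential testing is
out of scope. A minimal SAM importer (mandatory columns + `NM` tag)
admits placements from external aligners.

## In-silico PCR (insilico_pcr)

Primer sites are scored at every offset on both strands; the reverse
primer is the 5'→3' minus-strand sequence, so its reverse complement is
scanned on the template. The 3'-terminal base must match exactly by
default, reflecting polymerase extension chemistry (configurable off for
pure search). Amplicon choice is deterministic: leftmost forward site,
nearest downstream reverse site, length cap 5,000 bp. Digestion cuts
after `cut_offset` within each leftmost non-overlapping site occurrence
(PstI = CTGCA^G ships built in); fragment lengths always sum to the input
length. Discrimination matches the observed fragment multiset against
expected patterns within ±5 bp per fragment; zero or multiple matches are
"inconclusive". The built-in paralog-specific primer constants reproduce
their printed 12.0%/9.5% position-wise divergence; one of the printed
reverse primers appears without a 3' terminator mark in its source and is
used as printed.

## Promoter conservation (promoter_conservation)

Promoters default to 1,000 bp upstream of the transcription start on the
gene strand, truncated with a warning at contig edges. Cross-species
comparison uses reference-anchored pairwise global alignments instead of
true multiple alignment: conservation calls only need each species
projected into reference coordinates, and externally computed alignments
can be substituted. PWM scanning scores
`Σ log2((f + 0.5·bg) / ((N + 0.5)·bg))` with pseudocount 0.5 and uniform
background by default, on both strands; relative score rescales between
the matrix's minimum and maximum achievable scores, so 1.0 is a consensus
match, and the default hit threshold is 0.8. Windows containing non-ACGT
characters are skipped. A reference hit is *conserved* when every other
species has a same-motif hit whose reference-projected footprint overlaps
at least 50% of it — "completely conserved" needs a coordinate tolerance
and 50% footprint overlap is the declared one. Removing a species can
only grow the conserved set (monotonicity). Regulatory-element boundaries
derived from external chromatin data are accepted as configuration, not
derived.

## Synthetic data (synthetic_data)

The generator is the package's study-condition definition, not a tuning
surface. A cluster is `marker5 + gene1 + gap + … + marker3`: each planted
gene is one reading frame with an ATG-initiated N-terminal exon (filler
residues drawn from a low-P/T/S, low-hydropathy alphabet), a PTS exon
back-translated from the 17-residue consensus unit times a per-gene copy
number (one fixed most-used human codon per residue, so nucleotide-level
repeats are perfect), and a C-terminal exon carrying the synthetic
SEA-like segment, a 19-leucine transmembrane stretch and a `…TSL` PDZ
terminus. Default layout: three genes, copy numbers (30, 45, 25),
intergenic gaps (10,939 bp, 2,469 bp) matching the reported
mucin-cluster intergenic distances, 2-kb markers. An 11-nt guard with a
stop codon in every frame precedes each gene so no upstream ATG can
extend a planted frame — making planted coordinates exactly recoverable.

Genes 1 and 2 form the designated paralog pair (default target identity
93%): gene 2's non-PTS exons derive from gene 1 by frame-preserving
mutation — substitutions that would create an in-frame stop are reverted,
and start codons are kept — a crude stand-in for purifying selection
against nonsense changes. This biases measured identity slightly above
target (reverts restore whole codons), which is why the in-cluster
identity check carries a ±2-point band while the substitution-only mode
meets ±1.5 points at ≥ 5 kb. Whole-cluster noise (`add_noise`) applies
the same frame-preserving rule inside gene bodies and free substitution
elsewhere, so gene *count* recovery can be tested at 2% noise without the
test silently measuring stop-codon lottery outcomes.

The read simulator draws origins proportional to abundance × transcript
length (molar abundance times available start positions), uniform starts,
per-base substitution errors at a flat rate (default 1%), and constant
Phred qualities encoding that rate. It does not model quality-score
decay along reads, indel errors, paired ends, positional coverage bias,
or inter-individual VNTR length polymorphism — so passing recovery tests
demonstrate estimator correctness under uniform coverage, not robustness
to real library artefacts.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen to exercise every
code path in seconds: ~25-kb synthetic genomes, repeat arrays up to 600
copies (10.2 kaa), 50,000 reads for abundance recovery, brute-force
oracle comparisons on hundreds of randomized small instances with fixed
seeds. Exhaustive oracle spaces (e.g. all pairs of 6-mers for alignment)
are sampled rather than enumerated. All "best hit" selections break ties
toward the lower start coordinate; consensus ties break lexicographically;
every stochastic fixture is seeded.

## Known limitations

- The criteria scanner calls genes as N-term/PTS/C-term blocks; it does
  not model multi-exon splice structure (full exon architecture is
  accepted from GFF3 when available).
- The perfect/imperfect repeat rule (70% identity at exact unit length)
  is a declared interpretation; published perfect-repeat counts for real
  loci are sensitive to this rule and to the cutting phase.
- Shared-read apportionment is proportional, not likelihood-based; at
  extreme abundance skew with few unique positions it underperforms EM.
- Reference-anchored pairwise alignment can misproject footprints through
  low-identity promoters where a true MSA would not.
- The alignment-parameter choices behind published region-identity
  percentages for real loci are not recoverable from their description;
  exact reproduction of those percentages is not promised.
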