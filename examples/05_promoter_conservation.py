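"""Call conserved transcription-factor binding sites across species.

Plants a motif consensus in a reference promoter, derives three diverged
species promoters (one with the motif ablated), scans all promoters with
the position-frequency matrix, and projects hits through pairwise
alignments to the reference. Only sites supported in every species are
reported conserved — the ablated species removes its site from the
conserved set.
"""

import numpy as np

from mucloc.promoter_conservation import (align_to_reference, conserved_sites,
                                          parse_jaspar, pwm_scan)
from mucloc.synthetic_data import mutate_sequence

PFM_TEXT = """>MA0001.1 TOY1
A [ 12  0  0 12  2  0 ]
C [  0 12  0  0 10  0 ]
G [  0  0 12  0  0  0 ]
T [  0  0  0  0  0 12 ]
"""
(pfm,) = parse_jaspar(PFM_TEXT)
print(f"motif {pfm.motif_id} consensus: {pfm.consensus}")

rng = np.random.default_rng(17)
dna = lambda n: "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
ref = dna(400) + pfm.consensus + dna(200)

promoters = {"human": ref}
for i, sp in enumerate(("chimp", "rhesus", "baboon")):
    diverged = list(mutate_sequence(ref, 0.03 * (i + 1), seed=i))
    # the binding site itself is under purifying selection: keep it intact
    diverged[400:406] = pfm.consensus
    promoters[sp] = "".join(diverged)
ablated = list(promoters["baboon"])
ablated[400:406] = "TTTTTT"   # lineage-specific loss of the site
promoters["baboon"] = "".join(ablated)

alignments = align_to_reference(promoters, "human")
for sp, aln in alignments.items():
    print(f"  {sp:7s} identity to reference: {aln.identity:.1f}%")

hits = {sp: pwm_scan(seq, pfm, min_rel_score=0.9)
        for sp, seq in promoters.items()}
print("hits per species:", {sp: len(h) for sp, h in hits.items()})

cons = conserved_sites(hits, alignments, "human")
print(f"conserved sites (all 4 species): {len(cons)}")

hits_no_baboon = {sp: h for sp, h in hits.items() if sp != "baboon"}
cons3 = conserved_sites(hits_no_baboon, alignments, "human")
print(f"conserved sites without the ablated species: "
      f"{[(c.motif_id, c.reference_hit.start) for c in cons3]}")
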