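"""Marker anchoring, mucin-criteria gene calling, and cluster metrics."""

import re

import numpy as np
import pytest

from mucloc.cluster_scanner import (ScanParams, call_mucin_genes,
                                    cluster_metrics, conservation_vs_time,
                                    detect_cterm_features, detect_sea,
                                    find_orfs, locate_marker, pts_scan,
                                    region_identity)
from mucloc.constants import (KYTE_DOOLITTLE, MUC3_REPEAT_UNIT,
                              SEA_REFERENCE_SYNTHETIC)
from mucloc.io_core import Contig, revcomp
from mucloc.synthetic_data import (ClusterSpec, add_noise,
                                   build_cluster_genome, mutate_sequence)
from tests.conftest import random_dna, random_protein


def nw_score_bruteforce(a, b, match=1, mismatch=-1, gap=-2, ext=-1):
    """Optimal affine-gap global alignment score by three-state DP (Gotoh)."""
    inf = float("-inf")
    n, m = len(a), len(b)
    M = [[inf] * (m + 1) for _ in range(n + 1)]   # ends in match/mismatch
    X = [[inf] * (m + 1) for _ in range(n + 1)]   # ends in gap in b
    Y = [[inf] * (m + 1) for _ in range(n + 1)]   # ends in gap in a
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = gap + ext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap + ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap, X[i - 1][j] + ext, Y[i - 1][j] + gap)
            Y[i][j] = max(M[i][j - 1] + gap, Y[i][j - 1] + ext, X[i][j - 1] + gap)
    return max(M[n][m], X[n][m], Y[n][m])


class TestRegionIdentity:
    def test_identical(self):
        assert region_identity("ACGTACGT", "ACGTACGT")[0] == 100.0

    def test_hand_alignment(self):
        ident, cols = region_identity("ACGT", "ACGA")
        assert (ident, cols) == (75.0, 4)

    def test_symmetry(self, rng):
        for _ in range(50):
            a = random_dna(rng, int(rng.integers(5, 40)))
            b = random_dna(rng, int(rng.integers(5, 40)))
            assert region_identity(a, b)[0] == pytest.approx(region_identity(b, a)[0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            region_identity("", "ACGT")

    def test_optimal_score_matches_bruteforce_dp_on_6mers(self, rng):
        """Optimal global score agrees with an affine-gap DP oracle on
        random 6-mer pairs (sampled from the 4^6 x 4^6 space)."""
        from mucloc.alignment import pairwise_align
        for _ in range(200):
            a, b = random_dna(rng, 6), random_dna(rng, 6)
            res = pairwise_align(a, b, "global")
            assert res.score == pytest.approx(nw_score_bruteforce(a, b))


class TestLocateMarker:
    def test_verbatim_marker(self, rng):
        marker = random_dna(rng, 400)
        contig = Contig("c", random_dna(rng, 500) + marker + random_dna(rng, 500))
        anchor = locate_marker(contig, marker, "m")
        assert anchor.interval.start == 500
        assert anchor.identity == 100.0

    def test_mutated_marker(self, rng):
        marker = random_dna(rng, 400)
        mutated = mutate_sequence(marker, 0.05, seed=3)
        contig = Contig("c", random_dna(rng, 300) + mutated + random_dna(rng, 300))
        anchor = locate_marker(contig, marker, "m")
        assert abs(anchor.interval.start - 300) <= 2
        assert anchor.identity >= 90.0

    def test_absent_marker(self, rng):
        contig = Contig("c", random_dna(rng, 2000))
        with pytest.raises(ValueError, match="not found"):
            locate_marker(contig, "ACGT" * 25, "m")


class TestFindOrfs:
    def test_hand_scan(self):
        # one ATG-initiated ORF ending at its first in-frame stop
        seq = "ATG" + "AAA" * 9 + "TAG"
        assert find_orfs(seq, 30) == [(0, 33, 0, "+")]

    def test_no_atg(self):
        assert find_orfs("AAATTTCCCGGG" * 10, 30) == []

    def test_matches_six_frame_bruteforce(self, rng):
        def brute(seq, min_len):
            out = []
            n = len(seq)
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                for i in range(n - 2):
                    if s[i:i + 3] != "ATG":
                        continue
                    for j in range(i, n - 2, 3):
                        if s[j:j + 3] in ("TAA", "TAG", "TGA"):
                            if j + 3 - i >= min_len:
                                if strand == "+":
                                    out.append((i, j + 3, i % 3, "+"))
                                else:
                                    out.append((n - j - 3, n - i, i % 3, "-"))
                            break
            return sorted(out)

        for _ in range(50):
            seq = random_dna(rng, 300)
            assert find_orfs(seq, 30) == brute(seq, 30)

    def test_bad_min_len_rejected(self):
        with pytest.raises(ValueError):
            find_orfs("ATGTAA", 31)


class TestPtsScan:
    def test_hand_count(self):
        # window covering "TTSPPA" + 4 filler: 5 of 10 residues are P/T/S
        (seg,) = pts_scan("TTSPPA" + "GGGG", window=10, min_frac=0.5)
        assert (seg.start, seg.end) == (0, 10)
        assert seg.fraction == pytest.approx(0.5)

    def test_shorter_than_window_empty(self):
        assert pts_scan("TTSPPA", window=10, min_frac=0.5) == []

    def test_poly_g_empty(self):
        assert pts_scan("G" * 400) == []

    def test_planted_repeat_array_covered(self):
        array = MUC3_REPEAT_UNIT * 50
        protein = "W" * 120 + array + "W" * 120
        segs = pts_scan(protein)
        assert len(segs) == 1
        overlap = min(segs[0].end, 120 + len(array)) - max(segs[0].start, 120)
        assert overlap / len(array) >= 0.95

    def test_fraction_reported(self):
        segs = pts_scan("TTSPP" * 4 + "AAAAA" * 16, window=10, min_frac=0.5)
        assert segs and segs[0].fraction >= 0.5


class TestDetectSea:
    def test_verbatim_reference(self, rng):
        protein = random_protein(rng, 150) + SEA_REFERENCE_SYNTHETIC + \
            random_protein(rng, 50)
        hit = detect_sea(protein)
        assert hit is not None
        assert hit.identity == 100.0
        assert (hit.start, hit.end) == (150, 150 + len(SEA_REFERENCE_SYNTHETIC))

    def test_diverged_reference(self, rng):
        ref = SEA_REFERENCE_SYNTHETIC
        aas = "ACDEFGHIKLMNPQRSTVWY"
        mutated = "".join(
            c if rng.random() > 0.4 else aas[rng.integers(0, 20)] for c in ref)
        protein = random_protein(rng, 100) + mutated + random_protein(rng, 100)
        hit = detect_sea(protein)
        assert hit is not None
        assert abs(hit.identity - 60.0) <= 6.0

    def test_unrelated_protein_no_hit(self, rng):
        for _ in range(5):
            assert detect_sea(random_protein(rng, 500)) is None

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            detect_sea("ACDEF" * 40, sea_refs=[])


class TestCtermFeatures:
    def test_hydrophobic_window_found(self):
        protein = "D" * 40 + "L" * 19 + "D" * 40
        tm, _ = detect_cterm_features(protein)
        assert tm == (40, 59)

    @pytest.mark.parametrize("tail,expected", [("TSL", True), ("TSG", False),
                                               ("SAV", True), ("AAL", False)])
    def test_pdz_motif(self, tail, expected):
        assert detect_cterm_features("D" * 40 + tail)[1] is expected

    def test_pdz_matches_regex_oracle(self, rng):
        pat = re.compile(r"[ST].[LIVFM]$")
        for _ in range(1000):
            tail = random_protein(rng, 30)
            assert detect_cterm_features(tail)[1] == bool(pat.search(tail))

    def test_no_tm_in_hydrophilic_protein(self):
        assert all(KYTE_DOOLITTLE[c] < 0 for c in "DEKR")
        tm, _ = detect_cterm_features("DEKR" * 30)
        assert tm is None


def _anchors(contig, truth):
    m5 = truth.marker_intervals["marker5"]
    m3 = truth.marker_intervals["marker3"]
    return (locate_marker(contig, contig.seq[m5.start:m5.end], "m5"),
            locate_marker(contig, contig.seq[m3.start:m3.end], "m3"))


class TestCallMucinGenes:
    def test_recovers_planted_genes(self, cluster):
        spec, contig, truth = cluster
        cands = call_mucin_genes(contig, _anchors(contig, truth))
        assert len(cands) == len(truth.gene_models)
        for cand, model in zip(cands, truth.gene_models):
            assert abs(cand.start - model.genomic_start) <= 5
            assert abs(cand.end - model.genomic_end) <= 5
            pts = model.exons[model.exon_roles.index("PTS")]
            assert abs(cand.pts_exon.start - pts.start) <= 5
            assert abs(cand.pts_exon.end - pts.end) <= 5
            assert cand.pdz
            assert cand.tm_segment is not None

    def test_count_exact_at_two_percent_noise(self, cluster):
        spec, contig, truth = cluster
        noisy = add_noise(contig, truth, 0.02, seed=13)
        cands = call_mucin_genes(noisy, _anchors(noisy, truth))
        assert len(cands) == len(truth.gene_models)

    def test_near_identical_neighbours_merged(self):
        # paralog pair at 99% non-PTS identity -> criterion 4 merges them
        spec = ClusterSpec(n_genes=2, repeat_counts=[20, 30],
                           intergenic_lengths=[800], paralog_identity=0.99,
                           seed=21)
        contig, truth = build_cluster_genome(spec)
        cands = call_mucin_genes(contig, _anchors(contig, truth))
        assert len(cands) == 1
        assert cands[0].merged_ids  # the merge is recorded

    def test_marker_only_contig(self, rng):
        contig = Contig("c", random_dna(rng, 6000))
        m5 = contig.seq[:400]
        m3 = contig.seq[-400:]
        a5 = locate_marker(contig, m5, "m5")
        a3_candidates = locate_marker(contig, m3, "m3")
        assert call_mucin_genes(contig, (a5, a3_candidates)) == []

    def test_missing_anchor_rejected(self, cluster):
        _, contig, truth = cluster
        a5, _ = _anchors(contig, truth)
        with pytest.raises(ValueError):
            call_mucin_genes(contig, (a5, None))


class TestClusterMetrics:
    def test_planted_intergenic_recovered(self, cluster):
        spec, contig, truth = cluster
        metrics = cluster_metrics(truth.gene_models)
        assert metrics.intergenic_bp == spec.intergenic_lengths

    def test_planted_round_trip_values(self):
        from mucloc.io_core import GeneModel, Interval
        g1 = GeneModel("a", [Interval("c", 0, 10000)], "+")
        g2 = GeneModel("b", [Interval("c", 12469, 20000)], "+")
        m = cluster_metrics([g1, g2])
        assert m.intergenic_bp == [2469]
        g3 = GeneModel("x", [Interval("c", 1000, 154000)], "+")
        assert cluster_metrics([g3]).span_kbp == 153.0
        assert cluster_metrics([g3]).intergenic_bp == []

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_metrics([])


class TestConservationVsTime:
    def test_identical_sequences_flat(self, rng):
        seq = random_dna(rng, 500)
        pairs = [(f"p{t}", "N-term", seq, seq) for t in (5, 10, 20)]
        times = {f"p{t}": t for t in (5, 10, 20)}
        points, slopes = conservation_vs_time(pairs, times)
        assert all(p.identity == 100.0 for p in points)
        assert slopes["N-term"] == pytest.approx(0.0)

    def test_decay_gives_negative_slope(self, rng):
        seq = random_dna(rng, 2000)
        pairs, times = [], {}
        for t in (5, 15, 30):
            times[f"p{t}"] = t
            pairs.append((f"p{t}", "PTS", seq,
                          mutate_sequence(seq, 0.004 * t, seed=t)))
        _, slopes = conservation_vs_time(pairs, times)
        assert slopes["PTS"] < 0

    def test_single_pair_slope_none(self, rng):
        seq = random_dna(rng, 100)
        points, slopes = conservation_vs_time(
            [("p", "C-term", seq, seq)], {"p": 9.0})
        assert len(points) == 1
        assert slopes["C-term"] is None

    def test_missing_time_rejected(self, rng):
        seq = random_dna(rng, 50)
        with pytest.raises(ValueError):
            conservation_vs_time([("p", "PTS", seq, seq)], {})
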