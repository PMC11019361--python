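import itertools
from math import comb

import numpy as np
import pytest

from secgram.interpret import (
    MotifPattern, apply_motif_ablation, bin_enrichment_profile,
    equal_population_bins, motif_ablation, mutual_information_bits,
    purge_similar, saliency, select_confident,
)


class TestSelectConfident:
    @pytest.mark.parametrize(
        "label,p,tier",
        [
            ("EC", 0.97, "ECX"),
            ("IC", 0.03, "ICX"),
            ("IC", 0.97, "none"),  # false positive is never ECX
            ("EC", 0.03, "none"),  # false negative is never ICX
            ("EC", 0.95, "none"),  # strict inequality
            ("IC", 0.05, "none"),
        ],
    )
    def test_tiers(self, label, p, tier):
        out = select_confident([("x", label, p)])
        assert out[0].tier == tier

    def test_partition_exhaustive_disjoint(self):
        rng = np.random.default_rng(21)
        rows = [(f"r{i}", "EC" if rng.random() < 0.3 else "IC", rng.random())
                for i in range(200)]
        tiers = [a.tier for a in select_confident(rows)]
        assert all(t in ("ECX", "ICX", "none") for t in tiers)
        assert len(tiers) == 200

    def test_probability_out_of_range(self):
        with pytest.raises(ValueError):
            select_confident([("x", "EC", 1.5)])


class TestPurgeSimilar:
    def test_identical_twenty_mers_second_dropped(self):
        s = "ACGTACGTACGTACGTACGT"
        assert purge_similar([s, s]) == [s]  # self-score 20*5 = 100 >= 50

    def test_dissimilar_pair_kept(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "TTCCTTGGTTCCTTGGTTAA"
        # oracle: Biopython local alignment score checked below threshold
        from Bio import Align

        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score, al.mismatch_score = 5, -4
        al.open_gap_score, al.extend_gap_score = -10, -1
        assert al.score(a, b) < 50
        assert purge_similar([a, b]) == [a, b]

    def test_empty_input(self):
        assert purge_similar([]) == []

    def test_greedy_keeps_first(self):
        s = "ACGTACGTACGTACGTACGT"
        near = s[:-1] + "A"
        assert purge_similar([s, near]) == [s]


class TestMotifPattern:
    def test_rna_dna_normalization(self):
        m = MotifPattern("CCUGGC")
        assert m.contains("AACCTGGCAA")
        assert m.contains("AACCUGGCAA")

    def test_letter_classes(self):
        m = MotifPattern("[ACU]AG[GU][GU]")
        assert m.contains("TTCAGGTTT")   # C-A-G-G-T
        assert not m.contains("GGGGGGGG")

    def test_all_offsets_including_overlap(self):
        m = MotifPattern("AA")
        assert m.find_all("AAA") == [0, 1]

    def test_malformed_patterns(self):
        for bad in ("", "[]AC", "A[", "AXG"):
            with pytest.raises(ValueError):
                MotifPattern(bad)


class TestBins:
    def test_equal_population_sizes(self):
        rng = np.random.default_rng(22)
        vals = rng.random(100)
        bins = equal_population_bins(vals, 9)
        sizes = np.bincount(bins)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 100
        # bins ordered by value
        for b in range(8):
            assert vals[bins == b].max() <= vals[bins == b + 1].min() + 1e-12

    def test_too_many_bins(self):
        with pytest.raises(ValueError):
            equal_population_bins([1.0, 2.0], 3)


class TestEnrichmentProfile:
    def test_hypergeometric_example_exact(self):
        # 10 items, 5 with motif, 2 bins, top bin holds 4 of 5 motif items:
        # upper tail = (C(5,4)C(5,1) + C(5,5)C(5,0)) / C(10,5) = 26/252
        values = list(range(10))
        flags = [False, False, False, False, True,
                 True, True, True, True, False]
        prof = bin_enrichment_profile(values, flags, n_bins=2, n_shuffles=50, seed=0)
        assert list(prof.bin_motif_counts) == [1, 4]
        p_top = 10 ** (-prof.signed_log10_p[1])
        assert p_top == pytest.approx(26 / 252, rel=1e-9)

    def test_tails_match_enumeration_for_small_instances(self):
        # exhaustive oracle over all (N <= 12, K, bin size) configurations
        rng = np.random.default_rng(23)
        from scipy.stats import hypergeom  # noqa: F401  (implementation side)

        for _ in range(40):
            N = int(rng.integers(4, 13))
            K = int(rng.integers(1, N))
            n_bins = int(rng.integers(2, min(4, N) + 1))
            values = rng.random(N)
            flag_idx = rng.choice(N, size=K, replace=False)
            flags = np.zeros(N, dtype=bool)
            flags[flag_idx] = True
            prof = bin_enrichment_profile(values, flags, n_bins=n_bins,
                                          n_shuffles=10, seed=0)
            for b in range(n_bins):
                m = int(prof.bin_sizes[b])
                k = int(prof.bin_motif_counts[b])
                # enumeration oracle: P(X >= k) and P(X <= k) by direct sums
                denom = comb(N, m)
                p_over = sum(comb(K, x) * comb(N - K, m - x)
                             for x in range(k, min(K, m) + 1)) / denom
                p_under = sum(comb(K, x) * comb(N - K, m - x)
                              for x in range(0, k + 1)) / denom
                signed = prof.signed_log10_p[b]
                if signed >= 0:
                    assert 10 ** (-signed) == pytest.approx(p_over, rel=1e-9)
                else:
                    assert 10 ** signed == pytest.approx(p_under, rel=1e-9)

    def test_mi_one_bit_perfect_balanced(self):
        prof = bin_enrichment_profile(list(range(10)), [False] * 5 + [True] * 5,
                                      n_bins=2, n_shuffles=50, seed=0)
        assert prof.mi_bits == pytest.approx(1.0)

    def test_mi_invariant_under_bin_relabeling(self):
        rng = np.random.default_rng(24)
        flags = rng.random(60) < 0.4
        bins = rng.integers(0, 3, 60)
        mi1 = mutual_information_bits(flags.astype(int), bins, 3)
        relabel = np.array([2, 0, 1])[bins]
        mi2 = mutual_information_bits(flags.astype(int), relabel, 3)
        assert mi1 == pytest.approx(mi2)

    def test_mi_zero_when_joint_equals_product(self):
        # constructed independence: every bin has the same flag composition
        flags = np.array([1, 0, 1, 0, 1, 0])
        bins = np.array([0, 0, 1, 1, 2, 2])
        assert mutual_information_bits(flags, bins, 3) == pytest.approx(0.0, abs=1e-12)

    def test_null_zscore_within_three(self):
        rng = np.random.default_rng(25)
        values = rng.random(300)
        flags = rng.random(300) < 0.3  # independent of values
        prof = bin_enrichment_profile(values, flags, n_bins=9,
                                      n_shuffles=1000, seed=1)
        assert abs(prof.z_score) < 3

    def test_requires_motif_bearing_item(self):
        with pytest.raises(ValueError):
            bin_enrichment_profile([1.0, 2.0], [False, False], n_bins=2)


class TestAblation:
    def test_mask_vs_remove_length_bookkeeping(self, motif_oracle):
        seq = "AAA" + "CCTGGC" + "TTTTTTTTT"  # motif spans 3-8
        masked = apply_motif_ablation(seq, MotifPattern("CCTGGC"), "mask")
        removed = apply_motif_ablation(seq, MotifPattern("CCTGGC"), "remove")
        assert len(masked) == len(seq)
        assert masked[3:9] == "NNNNNN"
        assert len(removed) == len(seq) - 6

    def test_absent_motif_empty_report(self, motif_oracle):
        rep = motif_ablation(motif_oracle, ["AAAAAAAAAAAAAAAAAA"], "CCTGGC")
        assert rep.n == 0
        assert rep.n_excluded == 1

    def test_oracle_model_mask_drops_probability(self, motif_oracle):
        seqs = ["AAAA" + "CCTGGC" + "ACGTACGT"] * 3
        rep = motif_ablation(motif_oracle, seqs, "CCTGGC", mode="remove")
        assert rep.mean_prob_before == pytest.approx(0.95)
        assert rep.mean_prob_after == pytest.approx(0.05)

    def test_trained_fixture_mask_demotes_ecx(self, tiny_planted, tiny_gru):
        seqs, labels = tiny_planted
        bearing = [s for s, l in zip(seqs, labels) if l == 1]
        rep = motif_ablation(tiny_gru, bearing, "CCTGGC", mode="mask")
        assert rep.mean_prob_after < rep.mean_prob_before

    def test_remove_never_increases_mean_probability(self, tiny_planted, tiny_gru):
        seqs, labels = tiny_planted
        bearing = [s for s, l in zip(seqs, labels) if l == 1]
        rep = motif_ablation(tiny_gru, bearing, "CCTGGC", mode="remove")
        assert rep.mean_prob_after <= rep.mean_prob_before


class TestSaliency:
    def test_motif_positions_attributed_in_aggregate(self, tiny_planted, tiny_gru):
        seqs, labels = tiny_planted
        motif_attr, bg_attr = [], []
        for s, l in zip(seqs, labels):
            if l != 1:
                continue
            att = np.abs(saliency(tiny_gru, s))
            off = s.find("CCTGGC")
            motif_attr.append(att[off:off + 6].mean())
            bg_attr.append(np.concatenate([att[:off], att[off + 6:]]).mean())
        assert np.mean(motif_attr) > np.mean(bg_attr)

    def test_zero_head_gives_zero_attribution(self, tiny_planted, tiny_gru):
        import copy

        seqs, _ = tiny_planted
        clf = copy.deepcopy(tiny_gru)
        clf.params_["W_out"].data[:] = 0.0
        clf.params_["b_out"].data[:] = 0.0
        att = saliency(clf, seqs[0])
        np.testing.assert_allclose(att, 0.0, atol=1e-15)

    def test_length_matches_sequence(self, tiny_gru):
        for L in (18, 50):
            seq = ("ACGT" * 13)[:L]
            assert len(saliency(tiny_gru, seq)) == L

    def test_non_differentiable_family_rejected(self):
        from secgram.models import RandomForestSecretionClassifier

        with pytest.raises(TypeError, match="ablation"):
            saliency(RandomForestSecretionClassifier(), "ACGT")
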