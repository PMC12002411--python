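"""Hexamer counting, enrichment z, PSSM building, exact-p scanning."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from polytrans.motif import (KmerCounts, base_composition, build_pssm,
                             count_kmers, feature_map, kmer_enrichment_z,
                             scan_many, scan_sites, score_correlation,
                             score_word)


class TestCountKmers:
    def test_seven_g(self):
        kc = count_kmers(["GGGGGGG"])
        assert kc.counts["GGGGGG"] == 2
        assert kc.total_windows == 2

    def test_single_window(self):
        kc = count_kmers(["ACGTAC"])
        assert kc.total_windows == 1
        assert kc.counts["ACGTAC"] == 1

    def test_short_sequence_no_windows(self):
        kc = count_kmers(["ACGTA", "ACGTGCA"])
        assert kc.total_windows == 2  # only the 7-mer contributes

    def test_n_windows_skipped(self):
        kc = count_kmers(["ACGNACGTACG"])
        # windows 0..3 contain the N at position 3; windows 4 and 5 are clean
        assert kc.skipped_windows == 4
        assert kc.total_windows == 2

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(5)]
        kc = count_kmers(seqs)
        assert kc.frequencies.sum() == pytest.approx(1.0)
        assert kc.total_windows == sum(len(s) - 5 for s in seqs)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_kmers([])

    def test_lowercase_tolerated(self):
        assert count_kmers(["ggcggg"]).counts["GGCGGG"] == 1


class TestEnrichmentZ:
    def test_equal_proportions_z_zero(self):
        fg = count_kmers(["ACGTAC"] * 10)
        bg = count_kmers(["ACGTAC"] * 7)
        z = kmer_enrichment_z(fg, bg)
        assert z.loc[z["hexamer"] == "ACGTAC", "z"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_pooled_statistic(self):
        fg = KmerCounts(pd.Series({"GGCGGG": 50.0, "AAAAAA": 950.0}), 1000)
        bg = KmerCounts(pd.Series({"GGCGGG": 10.0, "AAAAAA": 990.0}), 1000)
        z = kmer_enrichment_z(fg, bg).set_index("hexamer")["z"]
        p_fg, p_bg = 0.05, 0.01
        pooled = 60 / 2000
        expected = (p_fg - p_bg) / np.sqrt(pooled * (1 - pooled) * (2 / 1000))
        assert z["GGCGGG"] == pytest.approx(expected, rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        seqs_a = ["".join(rng.choice(list("ACGT"), size=80))
                  for _ in range(20)]
        seqs_b = ["".join(rng.choice(list("ACGT"), size=80))
                  for _ in range(20)]
        fg, bg = count_kmers(seqs_a), count_kmers(seqs_b)
        z_ab = kmer_enrichment_z(fg, bg).set_index("hexamer")["z"]
        z_ba = kmer_enrichment_z(bg, fg).set_index("hexamer")["z"]
        np.testing.assert_allclose(z_ab, -z_ba.loc[z_ab.index], atol=1e-12)

    def test_planted_motif_top_ranked(self):
        from polytrans.io import split_regions
        from polytrans.simulate import SimConfig, simulate_transcripts

        cfg = SimConfig(seed=13, motif="GGCGGG", motif_rate=2.0)
        seqs, _ = simulate_transcripts(cfg, 200, 200)
        utrs = split_regions(seqs)["5UTR"]
        fg = count_kmers([s for t, s in utrs.items() if t.startswith("fg")])
        bg = count_kmers([s for t, s in utrs.items() if t.startswith("bg")])
        table = kmer_enrichment_z(fg, bg)
        assert table.iloc[0]["hexamer"] == "GGCGGG"
        assert table.iloc[0]["z"] > 3


class TestBuildPssm:
    def test_single_hexamer_counts(self):
        model = build_pssm(["GGCGGG"])
        expected = np.zeros((6, 4))
        for i, b in enumerate("GGCGGG"):
            expected[i, "ACGT".index(b)] = 1
        np.testing.assert_array_equal(model.counts, expected)

    def test_symmetric_stack_uniform(self):
        model = build_pssm(["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT"],
                           pseudocount=0)
        np.testing.assert_allclose(model.frequencies, 0.25)

    def test_uniform_weights_zero(self):
        model = build_pssm(["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT"],
                           pseudocount=0)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-12)

    def test_mixed_length_rejected(self):
        with pytest.raises(ValueError, match="length 6"):
            build_pssm(["GGCGGG", "GGCGG"])

    def test_frequencies_sum_to_one(self):
        model = build_pssm(["GGCGGG", "GGGGGG"], pseudocount=1)
        np.testing.assert_allclose(model.frequencies.sum(axis=1), 1.0)


class TestScanSites:
    def test_uniform_model_no_significant(self):
        model = build_pssm(["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT"],
                           pseudocount=0)
        sites = scan_sites("ACGTACGTACGT", model)
        assert (sites["score"] == 0).all()
        np.testing.assert_allclose(sites["p"], 1.0)
        assert not sites["significant"].any()

    def test_single_hexamer_max_score_p(self):
        model = build_pssm(["GGCGGG"], pseudocount=0.01)
        sites = scan_sites("AAGGCGGGAA", model)
        best = sites.loc[sites["score"].idxmax()]
        assert best["start"] == 2
        assert best["p"] == pytest.approx(1 / 4096, rel=1e-9)

    def test_p_threshold_boundary(self):
        # a window with p >= 0.05 is present but not flagged
        model = build_pssm(["GGCGGG"], pseudocount=0.5)
        sites = scan_sites("ACGTACGTAC", model)
        weak = sites[sites["p"] >= 0.05]
        assert len(weak) > 0
        assert not weak["significant"].any()

    def test_exact_p_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        hexamers = ["".join(rng.choice(list("ACGT"), size=6))
                    for _ in range(3)]
        bgp = rng.dirichlet(np.ones(4))
        model = build_pssm(hexamers, pseudocount=0.7, background=bgp)
        word_scores = {}
        for word in map("".join, product("ACGT", repeat=6)):
            word_scores[word] = score_word(word, model)
        probs = {w: np.prod([bgp["ACGT".index(b)] for b in w])
                 for w in word_scores}
        seq = "".join(rng.choice(list("ACGT"), size=60))
        sites = scan_sites(seq, model)
        for _, row in sites.iterrows():
            s = row["score"]
            expected = sum(p for w, p in probs.items()
                           if word_scores[w] >= s - 1e-9)
            assert row["p"] == pytest.approx(expected, rel=1e-9)

    def test_n_windows_skipped(self):
        model = build_pssm(["GGCGGG"])
        sites = scan_sites("GGNGGGGGGGGG", model)
        assert (sites["start"] >= 3).all()  # windows crossing the N skipped

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            scan_sites("ACGTA", build_pssm(["GGCGGG"]))


class TestFeatureMap:
    def test_ordering_and_empty_entries(self):
        sites = {
            "tx1": pd.DataFrame({"start": [10, 3], "score": [1.0, 2.0],
                                 "p": [0.01, 0.02],
                                 "significant": [True, True]}),
            "tx2": pd.DataFrame({"start": [5], "score": [0.1], "p": [0.9],
                                 "significant": [False]}),
        }
        fmap = feature_map(sites)
        assert fmap["tx1"] == [3, 10]
        assert fmap["tx2"] == []

    def test_counts_match_recount(self):
        rng = np.random.default_rng(3)
        model = build_pssm(["GGCGGG", "GGGCGG"], pseudocount=0.5)
        seqs = {f"tx{i}": "".join(rng.choice(list("ACGT"), size=150,
                                             p=[0.2, 0.2, 0.4, 0.2]))
                for i in range(10)}
        scans = scan_many(seqs, model)
        fmap = feature_map(scans)
        for tx, df in scans.items():
            assert len(fmap[tx]) == int((df["p"] < 0.05).sum())


class TestScoreCorrelation:
    @staticmethod
    def _table(hexamers, z):
        return pd.DataFrame({"hexamer": hexamers, "z": z,
                             "enriched": np.asarray(z) > 3})

    def test_identical_r_one(self):
        t = self._table(["AAAAAA", "CCCCCC", "GGGGGG"], [1.0, 2.0, 3.5])
        assert score_correlation(t, t) == pytest.approx(1.0)

    def test_negated_r_minus_one(self):
        t = self._table(["AAAAAA", "CCCCCC", "GGGGGG"], [1.0, 2.0, 3.5])
        t2 = self._table(["AAAAAA", "CCCCCC", "GGGGGG"], [-1.0, -2.0, -3.5])
        assert score_correlation(t, t2) == pytest.approx(-1.0)

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(4)
        hexamers = ["".join(w) for w in product("ACGT", repeat=3)]
        za = rng.normal(size=len(hexamers))
        zb = 0.5 * za + rng.normal(size=len(hexamers))
        r = score_correlation(self._table(hexamers, za),
                              self._table(hexamers, zb))
        expected = np.corrcoef(za, zb)[0, 1]
        assert r == pytest.approx(expected, rel=1e-9)

    def test_too_few_shared_rejected(self):
        t1 = self._table(["AAAAAA", "CCCCCC"], [1.0, 2.0])
        t2 = self._table(["AAAAAA", "GGGGGG"], [1.0, 2.0])
        with pytest.raises(ValueError, match="shared"):
            score_correlation(t1, t2)


def test_null_false_enrichment_matches_binomial_expectation():
    # at large window totals, z ~ N(0,1) per hexamer: the count of z > 3
    # should track 4096 * P(Z > 3) within Monte-Carlo error
    from scipy import stats

    from polytrans.io import split_regions
    from polytrans.simulate import SimConfig, simulate_transcripts

    counts = []
    for seed in range(5):
        cfg = SimConfig(seed=2000 + seed, motif_rate=0.0,
                        utr_len_range=(80, 300))
        seqs, _ = simulate_transcripts(cfg, 200, 200)
        utrs = split_regions(seqs)["5UTR"]
        fg = count_kmers([s for t, s in utrs.items() if t.startswith("fg")])
        bg = count_kmers([s for t, s in utrs.items() if t.startswith("bg")])
        counts.append(int((kmer_enrichment_z(fg, bg)["z"] > 3).sum()))
    expectation = 4096 * stats.norm.sf(3)
    assert np.mean(counts) <= expectation + 3 * np.sqrt(expectation / 5)


def test_base_composition():
    comp = base_composition(["AACC", "GGTT"])
    np.testing.assert_allclose(comp, 0.25)
    comp2 = base_composition({"x": "GGGG"})
    np.testing.assert_allclose(comp2, [0, 0, 1, 0])
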