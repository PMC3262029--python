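"""Background models and exact enrichment statistics."""

import numpy as np
import pytest

from _oracles import (
    bh_stepup,
    fisher_two_sided_exact,
    hypergeom_upper_tail,
    poisson_upper_tail,
)
from ltsmscan import (
    CANONICAL_LTSM,
    BackgroundModel,
    ScanConfig,
    TandemMotif,
    bh_adjust,
    bin_enrichment,
    build_histogram,
    estimate_background,
    expected_hits,
    fisher_exact_2x2,
    motif_probability,
    set_overlap_test,
)


class TestEstimateBackground:
    def test_pseudocount_arithmetic(self):
        bg = estimate_background(["ACGT"], order=0)
        assert np.allclose(bg.base_freqs, [2 / 8] * 4)

    def test_skewed_composition(self):
        bg = estimate_background(["AAAA", "TTTT"], order=0)
        assert np.allclose(bg.base_freqs, [5 / 12, 1 / 12, 1 / 12, 5 / 12])

    def test_masked_bases_excluded(self):
        soft = estimate_background(["AAAAcccc"], order=0, mask_policy="skip_masked")
        assert np.allclose(soft.base_freqs, [5 / 8, 1 / 8, 1 / 8, 1 / 8])
        hard = estimate_background(["AAAANNNN"], order=0)
        assert np.allclose(hard.base_freqs, [5 / 8, 1 / 8, 1 / 8, 1 / 8])

    def test_simulation_consistency(self, rng):
        truth = np.array([0.1, 0.2, 0.3, 0.4])
        seq = "".join(rng.choice(list("ACGT"), size=10_000, p=truth))
        est = np.array(estimate_background([seq], order=0).base_freqs)
        se = np.sqrt(truth * (1 - truth) / 10_000)
        assert (np.abs(est - truth) < 3 * se + 5e-4).all()

    def test_order1_rows_stochastic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        bg = estimate_background([seq], order=1)
        t = np.asarray(bg.transition)
        assert np.allclose(t.sum(axis=1), 1.0)
        assert np.allclose(sum(bg.base_freqs), 1.0)


class TestMotifProbability:
    def test_uniform_closed_form(self):
        p = motif_probability(CANONICAL_LTSM, (7,), BackgroundModel.uniform())
        assert p == pytest.approx(0.25**6, abs=0)

    def test_gc_skewed_closed_form(self):
        bg = BackgroundModel.from_gc(0.6)
        p = motif_probability(CANONICAL_LTSM, (7,), bg)
        assert p == pytest.approx((0.2 * 0.2 * 0.3) ** 2, rel=1e-12)

    def test_order1_uniform_chain_equals_iid(self):
        bg1 = BackgroundModel(1, (0.25,) * 4, tuple((0.25,) * 4 for _ in range(4)))
        p = motif_probability(CANONICAL_LTSM, (7,), bg1)
        assert p == pytest.approx(0.25**6, rel=1e-12)

    def test_monte_carlo_oracle(self, rng):
        bg = BackgroundModel(0, (0.1, 0.2, 0.3, 0.4))
        p = motif_probability(CANONICAL_LTSM, (7,), bg)
        n = 1_000_000
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=(n, 13),
                           p=bg.base_freqs)
        ok = np.ones(n, dtype=bool)
        for off, ch in CANONICAL_LTSM.flank_positions((7,)):
            ok &= bases[:, off] == ord(ch)
        emp = ok.mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(emp - p) < 3 * se


class TestExpectedHits:
    def test_forward_only(self):
        e = expected_hits(1000, CANONICAL_LTSM, ScanConfig(strands="forward"),
                          BackgroundModel.uniform())
        assert e == pytest.approx(988 * 0.25**6, abs=0)

    def test_both_strands_doubles_under_uniform(self):
        e = expected_hits(1000, CANONICAL_LTSM, ScanConfig(strands="both"),
                          BackgroundModel.uniform())
        assert e == pytest.approx(0.482421875, abs=0)

    def test_spacer_range_sums_over_lengths(self):
        motif = TandemMotif("m", ("ATC", "ATC"), ((6, 8),))
        e = expected_hits(1000, motif, ScanConfig(strands="forward"),
                          BackgroundModel.uniform())
        assert e == pytest.approx((989 + 988 + 987) * 0.25**6, abs=0)

    def test_additive_over_disjoint_windows(self):
        cfg = ScanConfig(strands="forward")
        bg = BackgroundModel.from_gc(0.42)
        # windows of L1 and L2 overlapping by motif length - 1 share no starts
        e_500 = expected_hits(500, CANONICAL_LTSM, cfg, bg)
        e_1000 = expected_hits(1000, CANONICAL_LTSM, cfg, bg)
        e_512 = expected_hits(512, CANONICAL_LTSM, cfg, bg)
        assert e_500 + e_512 == pytest.approx(e_1000, rel=1e-12)

    def test_strand_asymmetry_respected(self):
        # C/G-asymmetric background: ATC and its complement content GAT differ
        bg = BackgroundModel(0, (0.4, 0.3, 0.1, 0.2))
        fwd = expected_hits(100, CANONICAL_LTSM, ScanConfig(strands="forward"), bg)
        rev = expected_hits(100, CANONICAL_LTSM, ScanConfig(strands="reverse"), bg)
        assert fwd != pytest.approx(rev)


class TestBinEnrichment:
    def make_hist(self, rels, n_seq=100):
        from ltsmscan import MotifHit

        hits = [MotifHit("t", 0, 13, "+", (7,), 0, "", rel_start=r) for r in rels]
        return build_histogram(hits, window=(-100, 100), n_sequences=n_seq)

    def test_poisson_tail_against_partial_sum(self):
        # five observed on an expectation of 0.5
        hist = self.make_hist([5, 7, 9, 11, 13], n_seq=103)
        df = bin_enrichment(hist, BackgroundModel.uniform(), CANONICAL_LTSM,
                            ScanConfig(strands="forward"))
        row = df[df.bin_low == 1].iloc[0]
        assert row.observed_fwd == 5
        assert row.expected == pytest.approx(103 * 20 * 0.25**6, rel=1e-12)
        assert row.p == pytest.approx(poisson_upper_tail(5, row.expected), rel=1e-9)
        assert poisson_upper_tail(5, 0.5) == pytest.approx(1.72e-4, rel=0.01)

    def test_zero_observed_gives_p_one(self):
        hist = self.make_hist([])
        df = bin_enrichment(hist, BackgroundModel.uniform(), CANONICAL_LTSM)
        assert (df.p == 1.0).all()

    def test_downstream_edge_expectation_shrinks(self):
        hist = self.make_hist([])
        df = bin_enrichment(hist, BackgroundModel.uniform(), CANONICAL_LTSM,
                            ScanConfig(strands="forward"))
        # last bin [81,100]: only starts up to +88 fit a 13-mer
        last, mid = df.iloc[-1], df.iloc[-2]
        assert last.expected == pytest.approx(mid.expected * 8 / 20, rel=1e-12)

    def test_null_calibration(self, rng):
        from ltsmscan import ScanConfig, SyntheticSpec, generate_promoters, scan_promoters

        spec = SyntheticSpec(n_promoters=4000, plant_fraction=0.0, seed=11)
        regions, _ = generate_promoters(spec)
        cfg = ScanConfig(strands="forward")
        hits = scan_promoters(regions, CANONICAL_LTSM, cfg)
        hist = build_histogram(hits, window=(-500, 500), n_sequences=4000)
        df = bin_enrichment(hist, BackgroundModel.uniform(), CANONICAL_LTSM, cfg)
        frac = (df.p < 0.05).mean()
        # binomial 99% bound around 0.05 with 50 bins
        assert frac <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / len(df))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [([[1, 0], [0, 1]], 1.0), ([[2, 0], [0, 2]], 1 / 3)],
    )
    def test_small_exact_values(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-12)

    def test_subunit_table_against_enumeration(self):
        p = fisher_exact_2x2([[26, 21], [9, 25]])
        oracle = float(fisher_two_sided_exact(26, 21, 9, 25))
        assert p == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_scipy(self, rng):
        from scipy.stats import fisher_exact as scipy_fisher

        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
            if 0 in (a + b, c + d, a + c, b + d):
                continue
            ours = fisher_exact_2x2([[a, b], [c, d]])
            theirs = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-7, abs=1e-12)

    def test_row_column_swap_invariance(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 25, size=4))
            p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_exact_2x2([[d, c], [b, a]]), rel=1e-12)
            assert 0 < p <= 1

    def test_zero_margin_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestBHAdjust:
    def test_closed_form(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_identity(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_matches_literal_stepup(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_stepup(list(p)), atol=1e-12)

    def test_largest_p_unchanged_and_monotone(self, rng):
        p = np.sort(rng.random(30))
        q = bh_adjust(p)
        assert q[-1] == pytest.approx(p[-1], abs=1e-15)
        assert (np.diff(q) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSetOverlap:
    def test_intersection_count(self):
        overlap, _ = set_overlap_test({"g1", "g2"}, {"g2", "g3"}, 10)
        assert overlap == 1

    def test_disjoint_sets(self):
        overlap, p = set_overlap_test({"a", "b"}, {"c", "d"}, 10)
        assert overlap == 0 and p == 1.0

    def test_against_enumeration(self, rng):
        for _ in range(20):
            universe = list(range(30))
            a = set(rng.choice(universe, size=8, replace=False).tolist())
            b = set(rng.choice(universe, size=10, replace=False).tolist())
            overlap, p = set_overlap_test(a, b, 30)
            oracle = float(hypergeom_upper_tail(overlap, 30, len(a), len(b)))
            assert p == pytest.approx(oracle, abs=1e-12)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError):
            set_overlap_test({1, 2, 3}, {4, 5}, 4)
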