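import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from chicpeaks.genome import CaptureRegion, GenomicInterval, RiskSNP, define_loci, mark_captured
from chicpeaks.peaks import (
    CAPTURE_TO_CIS,
    WITHIN_CAPTURE,
    adjust_fdr,
    assign_distance_bins,
    call_peaks,
    enumerate_candidate_pairs,
    fit_background_model,
    pair_pvalue,
    score_candidates,
)

from conftest import uniform_fragment_map


@pytest.fixture
def small_design():
    """chr1 tiled by 4 kb fragments over 2 Mb; two capture regions."""
    fm = uniform_fragment_map({"chr1": 2_000_000}, 4_000)
    regions = [
        CaptureRegion("r1", GenomicInterval("chr1", 100_000, 116_000), ("rs1",)),
        CaptureRegion("r2", GenomicInterval("chr1", 900_000, 916_000), ("rs2",)),
    ]
    snps = [RiskSNP("rs1", "chr1", 108_000), RiskSNP("rs2", "chr1", 908_000)]
    fm = mark_captured(fm, regions)
    loci = define_loci(regions, snps)
    return fm, loci


def _trans_counts(frag_ids, value=100):
    rows = []
    for rep in ("rep1", "rep2"):
        rows.append(pd.DataFrame({"frag_id": frag_ids, "replicate_id": rep, "n_trans": value}))
    return pd.concat(rows, ignore_index=True)


class TestEnumeration:
    def test_all_in_range_partners_enumerated_with_zeros(self, small_design):
        fm, loci = small_design
        cap = fm.captured_frag_ids()
        bait = cap[:1]
        tc = _trans_counts(cap)
        wide = pd.DataFrame(
            {"frag_lo": [bait[0]], "frag_hi": [bait[0] + 20], "pair_class": CAPTURE_TO_CIS,
             "distance": [80_000.0], "combined_count": [9]}
        )
        cand = enumerate_candidate_pairs(fm, loci, bait, wide, tc, 10_000, 200_000)
        # fragments of 4 kb: partners at midpoint distance in [10 kb, 200 kb]
        # on both sides, minus the other captured fragments dropped as excluded
        assert (cand["y"] == 0).sum() == len(cand) - 1
        assert cand.loc[cand["frag_hi"] == bait[0] + 20, "y"].iloc[0] == 9
        assert (cand["distance"] >= 10_000).all() and (cand["distance"] <= 200_000).all()

    def test_close_partner_not_candidate(self, small_design):
        fm, loci = small_design
        cap = fm.captured_frag_ids()
        tc = _trans_counts(cap)
        cand = enumerate_candidate_pairs(fm, loci, cap, pd.DataFrame(), tc, 10_000, 5_000_000)
        # adjacent fragments are 4 kb apart -> below the 10 kb floor
        assert cand["distance"].min() >= 10_000

    def test_far_bait_pair_is_within_capture(self, small_design):
        fm, loci = small_design
        cap = fm.captured_frag_ids()
        tc = _trans_counts(cap)
        cand = enumerate_candidate_pairs(fm, loci, cap, pd.DataFrame(), tc, 10_000, 5_000_000)
        # the two capture regions are 800 kb apart: their fragments pair as within_capture
        wc = cand[cand["pair_class"] == WITHIN_CAPTURE]
        assert len(wc) > 0
        assert wc["distance"].max() > 700_000

    def test_excluded_captured_partner_dropped(self, small_design):
        fm, loci = small_design
        cap = fm.captured_frag_ids()
        kept = cap[:4]  # region 2 baits all excluded
        tc = _trans_counts(cap)
        cand = enumerate_candidate_pairs(fm, loci, kept, pd.DataFrame(), tc, 10_000, 5_000_000)
        excluded = set(cap) - set(kept)
        assert not cand["frag_lo"].isin(excluded).any()
        assert not cand["frag_hi"].isin(excluded).any()


class TestDistanceBins:
    def _cand(self, distances):
        return pd.DataFrame(
            {"distance": distances, "pair_class": CAPTURE_TO_CIS, "y": 0}
        )

    def test_equal_count_bins(self):
        cand = self._cand(np.arange(300) * 1000.0 + 10_000)
        out = assign_distance_bins(cand, n_bins=100, min_bin_pairs=3)
        sizes = out.groupby("bin_id").size()
        assert len(sizes) == 100 and (sizes == 3).all()

    def test_identical_distances_single_bin(self):
        cand = self._cand(np.full(500, 50_000.0))
        out = assign_distance_bins(cand, n_bins=100, min_bin_pairs=3)
        assert out["bin_id"].nunique() == 1

    def test_few_candidates_collapse_to_one_bin(self):
        cand = self._cand(np.arange(150) * 1000.0 + 10_000)
        out = assign_distance_bins(cand, n_bins=100, min_bin_pairs=200)
        assert out["bin_id"].nunique() == 1

    def test_bins_are_distance_contiguous(self):
        rng = np.random.default_rng(5)
        cand = self._cand(rng.uniform(10_000, 2e6, 2300))
        out = assign_distance_bins(cand, n_bins=10, min_bin_pairs=200)
        by_bin = out.groupby("bin_id")["distance"].agg(["min", "max"]).sort_values("min")
        assert (by_bin["max"].to_numpy()[:-1] <= by_bin["min"].to_numpy()[1:]).all()


class TestBackgroundModel:
    def test_constant_covariates_poisson_intercept(self):
        rng = np.random.default_rng(31)
        n = 4000
        df = pd.DataFrame(
            {
                "y": rng.poisson(5, n),
                "ln_d": 10.0,
                "ln_nt_bait_rep1": 4.0,
                "ln_nt_bait_rep2": 4.0,
                "bin_id": 0,
            }
        )
        fit = fit_background_model(df, CAPTURE_TO_CIS, ["rep1", "rep2"])
        mu = np.exp(fit.coefficients["const"])
        assert abs(np.log(mu) - np.log(5)) < 0.05
        assert 1 + mu / fit.size < 1.1  # near-Poisson variance/mean ratio

    def test_recovers_simulated_coefficients(self):
        rng = np.random.default_rng(32)
        n = 5000
        ln_nt1 = rng.normal(5.5, 0.5, n)
        ln_nt2 = rng.normal(5.5, 0.5, n)
        ln_d = rng.uniform(10, 12, n)
        beta = {"const": -1.0, "ln_nt_bait_rep1": 1.0, "ln_nt_bait_rep2": 0.8, "ln_d": -0.5}
        eta = (
            beta["const"] + beta["ln_nt_bait_rep1"] * ln_nt1
            + beta["ln_nt_bait_rep2"] * ln_nt2 + beta["ln_d"] * ln_d
        )
        mu = np.exp(eta)
        size = 6.0
        y = rng.negative_binomial(size, size / (size + mu))
        df = pd.DataFrame(
            {"y": y, "ln_nt_bait_rep1": ln_nt1, "ln_nt_bait_rep2": ln_nt2, "ln_d": ln_d, "bin_id": 0}
        )
        fit = fit_background_model(df, CAPTURE_TO_CIS, ["rep1", "rep2"])
        for name, true in beta.items():
            assert abs(fit.coefficients[name] - true) < 0.3, name
        assert abs(fit.size - size) / size < 0.3

    def test_all_zero_bin_degenerate(self):
        df = pd.DataFrame(
            {"y": 0, "ln_nt_bait_rep1": np.random.default_rng(0).normal(5, 1, 300),
             "ln_nt_bait_rep2": 5.0, "ln_d": 11.0, "bin_id": 0}
        )
        fit = fit_background_model(df, CAPTURE_TO_CIS, ["rep1", "rep2"])
        mu = np.exp(fit.coefficients["const"])
        assert mu < 1e-6
        assert pair_pvalue(0, mu, fit.size) == 1.0


class TestPairPvalue:
    def test_zero_count_full_tail(self):
        assert pair_pvalue(0, 5.0, 2.0) == 1.0

    def test_poisson_limit_closed_form(self):
        # P(Y >= 3) for Poisson(2) = 1 - 5 e^-2
        p = pair_pvalue(3, 2.0, 1e9)
        assert abs(p - (1 - 5 * np.exp(-2))) < 1e-5

    def test_geometric_closed_form(self):
        # size=1, mu=1: P(Y >= 2) = (1/2)^2
        assert abs(pair_pvalue(2, 1.0, 1.0) - 0.25) < 1e-12

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(40)
        for mu, size in [(0.5, 0.7), (3, 2), (20, 6), (100, 50)]:
            for y in rng.integers(1, 200, 5):
                brute = 1 - sum(stats.nbinom.pmf(k, size, size / (size + mu)) for k in range(y))
                assert abs(pair_pvalue(int(y), mu, size) - brute) < 1e-10


class TestFDR:
    def test_hand_computed_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjust_fdr(p), [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert adjust_fdr(np.array([0.3]))[0] == 0.3

    def test_capped_at_one(self):
        assert np.allclose(adjust_fdr(np.array([1.0, 1.0])), [1.0, 1.0])

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            ours = adjust_fdr(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)

    def test_grouped_adjustment_independent_between_groups(self):
        p = np.array([0.01, 0.5, 0.01, 0.5])
        g = np.array(["a", "a", "b", "b"])
        out = adjust_fdr(p, g)
        assert np.allclose(out, [0.02, 0.5, 0.02, 0.5])


class TestCallPeaks:
    def _scored(self, p_adj_target, distance):
        return pd.DataFrame(
            {
                "frag_lo": [1], "frag_hi": [2], "locus_id": ["L"], "pair_class": [CAPTURE_TO_CIS],
                "y": [50], "distance": [distance], "p": [p_adj_target], "mu_hat": [5.0],
            }
        )

    @pytest.mark.parametrize(
        "p,distance,expected",
        [(0.009, 100_000, True), (0.009, 8_000, False), (0.011, 100_000, False)],
    )
    def test_threshold_and_window(self, p, distance, expected):
        out = call_peaks(self._scored(p, distance), alpha=0.01)
        assert bool(out["significant"].iloc[0]) is expected

    def test_row_order_invariance(self, small_design):
        fm, loci = small_design
        cap = fm.captured_frag_ids()
        rng = np.random.default_rng(50)
        tc = _trans_counts(cap, value=120)
        cand = enumerate_candidate_pairs(fm, loci, cap, pd.DataFrame(), tc, 10_000, 5_000_000)
        cand["y"] = rng.poisson(3, len(cand))
        cand = assign_distance_bins(cand, n_bins=5, min_bin_pairs=50)
        scored1, _ = score_candidates(cand, ["rep1", "rep2"])
        shuffled = cand.sample(frac=1, random_state=1).reset_index(drop=True)
        scored2, _ = score_candidates(shuffled, ["rep1", "rep2"])
        a = scored1.sort_values(["frag_lo", "frag_hi"]).reset_index(drop=True)
        b = scored2.sort_values(["frag_lo", "frag_hi"]).reset_index(drop=True)
        assert np.allclose(a["p"], b["p"], rtol=1e-9)
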