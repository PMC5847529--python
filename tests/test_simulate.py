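import numpy as np
import pandas as pd
import pytest

from chicpeaks.interactability import select_truncation_point
from chicpeaks.simulate import (
    SimConfig,
    preset_config,
    simulate_cell_line,
    simulate_ditags,
    simulate_fragment_map,
    simulate_interactability,
    truth_evaluation,
)
from dataclasses import replace


SMALL = SimConfig(n_chroms=4, chrom_length=1_000_000, n_capture_regions=8)


class TestFragmentMapSim:
    def test_expected_fragment_count(self):
        cfg = SimConfig(n_chroms=1, chrom_length=10_000_000, n_capture_regions=2)
        counts = [
            len(simulate_fragment_map(cfg, seed)[0]) for seed in range(3)
        ]
        for n in counts:
            assert abs(n - 2500) / 2500 < 0.10

    def test_no_capture_regions(self):
        cfg = replace(SMALL, n_capture_regions=0)
        fm, regions, snps, loci = simulate_fragment_map(cfg, 0)
        assert len(fm.captured_frag_ids()) == 0 and regions == [] == snps

    def test_determinism(self):
        a = simulate_fragment_map(SMALL, 5)
        b = simulate_fragment_map(SMALL, 5)
        pd.testing.assert_frame_equal(a[0].df, b[0].df)
        assert [r.interval for r in a[1]] == [r.interval for r in b[1]]

    def test_overlap_impossible_raises(self):
        cfg = replace(SMALL, region_width=600_000)
        with pytest.raises(ValueError):
            simulate_fragment_map(cfg, 0)

    def test_one_snp_per_region_at_midpoint(self):
        fm, regions, snps, _ = simulate_fragment_map(SMALL, 3)
        assert len(snps) == len(regions)
        for r, s in zip(regions, snps):
            assert r.interval.start <= s.pos - 1 < r.interval.end


class TestInteractabilitySim:
    def test_zero_noise_unimodal(self):
        cfg = replace(SimConfig(), noise_fraction=0.0)
        fm, *_ = simulate_fragment_map(cfg, 1)
        _, labels, trans = simulate_interactability(fm, cfg, 1)
        assert (labels == "signal").all()
        x = trans[trans["replicate_id"] == "rep1"]["n_trans"].to_numpy()
        with pytest.warns(UserWarning):
            assert select_truncation_point(x) == 0

    def test_noise_fraction_recovered(self):
        cfg = SimConfig(n_capture_regions=40, n_chroms=10, chrom_length=2_000_000)
        fm, *_ = simulate_fragment_map(cfg, 2)
        fracs = []
        for seed in range(5):
            _, labels, _ = simulate_interactability(fm, cfg, seed)
            fracs.append((labels == "noise").mean())
        assert abs(np.mean(fracs) - 0.2) < 0.05

    def test_replicate_scales_shift_means(self):
        cfg = replace(SimConfig(), replicate_scales=(1.0, 2.0))
        fm, *_ = simulate_fragment_map(cfg, 1)
        _, labels, trans = simulate_interactability(fm, cfg, 1)
        sig = trans[trans["frag_id"].isin(labels[labels == "signal"].index)]
        means = sig.groupby("replicate_id")["n_trans"].mean()
        assert abs(means["rep2"] / means["rep1"] - 2.0) < 0.15

    def test_bimodal_histogram_has_valley(self):
        cfg = SimConfig()
        fm, *_ = simulate_fragment_map(cfg, 4)
        _, _, trans = simulate_interactability(fm, cfg, 4)
        x = trans[trans["replicate_id"] == "rep1"]["n_trans"].to_numpy()
        t = select_truncation_point(x)
        assert t > 0  # valley exists between noise and signal components


class TestDitagSim:
    def test_determinism(self):
        cfg = preset_config("default")
        fm, *_ = simulate_fragment_map(cfg, 1)
        a = simulate_cell_line(cfg, fm, 9)
        b = simulate_cell_line(cfg, fm, 9)
        pd.testing.assert_frame_equal(a["pair_counts"], b["pair_counts"])
        pd.testing.assert_frame_equal(a["truth"].planted, b["truth"].planted)

    def test_distance_decay_halves_mean(self):
        # alpha = 1: expected counts at distance D vs 2D differ two-fold;
        # check the empirical decay of unplanted counts across distance bins
        cfg = preset_config("null")
        fm, *_ = simulate_fragment_map(cfg, 1)
        sim = simulate_cell_line(cfg, fm, 3)
        pc = sim["pair_counts"]
        near = pc[(pc["distance"] >= 20_000) & (pc["distance"] < 25_000)]["count"]
        far = pc[(pc["distance"] >= 40_000) & (pc["distance"] < 50_000)]["count"]
        # zero rows are omitted from the table; compare per-pair sums over a
        # distance window via totals normalised by pair counts in the window
        cand_near = ((pc["distance"] >= 20_000) & (pc["distance"] < 25_000)).sum()
        cand_far = ((pc["distance"] >= 40_000) & (pc["distance"] < 50_000)).sum()
        assert near.mean() > far.mean()

    def test_planted_enrichment_scales_mean(self):
        cfg = replace(preset_config("power"), planted_enrichment=10.0)
        fm, *_ = simulate_fragment_map(cfg, 1)
        B, labels, _ = simulate_interactability(fm, cfg, 5)
        table, truth = simulate_ditags(fm, B, labels, cfg, 5)
        merged = table.merge(truth.planted[["frag_lo", "frag_hi"]], on=["frag_lo", "frag_hi"])
        # planted pairs had background mean >= 20 combined; at enrichment 10
        # their mean observed count should be large
        assert merged["count"].mean() > 50

    def test_zero_base_rate_no_counts(self):
        cfg = replace(SMALL, base_rate=0.0)
        fm, *_ = simulate_fragment_map(cfg, 1)
        B, labels, _ = simulate_interactability(fm, cfg, 1)
        table, _ = simulate_ditags(fm, B, labels, cfg, 1)
        assert table.empty

    def test_moment_match_by_distance_decile(self):
        # empirical mean of unplanted counts tracks the generative mean
        cfg = preset_config("null")
        fm, *_ = simulate_fragment_map(cfg, 2)
        B, labels, _ = simulate_interactability(fm, cfg, 2)
        table, _ = simulate_ditags(fm, B, labels, cfg, 2)
        from chicpeaks.simulate import _cis_candidate_pairs

        pairs = _cis_candidate_pairs(fm, cfg.max_dist)
        pairs = pairs[pairs["distance"] > 0]
        b_lo = B.reindex(pairs["frag_lo"]).fillna(1.0).to_numpy()
        b_hi = B.reindex(pairs["frag_hi"]).fillna(1.0).to_numpy()
        mu = cfg.base_rate * b_lo * b_hi * pairs["distance"].to_numpy() ** -1.0
        expected = pd.Series(mu * sum(cfg.replicate_scales), index=pd.MultiIndex.from_frame(pairs[["frag_lo", "frag_hi"]]))
        observed = table.groupby(["frag_lo", "frag_hi"])["count"].sum().reindex(expected.index).fillna(0)
        decile = pd.qcut(pairs["distance"].to_numpy(), 10, labels=False)
        for d in range(10):
            m = decile == d
            ratio = observed.to_numpy()[m].mean() / expected.to_numpy()[m].mean()
            assert 0.9 < ratio < 1.1


class TestTruthEvaluation:
    def _truth(self, planted_pairs):
        from chicpeaks.simulate import SimTruth

        planted = pd.DataFrame(
            {
                "frag_lo": [p[0] for p in planted_pairs],
                "frag_hi": [p[1] for p in planted_pairs],
                "pair_class": "capture_to_cis",
                "distance": 50_000.0,
                "enrichment": 8.0,
            }
        )
        return SimTruth(planted, pd.Series(dtype=float), pd.Series(dtype=object))

    def _calls(self, pairs):
        return pd.DataFrame(
            {"frag_lo": [p[0] for p in pairs], "frag_hi": [p[1] for p in pairs], "significant": True}
        )

    def test_no_calls(self):
        ev = truth_evaluation(self._calls([]), self._truth([(1, 2)]))
        assert ev["fdp"] == 0.0 and ev["sensitivity"] == 0.0

    def test_perfect_calls(self):
        pairs = [(1, 2), (3, 4)]
        ev = truth_evaluation(self._calls(pairs), self._truth(pairs))
        assert ev["fdp"] == 0.0 and ev["sensitivity"] == 1.0

    def test_partial_recovery_arithmetic(self):
        planted = [(i, i + 1) for i in range(0, 20, 2)]  # 10 planted
        called = planted[:8] + [(100, 101)]  # 8 true + 1 spurious
        ev = truth_evaluation(self._calls(called), self._truth(planted))
        assert abs(ev["fdp"] - 1 / 9) < 1e-12
        assert abs(ev["sensitivity"] - 0.8) < 1e-12
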