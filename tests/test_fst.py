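import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sweepscan as ss
from sweepscan.fst import classify_chicken_chrom, stratified_mean_fst
from sweepscan.windows import make_window_grid, window_mean

from .oracles import wc84_oracle

# regression constant: WC84 theta-hat at (p1=0.8, p2=0.2, n1=n2=100 haplotypes),
# computed independently with exact rational arithmetic: 437/833
WC84_REGRESSION = 437.0 / 833.0


class TestWcFstSite:
    def test_matches_independent_oracle_on_random_grid(self):
        rng = np.random.default_rng(123)
        p1 = rng.uniform(0, 1, 2_000)
        p2 = rng.uniform(0, 1, 2_000)
        n1 = rng.integers(4, 300, 2_000).astype(float)
        n2 = rng.integers(4, 300, 2_000).astype(float)
        theta = ss.wc_fst_site(p1, p2, n1, n2)
        expected = np.array(
            [wc84_oracle([a, b], [c, d]) for a, b, c, d in zip(p1, p2, n1, n2)]
        )
        np.testing.assert_allclose(theta, expected, atol=1e-12, equal_nan=True)

    def test_frozen_regression_value(self):
        assert ss.wc_fst_site(0.8, 0.2, 100, 100) == pytest.approx(
            WC84_REGRESSION, abs=1e-12
        )

    def test_equal_frequencies_give_non_positive_theta(self):
        for p in (0.1, 0.5, 0.9):
            assert ss.wc_fst_site(p, p, 50, 50) <= 0

    def test_fixed_difference_approaches_one(self):
        assert ss.wc_fst_site(1.0, 0.0, 10_000, 10_000) == pytest.approx(1.0, abs=1e-3)

    def test_both_fixed_same_allele_undefined(self):
        assert np.isnan(ss.wc_fst_site(0.0, 0.0, 50, 50))
        assert np.isnan(ss.wc_fst_site(1.0, 1.0, 50, 50))

    def test_too_few_haplotypes_rejected(self):
        with pytest.raises(ValueError):
            ss.wc_fst_site(0.5, 0.5, 1, 50)

    def test_hudson_cross_check_close_at_equal_sample_sizes(self):
        rng = np.random.default_rng(5)
        p1 = rng.uniform(0, 1, 5_000)
        p2 = rng.uniform(0, 1, 5_000)
        n = rng.integers(20, 200, 5_000).astype(float)
        wc = ss.wc_fst_site(p1, p2, n, n)
        hu = ss.hudson_fst_site(p1, p2, n, n)
        ok = ~np.isnan(wc) & ~np.isnan(hu)
        assert np.abs(wc[ok] - hu[ok]).max() < 0.01
        assert np.corrcoef(wc[ok], hu[ok])[0, 1] > 0.999

    def test_hudson_frozen_arithmetic(self):
        # N = 0.36 - 2*0.16/99, D = 0.68
        expected = (0.36 - 2 * 0.16 / 99) / 0.68
        assert ss.hudson_fst_site(0.8, 0.2, 100, 100) == pytest.approx(expected)


class TestEmpiricalP:
    def test_hand_counted_example(self):
        assert ss.empirical_p(np.array([1.0, 2.0, 3.0, 4.0]), 3.0) == pytest.approx(0.5)

    def test_maximum_of_distinct_values_gets_one_over_n(self):
        vals = np.arange(10, dtype=float)
        assert ss.empirical_p(vals, vals.max()) == pytest.approx(0.1)

    def test_all_equal_values_give_p_one(self):
        vals = np.full(7, 3.3)
        assert ss.empirical_p(vals, 3.3) == 1.0

    @settings(max_examples=40, derandomize=True)
    @given(
        vals=st.lists(st.floats(-10, 10), min_size=1, max_size=50),
        o1=st.floats(-10, 10),
        o2=st.floats(-10, 10),
    )
    def test_monotone_non_increasing_in_observation(self, vals, o1, o2):
        lo, hi = sorted([o1, o2])
        v = np.array(vals)
        assert ss.empirical_p(v, hi) <= ss.empirical_p(v, lo)


class TestTopQuantileThreshold:
    def test_distinct_values_flag_exactly_one_percent(self):
        vals = np.arange(1, 101, dtype=float)
        t = ss.top_quantile_threshold(vals, q=0.99)
        assert (vals >= t).sum() == 1
        assert t == 100.0

    def test_q_near_zero_flags_everything(self):
        vals = np.array([3.0, 1.0, 2.0])
        t = ss.top_quantile_threshold(vals, q=1e-9)
        assert t == 1.0
        assert (vals >= t).all()

    def test_ties_at_threshold_all_flagged(self):
        vals = np.full(50, 2.5)
        t = ss.top_quantile_threshold(vals, q=0.99)
        assert (vals >= t).sum() == 50

    @settings(max_examples=40, derandomize=True)
    @given(st.data())
    def test_flag_count_is_nearest_rank_size_for_distinct_values(self, data):
        n = data.draw(st.integers(2, 200))
        q = data.draw(st.floats(0.5, 0.99))
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.arange(n, dtype=float))  # distinct
        t = ss.top_quantile_threshold(vals, q=q)
        assert (vals >= t).sum() == int(np.ceil((1 - q) * n - 1e-9))


class TestClusterDivergentWindows:
    def _ws(self, values):
        values = np.asarray(values, dtype=float)
        grid = make_window_grid((values.size - 1) * 5_000 + 40_000)
        return ss.WindowStat(
            grid=grid, value=values, n_snps=np.full(values.size, 10)
        )

    def test_single_flagged_window(self):
        ws = self._ws([0.1, 0.9, 0.1])
        regions = ss.cluster_divergent_windows(ws, threshold=0.5)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_windows) == (5_000, 45_000, 1)
        assert r.max_fst == pytest.approx(0.9)
        assert r.min_p == pytest.approx(1 / 3)

    def test_forty_one_contiguous_windows_span_formula(self):
        # 41 adjacent flagged windows extend over 40*step + window_size bp
        vals = np.concatenate([[0.0], np.full(41, 0.9), [0.0]])
        regions = ss.cluster_divergent_windows(self._ws(vals), threshold=0.5)
        assert len(regions) == 1
        r = regions[0]
        assert r.n_windows == 41
        assert r.end - r.start == 40 * 5_000 + 40_000  # just over 0.2 Mb per 41 windows

    def test_no_window_above_threshold_gives_empty_list(self):
        assert ss.cluster_divergent_windows(self._ws([0.1, 0.2]), threshold=0.5) == []

    def test_region_p_uses_reference_distribution_when_given(self):
        ws = self._ws([0.1, 0.9])
        reference = np.array([0.9, 0.8, 0.7, 0.6] + [0.1] * 6)
        regions = ss.cluster_divergent_windows(ws, 0.5, p_reference=reference)
        assert regions[0].min_p == pytest.approx(0.1)


class TestStratifiedMeanAndHet:
    def _ws_const(self, chrom, value, n=5):
        grid = make_window_grid(60_000, chrom=chrom)
        return ss.WindowStat(
            grid=grid, value=np.full(grid.n_windows, value), n_snps=np.full(grid.n_windows, 9)
        )

    def test_default_chicken_karyotype_classes(self):
        assert classify_chicken_chrom("1") == "macro"
        assert classify_chicken_chrom("chr5") == "macro"
        assert classify_chicken_chrom("7") == "intermediate"
        assert classify_chicken_chrom("11") == "micro"
        assert classify_chicken_chrom("28") == "micro"
        assert classify_chicken_chrom("Z") == "other"

    def test_per_class_means_of_disjoint_constants(self):
        stats = {"2": self._ws_const("2", 0.184), "15": self._ws_const("15", 0.186)}
        means = stratified_mean_fst(stats)
        assert means["macro"] == pytest.approx(0.184)
        assert means["micro"] == pytest.approx(0.186)

    def test_empty_class_reported_missing(self):
        grid = make_window_grid(60_000, chrom="1")
        empty = ss.WindowStat(
            grid=grid,
            value=np.full(grid.n_windows, np.nan),
            n_snps=np.zeros(grid.n_windows, dtype=int),
        )
        means = stratified_mean_fst({"1": empty})
        assert np.isnan(means["macro"])

    @pytest.mark.parametrize("p, het", [(0.5, 0.5), (0.0, 0.0), (1.0, 0.0), (0.2, 0.32)])
    def test_expected_heterozygosity_values(self, p, het):
        track = ss.FrequencyTrack(
            chrom=np.array(["1"]),
            positions=np.array([0]),
            freq=np.array([p]),
            n_obs=np.array([10]),
            pop_id="t",
        )
        assert ss.expected_heterozygosity(track)[0] == pytest.approx(het)


class TestSelfComparisonAndSweeps:
    def test_group_compared_to_itself_has_non_positive_windowed_fst(self, neutral_sim):
        panel = neutral_sim.panel
        track = ss.genotype_freq(_gm_from_panel(panel, "WL"), pop_id="WL")
        from sweepscan.fst import fst_track

        site = fst_track(track, track)
        grid = make_window_grid(neutral_sim.config.chrom_length)
        ws = window_mean(site["pos"].to_numpy(), site["fst"].to_numpy(), grid)
        defined = ws.value[~np.isnan(ws.value)]
        assert defined.max() <= 1e-9

    def test_heterozygosity_dips_at_implanted_sweep_centers(self):
        """Directional paired check: the window-mean HWE heterozygosity at the
        sweep center is below the distal flanks in essentially all replicates."""
        wins = 0
        n_reps = 20
        for rep in range(n_reps):
            L, C = 600_000, 300_000
            cfg = ss.SimulationConfig(
                seed=300 + rep,
                chrom_length=L,
                sweeps=(
                    ss.SweepSpec(
                        center=C, target_pops=("WL", "BL"), p_sweep=0.95,
                        decay_length=100_000,
                    ),
                ),
            )
            data = ss.simulate(cfg)
            f = data.panel.derived_freq("WL")
            het = 2 * f * (1 - f)
            grid = make_window_grid(L)
            ws = window_mean(data.panel.positions, het, grid)
            centers = grid.centers()
            center_val = np.nanmean(ws.value[np.abs(centers - C) <= 20_000])
            flank_val = np.nanmean(ws.value[np.abs(centers - C) >= 200_000])
            wins += center_val < flank_val
        assert wins >= 18

    def test_broiler_only_sweep_yields_divergence_region_over_center(self):
        L, C = 600_000, 300_000
        cfg = ss.SimulationConfig(
            seed=77,
            chrom_length=L,
            sweeps=(
                ss.SweepSpec(
                    center=C, target_pops=("BR1", "BR2", "BR3"), p_sweep=0.95,
                    decay_length=100_000,
                ),
            ),
        )
        data = ss.simulate(cfg)
        layer_tracks = [
            ss.FrequencyTrack(
                chrom=np.array([data.panel.chrom] * data.panel.n_sites),
                positions=data.panel.positions,
                freq=data.panel.derived_freq(p),
                n_obs=np.full(data.panel.n_sites, 50),
                pop_id=p,
            )
            for p in ("WL", "BL")
        ]
        lt = ss.group_mean_freq(layer_tracks, pop_id="L")
        bt = ss.group_mean_freq(
            [ss.pool_freq(data.pools, p) for p in data.pools.pools], pop_id="BR"
        )
        from sweepscan.fst import fst_track

        site = fst_track(lt, bt, max_pool_n=50)
        grid = make_window_grid(L)
        ws = window_mean(site["pos"].to_numpy(), site["fst"].to_numpy(), grid)
        t = ss.top_quantile_threshold(ws.value, q=0.99)
        regions = ss.cluster_divergent_windows(ws, t)
        assert any(r.start <= C < r.end for r in regions)


def _gm_from_panel(panel, pop):
    import pandas as pd

    rows = panel.rows_of(pop)
    dosage = (panel.haplotypes[rows[0::2]] + panel.haplotypes[rows[1::2]]).T.astype(float)
    sites = pd.DataFrame(
        {
            "chrom": [panel.chrom] * panel.n_sites,
            "pos": panel.positions,
            "ref": "A",
            "alt": "G",
            "qual": 50.0,
            "depth": 100.0,
        }
    )
    samples = [f"{pop}_{i}" for i in range(len(rows) // 2)]
    return ss.GenotypeMatrix(sites=sites, samples=samples, dosage=dosage)
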