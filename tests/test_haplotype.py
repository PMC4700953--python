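import math

import numpy as np
import pytest

import sweepscan as ss
from sweepscan.haplotype import standardize_ihs, windowed_abs_ihs
from sweepscan.windows import make_window_grid

from .oracles import ehh_oracle, ihs_oracle

# frozen by exhaustive pair enumeration on the 4-haplotype toy panel:
# ihh_a = 200 bp, ihh_d = 400 bp, ihs_raw = ln(200/400) = -ln 2
TOY_IHH_A = 200.0
TOY_IHH_D = 400.0
TOY_IHS_RAW = -math.log(2.0)


def _small_panel(seed=0, n_hap=20, n_sites=60, spacing=100):
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.2, 0.8, n_sites)
    hap = (rng.random((n_hap, n_sites)) < freqs).astype(np.uint8)
    return ss.HaplotypePanel(
        chrom="1",
        chrom_length=n_sites * spacing + 1,
        positions=np.arange(n_sites) * spacing,
        haplotypes=hap,
        pop_labels=np.array(["P"] * n_hap),
    )


class TestEhh:
    def test_equals_one_at_core(self, toy_panel):
        up, down = ss.ehh(toy_panel, core=3, allele=1)
        assert up.ehh[0] == 1.0 and down.ehh[0] == 1.0

    def test_identical_carriers_stay_at_one_to_the_edge(self):
        hap = np.vstack([np.tile([1, 0, 1, 1, 0], (3, 1)), [[0, 1, 0, 1, 1]]]).astype(np.uint8)
        panel = ss.HaplotypePanel(
            chrom="1", chrom_length=500, positions=np.arange(5) * 100,
            haplotypes=hap, pop_labels=np.array(["P"] * 4),
        )
        up, down = ss.ehh(panel, core=2, allele=1)
        assert np.all(up.ehh == 1.0) and np.all(down.ehh == 1.0)
        assert not up.truncated and not down.truncated

    def test_pairwise_distinct_adjacent_site_drops_to_zero(self):
        hap = np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1]], dtype=np.uint8)
        panel = ss.HaplotypePanel(
            chrom="1", chrom_length=300, positions=np.array([0, 100, 200]),
            haplotypes=hap, pop_labels=np.array(["P"] * 3),
        )
        _, down = ss.ehh(panel, core=0, allele=1)
        assert down.ehh[1] == 0.0

    def test_fewer_than_two_carriers_rejected(self, toy_panel):
        panel = toy_panel.copy()
        panel.haplotypes[:, 3] = [1, 0, 0, 0]
        with pytest.raises(ValueError):
            ss.ehh(panel, core=3, allele=1)

    def test_monotone_non_increasing_and_matches_pair_oracle(self):
        panel = _small_panel(seed=3)
        for core in (10, 30, 50):
            for allele in (0, 1):
                if (panel.haplotypes[:, core] == allele).sum() < 2:
                    continue
                up, down = ss.ehh(panel, core, allele, truncation=0.0, max_gap=None)
                for curve in (up, down):
                    assert np.all(np.diff(curve.ehh) <= 1e-12)
                    step = -1 if curve.direction == "upstream" else 1
                    for k in range(len(curve.ehh)):
                        expected = ehh_oracle(
                            panel.haplotypes, panel.positions, core, allele, core + step * k
                        )
                        assert curve.ehh[k] == pytest.approx(expected, abs=1e-12)


class TestIhs:
    def test_toy_panel_matches_frozen_enumeration(self, toy_panel):
        df = ss.ihs(toy_panel, maf_min=0.05)
        row = df[df.pos == 300].iloc[0]
        assert row.ihh_a == pytest.approx(TOY_IHH_A)
        assert row.ihh_d == pytest.approx(TOY_IHH_D)
        assert row.ihs_raw == pytest.approx(TOY_IHS_RAW, abs=1e-12)
        assert row.ihs_raw == pytest.approx(
            ihs_oracle(toy_panel.haplotypes, toy_panel.positions, 3), abs=1e-12
        )

    def test_antisymmetric_under_allele_relabeling(self):
        panel = _small_panel(seed=7)
        flipped = panel.copy()
        flipped.haplotypes = (1 - flipped.haplotypes).astype(np.uint8)
        a = ss.ihs(panel)
        b = ss.ihs(flipped)
        assert len(a) == len(b)
        both = ~a["ihs_raw"].isna().to_numpy() & ~b["ihs_raw"].isna().to_numpy()
        assert both.any()
        np.testing.assert_allclose(
            a["ihs_raw"].to_numpy()[both], -b["ihs_raw"].to_numpy()[both], atol=1e-12
        )
        np.testing.assert_allclose(
            a["daf"].to_numpy(), 1 - b["daf"].to_numpy(), atol=1e-12
        )

    def test_equal_integrals_give_zero_score(self, toy_panel):
        # symmetric panel: derived and ancestral classes mirror each other
        hap = np.array(
            [[0, 1, 0, 0], [1, 1, 1, 0], [0, 0, 0, 1], [1, 0, 1, 1]], dtype=np.uint8
        )
        panel = ss.HaplotypePanel(
            chrom="1", chrom_length=400, positions=np.array([0, 100, 200, 300]),
            haplotypes=hap, pop_labels=np.array(["P"] * 4),
        )
        df = ss.ihs(panel, maf_min=0.05)
        row = df[df.pos == 100]
        if not row.empty and not np.isnan(row.iloc[0].ihs_raw):
            assert row.iloc[0].ihh_a == pytest.approx(row.iloc[0].ihh_d)
            assert row.iloc[0].ihs_raw == pytest.approx(0.0, abs=1e-12)

    def test_low_maf_cores_skipped(self):
        panel = _small_panel(seed=9)
        df = ss.ihs(panel, maf_min=0.2)
        assert ((df["daf"] >= 0.2) & (df["daf"] <= 0.8)).all()

    def test_edge_censored_cores_reported_missing(self):
        # identical carriers to the chromosome edge: integral undefined
        hap = np.vstack(
            [np.tile([1, 1, 1, 1, 1], (3, 1)), np.tile([0, 0, 0, 0, 0], (3, 1))]
        ).astype(np.uint8)
        panel = ss.HaplotypePanel(
            chrom="1", chrom_length=500, positions=np.arange(5) * 100,
            haplotypes=hap, pop_labels=np.array(["P"] * 6),
        )
        df = ss.ihs(panel, maf_min=0.05)
        assert df["ihs_raw"].isna().all()


class TestStandardizeIhs:
    def test_bins_standardized_to_zero_mean_unit_sd(self):
        panel = _small_panel(seed=11, n_hap=30, n_sites=200)
        df = standardize_ihs(ss.ihs(panel), n_bins=5)
        got_any = False
        edges = np.linspace(0, 1, 6)
        b = np.clip(np.digitize(df["daf"], edges) - 1, 0, 4)
        for k in range(5):
            scores = df.loc[(b == k) & df["ihs_std"].notna(), "ihs_std"].to_numpy()
            if scores.size >= 2:
                got_any = True
                assert scores.mean() == pytest.approx(0.0, abs=1e-9)
                assert scores.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert got_any

    def test_single_score_bin_left_missing(self):
        import pandas as pd

        df = pd.DataFrame(
            {"pos": [0, 100], "daf": [0.1, 0.9], "ihh_a": 1.0, "ihh_d": 1.0,
             "ihs_raw": [0.5, -0.5]}
        )
        out = standardize_ihs(df, n_bins=2)
        assert out["ihs_std"].isna().all()

    def test_zero_spread_bin_warns_and_stays_missing(self):
        import pandas as pd

        df = pd.DataFrame(
            {"pos": [0, 100, 200], "daf": [0.4, 0.45, 0.5], "ihh_a": 1.0,
             "ihh_d": 1.0, "ihs_raw": [0.7, 0.7, 0.7]}
        )
        with pytest.warns(UserWarning, match="zero spread"):
            out = standardize_ihs(df, n_bins=2)
        assert out["ihs_std"].isna().all()


class TestWindowedAbsIhs:
    def test_mixed_signs_equal_magnitude_average_to_magnitude(self):
        import pandas as pd

        df = pd.DataFrame(
            {"pos": [100, 200, 300], "ihs_std": [1.5, -1.5, 1.5]}
        )
        ws = windowed_abs_ihs(df, make_window_grid(40_000), min_snps=3)
        assert ws.value[0] == pytest.approx(1.5)

    def test_unscored_windows_missing(self):
        import pandas as pd

        df = pd.DataFrame({"pos": [100], "ihs_std": [np.nan]})
        ws = windowed_abs_ihs(df, make_window_grid(40_000), min_snps=1)
        assert np.isnan(ws.value[0])


def test_swept_windows_carry_elevated_abs_ihs():
    """Directional power check: with a shared core haplotype implanted at
    derived frequency 0.8, mean |iHS| inside the swept tract exceeds the
    panel-wide mean in nearly all replicates."""
    wins = 0
    n_reps = 50
    for rep in range(n_reps):
        cfg = ss.SimulationConfig(
            seed=900 + rep,
            chrom_length=400_000,
            mean_spacing=500,
            sweeps=(
                ss.SweepSpec(
                    center=200_000, target_pops=("WL",), p_sweep=0.8,
                    decay_length=8_000, core_haplotype=True,
                ),
            ),
        )
        data = ss.simulate(cfg)
        panel = data.panel.subset_pops(["WL"])
        df = standardize_ihs(ss.ihs(panel))
        s = df["ihs_std"].abs()
        near = s[(df["pos"] - 200_000).abs() < 20_000].mean()
        wins += near > s.mean()
    assert wins >= 40
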