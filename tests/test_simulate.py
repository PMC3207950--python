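import numpy as np
import pandas as pd
import pytest

from bsascan import (KernelSpec, SimDesign, qtl_effect_for_variance,
                     run_null_calibration, run_power, simulate_f2_bulks,
                     truncation_selection_theory)

SPEC = KernelSpec(half_width=5.0, unit="cm")


def small_design(**kw):
    defaults = dict(N=200, n=30, C=30.0, chrom_length_cm=10.0, snp_density_d=5.0)
    defaults.update(kw)
    return SimDesign(**defaults)


class TestTruncationTheory:
    def test_printed_shift_triple(self):
        # additive locus, alpha = 0.1, p0 = 0.5; top 20% / 10% / 1%
        for frac, expected in ((0.20, 3.5), (0.10, 4.4), (0.01, 6.7)):
            _, dp = truncation_selection_theory(0.1, 0.5, frac)
            assert round(100 * dp, 1) == expected

    def test_no_selection_limit(self):
        i, dp = truncation_selection_theory(0.1, 0.5, 1 - 1e-12)
        assert i == pytest.approx(0.0, abs=1e-6)
        assert dp == pytest.approx(0.0, abs=1e-7)

    def test_intensity_grows_sublinearly_with_stringency(self):
        i1 = truncation_selection_theory(0.1, 0.5, 0.01)[0]
        i10 = truncation_selection_theory(0.1, 0.5, 0.10)[0]
        i20 = truncation_selection_theory(0.1, 0.5, 0.20)[0]
        assert i1 > i10 > i20
        assert i1 / i20 < 20 / 5  # 20-fold stricter selection, far less than 20x intensity

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            truncation_selection_theory(0.1, 0.5, 1.5)


class TestQtlEffect:
    def test_two_percent_variance(self):
        delta = qtl_effect_for_variance(0.02)
        assert delta**2 / 8 / (delta**2 / 8 + 1.0) == pytest.approx(0.02, rel=1e-12)

    def test_null_effect(self):
        assert qtl_effect_for_variance(0.0) == 0.0


class TestSimulateF2Bulks:
    def test_table_layout(self, rng):
        table, info = simulate_f2_bulks(small_design(), rng)
        assert len(table) == 51
        assert info["qtl_index"] == 25
        assert (table["pos"].diff().dropna() > 0).all()
        assert table[["n_hi_L", "n_lo_L", "n_hi_H", "n_lo_H"]].ge(0).all().all()

    def test_null_frequencies_centre_on_half(self):
        r = np.random.default_rng(5)
        freqs = [simulate_f2_bulks(small_design(), r)[1] for _ in range(300)]
        p = np.array([f["p_low"] for f in freqs] + [f["p_high"] for f in freqs])
        se = np.sqrt(0.25 / 60 / 600)
        assert p.mean() == pytest.approx(0.5, abs=4 * se)
        assert np.abs(p.mean(axis=0) - 0.5).max() < 0.03  # every SNP individually

    def test_selection_shifts_frequencies_as_theory_predicts(self):
        # realised mean delta-p in the high bulk vs i*p*q*alpha at matched parameters
        delta = 0.8
        design = SimDesign(N=1000, n=150, C=30.0, snp_density_d=2.0,
                           qtl_effect_delta=delta)
        sigma_p = np.sqrt(delta**2 / 8 + 1.0)
        alpha = (delta / 2) / sigma_p
        _, dp_theory = truncation_selection_theory(alpha, 0.5, 150 / 1000)
        r = np.random.default_rng(11)
        reps = 400
        dp = [simulate_f2_bulks(design, r)[1]["p_high"][design.qtl_index] - 0.5
              for _ in range(reps)]
        se = np.std(dp, ddof=1) / np.sqrt(reps)
        assert np.mean(dp) == pytest.approx(dp_theory, abs=3 * se)

    def test_linkage_decay_with_distance(self):
        # long chromosome so linkage decays appreciably: corr ~ (1-2r) = e^(-d/50)
        design = SimDesign(N=400, n=60, C=30.0, chrom_length_cm=40.0,
                           snp_density_d=0.5, qtl_effect_delta=2.0)
        r = np.random.default_rng(3)
        qi = design.qtl_index
        devs = np.array([simulate_f2_bulks(design, r)[1]["p_high"] - 0.5
                         for _ in range(300)])
        corr = np.array([np.corrcoef(devs[:, qi], devs[:, j])[0, 1]
                         for j in range(qi, devs.shape[1], 2)])
        assert corr[0] == pytest.approx(1.0)
        assert corr[-1] < 0.8  # e^(-20/50) = 0.67 plus Monte-Carlo jitter
        # downward trend with distance (allowing Monte-Carlo jitter per bin)
        slope = np.polyfit(np.arange(len(corr)), corr, 1)[0]
        assert slope < 0

    def test_total_depth_is_poisson_with_mean_coverage(self):
        design = small_design(C=40.0)
        r = np.random.default_rng(9)
        depths = np.concatenate([
            (t := simulate_f2_bulks(design, r)[0])["n_hi_L"].to_numpy() + t["n_lo_L"].to_numpy()
            for _ in range(200)
        ])
        assert depths.mean() == pytest.approx(40.0, rel=0.02)
        assert depths.var() == pytest.approx(40.0, rel=0.06)  # Poisson: var = mean

    def test_homozygous_design_halves_allele_count(self):
        r = np.random.default_rng(21)
        design = small_design(homozygous=True)
        _, info = simulate_f2_bulks(design, r)
        # n individuals, one doubled gamete each: frequencies on a grid of 1/n
        assert np.allclose(np.round(info["p_low"] * design.n), info["p_low"] * design.n)

    def test_seed_reproducibility(self):
        t1, _ = simulate_f2_bulks(small_design(seed=42))
        t2, _ = simulate_f2_bulks(small_design(seed=42))
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_design(self):
        with pytest.raises(ValueError):
            SimDesign(N=100, n=60)


class TestDrivers:
    def test_null_calibration_moments_and_rates(self):
        cal = run_null_calibration(small_design(), SPEC, reps=300,
                                   rng=np.random.default_rng(8))
        mean_g, var_g = cal.g_moments
        # theory for this design: E[G] = 1 + 30/60 = 1.5, Var[G] = 4.5
        assert 1.1 < mean_g < 2.0 and 2.0 < var_g < 8.0
        for key, rate in cal.rates.items():
            assert 0.0 <= rate <= 0.25

    def test_null_calibration_rejects_qtl_design(self):
        with pytest.raises(ValueError):
            run_null_calibration(small_design(qtl_effect_delta=1.0), SPEC, 10)

    def test_power_grid_shape_and_monotonicity_in_effect(self):
        rngs = np.random.default_rng(4)
        grid = [small_design(qtl_effect_delta=d) for d in (0.0, 2.0)]
        table = run_power(grid, SPEC, reps=200, rng=rngs)
        assert len(table) == 2
        assert table.loc[1, "power_gprime_0.05"] > table.loc[0, "power_gprime_0.05"]
        assert table.loc[1, "mean_gprime_causal"] > table.loc[0, "mean_gprime_causal"]

    def test_power_single_replicate_ok(self):
        table = run_power([small_design()], SPEC, reps=1, rng=np.random.default_rng(0))
        assert len(table) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_power([], SPEC, reps=10)
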