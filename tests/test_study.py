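"""Discretization-study driver and its statistical machinery.

The statistics are each checked against an independent oracle: full
permutation enumeration for Spearman, sign-flip enumeration for the
signed-rank test, and closed-form synthetic data for the power-law fit.
"""

import itertools

import numpy as np
import pytest

from srsqa import (
    ClinicalCaseSpec,
    StudyConfig,
    effect_size_and_n,
    fit_power_law,
    make_clinical_like_case,
    paired_compare,
    run_study,
    spearman_ratio_analysis,
)


class TestSpearman:
    def test_strictly_increasing_gives_rho_one(self):
        rho, p = spearman_ratio_analysis([1, 2, 3, 4, 5], [1.1, 1.2, 1.3, 1.4, 1.5])
        assert rho == pytest.approx(1.0)

    def test_constant_ratios_reported_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_ratio_analysis([1, 2, 3, 4, 5], [1.0] * 5)
        assert rho == 0.0

    def test_exact_p_matches_brute_force_enumeration(self):
        x = [0.3, 1.2, 0.7, 2.5, 1.9, 0.5]
        y = [0.91, 1.02, 0.97, 1.01, 0.99, 0.96]
        rho, p = spearman_ratio_analysis(x, y)
        # brute force over all 720 rank permutations
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        rho_obs = np.corrcoef(rx, ry)[0, 1]
        hits = sum(
            abs(np.corrcoef(rx, np.array(perm))[0, 1]) >= abs(rho_obs) - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert p == pytest.approx(hits / 720)
        assert rho == pytest.approx(rho_obs)


class TestPowerLawFit:
    def test_noise_free_parameter_recovery_to_1e6(self):
        x = np.geomspace(0.05, 15.0, 60)
        y = -0.5 * x**-1.0 + 1.0
        fit = fit_power_law(x, y)
        assert fit.a == pytest.approx(-0.5, abs=1e-6)
        assert fit.b == pytest.approx(-1.0, abs=1e-6)
        assert fit.c == pytest.approx(1.0, abs=1e-6)
        assert fit.nrmse < 1e-8

    def test_constant_data_degenerate_guard(self):
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_power_law(np.linspace(1, 5, 10), np.full(10, 0.98))
        assert fit.a == 0.0
        assert fit.c == pytest.approx(0.98)
        assert fit.nrmse == 0.0

    def test_noisy_data_nrmse_order_1e2(self):
        rng = np.random.default_rng(3)
        x = np.geomspace(0.1, 15.0, 120)
        y = -0.04 * x**-0.8 + 1.0 + rng.normal(0.0, 0.02, size=x.size)
        fit = fit_power_law(x, y)
        assert 0.005 < fit.nrmse < 0.3

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, -2.0, 3.0, 4.0, 5.0], [1.0] * 5)
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0, 3.0], [1.0, 1.1, 1.2])


class TestPairedCompare:
    def test_identical_samples_p_is_one(self):
        res = paired_compare([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.p == 1.0
        assert "zero" in res.note

    def test_constant_shift_exact_p(self):
        ref = np.arange(10, dtype=float)
        res = paired_compare(ref, ref + 0.7)
        assert res.p == pytest.approx(2 * 0.5**10)

    def test_antisymmetric_differences_p_near_one(self):
        ref = np.zeros(10)
        ev = np.array([0.5, -0.5, 1.0, -1.0, 1.5, -1.5, 2.0, -2.0, 2.5, -2.5])
        res = paired_compare(ref, ev)
        assert res.p > 0.9

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_exact_distribution_matches_signflip_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(0.4, 1.0, size=n)
        while np.any(d == 0):  # pragma: no cover - measure-zero
            d = rng.normal(0.4, 1.0, size=n)
        res = paired_compare(np.zeros(n), d)
        # oracle: enumerate all 2^n sign assignments of the rank vector
        from scipy.stats import rankdata

        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        mu = n * (n + 1) / 4
        stats = []
        for mask in range(2**n):
            signs = np.array([(mask >> k) & 1 for k in range(n)], dtype=bool)
            stats.append(ranks[signs].sum())
        stats = np.array(stats)
        p_oracle = np.mean(np.abs(stats - mu) >= abs(w_obs - mu) - 1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)


class TestEffectSize:
    def test_unit_effect(self):
        x = np.sqrt(5.0 / 6.0)  # mean 1, sample sd exactly 1
        d = np.array([1 + x, 1 - x] * 3)
        eff, n = effect_size_and_n(d)
        assert eff == pytest.approx(1.0)

    def test_reported_effect_size_gives_8_cases(self):
        # d = 1.03 at α = 0.05, power = 0.8 → n ≈ 8
        base = np.array([1.0, -1.0, 1.0, -1.0, 0.5, -0.5, 0.3, -0.3])
        d = base - base.mean() + 1.03 * base.std(ddof=1)
        eff, n = effect_size_and_n(d)
        assert eff == pytest.approx(1.03, rel=1e-9)
        assert n in (7, 8, 9)

    def test_scale_invariance(self):
        d = np.array([0.5, 1.5, 1.0, 2.0, 0.7])
        eff1, n1 = effect_size_and_n(d)
        eff2, n2 = effect_size_and_n(10.0 * d)
        assert eff2 == pytest.approx(eff1, rel=1e-12)
        assert n2 == n1

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            effect_size_and_n([1.0, 1.0, 1.0])


@pytest.fixture(scope="module")
def tiny_study():
    """Three small clinical-like cases through the full ST/DG driver."""
    cases = [
        make_clinical_like_case(ClinicalCaseSpec(diameters_mm=d, seed=50 + i))
        for i, d in enumerate([(6.0,), (15.0,), (30.0, 6.0)])
    ]
    config = StudyConfig(st_list_mm=(1.0, 2.0), dg_list_mm=(1.0, 2.0, 3.0))
    return run_study(cases, config), config


class TestRunStudy:
    def test_identity_perturbation_ratios_are_one(self, tiny_study):
        result, _ = tiny_study
        ref = result.records[result.records.perturbation == "reference"]
        np.testing.assert_allclose(ref.ratio, 1.0, rtol=1e-12)

    def test_record_count_is_targets_by_quantities_by_perturbations(self, tiny_study):
        result, config = tiny_study
        n_targets = 4
        n_quantities = len(config.levels_pct) + 4  # V_dose levels + D95, V30Gy, CI, GI
        n_perturb = 1 + 2 + 1  # reference + two DGs + one ST
        assert len(result.records) == n_targets * n_quantities * n_perturb

    def test_small_lesion_v100_further_from_one_than_large(self, tiny_study):
        result, _ = tiny_study
        rec = result.records
        sub = rec[(rec.perturbation == "DG") & (rec.value_mm == 2.0) & (rec.quantity == "V100")]
        small = sub[sub.diameter_mm == 6.0]["ratio"].to_numpy()
        large = sub[sub.diameter_mm == 30.0]["ratio"].to_numpy()
        assert np.abs(small - 1.0).mean() > np.abs(large - 1.0).mean()
        assert np.all(small < 1.0)  # coarse DG underestimates small isodose volumes

    def test_gi_more_dg_sensitive_than_d95(self, tiny_study):
        result, _ = tiny_study
        rec = result.records
        dg3 = rec[(rec.perturbation == "DG") & (rec.value_mm == 3.0)]
        gi = dg3[dg3.quantity == "GI"]["pct_diff"].abs().mean()
        d95 = dg3[dg3.quantity == "D95"]["pct_diff"].abs().mean()
        assert gi >= d95

    def test_fits_present_for_each_non_reference_perturbation(self, tiny_study):
        result, _ = tiny_study
        assert set(result.fits) == {("DG", 2.0), ("DG", 3.0), ("ST", 2.0)}
        for fit in result.fits.values():
            assert fit.nrmse >= 0.0
            assert abs(fit.rho) <= 1.0

    def test_determinism_of_the_full_driver(self, tiny_study):
        result, config = tiny_study
        cases = [
            make_clinical_like_case(ClinicalCaseSpec(diameters_mm=d, seed=50 + i))
            for i, d in enumerate([(6.0,), (15.0,), (30.0, 6.0)])
        ]
        again = run_study(cases, config)
        np.testing.assert_array_equal(
            result.records["eval"].to_numpy(), again.records["eval"].to_numpy()
        )
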