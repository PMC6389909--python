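"""Coupled folding/binding equilibrium: solver, fit, and closed forms."""

import numpy as np
import pytest

from dsf_isofit import (
    FlatDataError,
    IsothermalDataset,
    StoichiometricRegimeError,
    ec50_from_kd,
    ec50_hill,
    fit_isothermal,
    fraction_unfolded_model,
    free_ligand,
    kd_from_ec50,
)

uM = 1e-6


def quadratic_root_oracle(L_total, P_total, K_d, K_U):
    """Independent brute-force root of the free-ligand quadratic."""
    q = K_d * (1.0 + K_U)
    roots = np.roots([1.0, P_total - L_total + q, -L_total * q])
    phys = [r.real for r in roots if abs(r.imag) < 1e-30 and r.real >= 0]
    assert len(phys) == 1
    return phys[0]


def species(L, L_total, P_total, K_d, K_U):
    """Reconstruct [F], [U], [FL] from the free-ligand value."""
    FL = L_total - L
    F = K_d * FL / L if L > 0 else P_total / (1.0 + K_U)
    U = K_U * F
    return F, U, FL


class TestFreeLigand:
    def test_no_ligand_gives_zero(self):
        assert free_ligand(0.0, 2 * uM, 1 * uM, 1.0) == 0.0

    def test_no_protein_gives_all_free(self):
        assert free_ligand(10 * uM, 0.0, 1 * uM, 1.0) == 10 * uM

    def test_matches_independent_root_finder(self):
        L_total, P_total, K_d, K_U = 10 * uM, 2 * uM, 1 * uM, 1.0
        L = free_ligand(L_total, P_total, K_d, K_U)
        assert L == pytest.approx(
            quadratic_root_oracle(L_total, P_total, K_d, K_U), rel=1e-12
        )

    def test_mass_balance_residuals_tiny(self):
        L_total, P_total, K_d, K_U = 10 * uM, 2 * uM, 1 * uM, 1.0
        L = free_ligand(L_total, P_total, K_d, K_U)
        F, U, FL = species(L, L_total, P_total, K_d, K_U)
        assert F + U + FL == pytest.approx(P_total, rel=1e-12)
        assert L + FL == pytest.approx(L_total, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            free_ligand(-1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            free_ligand(1.0, 1.0, 0.0, 1.0)


class TestFractionUnfoldedModel:
    def test_zero_ligand_reduces_to_unfolding_constant(self):
        assert fraction_unfolded_model(0.0, 2 * uM, 1 * uM, 1.0) == pytest.approx(0.5)
        assert fraction_unfolded_model(0.0, 2 * uM, 1 * uM, 3.0) == pytest.approx(0.75)

    def test_saturating_ligand_drives_fu_to_zero(self):
        f = fraction_unfolded_model(10.0, 2 * uM, 1 * uM, 1.0)  # 10 M ligand
        assert f < 1e-6

    def test_fu_at_ec50_is_half_the_plateau(self):
        K_d, K_U, P = 1 * uM, 1.0, 2 * uM
        fu0 = K_U / (1 + K_U)
        ec50 = ec50_from_kd(K_d, P, fu0)
        assert fraction_unfolded_model(ec50, P, K_d, K_U) == pytest.approx(
            fu0 / 2.0, abs=1e-10
        )

    def test_strictly_decreasing_in_ligand(self):
        L = np.geomspace(1e-9, 1e-3, 40)
        f = fraction_unfolded_model(L, 2 * uM, 1 * uM, 1.0)
        assert np.all(np.diff(f) < 0)


class TestClosedForms:
    def test_mbp_worked_example(self):
        # EC50 6.8 uM, 2 uM protein, K_U 1.3 -> K_d 2.5 uM (2 sig figs)
        fu0 = 1.3 / 2.3
        kd = kd_from_ec50(6.8 * uM, 2 * uM, fu0)
        assert round(kd / uM, 1) == 2.5

    def test_boundary_example(self):
        assert ec50_from_kd(0.5 * uM, 2 * uM, 0.5) == pytest.approx(2 * uM, rel=1e-12)

    def test_fully_folded_limit(self):
        K_d, P = 3 * uM, 2 * uM
        assert kd_from_ec50(K_d + P / 2, P, 0.0) == pytest.approx(K_d, rel=1e-12)

    def test_round_trip_is_identity(self):
        for kd in (0.1 * uM, 1 * uM, 100 * uM):
            for fu0 in (0.0, 0.3, 0.9):
                ec50 = ec50_from_kd(kd, 2 * uM, fu0)
                assert kd_from_ec50(ec50, 2 * uM, fu0) == pytest.approx(kd, rel=1e-14)

    def test_tight_binding_limit_is_stoichiometric(self):
        assert ec50_from_kd(1e-12, 2 * uM, 0.5) == pytest.approx(1 * uM, rel=1e-5)

    def test_stoichiometric_regime_raises(self):
        with pytest.raises(StoichiometricRegimeError):
            kd_from_ec50(0.9 * uM, 2 * uM, 0.5)

    def test_fully_unfolded_plateau_rejected(self):
        with pytest.raises(ValueError):
            ec50_from_kd(1 * uM, 2 * uM, 1.0)


def make_dataset(K_d=1 * uM, K_U=1.0, P=2 * uM, noise=0.0, seed=None, sem=None):
    ladder = np.concatenate([[0.0], 500e-6 / 2.0 ** np.arange(11)[::-1]])
    f = fraction_unfolded_model(ladder, P, K_d, K_U)
    if noise > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f + rng.normal(0, noise, f.size), 0.0, 1.0)
    return IsothermalDataset(50.0, ladder, f, P, sem=sem)


class TestIsothermalFit:
    def test_noiseless_round_trip(self):
        fit = fit_isothermal(make_dataset())
        assert fit.K_d == pytest.approx(1 * uM, rel=1e-6)
        assert fit.K_U == pytest.approx(1.0, rel=1e-6)
        assert fit.f_u0 == pytest.approx(0.5, rel=1e-6)
        assert not fit.stoichiometric_regime

    def test_ec50_consistent_with_closed_form(self):
        fit = fit_isothermal(make_dataset())
        assert fit.EC50 == pytest.approx(
            ec50_from_kd(fit.K_d, fit.P_total, fit.f_u0), rel=1e-12
        )

    def test_noisy_recovery_stays_accurate(self):
        """Gaussian noise on the sliced f_u points perturbs K_d roughly in
        proportion; at sigma = 0.01 the median error stays well inside 20%.
        (Noise on the melt curves themselves, where averaging over the
        trace applies, is exercised by the end-to-end robustness tests.)"""
        errs = []
        for seed in range(25):
            fit = fit_isothermal(make_dataset(noise=0.01, seed=seed))
            errs.append(abs(fit.K_d - 1 * uM) / (1 * uM))
        assert np.median(errs) <= 0.20

    def test_fixed_ku_path_agrees_with_free_fit(self):
        free = fit_isothermal(make_dataset(noise=0.02, seed=7))
        fixed = fit_isothermal(make_dataset(noise=0.02, seed=7), fix_K_U=free.K_U)
        se = (free.K_d_se or 0.0) + (fixed.K_d_se or 0.0)
        assert abs(fixed.K_d - free.K_d) <= max(se, 0.2 * free.K_d)
        assert fixed.K_U_fixed and not free.K_U_fixed

    def test_weighted_fit_uses_sems(self):
        ds = make_dataset(noise=0.02, seed=3,
                          sem=np.full(12, 0.02))
        fit = fit_isothermal(ds)
        assert fit.K_d == pytest.approx(1 * uM, rel=0.5)

    def test_flat_data_is_informative_failure(self):
        ladder = np.concatenate([[0.0], np.geomspace(1e-9, 5e-4, 11)])
        ds = IsothermalDataset(50.0, ladder, np.full(12, 0.5), 2 * uM)
        with pytest.raises(FlatDataError, match="does not measurably stabilize"):
            fit_isothermal(ds)

    def test_needs_zero_point_or_fixed_ku(self):
        ladder = np.geomspace(1e-7, 5e-4, 12)
        f = fraction_unfolded_model(ladder, 2 * uM, 1 * uM, 1.0)
        ds = IsothermalDataset(50.0, ladder, f, 2 * uM)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_isothermal(ds)
        fit = fit_isothermal(ds, fix_K_U=1.0)
        assert fit.K_d == pytest.approx(1 * uM, rel=1e-4)

    def test_too_few_concentrations_rejected(self):
        ladder = np.array([0.0, 1e-6, 1e-5])
        f = fraction_unfolded_model(ladder, 2 * uM, 1 * uM, 1.0)
        ds = IsothermalDataset(50.0, ladder, f, 2 * uM)
        with pytest.raises(ValueError, match="4 distinct"):
            fit_isothermal(ds)

    def test_stoichiometric_regime_flagged_with_upper_bound(self):
        fit = fit_isothermal(make_dataset(K_d=0.01 * uM, P=10 * uM))
        assert fit.stoichiometric_regime
        assert fit.kd_upper_bound == pytest.approx(
            (1 - fit.f_u0) * 5 * uM, rel=1e-9
        )

    def test_bootstrap_errors_are_reproducible(self):
        a = fit_isothermal(make_dataset(noise=0.03, seed=1), bootstrap=50, seed=11)
        b = fit_isothermal(make_dataset(noise=0.03, seed=1), bootstrap=50, seed=11)
        assert a.K_d_se == b.K_d_se
        assert a.K_d_se > 0


class TestHillEstimate:
    def test_self_consistent_midpoint(self):
        """Logistic data with plateau 0.5 and midpoint 6.8 uM round-trips."""
        ladder = np.concatenate([[0.0], np.geomspace(0.05e-6, 500e-6, 11)])
        x = np.log10(np.where(ladder > 0, ladder, 0.05e-6 / 100))
        f = 0.5 / (1.0 + 10.0 ** (1.0 * (x - np.log10(6.8e-6))))
        ds = IsothermalDataset(50.0, ladder, f, 2 * uM)
        assert ec50_hill(ds) == pytest.approx(6.8 * uM, rel=1e-3)

    def test_agrees_with_rigorous_fit_on_model_data(self):
        ds = make_dataset()
        fit = fit_isothermal(ds)
        assert ec50_hill(ds) == pytest.approx(fit.EC50, rel=0.05)

    def test_nonresponsive_data_rejected(self):
        ladder = np.concatenate([[0.0], np.geomspace(1e-7, 5e-4, 11)])
        f = np.linspace(0.4, 0.6, 12)  # increases with ligand
        ds = IsothermalDataset(50.0, ladder, f, 2 * uM)
        with pytest.raises(FlatDataError):
            ec50_hill(ds)


class TestDatasetValidation:
    def test_rejects_out_of_range_fractions(self):
        with pytest.raises(ValueError):
            IsothermalDataset(50.0, np.array([0.0, 1e-6, 1e-5, 1e-4]),
                              np.array([0.5, 0.4, 1.2, 0.1]), 2 * uM)

    def test_rejects_nonpositive_protein(self):
        with pytest.raises(ValueError):
            IsothermalDataset(50.0, np.array([0.0, 1e-6, 1e-5, 1e-4]),
                              np.array([0.5, 0.4, 0.3, 0.1]), 0.0)

    def test_sorts_by_concentration(self):
        ds = IsothermalDataset(50.0, np.array([1e-5, 0.0, 1e-6, 1e-4]),
                               np.array([0.2, 0.5, 0.4, 0.1]), 2 * uM)
        assert np.all(np.diff(ds.L_total) > 0)
        assert ds.f_u[0] == 0.5
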