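"""FRAP fitting and displacement-ratio mobility estimation."""

import numpy as np
import pytest

from coacwet import dynamics, synth
from coacwet.dynamics import (
    FrapCurve,
    classify_contact_lipids,
    d_apparent,
    displacement_ratio,
    fit_frap,
    frap_model,
    frap_ratio,
)


class TestFrapFit:
    def test_noiseless_parameter_recovery(self):
        curve, gt = synth.gen_frap_curve(I0=0.2, Imax=1.0, tau_half=5.0, noise=0.0)
        fit = fit_frap(curve)
        assert fit.I0 == pytest.approx(0.2, abs=1e-6)
        assert fit.Imax == pytest.approx(1.0, abs=1e-6)
        assert fit.tau_half == pytest.approx(5.0, abs=1e-6)

    def test_halftime_definition(self):
        """At x = tau_half the model sits exactly midway between I0 and Imax."""
        assert frap_model(5.0, 0.2, 1.0, 5.0) == pytest.approx((0.2 + 1.0) / 2)

    def test_noisy_recovery_within_five_percent(self):
        curve, _ = synth.gen_frap_curve(I0=0.2, Imax=1.0, tau_half=5.0,
                                        noise=0.01, n_points=100, seed=11)
        fit = fit_frap(curve)
        assert fit.tau_half == pytest.approx(5.0, rel=0.05)

    def test_scale_equivariance(self):
        curve, _ = synth.gen_frap_curve(noise=0.01, seed=3)
        fit1 = fit_frap(curve)
        scaled = FrapCurve(curve.time, 3.0 * curve.intensity)
        fit2 = fit_frap(scaled)
        assert fit2.I0 == pytest.approx(3 * fit1.I0, rel=1e-6)
        assert fit2.Imax == pytest.approx(3 * fit1.Imax, rel=1e-6)
        assert fit2.tau_half == pytest.approx(fit1.tau_half, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_frap(FrapCurve(np.arange(4.0), np.arange(4.0)))

    def test_unconstrained_halftime_refused(self):
        t = np.linspace(0, 1.0, 30)
        y = frap_model(t, 0.2, 1.0, 500.0)  # recovery far beyond window
        with pytest.raises(dynamics.FitError):
            fit_frap(FrapCurve(t, y))


class TestDiffusionAlgebra:
    def test_unit_substitution(self):
        assert d_apparent(1.0, 1.0, 1.0) == 0.25

    def test_quadratic_spot_size_scaling(self):
        assert d_apparent(2.0, 1.0, 1.0) == 4 * d_apparent(1.0, 1.0, 1.0)

    def test_experimental_spot_example(self):
        # 2 um bleach-spot diameter, tau_half = 2 s
        assert d_apparent(1.0, 1.0, 2.0) == pytest.approx(0.125)

    def test_ratio_identity_and_reciprocity(self):
        assert frap_ratio(1.0, 1.0) == 1.0
        assert frap_ratio(1.7, 1.0) == pytest.approx(1.7)
        assert frap_ratio(2.0, 3.0) * frap_ratio(3.0, 2.0) == pytest.approx(1.0)

    def test_geometry_cancels_between_equations(self):
        """D_app ratios from two fits equal the half-time ratio exactly."""
        tau_wet, tau_bare = 3.4, 2.0
        r0, nu = 1.0, 0.88
        ratio_d = d_apparent(r0, nu, tau_bare) / d_apparent(r0, nu, tau_wet)
        assert ratio_d == pytest.approx(frap_ratio(tau_wet, tau_bare), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            d_apparent(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            frap_ratio(0.0, 1.0)


class TestContactClassification:
    def test_no_polymers_all_far(self):
        state = synth.gen_small_cg_fixtures("patch128", seed=0)
        labels = classify_contact_lipids(state, cutoff=1.5)
        assert np.all(labels == "far")

    def test_constructed_contacts_counted(self):
        from coacwet.builders import _add_lipid, _state
        from coacwet.model import PairTable, SPECIES

        rng = np.random.default_rng(0)
        species, mol, pos, bonds = [], [], [], []
        bead = 0
        for i in range(10):
            bead = _add_lipid(species, mol, pos, bonds,
                              np.array([4.0 * i + 2.0, 5.0, 5.0]),
                              np.array([0.0, 0.0, 1.0]), i, bead)
        # one polymer bead 1.0 above the first k head beads
        k = 3
        for i in range(k):
            species.append(SPECIES["A"])
            mol.append(100 + i)
            pos.append(np.array([4.0 * i + 2.0, 5.0, 4.0]))
        state = _state(40.0, species, mol, pos, bonds, PairTable.default(), 0.0, rng)
        labels = classify_contact_lipids(state, cutoff=1.5)
        assert np.sum(labels == "contact") == k

    def test_contact_count_monotone_in_cutoff(self, rng):
        from coacwet.builders import _add_lipid, _state
        from coacwet.model import PairTable, SPECIES

        species, mol, pos, bonds = [], [], [], []
        bead = 0
        for i in range(30):
            bead = _add_lipid(species, mol, pos, bonds,
                              rng.uniform(5, 25, size=3),
                              np.array([0.0, 0.0, 1.0]), i, bead)
        for j in range(10):
            species.append(SPECIES["B"])
            mol.append(100 + j)
            pos.append(rng.uniform(5, 25, size=3))
        state = _state(30.0, species, mol, pos, bonds, PairTable.default(),
                       0.0, rng)
        counts = [np.sum(classify_contact_lipids(state, c) == "contact")
                  for c in (1.0, 1.5, 2.0, 4.0, 8.0, 13.0)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] > counts[0]


class TestDisplacementRatio:
    def test_null_case_unit_ratio(self, rng):
        times, pos, labels, _ = synth.gen_brownian_walkers(
            d_wet=1.0, d_bare=1.0, seed=5)
        labels = rng.permutation(labels)
        curve = displacement_ratio(times, pos, labels, n_boot=300)
        assert abs(curve.plateau - 1.0) < 3 * curve.plateau_se

    def test_known_ratio_two_recovered(self):
        times, pos, labels, _ = synth.gen_brownian_walkers(
            d_wet=1.0, d_bare=2.0, seed=6)
        curve = displacement_ratio(times, pos, labels, n_boot=300)
        assert curve.plateau == pytest.approx(2.0, abs=0.1)

    def test_translation_invariance(self):
        times, pos, labels, _ = synth.gen_brownian_walkers(
            n_per_class=50, n_steps=100, seed=7)
        c1 = displacement_ratio(times, pos, labels, n_boot=50)
        c2 = displacement_ratio(times, pos + 113.7, labels, n_boot=50)
        assert np.allclose(c1.ratio, c2.ratio)

    def test_incommensurate_grid_rejected(self):
        times, pos, labels, _ = synth.gen_brownian_walkers(
            n_per_class=30, n_steps=50, seed=8)
        with pytest.raises(ValueError):
            displacement_ratio(times, pos, labels, dt_star_grid=np.array([0.3]))

    def test_class_starvation_reported(self):
        times, pos, labels, _ = synth.gen_brownian_walkers(
            n_per_class=5, n_steps=50, seed=9)
        with pytest.raises(dynamics.EstimationError, match="contact|far"):
            displacement_ratio(times, pos, labels)

    @pytest.mark.parametrize("true_ratio", [1.0, 1.35, 1.6, 1.8, 2.5])
    def test_ratio_grid_unbiased_within_ci(self, true_ratio):
        """Plateau estimates cover the truth at n=200 walkers, 500 windows."""
        times, pos, labels, _ = synth.gen_brownian_walkers(
            d_wet=1.0, d_bare=true_ratio, n_per_class=200, n_steps=500,
            seed=int(true_ratio * 100))
        curve = displacement_ratio(times, pos, labels, n_boot=500)
        assert abs(curve.plateau - true_ratio) < 2.5 * curve.plateau_se + 0.02


def test_wetted_lipids_slower_and_adhesion_dependent(wetted_mobility_curves):
    """On simulated droplet-on-patch systems, lipids under the droplet are
    slower (ratio > 1), the more so the stronger the adhesion."""
    weak = wetted_mobility_curves[0.7]
    strong = wetted_mobility_curves[1.3]
    assert weak.plateau > 1.0
    assert strong.plateau > 1.0
    assert strong.plateau > weak.plateau
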