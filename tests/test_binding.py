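"""Binding isotherm: forward model, dilution correction, fit, geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memquench import (
    BindingIsotherm,
    InvalidArgumentError,
    MembraneGeometry,
    TitrationCurve,
    bound_fraction,
    correct_dilution,
    fit_binding,
    make_titration,
    mean_interparticle_distance,
    saturation_lp_ratio,
)
from memquench.binding import bound_fraction_mass_action
from memquench.synthetic import get_scenario


class TestBoundFraction:
    def test_zero_lipid_gives_zero(self):
        assert bound_fraction(0.0, 1e-7, 60.0, 1e8) == 0.0

    def test_mass_action_value(self):
        # frozen from direct evaluation of the closed form, cross-checked
        # against the quadratic mass-action solver
        theta = bound_fraction(1.2e-5, 1e-7, 60.0, 1e8)
        assert theta == pytest.approx(0.915571122977524, abs=1e-12)

    def test_saturating_affinity_limit(self):
        theta = bound_fraction(2 * 60 * 1e-7, 1e-7, 60.0, 1e15)
        assert theta > 0.999999

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lipid_total=-1e-6, protein_total=1e-7, n=60, K_a=1e8),
            dict(lipid_total=1e-6, protein_total=0.0, n=60, K_a=1e8),
            dict(lipid_total=1e-6, protein_total=1e-7, n=-2, K_a=1e8),
            dict(lipid_total=1e-6, protein_total=1e-7, n=60, K_a=np.inf),
            dict(lipid_total=np.nan, protein_total=1e-7, n=60, K_a=1e8),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            bound_fraction(**kwargs)

    def test_agrees_with_independent_equilibrium_solver(self):
        L = np.geomspace(1e-8, 1e-3, 12)
        for ka in np.geomspace(1e6, 1e11, 8):
            closed = bound_fraction(L, 1e-7, 55.0, ka)
            oracle = bound_fraction_mass_action(L, 1e-7, 55.0, ka)
            assert np.max(np.abs(closed - oracle)) < 1e-9

    @given(
        lp=st.floats(0.1, 500.0),
        ka=st.floats(1e5, 1e12),
        n=st.floats(5.0, 200.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_theta_bounded_and_monotone(self, lp, ka, n):
        P = 1e-7
        theta = bound_fraction(lp * P, P, n, ka)
        assert 0.0 <= theta <= 1.0
        assert bound_fraction(lp * P * 2, P, n, ka) >= theta - 1e-12
        assert bound_fraction(lp * P, P, n, ka * 2) >= theta - 1e-12


class TestDilutionCorrection:
    def test_no_additions_is_identity(self):
        p, lipid = correct_dilution(1e-7, 2000.0, [])
        assert p[0] == 1e-7 and lipid[0] == 0.0

    def test_single_addition_arithmetic(self):
        p, lipid = correct_dilution(1e-7, 1000.0, [(100.0, 20e-3)])
        assert p[1] == pytest.approx(1e-7 / 1.1)
        assert lipid[1] == pytest.approx(20e-3 * 100 / 1100)

    def test_split_addition_equals_single(self):
        _, one = correct_dilution(1e-7, 1000.0, [(200.0, 20e-3)])
        _, two = correct_dilution(1e-7, 1000.0, [(100.0, 20e-3), (100.0, 20e-3)])
        assert one[-1] == pytest.approx(two[-1])

    def test_protein_mass_conserved(self):
        adds = [(50.0, 10e-3)] * 6
        p, _ = correct_dilution(2e-7, 1500.0, adds)
        vols = 1500.0 + 50.0 * np.arange(7)
        assert np.allclose(p * vols, 2e-7 * 1500.0)

    def test_rejects_nonpositive_volumes(self):
        with pytest.raises(InvalidArgumentError):
            correct_dilution(1e-7, 0.0, [])
        with pytest.raises(InvalidArgumentError):
            correct_dilution(1e-7, 1000.0, [(-5.0, 20e-3)])


class TestBindingFitter:
    def test_noise_free_roundtrip_recovers_parameters(self, stni_chol):
        curve = make_titration(stni_chol, noise_cv=0.0)
        fit = fit_binding(curve)
        n, ka, fb = stni_chol.binding
        assert fit.n == pytest.approx(n, rel=1e-2)
        assert fit.K_a == pytest.approx(ka, rel=1e-2)
        assert fit.F_b_ratio == pytest.approx(fb, rel=1e-2)
        assert fit.gof.rmsd < 1e-6
        assert fit.gof.residuals.size == curve.intensity.size

    def test_noisy_recovery_of_stoichiometry(self, stni_chol):
        errs = []
        for seed in range(100):
            curve = make_titration(stni_chol, seed=seed, noise_cv=0.02)
            fit = fit_binding(curve)
            errs.append(abs(fit.n - stni_chol.binding[0]) / stni_chol.binding[0])
        assert np.median(errs) < 0.10

    def test_constant_intensity_flagged(self):
        P = np.full(8, 1e-7)
        L = np.linspace(0, 3e-5, 8)
        curve = TitrationCurve(P, L, np.ones(8))
        with pytest.warns(UserWarning):
            fit = fit_binding(curve)
        assert "no_response" in fit.flags
        assert fit.F_b_ratio == pytest.approx(1.0, abs=0.05)

    def test_unsaturated_curve_warned(self, stni_chol):
        cfg = get_scenario("StnI_chol", lp_grid=(0.0, 20.0, 10))
        curve = make_titration(cfg, noise_cv=0.0)
        with pytest.warns(UserWarning, match="saturation"):
            fit = fit_binding(curve)
        assert "no_saturation" in fit.flags

    def test_estimator_predict_matches_data(self, stni_chol):
        curve = make_titration(stni_chol, noise_cv=0.0)
        X = np.column_stack([curve.lipid_total, curve.protein_total])
        est = BindingIsotherm().fit(X, curve.intensity)
        assert np.allclose(est.predict(X), curve.intensity, atol=1e-8)
        params = est.get_params()
        assert params["ka_init"] == 1e8  # sklearn param plumbing intact


class TestSaturationRatio:
    def test_saturation_below_80_lipids_per_protein(self, stni_chol):
        fit = fit_binding(make_titration(stni_chol, noise_cv=0.0))
        lp = saturation_lp_ratio(fit, threshold=0.95, protein_total=1e-7)
        assert lp < 80.0

    def test_monotone_in_threshold(self, stni_chol):
        fit = fit_binding(make_titration(stni_chol, noise_cv=0.0))
        lp50 = saturation_lp_ratio(fit, 0.5, 1e-7)
        lp99 = saturation_lp_ratio(fit, 0.99, 1e-7)
        assert lp50 < lp99

    def test_higher_affinity_does_not_raise_ratio(self, stni_chol):
        fit = fit_binding(make_titration(stni_chol, noise_cv=0.0))
        lp = saturation_lp_ratio(fit, 0.95, 1e-7)
        import dataclasses

        stronger = dataclasses.replace(fit, K_a=fit.K_a * 10)
        assert saturation_lp_ratio(stronger, 0.95, 1e-7) <= lp + 1e-9

    def test_invalid_threshold(self, stni_chol):
        fit = fit_binding(make_titration(stni_chol, noise_cv=0.0))
        with pytest.raises(InvalidArgumentError):
            saturation_lp_ratio(fit, 1.0, 1e-7)


class TestGeometry:
    def test_monomer_edge_to_edge_distance(self):
        geom = MembraneGeometry(lipid_per_protein=180, lipid_area=50,
                                oligomer_size=1, protein_radius=11)
        d = mean_interparticle_distance(geom)
        assert d.center_to_center == pytest.approx(np.sqrt(180 * 50) / 2)
        assert d.edge_to_edge == pytest.approx(25.4, abs=0.5)

    def test_octamer_distance_exceeds_100(self):
        geom = MembraneGeometry(180, 50, oligomer_size=8, protein_radius=11)
        d = mean_interparticle_distance(geom)
        assert d.center_to_center > 100.0
        assert d.center_to_center == pytest.approx(134.16, abs=0.1)

    def test_sqrt_scaling_with_lipid_area(self):
        a = mean_interparticle_distance(MembraneGeometry(180, 35))
        b = mean_interparticle_distance(MembraneGeometry(180, 70))
        assert b.center_to_center == pytest.approx(
            a.center_to_center * np.sqrt(2)
        )

    def test_outer_leaflet_convention_halves_area(self):
        both = mean_interparticle_distance(MembraneGeometry(180, 50))
        outer = mean_interparticle_distance(MembraneGeometry(180, 50),
                                            leaflet="outer")
        assert outer.center_to_center == pytest.approx(
            both.center_to_center / np.sqrt(2)
        )

    def test_insane_lipid_area_rejected(self):
        with pytest.raises(InvalidArgumentError):
            MembraneGeometry(180, 120.0)


class TestTitrationCurveInvariants:
    def test_rejects_decreasing_lipid(self):
        with pytest.raises(InvalidArgumentError):
            TitrationCurve(np.full(5, 1e-7), np.array([0, 2, 1, 3, 4]) * 1e-6,
                           np.ones(5))

    def test_rejects_short_series(self):
        with pytest.raises(InvalidArgumentError):
            TitrationCurve(np.full(4, 1e-7), np.arange(4) * 1e-6, np.ones(4))
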