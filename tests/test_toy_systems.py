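"""Toy landscapes and their canonical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcfold.constants import R_GAS
from mcfold.errors import (
    IncompatibleModelsError,
    InvalidParameterError,
    OracleRangeError,
)
from mcfold.toy_systems import (
    THETA_HELIX,
    canonical_oracle_eval,
    make_chain_model,
    make_double_well,
    make_harmonic,
    mix_energies,
)


def _numeric_gradient(model, x, eps=1e-6):
    g = np.empty(model.dim)
    for i in range(model.dim):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (model.energy(xp) - model.energy(xm)) / (2 * eps)
    return g


@pytest.mark.parametrize(
    "factory",
    [
        lambda: make_harmonic(3, 2.0),
        lambda: make_double_well(1.0, 0.2),
        lambda: make_double_well(2.0, 0.0),
        lambda: make_chain_model(8, 1.0),
        lambda: mix_energies(make_harmonic(1, 1.0), make_harmonic(1, 4.0), 0.3),
    ],
)
def test_gradient_matches_central_difference(factory, rng):
    """Analytic gradients agree with central differences at random points."""
    model = factory()
    for _ in range(100):
        x = rng.normal(scale=1.5, size=model.dim)
        g = model.gradient(x)
        num = _numeric_gradient(model, x)
        assert np.allclose(g, num, rtol=1e-5, atol=1e-7)
        assert np.isfinite(model.energy(x))


def test_batch_evaluators_match_scalar_path(rng):
    model = make_chain_model(9, 0.7)
    xs = rng.normal(size=(40, model.dim))
    assert np.allclose(model.energies(xs), [model.energy(x) for x in xs])
    assert np.allclose(model.gradients(xs), [model.gradient(x) for x in xs])


class TestHarmonic:
    def test_energy_value(self):
        assert make_harmonic(1, 1.0).energy(np.array([2.0])) == pytest.approx(2.0)

    def test_equipartition_mean(self):
        """dim/2 * RT closed form (here RT = 0.6 -> mean 0.6 for dim 2)."""
        h = make_harmonic(2, 1.0)
        T = 0.6 / R_GAS
        assert h.oracle.mean_E(T) == pytest.approx(0.6, rel=1e-12)

    def test_variance_against_boltzmann_quadrature(self):
        """Gamma(1/2, RT) variance vs direct quadrature of the 1D integral."""
        h = make_harmonic(1, 4.0)
        T = 1.0 / R_GAS
        x = np.linspace(-8.0, 8.0, 200_001)
        w = np.exp(-0.5 * 4.0 * x**2)  # RT = 1
        e = 0.5 * 4.0 * x**2
        mean = np.trapezoid(w * e, x) / np.trapezoid(w, x)
        var = np.trapezoid(w * (e - mean) ** 2, x) / np.trapezoid(w, x)
        assert var == pytest.approx(0.5, rel=1e-6)
        assert h.oracle.var_E(T) == pytest.approx(var, rel=1e-6)

    @pytest.mark.parametrize("bad", [dict(dim=0, k=1.0), dict(dim=2, k=0.0)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(InvalidParameterError):
            make_harmonic(**bad)


class TestDoubleWell:
    def test_symmetric_minimum_and_barrier(self):
        dw = make_double_well(1.0, 0.0)
        assert dw.energy(np.array([1.0])) == pytest.approx(0.0)
        assert dw.energy(np.array([0.0])) == pytest.approx(1.0)

    def test_left_well_probability_against_trapezoid(self):
        """P(x<0) at RT = 0.3 vs an independent trapezoid quadrature."""
        dw = make_double_well(1.0, 0.2)
        T = 0.3 / R_GAS
        x = np.linspace(-6.0, 6.0, 400_001)
        e = (x**2 - 1.0) ** 2 + 0.2 * x
        w = np.exp(-(e - e.min()) / 0.3)
        expected = np.trapezoid(w[x < 0], x[x < 0]) / np.trapezoid(w, x)
        # the indicator's half-bin at x = 0 limits agreement to ~1e-4
        assert dw.oracle.prob(T, lambda c: c[0] < 0) == pytest.approx(expected, abs=1e-4)

    def test_mean_energy_against_trapezoid(self):
        dw = make_double_well(1.0, 0.2)
        T = 0.5 / R_GAS
        x = np.linspace(-6.0, 6.0, 400_001)
        e = (x**2 - 1.0) ** 2 + 0.2 * x
        w = np.exp(-(e - e.min()) / 0.5)
        expected = np.trapezoid(w * e, x) / np.trapezoid(w, x)
        assert dw.oracle.mean_E(T) == pytest.approx(expected, abs=1e-5)

    def test_ground_state_limit(self):
        dw = make_double_well(1.0, 0.0)
        assert dw.oracle.mean_E(50.0) == pytest.approx(0.0, abs=0.1)

    def test_requires_positive_barrier_scale(self):
        with pytest.raises(InvalidParameterError):
            make_double_well(0.0)


class TestChainModel:
    def test_large_bias_forces_helical_minimum(self):
        ch = make_chain_model(6, 50.0)
        helical = np.full(ch.dim, THETA_HELIX)
        extended = np.full(ch.dim, THETA_HELIX + np.pi)
        assert ch.energy(helical) < ch.energy(extended)
        # helical configuration is a stationary point and a minimum
        assert np.allclose(ch.gradient(helical), 0.0, atol=1e-12)

    def test_zero_bias_degenerate_minima(self):
        ch = make_chain_model(6, 0.0)
        helical = np.full(ch.dim, THETA_HELIX)
        extended = np.full(ch.dim, THETA_HELIX + np.pi)
        assert ch.energy(helical) == pytest.approx(ch.energy(extended), abs=1e-12)

    def test_oracle_against_grid_quadrature(self):
        """Transfer-matrix oracle vs a direct 4-D periodic grid quadrature.

        The periodic rectangle rule is spectrally accurate for the smooth
        Boltzmann factor and mean energy; the helical fraction involves a
        discontinuous window indicator, so its grid error is O(1/m)."""
        ch = make_chain_model(7, 1.0)
        T = 0.6 / R_GAS
        m = 45
        theta = np.linspace(-np.pi, np.pi, m, endpoint=False)
        grids = np.meshgrid(*([theta] * ch.dim), indexing="ij")
        xs = np.stack([g.ravel() for g in grids], axis=1)
        e = ch.energies(xs)
        w = np.exp(-(e - e.min()) / 0.6)
        z = np.sum(w)
        hel = ch.meta["is_helical"](xs).mean(axis=1)
        assert ch.oracle.mean_E(T) == pytest.approx(float(np.sum(w * e) / z), abs=1e-6)
        assert ch.oracle.mean_helical_fraction(T) == pytest.approx(
            float(np.sum(w * hel) / z), abs=5e-3
        )

    def test_too_short_chain_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_chain_model(3)


class TestMixEnergies:
    def test_endpoints_reproduce_components(self, rng):
        a, b = make_harmonic(2, 1.0), make_harmonic(2, 3.0)
        x = rng.normal(size=2)
        assert mix_energies(a, b, 0.0).energy(x) == pytest.approx(a.energy(x))
        assert mix_energies(a, b, 1.0).energy(x) == pytest.approx(b.energy(x))

    def test_mixing_rate_arithmetic(self):
        """omega = 0.75 blend of energies 4 and 8 gives 7."""
        a = make_harmonic(1, 2.0)   # E(2) = 4
        b = make_harmonic(1, 4.0)   # E(2) = 8
        mixed = mix_energies(a, b, 0.75)
        assert mixed.energy(np.array([2.0])) == pytest.approx(7.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(-3.0, 3.0))
    def test_swap_symmetry(self, omega, x):
        a, b = make_harmonic(1, 1.0), make_harmonic(1, 5.0)
        xa = np.array([x])
        e1 = mix_energies(a, b, omega).energy(xa)
        e2 = mix_energies(b, a, 1.0 - omega).energy(xa)
        assert e1 == pytest.approx(e2, rel=1e-12, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(IncompatibleModelsError):
            mix_energies(make_harmonic(1, 1.0), make_harmonic(2, 1.0), 0.5)

    def test_omega_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            mix_energies(make_harmonic(1, 1.0), make_harmonic(1, 2.0), 1.5)


class TestOracleContracts:
    def test_pdf_integrates_to_one(self, double_well, harmonic2):
        # closed form: machine-precision normalisation
        E = np.linspace(0.0, 30.0, 60_001)
        assert np.trapezoid(harmonic2.oracle.pdf_E(315.0, E), E) == pytest.approx(
            1.0, abs=1e-6
        )
        # quadrature oracle: pdf is a finite difference of the exact CDF,
        # so its trapezoid integral carries the kink-smoothing error of
        # the 1-D density of states
        E = np.linspace(-0.5, 30.0, 60_001)
        assert np.trapezoid(double_well.oracle.pdf_E(400.0, E), E) == pytest.approx(
            1.0, abs=1e-3
        )
        cdf = double_well.oracle.cdf_E(400.0, E)
        assert cdf[0] == 0.0 and cdf[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(cdf) >= 0)

    def test_mean_energy_monotone_in_temperature(
        self, double_well, harmonic2, chain8
    ):
        temps = [150.0, 300.0, 500.0, 900.0]
        for model in (double_well, harmonic2, chain8):
            means = [model.oracle.mean_E(t) for t in temps]
            assert np.all(np.diff(means) > 0)

    def test_out_of_range_temperature_rejected(self, double_well):
        with pytest.raises(OracleRangeError):
            double_well.oracle.mean_E(5.0)

    def test_eval_dispatch(self, harmonic2):
        T = 1.0 / R_GAS
        assert canonical_oracle_eval(harmonic2.oracle, T, "mean_E") == pytest.approx(1.0)
        assert canonical_oracle_eval(harmonic2.oracle, T, "var_E") == pytest.approx(1.0)
        with pytest.raises(InvalidParameterError):
            canonical_oracle_eval(harmonic2.oracle, T, "entropy")

    def test_quadrature_convergence_on_refinement(self, double_well):
        """Halving the step changes the partition sum by < 1e-6 relative."""
        oracle = double_well.oracle
        x, E, p = oracle._grid(400.0)
        # the cache is populated only after the convergence test passed;
        # recompute at double resolution and compare the mean energy
        fine = np.linspace(x[0], x[-1], 2 * len(x) - 1)
        e = double_well.energies(fine[:, None])
        w = np.exp(-(e - e.min()) / (R_GAS * 400.0))
        mean_fine = np.sum(w * e) / np.sum(w)
        assert oracle.mean_E(400.0) == pytest.approx(mean_fine, rel=1e-6)
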