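import math

import numpy as np
import pytest

from turingtda import (
    Classification,
    LinearisedSystem,
    Model,
    ModelParams,
    critical_alphas,
    dispersion,
    dominant_mode,
    enumerate_modes,
    ermentrout,
    linearise,
    max_unstable_wavenumber,
    steady_state,
    turing_conditions,
)
from turingtda.kinetics import kinetics_rhs


class TestSteadyState:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (ModelParams(Model.CIMA, 5.0, 1.0, 1.5, 1.0), (1.0, 2.0)),
            (ModelParams(Model.CIMA, 0.0, 1.0, 1.5, 1.0), (0.0, 1.0)),
            (ModelParams(Model.SCHNAKENBERG, 0.1, 0.9, 30.0), (1.0, 0.9)),
        ],
    )
    def test_known_states(self, params, expected):
        u, v = steady_state(params)
        assert u == pytest.approx(expected[0], abs=1e-12)
        assert v == pytest.approx(expected[1], abs=1e-12)

    def test_kinetics_vanish(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = ModelParams(
                Model.CIMA,
                alpha=rng.uniform(0.1, 20),
                beta=rng.uniform(0.05, 5),
                delta=rng.uniform(0.5, 3),
                sigma=rng.uniform(1, 20),
            )
            u, v = steady_state(p)
            f, g = kinetics_rhs(u, v, p)
            assert max(abs(f), abs(g)) <= 1e-12 * max(u, v, 1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(Model.CIMA, alpha=-1.0, beta=1.0, delta=1.5)
        with pytest.raises(ValueError):
            ModelParams(Model.CIMA, alpha=1.0, beta=0.0, delta=1.5)
        with pytest.raises(ValueError):
            ModelParams(Model.SCHNAKENBERG, alpha=1.0, beta=1.0, delta=30.0, sigma=2.0)


class TestLinearise:
    def test_cima_example(self):
        lin = linearise(ModelParams(Model.CIMA, 5.0, 1.0, 1.5, 1.0))
        assert (lin.f_u, lin.f_v, lin.g_u, lin.g_v) == (-1.0, -2.0, 1.0, -0.5)
        assert lin.d_u == 1.0
        assert lin.d_v == 1.5

    def test_schnakenberg_example(self):
        lin = linearise(ModelParams(Model.SCHNAKENBERG, 0.1, 0.9, 30.0))
        assert (lin.f_u, lin.f_v, lin.g_u, lin.g_v) == pytest.approx(
            (0.8, 1.0, -1.8, -1.0)
        )
        assert lin.d_v == 30.0

    def test_f_v_negative_for_cima(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            lin = linearise(
                ModelParams(Model.CIMA, rng.uniform(0.1, 20), 1.0, 1.5, 1.0)
            )
            assert lin.f_v < 0

    @pytest.mark.parametrize("model", [Model.CIMA, Model.SCHNAKENBERG])
    def test_matches_numeric_jacobian(self, model):
        """Closed-form Jacobian entries agree with central differences of
        the kinetics at the steady state (the sigma prefactor of the CIMA
        v equation is folded into the g entries)."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            if model is Model.CIMA:
                p = ModelParams(
                    model,
                    alpha=rng.uniform(0.5, 20),
                    beta=rng.uniform(0.05, 5),
                    delta=rng.uniform(0.5, 3),
                    sigma=rng.uniform(1, 20),
                )
            else:
                p = ModelParams(
                    model,
                    alpha=rng.uniform(0.01, 0.5),
                    beta=rng.uniform(0.2, 2),
                    delta=rng.uniform(10, 50),
                )
            u, v = steady_state(p)
            lin = linearise(p)
            eps = 1e-6 * max(1.0, u, v)
            for attr, du, dv in (
                ("f_u", eps, 0.0),
                ("f_v", 0.0, eps),
                ("g_u", eps, 0.0),
                ("g_v", 0.0, eps),
            ):
                which = 0 if attr.startswith("f") else 1
                hi = kinetics_rhs(u + du, v + dv, p)[which]
                lo = kinetics_rhs(u - du, v - dv, p)[which]
                numeric = (hi - lo) / (2 * eps)
                assert numeric == pytest.approx(getattr(lin, attr), rel=2e-6, abs=2e-6)


class TestTuringConditions:
    def test_inside_example(self, cima_lin):
        assert turing_conditions(cima_lin).in_space

    def test_outside_example_c3(self):
        lin = linearise(ModelParams(Model.CIMA, 5.0, 1.0, 1.5, 1.0))
        tc = turing_conditions(lin)
        assert not tc.c3
        assert not tc.in_space

    def test_c3_needs_positive_entry(self):
        lin = LinearisedSystem(f_u=-0.5, f_v=-1.0, g_u=1.0, g_v=-0.2, d_v=10.0)
        assert not turing_conditions(lin).c3

    def test_hopf_boundary_is_outside(self):
        # trace exactly zero: C1 is strict, so the point is excluded
        lin = LinearisedSystem(f_u=1.0, f_v=-2.0, g_u=2.0, g_v=-1.0, d_v=20.0)
        tc = turing_conditions(lin)
        assert not tc.c1
        assert tc.c2 and tc.c3 and tc.c4
        assert not tc.in_space


class TestDispersion:
    def test_h_at_zero_is_determinant(self, cima_lin):
        h, _ = dispersion(cima_lin, 0.0)
        det = cima_lin.f_u * cima_lin.g_v - cima_lin.f_v * cima_lin.g_u
        assert h == pytest.approx(det, abs=1e-14)

    def test_h_example(self, cima_lin):
        h, lam = dispersion(cima_lin, 0.66)
        assert h == pytest.approx(30 * 0.66**2 - 39.6 * 0.66 + 12, abs=1e-10)
        assert h < 0 < lam

    def test_h_equals_shifted_determinant(self, cima_lin):
        rng = np.random.default_rng(3)
        for k2 in rng.uniform(0, 3, 50):
            h, _ = dispersion(cima_lin, k2)
            J = np.array(
                [
                    [cima_lin.f_u - cima_lin.d_u * k2, cima_lin.f_v],
                    [cima_lin.g_u, cima_lin.g_v - cima_lin.d_v * k2],
                ]
            )
            assert h == pytest.approx(np.linalg.det(J), abs=1e-10)

    def test_negative_h_forces_positive_lambda(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            lin = linearise(
                ModelParams(
                    Model.CIMA,
                    alpha=rng.uniform(0.5, 20),
                    beta=rng.uniform(0.05, 5),
                    delta=rng.uniform(0.5, 3),
                    sigma=rng.uniform(1, 20),
                )
            )
            k2 = rng.uniform(0, 3)
            h, lam = dispersion(lin, k2)
            if h < 0:
                assert lam > 0


class TestModes:
    def test_unstable_count_example(self, cima_lin):
        records = enumerate_modes(cima_lin, 20, 20, 10)
        assert sum(r.unstable for r in records) == 13
        magnitudes = {r.m**2 + r.n**2 for r in records if r.unstable}
        assert magnitudes == {20, 25, 26, 29, 32, 34}

    def test_matches_bruteforce_sign_check(self, cima_lin):
        records = enumerate_modes(cima_lin, 20, 20, 10)
        count = 0
        for m in range(11):
            for n in range(11):
                if m == n == 0:
                    continue
                k2 = np.pi**2 * (m**2 + n**2) / 400
                h, lam = dispersion(cima_lin, k2)
                count += h < 0 < lam
        assert count == sum(r.unstable for r in records)

    def test_no_instability_outside_turing_space(self):
        lin = linearise(ModelParams(Model.CIMA, 5.0, 1.0, 1.5, 1.0))
        records = enumerate_modes(lin, 20, 20, 10)
        assert sum(r.unstable for r in records) == 0

    def test_coverage_error(self, cima_lin):
        with pytest.raises(ValueError, match="does not cover"):
            enumerate_modes(cima_lin, 20, 20, 3)

    def test_band_independent_of_domain(self, cima_lin):
        """Doubling the domain leaves the k^2 band unchanged, so (m, n)
        unstable on L iff (2m, 2n) unstable on 2L."""
        small = {(r.m, r.n) for r in enumerate_modes(cima_lin, 20, 20, 10) if r.unstable}
        large = {(r.m, r.n) for r in enumerate_modes(cima_lin, 40, 40, 20) if r.unstable}
        assert {(2 * m, 2 * n) for m, n in small} <= large

    def test_dominant_mode_example(self, cima_lin):
        m, n, gap = dominant_mode(cima_lin, 20, 20, 10)
        assert m**2 + n**2 == 26
        assert gap > 0

    def test_square_domain_tie(self, cima_lin):
        m, n, _ = dominant_mode(cima_lin, 20, 20, 10)
        swapped = [
            r
            for r in enumerate_modes(cima_lin, 20, 20, 10)
            if (r.m, r.n) == (n, m)
        ][0]
        best = [
            r
            for r in enumerate_modes(cima_lin, 20, 20, 10)
            if (r.m, r.n) == (m, n)
        ][0]
        assert swapped.lambda_val == pytest.approx(best.lambda_val, abs=1e-15)

    def test_single_unstable_k2_zero_gap(self, cima_lin):
        # on a 6x6 domain only (1,1) falls inside the unstable band
        m, n, gap = dominant_mode(cima_lin, 6, 6, 4)
        assert (m, n) == (1, 1)
        assert gap == 0.0

    def test_no_unstable_mode_raises(self):
        lin = linearise(ModelParams(Model.CIMA, 5.0, 1.0, 1.5, 1.0))
        with pytest.raises(ValueError, match="no unstable mode"):
            dominant_mode(lin, 20, 20, 10)


class TestMaxUnstableWavenumber:
    def test_degenerate_bounds_dominate_single_point(self, cima_lin):
        """With the scan collapsed to alpha=10, sigma=20 (beta scanned),
        the result's k^2 must be at least that of any unstable mode at
        beta=0.3."""
        m, n = max_unstable_wavenumber(
            Model.CIMA,
            alpha_bounds=(10.0, 10.0),
            sigma_bounds=(20.0, 20.0),
            delta=1.5,
            Lx=20,
            Ly=20,
        )
        best_req = max(m, n)
        at_point = max(
            max(r.m, r.n)
            for r in enumerate_modes(cima_lin, 20, 20, 10)
            if r.unstable
        )
        assert best_req >= at_point

    def test_small_max_index_raises(self):
        with pytest.raises(ValueError, match="does not cover"):
            max_unstable_wavenumber(
                Model.CIMA,
                alpha_bounds=(10.0, 10.0),
                sigma_bounds=(20.0, 20.0),
                delta=1.5,
                Lx=20,
                Ly=20,
                max_index=3,
            )

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="no Turing-feasible"):
            max_unstable_wavenumber(
                Model.CIMA,
                alpha_bounds=(0.0, 1.0),
                sigma_bounds=(1.0, 2.0),
                delta=1.5,
                Lx=20,
                Ly=20,
            )


class TestErmentrout:
    def test_stripes_at_alpha_5(self):
        res = ermentrout(ModelParams(Model.CIMA, 5.0, 1.0, 1.5, 20.0))
        assert res.classification is Classification.STRIPES
        assert res.b < res.a < 0

    def test_spots_at_alpha_1(self):
        res = ermentrout(ModelParams(Model.CIMA, 1.0, 1.0, 1.5, 20.0))
        assert res.classification is Classification.SPOTS
        assert res.a < -abs(res.b) < 0

    def test_classification_independent_of_delta_sigma(self):
        for alpha in (1.0, 5.0, 12.0, 15.0):
            r1 = ermentrout(ModelParams(Model.CIMA, alpha, 1.0, 1.5, 20.0))
            r2 = ermentrout(ModelParams(Model.CIMA, alpha, 1.0, 2.0, 10.0))
            assert r1.classification == r2.classification

    def test_singular_prefactor_raises(self):
        with pytest.raises(ValueError, match="singular"):
            ermentrout(ModelParams(Model.CIMA, math.sqrt(75.0), 1.0, 1.5, 20.0))

    def test_cima_only(self):
        with pytest.raises(ValueError):
            ermentrout(ModelParams(Model.SCHNAKENBERG, 0.1, 0.9, 30.0))


class TestCriticalAlphas:
    def test_printed_triple(self):
        a1, a2, a3 = critical_alphas(1.5, 20.0)
        assert a1 == pytest.approx(2.501, abs=5e-4)
        assert a2 == pytest.approx(11.581, abs=5e-4)
        assert a3 == pytest.approx(12.630, abs=5e-4)

    def test_independent_of_delta_sigma(self):
        t1 = critical_alphas(1.5, 20.0)
        t2 = critical_alphas(2.0, 10.0)
        assert t1 == pytest.approx(t2, abs=2e-4)

    def test_classification_bands(self):
        a1, a2, a3 = critical_alphas(1.5, 20.0)
        cls = lambda a: ermentrout(
            ModelParams(Model.CIMA, a, 1.0, 1.5, 20.0)
        ).classification
        assert cls(a1 - 0.05) is Classification.SPOTS
        assert cls(0.5 * (a1 + a2)) is Classification.STRIPES
        assert cls(0.5 * (a2 + a3)) is Classification.SPOTS
        assert cls(a3 + 0.05) is Classification.NEITHER
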