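import math

import numpy as np
import pytest

from homeofront import (
    StimulusProtocol,
    external_tangency_test,
    find_critical_durations,
    find_extrema,
    front_finite_T,
    front_rare_limit,
    tangency_locus,
    tangency_residual,
)
from homeofront.front_analytic import finite_front_y0, rare_front_y0
from homeofront.performance import cost_fields


def rare_protocol(I0=1.0, I1=2.0, T=1e9):
    return StimulusProtocol(I0=I0, I1=I1, t_amb=T, t_step=1.0)


class TestRareLimitFront:
    def test_economy_end(self):
        # y0 -> I0 as k -> 0: no internal variable needed at baseline.
        y = rare_front_y0(np.array([0.0, 1e-9, 1e-6]), I0=2.0)
        np.testing.assert_allclose(y, 2.0, atol=1e-5)
        assert rare_front_y0(np.array([0.0]), I0=2.0)[0] == pytest.approx(2.0)

    def test_effectiveness_end_plateau(self):
        y = rare_front_y0(np.array([50.0, 1e3, np.inf]), I0=1.0)
        np.testing.assert_allclose(y, 0.25, atol=1e-12)

    def test_monotone_decreasing_in_k(self):
        k = np.logspace(-3, 3, 300)
        y = rare_front_y0(k, I0=1.0)
        # Strictly decreasing until the plateau saturates to 1/4 in
        # double precision (the exponential terms fall below machine
        # epsilon near k ~ 40).
        assert np.all(np.diff(y[k < 30]) < 0)
        assert np.all(np.diff(y) <= 0)
        assert np.all((y >= 0.25) & (y <= 1.0))

    def test_plateau_flatness(self):
        # |dy0/dlog k| small over a wide range near the effectiveness end.
        k = np.logspace(0.8, 3, 200)
        y = rare_front_y0(k, I0=1.0)
        slope = np.abs(np.gradient(y, np.log(k)))
        assert np.all(slope[k > 8.0] < 5e-3)

    def test_front_object_connects_archetypes(self):
        front = front_rare_limit(1.0)
        assert front.archetypes["economy"] == (0.0, 1.0)
        assert front.archetypes["effectiveness"] == (1.0, 0.0)
        assert front.y0[0] == pytest.approx(1.0)
        assert front.y0[-1] == pytest.approx(0.0)   # edge segment end
        assert front.n_global_components() == 1

    def test_invalid_I0(self):
        with pytest.raises(ValueError):
            front_rare_limit(0.0)

    def test_I1_invariance(self):
        # Acceptance-grade property: fronts computed from the tangency
        # condition at I1 = 2 I0 and 10 I0 agree to 1e-8 at large T.
        k = np.logspace(-2, 2, 100)
        y_a = finite_front_y0(k, rare_protocol(I1=2.0))
        y_b = finite_front_y0(k, rare_protocol(I1=10.0))
        assert np.max(np.abs(y_a - y_b)) < 1e-8


class TestTangencyLocus:
    def test_rare_front_satisfies_tangency(self):
        proto = rare_protocol(T=1e7)
        k = np.logspace(-1.5, 1.5, 50)
        y = rare_front_y0(k, proto.I0)
        res = tangency_residual(k, y, proto)
        assert np.max(np.abs(res)) < 1e-6

    def test_finite_T_curve_zeroes_residual(self):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=2.0, t_step=1.0)
        k = np.logspace(-2, 2, 60)
        y = finite_front_y0(k, proto)
        res = tangency_residual(k, y, proto)
        assert np.max(np.abs(res)) < 1e-10

    def test_off_locus_residual_bounded_away_from_zero(self, rng):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=2.0, t_step=1.0)
        k = rng.uniform(0.5, 5.0, size=10)
        y_on = finite_front_y0(k, proto)
        res = tangency_residual(k, y_on + 0.15, proto)
        assert np.all(np.abs(res) > 1e-3)

    def test_locus_sampling_and_polish_agree(self):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=2.0, t_step=1.0)
        kc, y = tangency_locus(proto, n_samples=64)
        kc_p, y_p = tangency_locus(proto, n_samples=64, polish=True)
        np.testing.assert_allclose(y, y_p, atol=1e-9)

    def test_economy_anchor_for_all_T(self):
        # The locus starts at (k = 0, y0 = I0) at every ambient interval.
        for T in (0.2, 1.0, 10.0):
            proto = StimulusProtocol(I0=1.3, I1=2.0, t_amb=T, t_step=1.0)
            assert finite_front_y0(np.array([1e-8]), proto)[0] == pytest.approx(
                1.3, abs=1e-6)


def _locally_dominated(k, y0, protocol, eps=1e-3):
    """Contour-following oracle for local Pareto optimality.

    Walks a short distance each way along the effectiveness-cost contour
    through the point and reports whether the economy cost drops: a
    direct brute-force probe of the neighborhood (the dominating lens of
    a tangency point is O(eps^2) thin, so plain ball sampling misses it).
    """
    from scipy.optimize import brentq
    from homeofront.performance import cost_gradients

    def J(kk, yy):
        a, b = cost_fields(np.array([kk]), np.array([yy]), protocol)
        return float(a[0]), float(b[0])

    J1k, J1y, _, _ = (float(v[0]) for v in cost_gradients(
        np.array([k]), np.array([y0]), protocol))
    g1 = np.array([J1k, J1y])
    n1 = g1 / np.linalg.norm(g1)
    t_hat = np.array([-n1[1], n1[0]])
    J1p, J2p = J(k, y0)
    scale = np.array([max(abs(k), 1.0), max(abs(y0), 1.0)])
    best = 0.0
    for s in (eps, -eps):
        base = np.array([k, y0]) + s * t_hat * scale
        f = lambda a: J(base[0] + a * n1[0] * scale[0],
                        base[1] + a * n1[1] * scale[1])[0] - J1p
        try:
            alpha = brentq(f, -5 * eps, 5 * eps, xtol=1e-15)
        except ValueError:
            continue
        x = base + alpha * n1 * scale
        best = min(best, J(x[0], x[1])[1] - J2p)
    return best < -1e-10


class TestExternalTangency:
    def test_rare_front_interior_points_external(self):
        proto = rare_protocol(T=1e5)
        for k in (0.3, 1.0, 3.0, 10.0):
            y = float(rare_front_y0(np.array([k]), proto.I0)[0])
            assert external_tangency_test((k, y), proto) == "external"

    def test_agrees_with_local_dominance_oracle(self):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=0.15, t_step=1.0)
        kc = np.linspace(0.05, 0.95, 19)
        k = kc / (1 - kc)
        y = finite_front_y0(k, proto)
        checked = 0
        for ki, yi in zip(k, y):
            if yi < 0:
                continue
            verdict = external_tangency_test((ki, yi), proto)
            if verdict == "indeterminate":
                continue
            dominated = _locally_dominated(ki, yi, proto)
            assert (verdict == "internal") == dominated, (ki, yi)
            checked += 1
        assert checked >= 10

    def test_small_T_curve_has_internal_stretch(self):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=0.1, t_step=1.0)
        kc = np.linspace(0.05, 0.95, 61)
        k = kc / (1 - kc)
        y = finite_front_y0(k, proto)
        verdicts = [external_tangency_test((ki, yi), proto)
                    for ki, yi in zip(k, y)]
        assert "internal" in verdicts and "external" in verdicts


class TestFiniteTFront:
    def test_converges_to_rare_limit(self):
        k = np.logspace(-1, 1.5, 60)
        y_inf = rare_front_y0(k, 1.0)
        err_prev = np.inf
        for T in (10.0, 100.0, 1000.0):
            proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=T, t_step=1.0)
            err = np.max(np.abs(finite_front_y0(k, proto) - y_inf))
            assert err < err_prev
            err_prev = err
        assert err_prev < 5e-3

    def test_rare_protocol_rejected(self):
        with pytest.raises(ValueError):
            front_finite_T(rare_protocol(T=math.inf))

    def test_large_T_component_structure(self):
        # At any finite interval the front splits into the curve arc plus
        # the archetype edge piece; above the critical durations the curve
        # arc itself is a single contiguous run with no internal stretch.
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=2.0, t_step=1.0)
        front, report = front_finite_T(proto, n_samples=200,
                                       oracle_resolution=400,
                                       with_critical_durations=False)
        assert front.n_global_components() == 2
        curve = front.segment == "curve"
        mask = (front.cls[curve] == "global").astype(int)
        assert int(np.sum(np.diff(np.r_[0, mask, 0]) == 1)) == 1
        # The internally tangent stretch is confined to the unstable
        # region near the effectiveness archetype at this interval.
        for poly in report.separatrix:
            assert np.all(poly[:, 0] > 0.7)
        assert set(front.cls) <= {"global", "local", "tangent_dominated"}

    def test_rare_front_single_component(self):
        assert front_rare_limit(1.0).n_global_components() == 1

    def test_small_T_two_components_and_separatrix(self):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=0.1, t_step=1.0)
        front, report = front_finite_T(proto, n_samples=300,
                                       oracle_resolution=500,
                                       with_critical_durations=False)
        assert front.n_global_components() == 2
        assert len(report.separatrix) >= 1

    def test_global_samples_not_dominated_in_oracle(self):
        from homeofront import grid_front, dominance_mask

        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=1.0, t_step=1.0)
        front, _ = front_finite_T(proto, n_samples=150, oracle_resolution=400,
                                  with_critical_durations=False)
        sel = front.global_mask & (front.segment == "curve")
        J1, J2 = cost_fields(front.k[sel], front.y0[sel], proto)
        # Pool front samples with a dense grid; the front samples must
        # survive the joint dominance filter.
        g = grid_front(((0.0, 1.0), (0.0, 1.5)), 120, proto)
        mask = dominance_mask(np.concatenate([J1, g.J_eff]),
                              np.concatenate([J2, g.J_econ]))
        assert np.all(mask[: len(J1)])

    def test_front_csv(self, tmp_path):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=1.0, t_step=1.0)
        front, _ = front_finite_T(proto, n_samples=50, oracle_resolution=200,
                                  with_critical_durations=False)
        path = tmp_path / "front.csv"
        front.write_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "kc,k,y0,class,J_eff,J_econ,T_amb,I0"


class TestExtremaAndCriticalDurations:
    def test_one_maximum_per_cost_above_critical(self):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=1.0, t_step=1.0)
        report = find_extrema(proto)
        assert report.n_maxima("effectiveness") == 1
        assert report.n_maxima("economy") == 1
        assert report.n_saddles("effectiveness") == 0
        assert report.n_saddles("economy") == 0

    def test_two_maxima_one_saddle_below_critical(self):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=0.08, t_step=1.0)
        report = find_extrema(proto)
        assert report.n_maxima("economy") == 2
        assert report.n_saddles("economy") == 1
        assert report.n_maxima("effectiveness") == 2
        assert report.n_saddles("effectiveness") == 1

    def test_critical_durations_ordered(self):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=1.0, t_step=1.0)
        tc = find_critical_durations(proto)
        assert tc["economy"] is not None and tc["effectiveness"] is not None
        # The economy regime changes first as the interval shrinks.
        assert tc["economy"] > tc["effectiveness"] > 0
        # For the quadratic costs the economy threshold is t_step / 3.
        assert tc["economy"] == pytest.approx(1.0 / 3.0, rel=1e-3)

    def test_counts_flip_exactly_at_detected_thresholds(self):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=1.0, t_step=1.0)
        tc = find_critical_durations(proto)
        for task in ("effectiveness", "economy"):
            above = StimulusProtocol(I0=1.0, I1=2.0, t_amb=tc[task] * 1.05,
                                     t_step=1.0)
            below = StimulusProtocol(I0=1.0, I1=2.0, t_amb=tc[task] * 0.95,
                                     t_step=1.0)
            assert find_extrema(above).n_maxima(task) == 1
            assert find_extrema(below).n_maxima(task) == 2

    def test_interior_classification_against_finite_difference_oracle(self):
        proto = StimulusProtocol(I0=1.0, I1=2.0, t_amb=0.08, t_step=1.0)
        report = find_extrema(proto)
        interior = [e for e in report.extrema if e["location"] == "interior"]
        assert interior
        for e in interior:
            which = 0 if e["task"] == "effectiveness" else 1
            k0, y0 = e["k"], e["y0"]
            # Probe a small circle of directions (saddles can have a
            # narrow negative cone that axis-aligned stencils miss).
            h = 1e-3
            theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
            kk = k0 + h * np.cos(theta) * max(k0, 1.0)
            yy = y0 + h * np.sin(theta)
            J = cost_fields(kk, yy, proto)[which]
            centre = float(cost_fields(np.array([k0]),
                                       np.array([y0]), proto)[which][0])
            if e["kind"] == "maximum":       # performance max = cost min
                assert np.all(J >= centre - 1e-12)
            else:
                assert np.any(J < centre - 1e-14)
                assert np.any(J > centre + 1e-14)
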