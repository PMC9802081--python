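"""Glide polars, maximum glide ratios, and circling envelopes."""

import math

import numpy as np
import pytest

from paleosoar.morphology import (
    BIRD_DRAG,
    PTEROSAUR_FAIRED_DRAG,
    Environment,
    SpeciesMorphology,
)
from paleosoar.thermal import (
    StallError,
    airspeed_at_cl,
    ask14_sink,
    circling_envelope_optimal,
    circling_envelope_parametric,
    glide_sink,
    limiting_radius,
    max_glide_ratio,
    min_sink,
    profile_drag_coefficient,
    span_factor,
)


class TestProfileDrag:
    def test_minimum_of_parabola(self):
        assert profile_drag_coefficient(0.77, BIRD_DRAG) == pytest.approx(0.019)

    def test_bird_at_clmax(self):
        assert profile_drag_coefficient(1.8, BIRD_DRAG) == pytest.approx(0.0508, abs=1e-4)

    def test_pterosaur_faired_at_clmax(self):
        assert profile_drag_coefficient(2.0, PTEROSAUR_FAIRED_DRAG) == pytest.approx(
            0.16, abs=1e-3
        )

    def test_negative_cl_rejected(self):
        with pytest.raises(ValueError):
            profile_drag_coefficient(-0.1, BIRD_DRAG)


class TestSpanFactor:
    def test_unity_at_stall(self):
        assert span_factor(10.0, 10.0, "linear_reduction", 5.0) == pytest.approx(1.0)

    def test_linear_midrange(self):
        assert span_factor(30.0, 10.0, "linear_reduction", 5.0) == pytest.approx(0.5)

    def test_fixed_rule(self):
        assert span_factor(37.0, 10.0, "fixed", 6.0) == 1.0

    def test_error_beyond_bstop(self):
        with pytest.raises(ValueError):
            span_factor(51.0, 10.0, "linear_reduction", 5.0)


def test_quetzalcoatlus_sink_worked_example(quetzalcoatlus, env):
    # term-by-term hand evaluation: profile+parasite 0.941, induced 1.034
    pt = glide_sink(15.0, quetzalcoatlus, env)
    assert pt.Vsink == pytest.approx(1.98, abs=0.02)
    assert pt.beta == 1.0


def test_stall_error_below_vs(albatross, env):
    with pytest.raises(StallError):
        glide_sink(10.0, albatross, env)


def test_ask14_polar_worked_example(reg, env):
    assert float(ask14_sink(20.0)) == pytest.approx(0.916, abs=1e-3)
    pt = glide_sink(20.0, reg["ask14"], env)
    assert pt.Vsink == pytest.approx(0.916, abs=1e-3)


def test_polar_identity_sink_formula(albatross, env):
    """The substituted polar equals the raw-coefficient form of the sink
    equation at random speeds (algebraic identity between the two forms)."""
    rng = np.random.default_rng(3)
    vs = albatross.stall_speed(env)
    mg = albatross.m * env.g
    for V in rng.uniform(vs, 3.0 * vs, size=12):
        pt = glide_sink(float(V), albatross, env)
        beta = pt.beta
        cdpro = profile_drag_coefficient(pt.CL, albatross.drag)
        direct = (
            0.5 * env.rho * (albatross.Sw / mg) * (beta * cdpro + 0.01) * V**3
            + (mg / albatross.Sw)
            * (2 * 1.1 / (env.rho * albatross.Ra * beta**2 * math.pi))
            / V
        )
        assert pt.Vsink == pytest.approx(direct, rel=1e-12)


def test_max_glide_ratio_speed_mass_scaling(env):
    """With the profile drag frozen at its minimum (kpro -> 0 effectively via
    a tiny curvature) and fixed span, quadrupling the mass leaves the best
    glide ratio unchanged and doubles the speed at which it occurs."""
    import dataclasses

    from paleosoar import morphology as M

    frozen = M.DragPolarParams(0.019, 1e-9, 0.77)
    old = dict(M.DRAG_SETS)
    M.DRAG_SETS["frozen"] = frozen
    try:
        base = SpeciesMorphology("s", "bird", 5.0, 2.0, 0.4, drag_set="frozen",
                                 span_rule="fixed", category="thermal_soarer")
        heavy = dataclasses.replace(base, name="s4", m=20.0)
        r1, v1, _ = max_glide_ratio(base, env)
        r2, v2, _ = max_glide_ratio(heavy, env)
        assert r2 == pytest.approx(r1, rel=1e-4)
        assert v2 == pytest.approx(2 * v1, rel=1e-3)
    finally:
        M.DRAG_SETS.clear()
        M.DRAG_SETS.update(old)


def test_max_glide_ratio_matches_grid_oracle(env):
    """Bounded-search optimum equals a dense grid search (dV = 0.01 m/s)."""
    from paleosoar.synthetic import SynthConfig, gen_morphologies

    for morph in gen_morphologies(SynthConfig(n_species=5, seed=11), env):
        ratio, v_at, _ = max_glide_ratio(morph, env)
        vs = morph.stall_speed(env)
        from paleosoar.thermal import _admissible_speed_range

        lo, hi = _admissible_speed_range(morph, env)
        grid = np.arange(lo * (1 + 1e-9), hi, 0.01)
        best = max(glide_sink(float(v), morph, env).glide_ratio for v in grid)
        assert ratio == pytest.approx(best, rel=0.005)


def test_extinct_ratio_range(extinct_configs, env):
    ratios = [round(max_glide_ratio(m, env)[0]) for m in extinct_configs]
    assert len(ratios) == 28
    assert min(ratios) >= 10
    assert max(ratios) <= 17


def test_polar_convexity_unique_min(albatross, env):
    vs = albatross.stall_speed(env)
    grid = np.linspace(vs * 1.001, 4.0 * vs, 300)
    sinks = np.array([glide_sink(float(v), albatross, env).Vsink for v in grid])
    # single sign change of the discrete derivative -> unique interior minimum
    dsign = np.sign(np.diff(sinks))
    changes = np.count_nonzero(np.diff(dsign[dsign != 0]))
    assert changes == 1


class TestCircling:
    def test_limiting_radius_albatross(self, albatross, env):
        assert limiting_radius(albatross, env) == pytest.approx(12.9, abs=0.1)

    def test_optimal_envelope_approaches_straight_min_sink(self, albatross, env):
        best = min_sink(albatross, env).Vsink
        far = circling_envelope_optimal([1e5], albatross, env)[0]
        assert far.Vsink_circle >= best - 1e-9
        assert far.Vsink_circle == pytest.approx(best, rel=2e-3)

    def test_infeasible_radius_marked(self, albatross, env):
        pt = circling_envelope_optimal([5.0], albatross, env)[0]
        assert not pt.feasible

    def test_parametric_phi_to_zero_limit(self, albatross, env):
        ms = min_sink(albatross, env)
        pt = circling_envelope_parametric([1e-4], albatross, env, CLstar="min_sink")[0]
        assert pt.Vsink_circle == pytest.approx(ms.Vsink, rel=1e-6)

    def test_parametric_radius_at_40_degrees(self, albatross, env):
        phi = math.radians(40.0)
        pt = circling_envelope_parametric([phi], albatross, env, CLstar="min_sink")[0]
        v = airspeed_at_cl(pt.CLstar, albatross, env)
        assert pt.r == pytest.approx(v**2 / (9.81 * math.sin(phi)), rel=1e-9)

    def test_clstar_above_clmax_rejected(self, albatross, env):
        with pytest.raises(ValueError):
            circling_envelope_parametric([0.3], albatross, env, CLstar=2.5)

    def test_optimal_dominates_parametric(self, reg, env):
        """Definition 1 minimizes over a superset, so its sink can never
        exceed definition 2's at the same radius."""
        for name in ("wandering_albatross", "quetzalcoatlus"):
            morph = reg[name]
            phis = np.radians(np.linspace(5.0, 40.0, 8))
            par = circling_envelope_parametric(phis, morph, env, CLstar="min_sink")
            radii = [p.r for p in par]
            opt = circling_envelope_optimal(radii, morph, env)
            for o, p in zip(opt, par):
                assert o.Vsink_circle <= p.Vsink_circle * (1 + 1e-9)

    def test_optimal_matches_grid_oracle(self, reg, env):
        """2-D grid search over (CL*, phi) confirms the nested optimizer."""
        for name in ("wandering_albatross", "quetzalcoatlus", "california_condor"):
            morph = reg[name]
            r_lim = limiting_radius(morph, env)
            radii = np.geomspace(1.3 * r_lim, 2e3, 10)
            opt = circling_envelope_optimal(radii, morph, env)
            cls = np.linspace(0.2, morph.CLmax, 400)
            for r, pt in zip(radii, opt):
                best = np.inf
                for cl in cls:
                    try:
                        v = airspeed_at_cl(float(cl), morph, env)
                    except ValueError:
                        continue
                    s = v**2 / (env.g * r)
                    if s >= math.sin(math.radians(89.9)):
                        continue
                    phi = math.asin(s)
                    vsink = glide_sink(v, morph, env).Vsink / math.cos(phi) ** 1.5
                    best = min(best, vsink)
                assert pt.Vsink_circle == pytest.approx(best, rel=0.01)

    def test_airspeed_at_cl_self_consistency(self, albatross, env):
        """V(CL*) inverts the equilibrium CL(V) under the span rule."""
        for cl in (0.6, 1.0, 1.5, 1.8):
            v = airspeed_at_cl(cl, albatross, env)
            pt = glide_sink(v, albatross, env)
            assert pt.CL == pytest.approx(cl, rel=1e-8)


def test_min_sink_scales_with_sqrt_wing_loading(env):
    """log-log slope of minimum sink vs wing loading is 1/2 for fixed-span
    wings with frozen profile drag and a common aspect ratio."""
    from paleosoar import morphology as M

    frozen = M.DragPolarParams(0.019, 1e-9, 0.77)
    old = dict(M.DRAG_SETS)
    M.DRAG_SETS["frozen"] = frozen
    try:
        loadings = np.array([40.0, 80.0, 160.0, 240.0])
        sinks = []
        for i, wl in enumerate(loadings):
            m = 10.0
            Sw = m * env.g / wl
            b = math.sqrt(8.0 * Sw)
            morph = SpeciesMorphology(f"wl{i}", "bird", m, b, Sw, drag_set="frozen",
                                      span_rule="fixed", category="thermal_soarer")
            sinks.append(min_sink(morph, env).Vsink)
        slope = np.polyfit(np.log(loadings), np.log(sinks), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.02)
    finally:
        M.DRAG_SETS.clear()
        M.DRAG_SETS.update(old)


def test_circle_radius_proportional_to_wing_loading(env):
    """At fixed bank angle and CL*, radius is linear in wing loading."""
    phi = math.radians(30.0)
    radii, loadings = [], [50.0, 100.0, 200.0]
    for i, wl in enumerate(loadings):
        m = 8.0
        Sw = m * env.g / wl
        b = math.sqrt(10.0 * Sw)
        morph = SpeciesMorphology(f"r{i}", "pterosaur", m, b, Sw,
                                  category="extinct")
        pt = circling_envelope_parametric([phi], morph, env, CLstar=1.2)[0]
        radii.append(pt.r)
    ratios = np.array(radii) / np.array(loadings)
    assert np.allclose(ratios, ratios[0], rtol=1e-9)
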