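"""Equilibria: survival condition, boundary/coexistence points, nullclines, labels."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from delaylv import (
    KernelSpec,
    SpeciesParams,
    TwoSpeciesModel,
    boundary_equilibrium,
    classify,
    coexistence_equilibrium,
    derive,
    discrete_limit_params,
    equilibrium_state,
    nullclines,
    rhs,
    survival_ratio_threshold,
    survives,
)
from delaylv.errors import DegenerateRegimeError, ExistenceError, ParameterError
from delaylv.kernels import percentile_shift

from conftest import random_model


def _species(r=1.0, m=0.3, mu=0.3, a=1.0, b=0.1, p=1, beta=1.0, delta=None, q=0.99):
    if delta is None:
        delta = percentile_shift(p, beta, q)
    return SpeciesParams(r, m, mu, a, b, KernelSpec(p, beta, delta))


class TestSurvives:
    def test_fast_maturation_survives(self):
        assert survives(_species(beta=1.0))

    def test_slow_maturation_goes_extinct(self):
        # mean delay 10 with r/m = 10/3: reproduction cannot compensate
        assert not survives(_species(beta=0.1))

    def test_no_immature_mortality_always_survives(self):
        sp = SpeciesParams(1.0, 0.3, 1e-300, 1.0, 0.1, KernelSpec(1, 1e-3, 5.0))
        assert survives(sp)


class TestSurvivalRatioThreshold:
    def test_reference_value(self):
        # boundary of the joint-extinction region: p/beta = 7.78 at p=1
        assert survival_ratio_threshold(1.0, 0.3, 0.3, 1) == pytest.approx(7.7778, abs=1e-3)

    def test_p20_value_by_independent_root_finding(self):
        def A_of_beta(beta, p):
            return math.log(0.3) + p * (math.log(beta + 0.3) - math.log(beta))

        beta_star = brentq(lambda b: A_of_beta(b, 20), 1e-3, 100.0, xtol=1e-12)
        assert survival_ratio_threshold(1.0, 0.3, 0.3, 20) == pytest.approx(
            20 / beta_star, rel=1e-9
        )
        assert survival_ratio_threshold(1.0, 0.3, 0.3, 20) == pytest.approx(4.14, abs=5e-3)

    def test_decreases_with_shape(self):
        # more deterministic maturation tolerates shorter delays only
        th = [survival_ratio_threshold(1.0, 0.3, 0.3, p) for p in (1, 2, 5, 20, 100)]
        assert all(a > b for a, b in zip(th, th[1:]))

    def test_mu_zero_sentinel(self):
        assert survival_ratio_threshold(1.0, 0.3, 0.0, 1) == math.inf

    def test_requires_r_above_m(self):
        with pytest.raises(ParameterError):
            survival_ratio_threshold(0.3, 0.3, 0.1, 1)


class TestBoundaryEquilibrium:
    def test_reference_value(self):
        sp = _species(m=0.2, mu=0.2, b=0.5, beta=0.5)
        d = derive(sp)
        assert boundary_equilibrium(sp) == pytest.approx(-d.A / d.tau, rel=1e-12)
        assert boundary_equilibrium(sp) == pytest.approx(0.6429, abs=2e-4)

    def test_inverse_in_intraspecific_coefficient(self):
        base = boundary_equilibrium(_species(m=0.2, mu=0.2, beta=0.5))
        doubled = boundary_equilibrium(_species(m=0.2, mu=0.2, a=2.0, beta=0.5))
        assert doubled == pytest.approx(base / 2, rel=1e-12)

    def test_mu_zero_untruncated_reduction(self):
        # N_bar -> (beta/a) ln(r/m) for p=1, no immature mortality, no truncation
        sp = SpeciesParams(1.0, 0.25, 1e-300, 0.8, 0.0, KernelSpec(1, 0.6, 1e4))
        assert boundary_equilibrium(sp) == pytest.approx(
            0.6 / 0.8 * math.log(1 / 0.25), rel=1e-9
        )

    def test_raises_without_survival(self):
        with pytest.raises(ExistenceError):
            boundary_equilibrium(_species(beta=0.1))


class TestCoexistenceEquilibrium:
    def test_symmetric_reduction(self):
        # identical species, a=1, b=0.5: N_bar = -A/(tau*(a+b)) for both
        sp = _species(m=0.2, mu=0.2, b=0.5, beta=0.5)
        m = TwoSpeciesModel(sp, sp)
        d = derive(sp)
        expected = -d.A / (d.tau * 1.5)
        N1, N2 = coexistence_equilibrium(m)
        assert N1 == pytest.approx(expected, rel=1e-12)
        assert N2 == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.4286, abs=2e-4)

    def test_symmetry_for_identical_species(self, rng):
        for _ in range(10):
            mdl = random_model(rng)
            sym = TwoSpeciesModel(mdl.species1, mdl.species1)
            N1, N2 = coexistence_equilibrium(sym)
            assert N1 == pytest.approx(N2, rel=1e-12)

    def test_equals_nullcline_linear_solve(self, rng):
        # independent 2x2 linear-algebra route
        for _ in range(20):
            mdl = random_model(rng)
            l1, l2 = nullclines(mdl)
            M = np.array([[l1.coef_self, l1.coef_other], [l2.coef_other, l2.coef_self]])
            try:
                pt = coexistence_equilibrium(mdl)
            except DegenerateRegimeError:
                continue
            sol = np.linalg.solve(M, [l1.constant, l2.constant])
            assert pt[0] == pytest.approx(sol[0], abs=1e-10)
            assert pt[1] == pytest.approx(sol[1], abs=1e-10)

    def test_degenerate_regime_raises(self):
        sp = _species(b=1.0)
        with pytest.raises(DegenerateRegimeError):
            coexistence_equilibrium(TwoSpeciesModel(sp, sp))


class TestNullclines:
    def test_no_interspecific_coupling_gives_axis_lines(self):
        sp1 = _species(m=0.2, mu=0.2, b=0.0, beta=0.5)
        sp2 = _species(m=0.2, mu=0.2, b=0.0, beta=0.5, p=2, q=0.99)
        m = TwoSpeciesModel(sp1, sp2)
        l1, l2 = nullclines(m)
        assert l1.coef_other == 0.0 and l2.coef_other == 0.0
        assert l1.constant / l1.coef_self == pytest.approx(
            boundary_equilibrium(sp1), rel=1e-12
        )
        assert l2.constant / l2.coef_self == pytest.approx(
            boundary_equilibrium(sp2), rel=1e-12
        )

    def test_growth_rate_vanishes_on_line(self, rng):
        # substituting points on nullcline i into the adult equation of the
        # chain system makes dN_i/dt vanish
        for _ in range(5):
            mdl = random_model(rng)
            l1, l2 = nullclines(mdl)
            for which, line in ((0, l1), (1, l2)):
                for N_self in np.linspace(0.05, 1.5, 5):
                    N_other = float(line.solve_other(N_self)) if line.coef_other else 0.3
                    if line.coef_other == 0:
                        N_self = line.constant / line.coef_self
                    if N_other < 0:
                        continue
                    pt = (N_self, N_other) if which == 0 else (N_other, N_self)
                    st = equilibrium_state(mdl, *pt)
                    dN = rhs(0.0, st, mdl)[mdl._blocks[which].iN]
                    assert abs(dN) < 1e-10


class TestClassify:
    def test_survival_failure_dominates_competition(self):
        # species 2 below the survival threshold: extinct regardless of b
        m = TwoSpeciesModel(_species(beta=1.0), _species(beta=1 / 8))
        assert classify(m).label == "sp1_only"

    def test_both_below_threshold(self):
        m = TwoSpeciesModel(_species(beta=0.1), _species(beta=0.11))
        rep = classify(m)
        assert rep.label == "both_extinct"
        assert rep.trivial_stable

    def test_weak_competition_coexistence(self):
        m = TwoSpeciesModel(_species(beta=1.0), _species(beta=0.5))
        rep = classify(m)
        assert rep.label == "coexistence_stable"
        assert rep.regime == "weak"
        assert rep.coexistence_stable
        # stable interior point <=> both boundary equilibria invadable
        assert rep.boundary1_stable is False and rep.boundary2_stable is False

    def test_strong_competition_bistable(self):
        m = TwoSpeciesModel(_species(b=3.0, beta=1.0), _species(b=3.0, beta=0.5))
        rep = classify(m)
        assert rep.label == "bistable"
        assert rep.regime == "strong"
        assert rep.coexistence_exists and rep.coexistence_stable is False
        assert rep.boundary1_stable and rep.boundary2_stable

    def test_weak_exclusion_without_interior_point(self, scenario):
        # stronger-shape variant: interior point leaves the positive quadrant
        # and the shorter-delay species wins
        rep = classify(scenario("fig4c_p20").model)
        assert rep.label == "sp1_only"
        assert rep.regime == "weak"
        assert not rep.coexistence_exists

    def test_report_json_roundtrip(self):
        import json

        rep = classify(TwoSpeciesModel(_species(), _species(beta=0.5)))
        payload = json.loads(rep.to_json())
        assert payload["label"] == rep.label
        assert payload["regime"] == rep.regime

    def test_conditions_mutually_exclusive(self, rng):
        # a stable interior point and a bistable pair cannot both be diagnosed
        for _ in range(50):
            mdl = random_model(rng)
            rep = classify(mdl)
            if rep.label == "coexistence_stable":
                assert rep.regime == "weak"
            if rep.label == "bistable":
                assert rep.regime == "strong"

    def test_truncation_far_out_converges(self, rng):
        # scaling both truncation shifts up leaves the classification at its
        # untruncated limit
        for _ in range(10):
            mdl = random_model(rng)
            labels = []
            for scale in (50.0, 500.0):
                def stretch(sp):
                    k = sp.kernel
                    return SpeciesParams(
                        sp.r, sp.m, sp.mu, sp.a, sp.b,
                        KernelSpec(k.p, k.beta, scale * k.p / k.beta),
                    )
                labels.append(classify(TwoSpeciesModel(stretch(mdl.species1),
                                                       stretch(mdl.species2))).label)
            assert labels[0] == labels[1]


class TestDiscreteLimit:
    def test_A_converges_at_fixed_ratio(self):
        # p -> inf with p/beta = 2 fixed, mu = 0.2
        T, mu = 2.0, 0.2
        sp_lim = _species(m=0.2, mu=mu, p=1, beta=1 / T)
        lim = discrete_limit_params(sp_lim)
        assert lim.A == pytest.approx(math.log(0.2) + mu * T, rel=1e-12)
        assert lim.tau == T and lim.alpha == 1.0
        p = 200
        sp = SpeciesParams(1.0, 0.2, mu, 1.0, 0.1, KernelSpec(p, p / T, 1e4))
        assert abs(derive(sp).A - lim.A) < 1e-3

    def test_survival_boundary_in_limit(self):
        # A_inf = 0  <=>  ln(r/m) = mu * T
        T = math.log(1 / 0.3) / 0.3
        sp = _species(p=1, beta=1 / T, delta=10 * T)
        lim = discrete_limit_params(sp)
        assert lim.A == pytest.approx(0.0, abs=1e-12)
        assert T == pytest.approx(4.01, abs=5e-3)

    def test_mu_zero_limit_equals_finite_p(self):
        sp = SpeciesParams(1.0, 0.25, 1e-300, 1.0, 0.1, KernelSpec(3, 1.0, 20.0))
        assert discrete_limit_params(sp).A == pytest.approx(derive(sp).A, abs=1e-9)
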