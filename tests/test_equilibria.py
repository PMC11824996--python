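"""Equilibrium branches, existence thresholds and Matignon stability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oncofrac import (FractionalOrder, scale_parameters,
                      tumor_free_equilibrium, coexisting_equilibria,
                      dead_equilibria, tumor_free_stability_conditions,
                      classify_stability, critical_alpha)
from oncofrac.equilibria import DegenerateParameterError, factored_eigenvalues


class TestTumorFree:
    def test_no_chemo_effector_and_normal_levels(self, sp1):
        eq = tumor_free_equilibrium(sp1, m_star=0.0)
        T, E, N, S, M = eq.point
        assert (T, S, M) == (0.0, 0.0, 0.0)
        assert E == pytest.approx(1.618, abs=1e-3)       # rho / mu
        assert N == pytest.approx(1960784313.726, abs=1e-3)  # 1 / b2
        assert eq.exists

    def test_steady_drug_shifts_normal_level(self, sp1):
        eq = tumor_free_equilibrium(sp1)  # M* = v / gamma2 = 1
        assert eq.point[4] == pytest.approx(1.0)
        assert eq.point[1] == pytest.approx(1.618, abs=1e-3)
        assert eq.point[2] == pytest.approx(1960784295.52, abs=1e-2)

    def test_no_drug_response_recovers_carrying_capacity(self, params):
        sp = scale_parameters(params.replace(kN=0.0), FractionalOrder(0.8))
        eq = tumor_free_equilibrium(sp)
        assert eq.point[2] == pytest.approx(1.0 / sp.b2, rel=1e-14)

    def test_existence_flips_across_drug_threshold(self, params):
        # r2 > kN * v / gamma2 is the survival threshold for normal cells
        sp_lo = scale_parameters(params.replace(kN=0.9 * params.r2),
                                 FractionalOrder(1.0))
        sp_hi = scale_parameters(params.replace(kN=1.1 * params.r2),
                                 FractionalOrder(1.0))
        assert tumor_free_equilibrium(sp_lo).exists
        assert not tumor_free_equilibrium(sp_hi).exists
        assert tumor_free_equilibrium(sp_lo).existence_margins[
            "normal_growth_vs_drug"] > 0

    def test_degenerate_denominator_raises(self, params):
        import dataclasses
        sp = scale_parameters(params.replace(p2=0.0, v=0.0), FractionalOrder(1.0))
        bad = dataclasses.replace(sp, mu=0.0)
        with pytest.raises(DegenerateParameterError):
            tumor_free_equilibrium(bad)


class TestTumorBearing:
    def test_dead_branch_matches_reference_values(self, sp1):
        dead = dead_equilibria(sp1, m_star=0.0)
        pts = sorted([e.point[:2].tolist() for e in dead])
        assert pts[0][0] == pytest.approx(0.0)
        assert pts[0][1] == pytest.approx(1.618, abs=1e-3)
        assert pts[1][0] == pytest.approx(980392135.34, abs=1e-2)
        assert pts[1][1] == pytest.approx(1.476, abs=1e-3)
        assert all(e.point[2] == 0.0 and e.branch == "dead" for e in dead)

    def test_interaction_free_limit_is_logistic_cap(self, params):
        sp = scale_parameters(params.replace(p3=0.0, kT=0.0, v=0.0),
                              FractionalOrder(0.9))
        eqs = coexisting_equilibria(sp, m_star=0.0)
        assert len(eqs) == 1
        assert eqs[0].point[0] == pytest.approx(1.0 / sp.b1, rel=1e-12)

    def test_root_satisfies_tumor_balance(self, sp1):
        # every returned root solves r1(1 - b1 T) = p3 E(T) + kT M* exactly
        for eq in coexisting_equilibria(sp1, m_star=0.0):
            T, E = eq.point[0], eq.point[1]
            resid = sp1.r1 * (1 - sp1.b1 * T) - sp1.p3 * E
            assert abs(resid) < 1e-12 * sp1.r1

    def test_baseline_coexisting_branch_requires_living_normals(self, sp1):
        # at baseline rates the positive tumor root drives N* negative,
        # so the coexisting branch does not exist and only its N=0
        # restriction (the dead branch) remains
        eqs = coexisting_equilibria(sp1, m_star=0.0)
        assert len(eqs) == 1 and not eqs[0].exists
        assert eqs[0].point[2] < 0

    def test_no_positive_root_returns_empty_list(self, params):
        # huge immune kill: r1 < p3 E(T) for all T in (0, 1/b1]
        sp = scale_parameters(params.replace(p3=1.0), FractionalOrder(1.0))
        assert coexisting_equilibria(sp, m_star=0.0) == []


class TestResidualInvariant:
    @pytest.mark.parametrize("alpha", [0.65, 0.85, 1.0])
    def test_all_branches_are_fixed_points(self, params, alpha):
        sp = scale_parameters(params, FractionalOrder(alpha))
        eqs = ([tumor_free_equilibrium(sp)]
               + coexisting_equilibria(sp)
               + dead_equilibria(sp))
        for eq in eqs:
            assert eq.residual(sp) < 1e-9, eq.branch


class TestSufficientConditions:
    def test_baseline_margins(self, sp1):
        eq = tumor_free_equilibrium(sp1)  # M* = 1
        conds = tumor_free_stability_conditions(sp1, eq)
        holds, margin = conds["tumor_suppression"]
        assert holds and margin == pytest.approx(
            sp1.p3 * eq.point[1] + sp1.kT - sp1.r1)
        # the drug cannot clear stem cells at baseline response rates
        assert not conds["stem_clearance"][0]
        assert conds["stem_clearance"][1] == pytest.approx(sp1.kS - sp1.gamma1)
        assert conds["normal_damping"][0]

    def test_strong_stem_response_satisfies_clearance(self, params):
        sp = scale_parameters(params.replace(kS=1.0), FractionalOrder(1.0))
        eq = tumor_free_equilibrium(sp)
        assert tumor_free_stability_conditions(sp, eq)["stem_clearance"][0]

    def test_wrong_branch_rejected(self, sp1):
        eq = dead_equilibria(sp1)[0]
        with pytest.raises(ValueError):
            tumor_free_stability_conditions(sp1, eq)


class TestMatignon:
    def test_real_negative_spectrum_stable_for_every_order(self, params):
        # with decaying stem cells the tumor-free point under steady drug
        # has a strictly negative real spectrum, hence |arg| = pi for all
        # eigenvalues and stability at every admissible order
        p = params.replace(stem_sign=-1)
        for alpha in (0.3, 0.65, 1.0):
            sp = scale_parameters(p, FractionalOrder(alpha))
            eq = tumor_free_equilibrium(sp)
            rep = classify_stability(eq, FractionalOrder(alpha), sp)
            assert np.all(rep.eigenvalues.real < 0)
            assert np.all(np.abs(rep.eigenvalues.imag) < 1e-12)
            assert rep.verdict == "stable"

    def test_purely_imaginary_pair_marginal_only_at_one(self):
        # |arg(+-i sqrt(c2))| = pi/2: the wedge closes exactly at order 1
        assert critical_alpha(0.0, 1.0) == pytest.approx(1.0)

    def test_unit_coefficients_closed_form(self):
        # (2/pi) * arctan(sqrt(3)) = 2/3 for lambda^2 + lambda + 1
        a_star = critical_alpha(1.0, 1.0)
        assert a_star == pytest.approx(2.0 / 3.0, abs=1e-14)

    def test_verdict_matches_classical_sign_test_at_alpha_one(self, sp1, rng):
        eq = tumor_free_equilibrium(sp1)
        rep = classify_stability(eq, FractionalOrder(1.0), sp1)
        classical_stable = np.all(rep.eigenvalues.real < 0)
        assert (rep.verdict == "stable") == bool(classical_stable)

    def test_verdict_monotone_in_alpha(self, sp1):
        eq = dead_equilibria(sp1, m_star=0.0)[1]  # tumor-bearing dead point
        verdicts = [classify_stability(eq, FractionalOrder(a), sp1).verdict
                    for a in (0.3, 0.65, 0.95)]
        # once unstable, larger alpha can never restore stability
        seen_unstable = False
        for v in verdicts:
            if seen_unstable:
                assert v == "unstable"
            seen_unstable = seen_unstable or v == "unstable"

    def test_factored_eigenvalues_match_dense_solve(self, sp1):
        for eq in [tumor_free_equilibrium(sp1), *dead_equilibria(sp1)]:
            dense = np.sort_complex(np.linalg.eigvals(
                __import__("oncofrac").jacobian(eq.point, sp1)))
            fact = np.sort_complex(factored_eigenvalues(eq, sp1))
            np.testing.assert_allclose(fact, dense, rtol=1e-8, atol=1e-12)


class TestCriticalAlpha:
    def test_closed_form_values(self):
        assert critical_alpha(1.0, 1.0) == pytest.approx(2.0 / 3.0)
        assert critical_alpha(2.0, 50.0) == pytest.approx(
            2.0 / math.pi * math.atan(7.0))

    def test_outside_the_formula_domain_absent(self):
        assert critical_alpha(3.0, 2.0) is None      # distinct real roots
        assert critical_alpha(2.0, 1.0) is None      # repeated root (boundary)
        assert critical_alpha(-1.0, 0.1) is None     # real, one positive
        assert critical_alpha(-1.0, 1.0) is None     # right-half-plane pair

    def test_left_half_plane_pair_is_stable_at_every_order(self):
        # the closed form is conservative: a c1 > 0 complex pair sits at
        # |arg| = pi - arctan(sqrt(disc)/c1) > pi/2, inside the Matignon
        # cone for every order in (0, 1]
        lam = np.roots([1.0, 1.0, 1.0])
        arg = float(np.min(np.abs(np.angle(lam))))
        assert arg == pytest.approx(2.0 * math.pi / 3.0)
        for alpha in (0.5, 2.0 / 3.0, 0.99, 1.0):
            assert arg > alpha * math.pi / 2.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c1=st.floats(0.05, 5.0), ratio=st.floats(1.01, 50.0))
    def test_formula_is_the_crossing_of_the_mirrored_pair(self, c1, ratio):
        # complex pair guaranteed by c2 = ratio * c1^2 / 4 > c1^2 / 4.
        # The closed form equals the brute-force wedge crossing of the
        # sign-mirrored pair (real part +c1/2), scanned at 1e-4
        # resolution in alpha.
        c2 = ratio * c1 * c1 / 4.0
        lam = np.roots([1.0, -c1, c2])  # mirrored: right-half-plane pair
        arg = float(np.min(np.abs(np.angle(lam))))
        alphas = np.arange(1e-4, 1.0, 1e-4)
        stable = arg > alphas * math.pi / 2.0
        flip = alphas[np.argmin(stable)] if not stable.all() else 1.0
        a_star = critical_alpha(c1, c2)
        assert a_star is not None
        assert abs(flip - min(a_star, 1.0)) <= 2e-4
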