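"""Forward-model unit and property tests: conformational partition,
species solver, readouts and the macroscopic descriptors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ire1link.linkage import (
    ClosedFormPcof,
    GridError,
    NoResponseError,
    apparent_kcof,
    conformational_partition,
    pcof,
    pcof_closed_form,
    predict_kobs,
    predict_od500,
    solve_species,
)
from ire1link.params import (
    AssayCondition,
    ConformationalParams,
    InvalidParameterError,
    KineticParams,
    LigandEntry,
    OpticsParams,
)


def make_params(L=0.01, kh=1.0, m=2, f_star=None, m_sat=None):
    f_apo = L / (1.0 + L)
    if f_star is None:
        f_star = f_apo + 0.5 * (1.0 - f_apo)
    return ConformationalParams(
        L_apo=L, K_half_uM=kh, m_apo=m, m_sat=m if m_sat is None else m_sat, f_star=f_star
    )


def four_state_partition(L, c, x):
    """Oracle: explicit four-state partition function (O, I, O.C, I.C)
    with statistical weights 1, L, x, L*c*x."""
    weights = {"O": 1.0, "I": L, "OC": x, "IC": L * c * x}
    Z = sum(weights.values())
    return (weights["I"] + weights["IC"]) / Z


class TestConformationalPartition:
    def test_apo_symmetry(self):
        # L_apo = 1 with no ligand splits the pool evenly
        p = make_params(L=1.0)
        assert conformational_partition([], p) == pytest.approx(0.5, abs=1e-15)

    def test_saturating_limit(self):
        # x -> infinity: f_I -> L c / (1 + L c); here 0.01*100 = 1 -> 0.5
        p = make_params(L=0.01)
        lig = LigandEntry("X", K_O_mM=1.0, latch=100.0)
        f = conformational_partition([(lig, 1e9)], p)
        assert f == pytest.approx(0.5, rel=1e-6)

    def test_matches_four_state_enumeration(self):
        # single ligand at [C] = K_O: frozen value 1.01/3.01 from the oracle
        p = make_params(L=0.01)
        lig = LigandEntry("X", K_O_mM=0.5, latch=100.0)
        f = conformational_partition([(lig, 0.5)], p)
        assert f == pytest.approx(four_state_partition(0.01, 100.0, 1.0), rel=1e-12)
        assert f == pytest.approx(1.01 / 3.01, rel=1e-12)

    @given(
        L=st.floats(1e-3, 1e3),
        c=st.floats(1e-3, 1e3),
        x=st.floats(0.0, 1e3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_function_equivalence(self, L, c, x):
        p = make_params(L=L)
        lig = LigandEntry("X", K_O_mM=1.0, latch=c)
        f = conformational_partition([(lig, x)], p)
        assert 0.0 < f < 1.0
        assert f == pytest.approx(four_state_partition(L, c, x), rel=1e-10)

    def test_independent_of_enzyme_concentration(self, wt):
        # f_I is a monomer property: no E_tot anywhere in the computation
        lig = LigandEntry("X", K_O_mM=0.3, latch=5.0)
        assert conformational_partition([(lig, 0.2)], wt) == conformational_partition(
            [(lig, 0.2)], wt
        )

    def test_invalid_inputs_raise(self):
        p = make_params()
        with pytest.raises(InvalidParameterError):
            conformational_partition([(LigandEntry("X", K_O_mM=1.0, latch=2.0), -1.0)], p)
        with pytest.raises(InvalidParameterError):
            LigandEntry("X", K_O_mM=-1.0, latch=2.0)


class TestSolveSpecies:
    def test_dilution_limit(self):
        p = make_params(L=0.5, kh=1.0, m=4)
        d = solve_species(AssayCondition(E_tot_uM=1e-12), p)
        assert d.A <= 1e-13
        assert d.M_free == pytest.approx(1e-12, rel=1e-6)

    def test_dimer_closed_form_oracle(self):
        # m=2, f_I=1: A = 2 M^2 / K_d with K_d = 1 uM corresponds to
        # K_half = K_d / 2; quadratic root at E_tot = 1 gives M = A = 0.5.
        K_d = 1.0
        p = make_params(L=1.0, kh=K_d / 2.0, m=2)
        d = solve_species(AssayCondition(E_tot_uM=1.0), p, f_I=1.0)
        # closed form: 2M^2/K_d + M = E
        M = (-1 + math.sqrt(1 + 8.0 * 1.0 / K_d)) / (4.0 / K_d)
        assert d.M_free == pytest.approx(M, abs=1e-10)
        assert d.A == pytest.approx(0.5, abs=1e-10)
        assert d.M_free == pytest.approx(0.5, abs=1e-10)

    @pytest.mark.parametrize("m", [3, 4, 5, 6, 7, 8])
    def test_dense_grid_bisection_oracle(self, m):
        # independent oracle: exhaustive bisection on a dense bracket
        p = make_params(L=0.25, kh=0.8, m=m)
        f = p.f_apo
        for E in (0.01, 0.5, 3.0, 30.0):
            d = solve_species(AssayCondition(E_tot_uM=E), p)
            lo, hi = 0.0, E
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                A = p.K_half_uM * (f * mid / p.K_half_uM) ** m
                if mid + A < E:
                    lo = mid
                else:
                    hi = mid
            assert d.M_free == pytest.approx(0.5 * (lo + hi), rel=1e-6)

    @given(
        L=st.floats(1e-3, 10.0),
        kh=st.floats(0.05, 50.0),
        m=st.integers(2, 10),
        E=st.floats(1e-6, 100.0),
        c=st.floats(0.1, 100.0),
        x=st.floats(0.0, 50.0),
    )
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_mass_conservation(self, L, kh, m, E, c, x):
        # conservation to 1e-9 relative over randomized valid parameter sets
        p = make_params(L=L, kh=kh, m=m)
        lig = LigandEntry("X", K_O_mM=1.0, latch=c)
        cond = AssayCondition(E_tot_uM=E, ligands=((lig, x),))
        d = solve_species(cond, p, warn_depletion=False)
        assert d.total() == pytest.approx(E, rel=1e-9)

    def test_oligomer_monotone_in_enzyme(self, wt):
        Es = np.logspace(-2, 2, 40)
        A = [solve_species(AssayCondition(E_tot_uM=e), wt).A for e in Es]
        assert np.all(np.diff(A) > 0)

    def test_shape_invariance_under_f(self):
        # at fixed m the oligomer-fraction curve vs log E superimposes
        # under different f_I after a horizontal translation
        m, kh = 5, 2.0
        p = make_params(L=1.0, kh=kh, m=m)
        logE = np.linspace(-2, 3, 61)

        def frac_curve(f, shift=0.0):
            return np.array([
                solve_species(AssayCondition(E_tot_uM=10 ** (le + shift)), p, f_I=f).A
                / 10 ** (le + shift)
                for le in logE
            ])

        f1, f2 = 0.3, 0.9
        # translation in log E that maps the f2 curve onto the f1 curve:
        # the dimensionless group f^m E^(m-1) must match
        shift = m / (m - 1) * (math.log10(f2) - math.log10(f1))
        c1 = frac_curve(f1, shift=shift)
        c2 = frac_curve(f2)
        assert np.max(np.abs(c1 - c2)) < 1e-6


class TestReadouts:
    def test_kobs_floor_half_and_plateau(self):
        kin = KineticParams(k2=1.0, K_M_uM=1.0, k_bg=0.001)
        p = make_params(L=1.0, kh=1.0, m=2)
        zero = solve_species(AssayCondition(E_tot_uM=0.0), p)
        assert predict_kobs(zero, kin) == pytest.approx(0.001)
        # A = K_M gives the half-saturation value k_bg + k2/2
        d_half = solve_species(AssayCondition(E_tot_uM=1.0), p, f_I=1.0)
        # construct A = K_M exactly by picking K_M equal to the solved A
        kin2 = KineticParams(k2=1.0, K_M_uM=d_half.A, k_bg=0.001)
        assert predict_kobs(d_half, kin2) == pytest.approx(0.501)
        big = solve_species(AssayCondition(E_tot_uM=1e5), p, f_I=1.0)
        assert predict_kobs(big, kin) == pytest.approx(1.001, rel=1e-3)

    def test_od500_linear_with_floor(self):
        opt = OpticsParams(alpha=0.05, od_floor=0.01)
        p = make_params(L=1.0, kh=1.0, m=2)
        zero = solve_species(AssayCondition(E_tot_uM=0.0), p)
        od, below = predict_od500(zero, opt)
        assert od == 0.0 and below
        d = solve_species(AssayCondition(E_tot_uM=10.0), p, f_I=1.0)
        od1, _ = predict_od500(d, opt)
        assert od1 == pytest.approx(0.05 * d.A)
        # homogeneity: doubling A doubles OD
        d2 = solve_species(AssayCondition(E_tot_uM=10.0), p, f_I=1.0)
        od2, _ = predict_od500(
            type(d2)(
                conc_O=d2.conc_O, conc_I=d2.conc_I, conc_bound=d2.conc_bound,
                A=2 * d2.A, f_I=d2.f_I, E_tot_uM=d2.E_tot_uM + d2.A,
            ),
            opt,
        )
        assert od2 == pytest.approx(2 * od1)


class TestPcof:
    @given(
        L=st.floats(1e-3, 10.0),
        kh=st.floats(0.1, 20.0),
        m=st.integers(2, 10),
        K_O=st.floats(1e-3, 10.0),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_neutral_at_latch_one(self, L, kh, m, K_O):
        # binding/activation uncoupling: a latch-1 binder never stimulates
        p = make_params(L=L, kh=kh, m=m)
        kin = KineticParams(k2=1.0, K_M_uM=0.5, k_bg=1e-3)
        lig = LigandEntry("silent", K_O_mM=K_O, latch=1.0)
        assert pcof(p, kin, lig, 3.0) == 1.0

    def test_deactivator_bounded_by_one(self, wt, kin):
        lig = LigandEntry("inactivating", K_O_mM=0.1, latch=0.01)
        assert pcof(wt, kin, lig, 3.0) <= 1.0

    def test_strictly_increasing_in_latch(self, wt, kin):
        latches = [1.01, 1.2, 1.5, 2.0, 5.0, 50.0]
        values = [
            pcof(wt, kin, LigandEntry("X", K_O_mM=0.1, latch=c), 3.0) for c in latches
        ]
        assert np.all(np.diff(values) > 0)

    def test_calibrated_adp_is_200(self, cal, wt, kin):
        # headline potency of the ADP Mg cofactor at the standard 3 uM
        p = pcof(wt, kin, cal.registry.get("ADP", "Mg"), 3.0)
        assert p == pytest.approx(200.0, rel=1e-6)


class TestPcofClosedForm:
    def test_latch_one_exact(self, wt, kin):
        res = pcof_closed_form(wt, kin, LigandEntry("s", K_O_mM=1.0, latch=1.0), 3.0)
        assert res.value == 1.0

    def test_agrees_with_numeric_in_regime(self):
        # A << K_M and oligomer fraction small: < 1% agreement
        p = make_params(L=0.01, kh=50.0, m=3)
        kin = KineticParams(k2=1.0, K_M_uM=1e6, k_bg=0.0)
        lig = LigandEntry("X", K_O_mM=0.1, latch=100.0)
        approx = pcof_closed_form(p, kin, lig, 3.0)
        exact = pcof(p, kin, lig, 3.0)
        assert approx.in_regime
        assert approx.value == pytest.approx(exact, rel=1e-2)

    def test_upper_bounds_numeric_value(self):
        # frozen magnitude: (0.5/0.0099)^3 ~ 1.3e5 bounds the numeric pcof
        p = make_params(L=0.01, kh=50.0, m=3)
        kin = KineticParams(k2=1.0, K_M_uM=1e6, k_bg=0.0)
        lig = LigandEntry("X", K_O_mM=0.1, latch=100.0)
        f_sat, f_apo = 0.5, 0.01 / 1.01
        bound = (f_sat / f_apo) ** 3
        assert bound == pytest.approx(1.3e5, rel=0.05)
        assert pcof(p, kin, lig, 3.0) <= bound * (1 + 1e-9)

    def test_degenerate_exponent_identity(self):
        # m = 1 (allowed only here): the ratio of I-state fractions itself
        p = make_params(L=0.01, kh=50.0, m=2)
        kin = KineticParams(k2=1.0, K_M_uM=1e6, k_bg=0.0)
        lig = LigandEntry("X", K_O_mM=0.1, latch=100.0)
        res = pcof_closed_form(p, kin, lig, 3.0, m_override=1.0)
        assert res.value == pytest.approx((0.5) / (0.01 / 1.01), rel=1e-12)

    def test_regime_violation_is_flagged(self, wt):
        kin = KineticParams(k2=1.0, K_M_uM=1e-4, k_bg=1e-3)
        lig = LigandEntry("X", K_O_mM=0.1, latch=50.0)
        res = pcof_closed_form(wt, kin, lig, 3.0)
        assert isinstance(res, ClosedFormPcof)
        assert not res.in_regime
        assert res.note


class TestApparentKcof:
    def test_weak_push_limit_approaches_K_O(self):
        # latch barely above 1 with small L*latch: midpoint ~ K_O within 5%
        p = make_params(L=0.01, kh=5.0, m=2)
        kin = KineticParams(k2=1.0, K_M_uM=1e5, k_bg=0.0)
        lig = LigandEntry("X", K_O_mM=0.1, latch=1.01)
        K = apparent_kcof(p, kin, lig, 3.0, c_grid_mM=np.logspace(-4, 2, 200))
        assert K == pytest.approx(0.1, rel=0.05)

    def test_silent_binder_raises(self, wt, kin):
        with pytest.raises(NoResponseError):
            apparent_kcof(wt, kin, LigandEntry("s", K_O_mM=0.1, latch=1.0), 3.0)

    def test_narrow_grid_raises(self, wt, kin, cal):
        adp = cal.registry.get("ADP", "Mg")
        with pytest.raises(GridError):
            apparent_kcof(wt, kin, adp, 3.0, c_grid_mM=np.logspace(0.8, 1, 5))

    def test_adp_and_atp_have_comparable_apparent_affinity(self, cal, wt, kin):
        # the model's realization of "similar apparent affinity": the
        # titration midpoints agree within threefold
        k_adp = apparent_kcof(wt, kin, cal.registry.get("ADP", "Mg"), 3.0)
        k_atp = apparent_kcof(wt, kin, cal.registry.get("ATP", "Mg"), 3.0)
        assert max(k_adp, k_atp) / min(k_adp, k_atp) < 3.0


class TestTwoReadoutOrdering:
    def test_rnase_responds_below_od_detection(self, cal, wt, kin, opt):
        # RNase half-plateau precedes the OD500 detection threshold on both
        # the apo and the ADP-saturated titration
        from scipy.optimize import brentq

        adp = cal.registry.get("ADP", "Mg")
        for ligands in ((), ((adp, 2.0),)):
            def A_at(E):
                return solve_species(
                    AssayCondition(E_tot_uM=E, ligands=ligands), wt, warn_depletion=False
                ).A

            E_half_kobs = brentq(lambda E: A_at(E) - kin.K_M_uM, 1e-3, 100.0)
            E_od = brentq(lambda E: A_at(E) - opt.od_floor / opt.alpha, 1e-3, 100.0)
            assert E_half_kobs < E_od
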