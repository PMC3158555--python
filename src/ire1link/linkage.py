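"""Forward conformational-selection model of Ire1 oligomerization.

The model couples three equilibria:

1. Conformation.  A free monomer interconverts between an inactive "O"
   conformation (alphaC-helix out) and an active "I" conformation
   (alphaC-helix in), with apo equilibrium constant ``L_apo = [I]/[O]``.
   ATP-pocket ligands bind either conformation of the single pocket
   competitively; ligand j binds the O state with dissociation constant
   ``K_O,j`` and the I state ``latch_j``-fold more tightly.  With reduced
   concentrations ``x_j = [C_j]/K_O,j`` the I-state fraction of the free
   monomer pool is

       f_I = L (1 + sum c_j x_j) / (1 + sum x_j + L (1 + sum c_j x_j)).

   ``f_I`` depends only on the ligands, not on enzyme concentration.

2. Assembly.  Only I-state monomers (apo or ligand-bound alike) assemble,
   all-or-none, into an oligomer of ``m`` protomers.  With I-pool
   concentration ``I = f_I * M`` (M = total free monomer) the
   oligomerized-protomer concentration is

       A = K_half * (I / K_half)**m,

   i.e. the assembly constant is expressed through ``K_half``, the I-pool
   concentration at which A equals the I-pool itself.  Mass balance
   ``M + A(f_I * M) = E_tot`` is closed by bracketed root finding.  The
   effective order m is interpolated in f_I between the apo value
   (Hill ~ 8 profiles) and the cofactor-saturated value (Hill ~ 3).

3. Readouts.  RNase: ``k_obs = k_bg + k2 * A/(K_M + A)`` (single-turnover
   rate, saturating in A — the kinetic plateau).  Turbidity:
   ``OD500 = alpha * A`` with a detection floor.

From these, the two macroscopic descriptors of a cofactor are computed:
``P_cof`` (k_obs at conformational saturation over apo k_obs, at the
standard enzyme concentration) and the apparent ``K_cof`` (titration
midpoint).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .params import (
    AssayCondition,
    ConformationalParams,
    InvalidParameterError,
    KineticParams,
    LigandEntry,
    OpticsParams,
    SpeciesDistribution,
)

__all__ = [
    "conformational_partition",
    "solve_species",
    "predict_kobs",
    "predict_od500",
    "pcof",
    "pcof_closed_form",
    "apparent_kcof",
    "LinkageModel",
    "ClosedFormPcof",
    "NoResponseError",
    "GridError",
    "NumericalError",
    "DepletionWarning",
]


class NoResponseError(RuntimeError):
    """A titration produced no response (conformationally silent ligand)."""


class GridError(RuntimeError):
    """The supplied grid does not bracket the feature being located."""


class NumericalError(RuntimeError):
    """A numerical routine failed to converge; diagnostics in the message."""


class DepletionWarning(UserWarning):
    """Ligand not in large excess over protein; free==total is assumed."""


def _ligand_terms(ligands: Sequence[tuple[LigandEntry, float]]) -> tuple[float, float]:
    """Return (sum x_j, sum c_j x_j) for the competitive single pocket."""
    sx = 0.0
    scx = 0.0
    for entry, conc_mM in ligands:
        if not (conc_mM >= 0 and math.isfinite(conc_mM)):
            raise InvalidParameterError(f"invalid concentration for {entry.name}: {conc_mM}")
        if entry.K_O_mM <= 0:
            raise InvalidParameterError(f"nonpositive K_O for {entry.name}")
        x = conc_mM / entry.K_O_mM
        sx += x
        scx += entry.latch * x
    return sx, scx


def conformational_partition(
    ligands: Sequence[tuple[LigandEntry, float]],
    params: ConformationalParams,
) -> float:
    """I-state fraction of the free monomer pool under competing ligands.

    Parameters
    ----------
    ligands : sequence of (LigandEntry, free concentration in mM)
    params : ConformationalParams

    Returns
    -------
    float
        ``f_I`` in (0, 1); independent of enzyme concentration.
    """
    L = params.L_apo
    sx, scx = _ligand_terms(ligands)
    num = L * (1.0 + scx)
    return num / (1.0 + sx + num)


def saturated_partition(ligand: LigandEntry, params: ConformationalParams) -> float:
    """Analytic x -> infinity limit of the partition for a single ligand."""
    Lc = params.L_apo * ligand.latch
    return Lc / (1.0 + Lc)


def _oligomer_A(I_pool: float, m: float, K_half: float) -> float:
    """Oligomerized protomers A = K_half * (I/K_half)**m (uM)."""
    if I_pool <= 0.0:
        return 0.0
    return K_half * (I_pool / K_half) ** m


def solve_species(
    condition: AssayCondition,
    params: ConformationalParams,
    *,
    f_I: float | None = None,
    warn_depletion: bool = True,
) -> SpeciesDistribution:
    """Solve the monomer/oligomer mass balance for one assay condition.

    ``E_tot = M + A(f_I * M)`` is solved for the free-monomer concentration
    M on [0, E_tot] by bracketed root finding (monotone in M), then the free
    pool is partitioned over the four-state (O, I, O.C_j, I.C_j) Boltzmann
    weights 1, L, x_j, L c_j x_j.

    ``f_I`` may be supplied to override the partition (used for analytic
    saturation limits); by default it is computed from the condition.
    """
    E = condition.E_tot_uM
    if warn_depletion and condition.depletion_warning():
        warnings.warn(
            "ligand concentration is not >=100-fold above protein; "
            "free-ligand == total-ligand assumption may degrade",
            DepletionWarning,
            stacklevel=2,
        )
    if f_I is None:
        f = conformational_partition(condition.ligands, params)
    else:
        if not (0.0 <= f_I <= 1.0):
            raise InvalidParameterError("f_I override must be in [0, 1]")
        f = f_I

    m_eff = params.assembly_order(f)
    K_half = params.K_half_uM

    if E == 0.0:
        return _distribution(condition, params, M=0.0, A=0.0, f=f)

    def residual(M: float) -> float:
        return M + _oligomer_A(f * M, m_eff, K_half) - E

    # residual(0) = -E < 0, residual(E) = A(f*E) >= 0: always bracketed.
    lo, hi = 0.0, E
    assert residual(lo) < 0.0 <= residual(hi), "root not bracketed for valid inputs"
    try:
        M = brentq(residual, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    except RuntimeError as err:  # pragma: no cover - brentq convergence failure
        raise NumericalError(
            f"mass-balance root finding failed: E={E}, f_I={f}, m={m_eff}, "
            f"K_half={K_half}: {err}"
        ) from err
    A = _oligomer_A(f * M, m_eff, K_half)
    if A > 1e-12 * E:
        # absorb the last-ulp residual into A so conservation is exact
        A = max(0.0, E - M)
    # else: A is below double-precision resolution of E - M; keep the model
    # value (conservation holds to << 1e-9 and A stays strictly monotone)
    return _distribution(condition, params, M=M, A=A, f=f)


def _distribution(
    condition: AssayCondition,
    params: ConformationalParams,
    M: float,
    A: float,
    f: float,
) -> SpeciesDistribution:
    L = params.L_apo
    sx, scx = _ligand_terms(condition.ligands)
    Z = 1.0 + L + sx + L * scx
    conc_O = M * 1.0 / Z
    conc_I = M * L / Z
    bound: dict[tuple[str, str], float] = {}
    for entry, conc_mM in condition.ligands:
        x = conc_mM / entry.K_O_mM
        # accumulate: the same species may appear twice in one condition
        # (e.g. self-competition designs)
        bound[(entry.name, "O")] = bound.get((entry.name, "O"), 0.0) + M * x / Z
        bound[(entry.name, "I")] = bound.get((entry.name, "I"), 0.0) + M * L * entry.latch * x / Z
    return SpeciesDistribution(
        conc_O=conc_O,
        conc_I=conc_I,
        conc_bound=bound,
        A=A,
        f_I=f,
        E_tot_uM=condition.E_tot_uM,
    )


def predict_kobs(dist: SpeciesDistribution, kin: KineticParams) -> float:
    """Single-turnover RNase rate constant (min^-1) for a species distribution."""
    A = dist.A
    return kin.k_bg + kin.k2 * A / (kin.K_M_uM + A)


def predict_od500(dist: SpeciesDistribution, opt: OpticsParams) -> tuple[float, bool]:
    """Turbidity readout: (OD500, below_detection flag)."""
    od = opt.alpha * dist.A
    return od, od < opt.od_floor


def _kobs_at_f(
    E_uM: float,
    f: float,
    params: ConformationalParams,
    kin: KineticParams,
) -> float:
    cond = AssayCondition(E_tot_uM=E_uM)
    dist = solve_species(cond, params, f_I=f, warn_depletion=False)
    return predict_kobs(dist, kin)


def pcof(
    params: ConformationalParams,
    kin: KineticParams,
    ligand: LigandEntry,
    E_std_uM: float = 3.0,
) -> float:
    """Cofactor potency: saturating k_obs over apo k_obs at E_std.

    Saturation is evaluated via the analytic x -> infinity limit of the
    conformational partition, f_sat = L*c/(1 + L*c), avoiding grid
    artifacts.  P_cof = 1 exactly for a conformationally silent binder
    (latch = 1) and is strictly increasing in the latch factor.
    """
    if E_std_uM <= 0:
        raise InvalidParameterError("E_std_uM must be > 0")
    f_sat = saturated_partition(ligand, params)
    k_sat = _kobs_at_f(E_std_uM, f_sat, params, kin)
    k_apo = _kobs_at_f(E_std_uM, params.f_apo, params, kin)
    if k_apo == 0.0:
        raise ZeroDivisionError("apo k_obs is zero; k_bg > 0 guards against this")
    return k_sat / k_apo


@dataclass(frozen=True)
class ClosedFormPcof:
    """Closed-form P_cof approximation plus a regime-validity flag."""

    value: float
    in_regime: bool
    note: str = ""

    def __float__(self) -> float:
        return self.value


def pcof_closed_form(
    params: ConformationalParams,
    kin: KineticParams,
    ligand: LigandEntry,
    E_std_uM: float = 3.0,
    *,
    m_override: float | None = None,
) -> ClosedFormPcof:
    """Closed-form P_cof valid when A << K_M and the oligomer fraction is small.

    In that regime M ~ E_tot at both endpoints and k_obs ~ k_bg + k2*A/K_M,
    so with A = K_half*(f*E/K_half)**m,

        P_cof ~ (k_bg + (k2/K_M) * K_half * (f_sat*E/K_half)**m_sat')
              / (k_bg + (k2/K_M) * K_half * (f_apo*E/K_half)**m_apo').

    When the effective orders coincide (m' = m) and k_bg is negligible this
    reduces to the pure conformational ratio (f_sat/f_apo)**m.  Outside the
    stated regime the value is still returned but flagged.

    ``m_override`` forces a single (possibly degenerate, m = 1) order at
    both endpoints; intended for testing the exponent identity.
    """
    f_sat = saturated_partition(ligand, params)
    f_apo = params.f_apo
    E = E_std_uM
    K_half = params.K_half_uM
    if m_override is not None:
        m_s = m_a = float(m_override)
    else:
        m_s = params.assembly_order(f_sat)
        m_a = params.assembly_order(f_apo)
    A_sat = _oligomer_A(f_sat * E, m_s, K_half)
    A_apo = _oligomer_A(f_apo * E, m_a, K_half)
    num = kin.k_bg + kin.k2 * A_sat / kin.K_M_uM
    den = kin.k_bg + kin.k2 * A_apo / kin.K_M_uM
    value = num / den
    in_regime = (A_sat < kin.K_M_uM / 100.0) and (A_sat < E / 100.0)
    note = "" if in_regime else (
        f"regime violated: A_sat={A_sat:.3g} uM vs K_M={kin.K_M_uM} uM, E={E} uM"
    )
    return ClosedFormPcof(value=value, in_regime=in_regime, note=note)


def apparent_kcof(
    params: ConformationalParams,
    kin: KineticParams,
    ligand: LigandEntry,
    E_std_uM: float = 3.0,
    c_grid_mM: Sequence[float] | None = None,
) -> float:
    """Apparent cofactor binding constant (mM) from the activity titration.

    Computes k_obs over the concentration grid and returns the ligand
    concentration at half-maximal stimulation by inverse interpolation in
    log concentration.  For a latch barely above 1 (and small L*latch) the
    midpoint approaches the microscopic O-state constant K_O.
    """
    if ligand.latch == 1.0:
        raise NoResponseError(f"{ligand.name}: latch = 1 produces a flat titration")
    if c_grid_mM is None:
        c_grid_mM = np.logspace(-3, 1, 25)
    c = np.asarray(c_grid_mM, dtype=float)
    if c.ndim != 1 or len(c) < 3 or np.any(np.diff(c) <= 0) or np.any(c <= 0):
        raise GridError("c_grid_mM must be a strictly increasing positive grid")

    def kobs_at(conc: float) -> float:
        f = conformational_partition([(ligand, conc)], params)
        return _kobs_at_f(E_std_uM, f, params, kin)

    k0 = _kobs_at_f(E_std_uM, params.f_apo, params, kin)
    ks = np.array([kobs_at(x) for x in c])
    k_end = ks[-1]
    if abs(k_end - k0) <= 1e-12 * max(k0, k_end):
        raise NoResponseError(f"{ligand.name}: titration is flat over the grid")
    k_half = 0.5 * (k0 + k_end)
    above = (ks - k_half) * np.sign(k_end - k0) >= 0
    if not above.any() or above[0]:
        raise GridError("half-maximal response not bracketed by the grid (grid too narrow)")
    i = int(np.argmax(above))
    # inverse interpolation in log10 concentration
    x0, x1 = math.log10(c[i - 1]), math.log10(c[i])
    y0, y1 = ks[i - 1], ks[i]
    t = (k_half - y0) / (y1 - y0)
    return float(10.0 ** (x0 + t * (x1 - x0)))


class LinkageModel:
    """Bundled forward model: conformational, kinetic and optical parameters.

    Thin object-oriented face over the module-level operations; useful when
    one parameter set is threaded through many predictions.
    """

    def __init__(
        self,
        conformational: ConformationalParams,
        kinetics: KineticParams | None = None,
        optics: OpticsParams | None = None,
    ):
        self.conformational = conformational
        self.kinetics = kinetics or KineticParams()
        self.optics = optics or OpticsParams()

    def species(self, condition: AssayCondition, **kw) -> SpeciesDistribution:
        return solve_species(condition, self.conformational, **kw)

    def kobs(self, condition: AssayCondition, **kw) -> float:
        return predict_kobs(self.species(condition, **kw), self.kinetics)

    def od500(self, condition: AssayCondition, **kw) -> tuple[float, bool]:
        return predict_od500(self.species(condition, **kw), self.optics)

    def pcof(self, ligand: LigandEntry, E_std_uM: float = 3.0) -> float:
        return pcof(self.conformational, self.kinetics, ligand, E_std_uM)

    def pcof_closed_form(self, ligand: LigandEntry, E_std_uM: float = 3.0, **kw) -> ClosedFormPcof:
        return pcof_closed_form(self.conformational, self.kinetics, ligand, E_std_uM, **kw)

    def apparent_kcof(self, ligand: LigandEntry, E_std_uM: float = 3.0, **kw) -> float:
        return apparent_kcof(self.conformational, self.kinetics, ligand, E_std_uM, **kw)
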