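"""Domain parameter types for the Ire1 conformational-linkage model.

Concentration conventions used throughout the package: protein (enzyme)
concentrations are in micromolar on a protomer basis; ATP-pocket ligand
concentrations are in millimolar.  Rates are per minute, turbidity in OD
units at 500 nm.

All parameter containers validate on construction and serialize to/from a
flat, unit-suffixed YAML mapping (see :func:`to_config` / :func:`from_config`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

CONFIG_SCHEMA_VERSION = 1

__all__ = [
    "ConformationalParams",
    "LigandEntry",
    "KineticParams",
    "OpticsParams",
    "AssayCondition",
    "SpeciesDistribution",
    "InvalidParameterError",
    "to_config",
    "from_config",
    "CONFIG_SCHEMA_VERSION",
]


class InvalidParameterError(ValueError):
    """A parameter or concentration violates its physical constraints."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class ConformationalParams:
    """Monomer O<->I equilibrium and oligomer-assembly parameters.

    Parameters
    ----------
    L_apo : float
        Conformational equilibrium constant [I]/[O] of the ligand-free
        monomer (dimensionless, > 0).
    m_apo, m_sat : int
        Phenomenological assembly order (protomers per oligomer) in the
        apo and the conformationally saturated regime.  The effective order
        is interpolated in the I-state fraction between the two (see
        :meth:`assembly_order`); the endpoints are integers >= 2.
    K_half_uM : float
        I-pool monomer concentration (uM) at which the oligomerized-protomer
        concentration equals the I-pool concentration; reparameterizes the
        assembly constant.
    f_star : float
        I-state fraction at which the effective assembly order reaches
        ``m_sat`` (conformational-saturation knot of the interpolation).
    variant_label : str
        Protein variant this parameter set describes.
    """

    L_apo: float
    K_half_uM: float
    m_apo: int = 8
    m_sat: int = 3
    f_star: float = 0.55
    variant_label: str = "wild-type phosphorylated"

    def __post_init__(self) -> None:
        _require(self.L_apo > 0 and math.isfinite(self.L_apo), "L_apo must be > 0")
        _require(self.K_half_uM > 0, "K_half_uM must be > 0")
        _require(int(self.m_apo) == self.m_apo and self.m_apo >= 2, "m_apo must be an integer >= 2")
        _require(int(self.m_sat) == self.m_sat and self.m_sat >= 2, "m_sat must be an integer >= 2")
        _require(0 < self.f_star <= 1, "f_star must be in (0, 1]")
        f_apo = self.L_apo / (1.0 + self.L_apo)
        _require(f_apo < self.f_star, "f_star must exceed the apo I-state fraction")

    @property
    def f_apo(self) -> float:
        """I-state fraction of the ligand-free monomer."""
        return self.L_apo / (1.0 + self.L_apo)

    def assembly_order(self, f_I: float) -> float:
        """Effective assembly order at I-state fraction ``f_I``.

        Linear in ``f_I`` between ``(f_apo, m_apo)`` and ``(f_star, m_sat)``,
        clamped to the endpoint values outside that interval.
        """
        if f_I <= self.f_apo:
            return float(self.m_apo)
        if f_I >= self.f_star:
            return float(self.m_sat)
        t = (f_I - self.f_apo) / (self.f_star - self.f_apo)
        return float(self.m_apo + (self.m_sat - self.m_apo) * t)


@dataclass(frozen=True)
class LigandEntry:
    """One (cofactor, metal) pair binding the single ATP pocket.

    ``K_O_mM`` is the dissociation constant from the inactive (O) monomer;
    ``latch`` is the conformational latch factor c = K_O/K_I, the preference
    of the ligand for the active (I) conformation.  c > 1 marks an
    activator, c = 1 a conformationally silent binder (the ADPbetaS + Mg
    case), c < 1 a deactivator.
    """

    name: str
    metal: str = "Mg"  # Mg | Mn | Cd | none
    K_O_mM: float = 0.1
    latch: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        _require(self.K_O_mM > 0 and math.isfinite(self.K_O_mM), "K_O_mM must be > 0")
        _require(self.latch > 0 and math.isfinite(self.latch), "latch must be > 0")

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.metal)


@dataclass(frozen=True)
class KineticParams:
    """Single-turnover RNase kinetics of the oligomer.

    k_obs = k_bg + k2 * A / (K_M + A), with A the oligomerized-protomer
    concentration (uM).  ``k2`` is the maximal cleavage rate at saturating
    oligomer, ``K_M_uM`` the half-saturating oligomerized-protomer
    concentration for RNA binding, ``k_bg`` the residual rate floor.
    """

    k2: float = 1.0  # min^-1
    K_M_uM: float = 1.5
    k_bg: float = 1e-3  # min^-1

    def __post_init__(self) -> None:
        _require(self.k_bg >= 0, "k_bg must be >= 0")
        _require(self.k2 > self.k_bg, "k2 must exceed k_bg")
        _require(self.K_M_uM > 0, "K_M_uM must be > 0")


@dataclass(frozen=True)
class OpticsParams:
    """Turbidity (OD500) readout: OD = alpha * A with a detection floor."""

    alpha: float = 0.05  # OD units per uM oligomerized protomer
    od_floor: float = 0.01  # OD units; readings below are below-detection

    def __post_init__(self) -> None:
        _require(self.alpha > 0, "alpha must be > 0")
        _require(self.od_floor >= 0, "od_floor must be >= 0")


@dataclass(frozen=True)
class AssayCondition:
    """Total enzyme plus the competing ATP-pocket ligands of one assay.

    ``ligands`` maps each :class:`LigandEntry` to its total concentration in
    mM.  Ligand depletion is ignored (free == total): ligands are in mM
    against uM protein.  A warning is recorded when that excess is < 100x.
    """

    E_tot_uM: float
    ligands: tuple[tuple[LigandEntry, float], ...] = ()
    temperature_C: float = 30.0
    buffer: str = "20 mM HEPES pH 7.4, 70 mM NaCl, 2 mM MgCl2"

    def __post_init__(self) -> None:
        _require(self.E_tot_uM >= 0 and math.isfinite(self.E_tot_uM), "E_tot_uM must be >= 0")
        object.__setattr__(self, "ligands", tuple(self.ligands))
        for entry, conc in self.ligands:
            _require(isinstance(entry, LigandEntry), "ligands must pair LigandEntry with mM")
            _require(conc >= 0 and math.isfinite(conc), f"concentration of {entry.name} must be >= 0")

    def depletion_warning(self) -> bool:
        """True when any ligand is not in >=100-fold excess over protein."""
        for _, conc_mM in self.ligands:
            if conc_mM > 0 and conc_mM * 1000.0 < 100.0 * self.E_tot_uM:
                return True
        return False


@dataclass(frozen=True)
class SpeciesDistribution:
    """Equilibrium concentrations (uM) of all monomer species and oligomer.

    ``conc_bound`` maps (ligand name, conformation 'O'|'I') to the bound
    monomer concentration.  ``A`` is the protomer concentration residing in
    oligomers; ``f_I`` the I-state fraction of the free-monomer pool.
    """

    conc_O: float
    conc_I: float
    conc_bound: Mapping[tuple[str, str], float]
    A: float
    f_I: float
    E_tot_uM: float

    def __post_init__(self) -> None:
        _require(self.conc_O >= 0 and self.conc_I >= 0 and self.A >= 0, "species must be >= 0")
        _require(all(v >= 0 for v in self.conc_bound.values()), "bound species must be >= 0")
        _require(0.0 <= self.f_I <= 1.0, "f_I must be in [0, 1]")
        total = self.total()
        if self.E_tot_uM > 0:
            _require(
                abs(total - self.E_tot_uM) <= 1e-9 * self.E_tot_uM,
                f"mass conservation violated: {total} != {self.E_tot_uM}",
            )

    def total(self) -> float:
        return self.conc_O + self.conc_I + sum(self.conc_bound.values()) + self.A

    @property
    def M_free(self) -> float:
        """Total free (non-oligomerized) monomer concentration."""
        return self.conc_O + self.conc_I + sum(self.conc_bound.values())


# ---------------------------------------------------------------------------
# Config serialization: flat, unit-suffixed keys, versioned.

def _conf_to_dict(p: ConformationalParams) -> dict:
    return {
        "L_apo": float(p.L_apo),
        "K_half_uM": float(p.K_half_uM),
        "m_apo": int(p.m_apo),
        "m_sat": int(p.m_sat),
        "f_star": float(p.f_star),
        "variant_label": p.variant_label,
    }


def _ligand_to_dict(e: LigandEntry) -> dict:
    return {
        "name": e.name,
        "metal": e.metal,
        "K_O_mM": float(e.K_O_mM),
        "latch": float(e.latch),
        "provenance": e.provenance,
    }


def to_config(
    conformational: ConformationalParams | None = None,
    kinetics: KineticParams | None = None,
    optics: OpticsParams | None = None,
    ligands: Sequence[LigandEntry] = (),
) -> str:
    """Serialize parameter sets to a versioned YAML document."""
    doc: dict = {"schema_version": CONFIG_SCHEMA_VERSION}
    if conformational is not None:
        doc["conformational"] = _conf_to_dict(conformational)
    if kinetics is not None:
        doc["kinetics"] = {
            "k2_per_min": float(kinetics.k2),
            "K_M_uM": float(kinetics.K_M_uM),
            "k_bg_per_min": float(kinetics.k_bg),
        }
    if optics is not None:
        doc["optics"] = {
            "alpha_OD_per_uM": float(optics.alpha),
            "od_floor_OD": float(optics.od_floor),
        }
    if ligands:
        doc["ligands"] = [_ligand_to_dict(e) for e in ligands]
    return yaml.safe_dump(doc, sort_keys=False)


def from_config(text: str) -> dict:
    """Parse a config document back into parameter objects.

    Returns a dict with any of the keys ``conformational``, ``kinetics``,
    ``optics``, ``ligands`` that were present.
    """
    doc = yaml.safe_load(text)
    version = doc.get("schema_version")
    if version != CONFIG_SCHEMA_VERSION:
        raise InvalidParameterError(f"unsupported config schema_version: {version!r}")
    out: dict = {}
    if "conformational" in doc:
        out["conformational"] = ConformationalParams(**doc["conformational"])
    if "kinetics" in doc:
        k = doc["kinetics"]
        out["kinetics"] = KineticParams(
            k2=k["k2_per_min"], K_M_uM=k["K_M_uM"], k_bg=k["k_bg_per_min"]
        )
    if "optics" in doc:
        o = doc["optics"]
        out["optics"] = OpticsParams(alpha=o["alpha_OD_per_uM"], od_floor=o["od_floor_OD"])
    if "ligands" in doc:
        out["ligands"] = [LigandEntry(**d) for d in doc["ligands"]]
    return out
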