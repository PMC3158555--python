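"""Seeded generators of synthetic Ire1 assay data.

The generators emulate the statistical structure of the wet-lab assays the
model describes: single-turnover cleavage time courses of a 5'-labeled RNA
hairpin (fraction cleaved vs time), paired RNase/OD500 protein titrations,
cofactor titrations at the 3 uM standard enzyme concentration, competition
series against a fixed 0.2 mM ADP background, and metal-rescue panels.

Noise structure (see :class:`NoiseModel`): additive Gaussian noise on the
fraction cleaved and on OD readings, and a shared lognormal "day factor" on
each series' rate constants emulating day-to-day preparation variability
(typically within twofold, default sigma = ln(2)/2).

Every stochastic output requires a seed and regenerates bit-identically
from the metadata it records.  Noise-free generation is a pure function of
the forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimators import TimeCourse
from .linkage import predict_kobs, predict_od500, solve_species
from .params import (
    AssayCondition,
    ConformationalParams,
    InvalidParameterError,
    KineticParams,
    LigandEntry,
    OpticsParams,
)

__all__ = [
    "NoiseModel",
    "AssaySeries",
    "gen_timecourse",
    "gen_protein_titration",
    "gen_cofactor_titration",
    "gen_competition_series",
    "gen_metal_rescue_panel",
    "default_protein_grid",
    "default_cofactor_grid",
    "default_competition_grid",
    "write_series",
    "read_series",
]

# Default designs: protein titrations 0.03-30 uM (15 log points), cofactor
# titrations 1 uM - 10 mM (12 points), competition 0.01-10 mM (10 points),
# time courses 8 points out to 3 half-lives.


def default_protein_grid() -> np.ndarray:
    return np.logspace(math.log10(0.03), math.log10(30.0), 15)


def default_cofactor_grid() -> np.ndarray:
    return np.logspace(-3, 1, 12)


def default_competition_grid() -> np.ndarray:
    return np.logspace(-2, 1, 10)


@dataclass(frozen=True)
class NoiseModel:
    """Noise structure of the synthetic assays.

    ``timecourse_sd``: additive SD on fraction cleaved.
    ``day_factor_sd``: SD of the lognormal multiplicative factor applied to
    the rate constants of one series (default ln(2)/2, matching day-to-day
    variability typically within twofold).
    ``od_sd``: additive SD on OD500 readings.
    ``seed``: mandatory for any stochastic output.
    """

    timecourse_sd: float = 0.02
    day_factor_sd: float = math.log(2.0) / 2.0
    od_sd: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.timecourse_sd, self.day_factor_sd, self.od_sd) < 0:
            raise InvalidParameterError("noise standard deviations must be >= 0")
        if self.is_stochastic and self.seed is None:
            raise InvalidParameterError("a seed is mandatory for stochastic output")

    @property
    def is_stochastic(self) -> bool:
        return max(self.timecourse_sd, self.day_factor_sd, self.od_sd) > 0

    @staticmethod
    def none() -> "NoiseModel":
        """Noise-free model (pure forward-model evaluation)."""
        return NoiseModel(0.0, 0.0, 0.0, seed=None)

    def rng(self, offset: int = 0) -> np.random.Generator:
        """Seeded stream; paired readouts use fixed sub-seed offsets."""
        if self.seed is None:
            raise InvalidParameterError("no seed recorded")
        return np.random.default_rng(int(self.seed) + offset)


@dataclass(frozen=True)
class AssaySeries:
    """One titration or dose series with full provenance.

    ``y`` has shape (n_replicates, n_points).  ``below_detection`` flags OD
    rows under the instrument floor.  ``meta`` records the generating
    parameters and seed completely enough to regenerate bit-identically.
    """

    design_name: str  # protein_titration | cofactor_titration | competition | metal_rescue | timecourse
    x: np.ndarray
    x_unit: str
    y: np.ndarray
    y_unit: str
    below_detection: np.ndarray | None = None
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.atleast_2d(np.asarray(self.y, dtype=float))
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if len(x) and np.any(np.diff(x) <= 0):
            raise InvalidParameterError("x grid must be strictly increasing")
        if y.shape[-1] != len(x):
            raise InvalidParameterError("y and x shapes disagree")
        if self.below_detection is not None:
            bd = np.atleast_2d(np.asarray(self.below_detection, dtype=bool))
            object.__setattr__(self, "below_detection", bd)

    @property
    def n_replicates(self) -> int:
        return self.y.shape[0]

    @property
    def y_mean(self) -> np.ndarray:
        return self.y.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep in range(self.y.shape[0]):
            for j, xv in enumerate(self.x):
                row = {"replicate": rep, "x": xv, "y": self.y[rep, j]}
                if self.below_detection is not None:
                    row["below_detection"] = bool(self.below_detection[rep, j])
                rows.append(row)
        return pd.DataFrame(rows)


def _day_factor(noise: NoiseModel, offset: int) -> float:
    if not noise.is_stochastic or noise.day_factor_sd == 0:
        return 1.0
    return float(np.exp(noise.rng(offset).normal(0.0, noise.day_factor_sd)))


def _record_meta(**kw) -> dict:
    meta = {}
    for key, value in kw.items():
        if isinstance(value, (ConformationalParams, KineticParams, OpticsParams, NoiseModel)):
            meta[key] = {f.replace("'", ""): getattr(value, f) for f in value.__dataclass_fields__}
        elif isinstance(value, LigandEntry):
            meta[key] = {
                "name": value.name,
                "metal": value.metal,
                "K_O_mM": value.K_O_mM,
                "latch": value.latch,
            }
        elif isinstance(value, np.ndarray):
            meta[key] = value.tolist()
        else:
            meta[key] = value
    return meta


def _kobs_under(
    E_uM: float,
    ligands: Sequence[tuple[LigandEntry, float]],
    params: ConformationalParams,
    kin: KineticParams,
) -> float:
    cond = AssayCondition(E_tot_uM=E_uM, ligands=tuple(ligands))
    dist = solve_species(cond, params, warn_depletion=False)
    return predict_kobs(dist, kin)


def gen_timecourse(
    condition: AssayCondition,
    params: ConformationalParams,
    kin: KineticParams,
    noise: NoiseModel | None = None,
    timepoints_min: Sequence[float] | None = None,
    amplitude: float = 0.8,
) -> TimeCourse:
    """Synthetic single-turnover cleavage time course.

    The true rate is ``predict_kobs`` under the condition; the noiseless
    curve is F(t) = amplitude * (1 - exp(-k t)).  The day factor perturbs k,
    additive noise perturbs F; values are clipped to [0, 1 + 3 sd].
    """
    noise = noise or NoiseModel.none()
    dist = solve_species(condition, params, warn_depletion=False)
    k_true = predict_kobs(dist, kin)
    k = k_true * _day_factor(noise, offset=0)
    if timepoints_min is None:
        t_half3 = 3.0 * math.log(2.0) / k
        timepoints_min = t_half3 * np.arange(1, 9) / 8.0
    t = np.asarray(timepoints_min, dtype=float)
    frac = amplitude * (1.0 - np.exp(-k * t))
    if noise.is_stochastic and noise.timecourse_sd > 0:
        frac = frac + noise.rng(1).normal(0.0, noise.timecourse_sd, size=frac.shape)
    hi = min(1.0 + 3.0 * noise.timecourse_sd, 1.05)
    frac = np.clip(frac, 0.0, hi)
    return TimeCourse(
        times_min=t,
        frac_cleaved=frac,
        condition=_record_meta(
            E_tot_uM=condition.E_tot_uM,
            ligands=[(e.name, e.metal, c) for e, c in condition.ligands],
            k_true=k_true,
            amplitude=amplitude,
            noise=noise,
        ),
        seed=noise.seed,
    )


def gen_protein_titration(
    params: ConformationalParams,
    kin: KineticParams,
    opt: OpticsParams,
    ligands: Sequence[tuple[LigandEntry, float]] = (),
    E_grid_uM: Sequence[float] | None = None,
    noise: NoiseModel | None = None,
    n_replicates: int = 1,
) -> tuple[AssaySeries, AssaySeries]:
    """Paired RNase (k_obs) and OD500 series over an enzyme titration.

    Returns ``(kobs_series, od_series)`` sharing one grid.  Paired readouts
    draw from independent sub-streams at fixed seed offsets (RNase: 10*rep,
    OD: 10*rep + 5).  A zero-length grid yields empty series.
    """
    noise = noise or NoiseModel.none()
    E = default_protein_grid() if E_grid_uM is None else np.asarray(E_grid_uM, dtype=float)
    nrep = n_replicates if noise.is_stochastic else 1
    kobs = np.empty((nrep, len(E)))
    od = np.empty((nrep, len(E)))
    bd = np.zeros((nrep, len(E)), dtype=bool)
    for j, e in enumerate(E):
        cond = AssayCondition(E_tot_uM=float(e), ligands=tuple(ligands))
        dist = solve_species(cond, params, warn_depletion=False)
        k_true = predict_kobs(dist, kin)
        od_true, _ = predict_od500(dist, opt)
        for rep in range(nrep):
            k = k_true * _day_factor(noise, offset=10 * rep)
            o = od_true
            if noise.is_stochastic and noise.od_sd > 0:
                o = od_true + float(noise.rng(10 * rep + 5).normal(0.0, noise.od_sd, size=len(E))[j])
            kobs[rep, j] = k
            od[rep, j] = o
            bd[rep, j] = o < opt.od_floor
    meta = _record_meta(
        params=params, kin=kin, opt=opt, noise=noise,
        ligands=[(e.name, e.metal, c) for e, c in ligands],
        E_grid_uM=E, n_replicates=nrep,
    )
    k_series = AssaySeries("protein_titration", E, "uM", kobs, "min^-1", None, {**meta, "readout": "kobs"})
    od_series = AssaySeries("protein_titration", E, "uM", od, "OD500", bd, {**meta, "readout": "od500"})
    return k_series, od_series


def gen_cofactor_titration(
    ligand: LigandEntry,
    params: ConformationalParams,
    kin: KineticParams,
    C_grid_mM: Sequence[float] | None = None,
    E_std_uM: float = 3.0,
    noise: NoiseModel | None = None,
    n_replicates: int = 1,
) -> AssaySeries:
    """k_obs vs cofactor concentration at the standard enzyme concentration.

    The apo rate (x = 0 background) is recorded in ``meta['background_kobs']``
    for downstream isotherm fitting.
    """
    noise = noise or NoiseModel.none()
    C = default_cofactor_grid() if C_grid_mM is None else np.asarray(C_grid_mM, dtype=float)
    nrep = n_replicates if noise.is_stochastic else 1
    k_true = np.array([_kobs_under(E_std_uM, [(ligand, float(c))], params, kin) for c in C])
    k_apo = _kobs_under(E_std_uM, [], params, kin)
    y = np.empty((nrep, len(C)))
    for rep in range(nrep):
        y[rep] = k_true * _day_factor(noise, offset=10 * rep)
    meta = _record_meta(
        params=params, kin=kin, noise=noise, ligand=ligand,
        E_tot_uM=E_std_uM, background_kobs=k_apo, C_grid_mM=C,
        n_replicates=nrep,
    )
    return AssaySeries("cofactor_titration", C, "mM", y, "min^-1", None, meta)


def gen_competition_series(
    inhibitor: LigandEntry,
    activator: LigandEntry,
    params: ConformationalParams,
    kin: KineticParams,
    I_grid_mM: Sequence[float] | None = None,
    activator_mM: float = 0.2,
    E_std_uM: float = 3.0,
    noise: NoiseModel | None = None,
    n_replicates: int = 1,
) -> AssaySeries:
    """k_obs vs inhibitor concentration at a fixed activator background.

    Emulates the competitive-inhibition design: the reaction is stimulated
    with 0.2 mM ADP and increasingly outcompeted by the titrated ligand at
    the single ATP pocket.
    """
    noise = noise or NoiseModel.none()
    I = default_competition_grid() if I_grid_mM is None else np.asarray(I_grid_mM, dtype=float)
    nrep = n_replicates if noise.is_stochastic else 1
    k_true = np.array([
        _kobs_under(E_std_uM, [(activator, activator_mM), (inhibitor, float(c))], params, kin)
        for c in I
    ])
    k_background = _kobs_under(E_std_uM, [(activator, activator_mM)], params, kin)
    y = np.empty((nrep, len(I)))
    for rep in range(nrep):
        y[rep] = k_true * _day_factor(noise, offset=10 * rep)
    meta = _record_meta(
        params=params, kin=kin, noise=noise,
        inhibitor=inhibitor, activator=activator,
        activator_mM=activator_mM, E_tot_uM=E_std_uM,
        background_kobs=k_background, I_grid_mM=I, n_replicates=nrep,
    )
    return AssaySeries("competition", I, "mM", y, "min^-1", None, meta)


def gen_metal_rescue_panel(
    pairs: Sequence[LigandEntry],
    params: ConformationalParams,
    kin: KineticParams,
    C_grid_mM: Sequence[float] | None = None,
    E_std_uM: float = 3.0,
    noise: NoiseModel | None = None,
) -> list[AssaySeries]:
    """Cofactor titrations for a list of (cofactor, metal) registry entries.

    Metal dependence lives at the registry level — each (cofactor, metal)
    pair carries its own latch — so a rescue panel is a set of titrations,
    one per pair (e.g. ADPbetaS+Mg flat at the apo level, ADPbetaS+Mn
    rescued to near-ADP stimulation).  The metal-concentration response
    itself is not modeled thermodynamically.
    """
    noise = noise or NoiseModel.none()
    out = []
    for i, entry in enumerate(pairs):
        sub = noise
        if noise.is_stochastic:
            sub = replace(noise, seed=int(noise.seed) + 1000 * i)
        series = gen_cofactor_titration(
            entry, params, kin, C_grid_mM=C_grid_mM, E_std_uM=E_std_uM, noise=sub
        )
        series.meta["design_name_detail"] = "metal_rescue"
        out.append(
            AssaySeries(
                "metal_rescue", series.x, series.x_unit, series.y, series.y_unit,
                series.below_detection, series.meta,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tabular I/O: data as a delimited table, metadata in a YAML sidecar.


def _meta_to_plain(obj):
    if isinstance(obj, dict):
        return {str(k): _meta_to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_meta_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_series(series: AssaySeries, path: str | Path) -> tuple[Path, Path]:
    """Write a series as CSV plus a YAML metadata sidecar (lossless)."""
    path = Path(path)
    df = series.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    doc = {
        "design_name": series.design_name,
        "x_unit": series.x_unit,
        "y_unit": series.y_unit,
        "n_replicates": series.n_replicates,
        "meta": _meta_to_plain(dict(series.meta)),
    }
    sidecar.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path, sidecar


def read_series(path: str | Path) -> AssaySeries:
    """Read back a series written by :func:`write_series`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".meta.yaml")
    doc = yaml.safe_load(sidecar.read_text())
    nrep = int(doc["n_replicates"])
    x = np.sort(df.loc[df["replicate"] == 0, "x"].to_numpy())
    y = np.empty((nrep, len(x)))
    bd = None
    if "below_detection" in df.columns:
        bd = np.zeros((nrep, len(x)), dtype=bool)
    for rep in range(nrep):
        sub = df[df["replicate"] == rep].sort_values("x")
        y[rep] = sub["y"].to_numpy()
        if bd is not None:
            bd[rep] = sub["below_detection"].to_numpy(dtype=bool)
    return AssaySeries(
        design_name=doc["design_name"],
        x=x,
        x_unit=doc["x_unit"],
        y=y,
        y_unit=doc["y_unit"],
        below_detection=bd,
        meta=doc["meta"],
    )
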