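"""Curve-fitting estimators for the single-turnover and titration assays.

Each estimator is a small model object built from data whose ``fit()``
returns a :class:`FitResult` carrying estimates, standard errors,
convergence diagnostics and a ``summary()`` table — plus module-level
one-call wrappers (``fit_single_exponential`` etc.) for pipeline use.

Fitting conventions: unweighted least squares, Levenberg–Marquardt
(via lmfit), analytic initial guesses (log-midpoints for binding
constants, endpoint asymptotes for amplitudes), standard errors from the
local curvature (covariance) at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np
import yaml

__all__ = [
    "FitResult",
    "TimeCourse",
    "SingleExponentialModel",
    "BindingIsothermModel",
    "HillModel",
    "CompetitiveInhibitionModel",
    "fit_single_exponential",
    "fit_isotherm",
    "fit_hill",
    "fit_competitive_ki",
    "estimate_pcof_from_titration",
    "max_loglog_slope",
    "DegenerateDataError",
    "MetadataError",
]


class DegenerateDataError(ValueError):
    """The data carry no signal the model could be identified from."""


class MetadataError(ValueError):
    """Two results being combined come from incompatible conditions."""


class NoResponseError(RuntimeError):
    """A series expected to respond is flat."""


class GridError(ValueError):
    """The x-grid does not cover the feature being fit."""


@dataclass(frozen=True)
class TimeCourse:
    """A single-turnover cleavage time course (fraction cleaved vs time)."""

    times_min: np.ndarray
    frac_cleaved: np.ndarray
    condition: Mapping = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        y = np.asarray(self.frac_cleaved, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "frac_cleaved", y)
        if t.ndim != 1 or len(t) < 4:
            raise DegenerateDataError("a time course needs >= 4 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(y) != len(t):
            raise ValueError("times and frac_cleaved must have equal length")
        if np.any(y < -1e-12) or np.any(y > 1.05):
            raise ValueError("frac_cleaved must lie within [0, 1.05]")


@dataclass(frozen=True)
class FitResult:
    """Estimates with uncertainties from one curve fit.

    ``estimates``/``stderr`` are parallel name->value mappings (stderr is
    NaN where the curvature was singular, but always present).  A
    nonconverged fit is returned with ``converged=False``, never silently.
    """

    estimates: Mapping[str, float]
    stderr: Mapping[str, float]
    units: Mapping[str, str]
    model_name: str
    converged: bool
    residual_norm: float
    flags: tuple[str, ...] = ()
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.estimates) - set(self.stderr)
        if missing:
            raise ValueError(f"stderr missing for estimates: {sorted(missing)}")

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]

    def summary(self) -> str:
        lines = [
            f"Model: {self.model_name}",
            f"Converged: {self.converged}   residual norm: {self.residual_norm:.6g}",
        ]
        if self.flags:
            lines.append("Flags: " + ", ".join(self.flags))
        lines.append(f"{'parameter':<14}{'estimate':>14}{'std err':>14}  unit")
        for name, value in self.estimates.items():
            se = self.stderr.get(name, float("nan"))
            unit = self.units.get(name, "")
            lines.append(f"{name:<14}{value:>14.6g}{se:>14.3g}  {unit}")
        return "\n".join(lines)

    def to_yaml(self) -> str:
        doc = {
            "model_name": self.model_name,
            "converged": bool(self.converged),
            "residual_norm": float(self.residual_norm),
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "stderr": {k: float(v) for k, v in self.stderr.items()},
            "units": dict(self.units),
            "flags": list(self.flags),
            "metadata": {str(k): v for k, v in self.metadata.items()},
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FitResult":
        doc = yaml.safe_load(text)
        return cls(
            estimates=doc["estimates"],
            stderr=doc["stderr"],
            units=doc.get("units", {}),
            model_name=doc["model_name"],
            converged=doc["converged"],
            residual_norm=doc["residual_norm"],
            flags=tuple(doc.get("flags", ())),
            metadata=doc.get("metadata", {}),
        )


def _result_from_lmfit(
    out: lmfit.minimizer.MinimizerResult,
    model_name: str,
    units: Mapping[str, str],
    flags: Sequence[str] = (),
    metadata: Mapping | None = None,
    rename: Mapping[str, str] | None = None,
) -> FitResult:
    rename = rename or {}
    estimates: dict[str, float] = {}
    stderr: dict[str, float] = {}
    for pname, par in out.params.items():
        name = rename.get(pname, pname)
        estimates[name] = float(par.value)
        stderr[name] = float(par.stderr) if par.stderr is not None else float("nan")
    residual_norm = float(np.sqrt(np.sum(np.asarray(out.residual) ** 2)))
    return FitResult(
        estimates=estimates,
        stderr=stderr,
        units={rename.get(k, k): v for k, v in units.items()},
        model_name=model_name,
        converged=bool(out.success),
        residual_norm=residual_norm,
        flags=tuple(flags),
        metadata=metadata or {},
    )


_FIT_KW = dict(xtol=1e-13, ftol=1e-13, gtol=1e-13)


class SingleExponentialModel:
    """F(t) = F_max * (1 - exp(-k t)): single-turnover cleavage kinetics."""

    model_name = "single_exponential"

    def __init__(self, timecourse: TimeCourse):
        self.timecourse = timecourse

    def fit(self) -> FitResult:
        t = self.timecourse.times_min
        y = self.timecourse.frac_cleaved
        span = float(np.max(y) - np.min(y))
        if span <= 1e-9 or float(np.max(np.abs(y))) <= 1e-9:
            raise DegenerateDataError("time course has no signal span")

        fmax0 = max(float(np.max(y)), 1e-6)
        # log-linear guess for k from the earliest point with signal
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.clip(1.0 - y / (fmax0 * 1.05), 1e-9, 1.0)
            slopes = -np.log(frac) / np.where(t > 0, t, np.inf)
        k0 = float(np.nanmedian(slopes[np.isfinite(slopes) & (slopes > 0)]))
        if not (k0 > 0 and math.isfinite(k0)):
            k0 = 1.0 / float(np.median(t))

        params = lmfit.Parameters()
        params.add("k_obs", value=k0, min=1e-12)
        params.add("amplitude", value=fmax0, min=1e-9)

        def residual(p):
            return p["amplitude"] * (1.0 - np.exp(-p["k_obs"] * t)) - y

        out = lmfit.minimize(residual, params, method="leastsq", **_FIT_KW)
        return _result_from_lmfit(
            out,
            self.model_name,
            units={"k_obs": "min^-1", "amplitude": "fraction"},
            metadata=dict(self.timecourse.condition),
        )


class BindingIsothermModel:
    """Hyperbolic binding isotherm with the baseline fixed to a background.

    y = y0 + (y_max - y0) * x / (K_app + x), y0 supplied (e.g. the rate
    measured without the titrated ligand) and held fixed.
    """

    model_name = "binding_isotherm"

    def __init__(self, xs_mM: np.ndarray, ys: np.ndarray, background: float):
        x = np.asarray(xs_mM, dtype=float)
        y = np.asarray(ys, dtype=float)
        if x.ndim != 1 or len(x) < 5:
            raise GridError("isotherm fitting needs >= 5 concentrations")
        pos = x[x > 0]
        if len(pos) and float(np.max(pos) / np.min(pos)) < 10.0:
            raise GridError("concentration grid must span >= 10-fold")
        self.x, self.y, self.background = x, y, float(background)

    def fit(self) -> FitResult:
        x, y, y0 = self.x, self.y, self.background
        if float(np.max(y) - np.min(y)) <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
            raise DegenerateDataError("all responses equal; no isotherm to fit")

        ymax0 = float(y[np.argmax(x)])
        half = y0 + 0.5 * (ymax0 - y0)
        above = (y - half) * np.sign(ymax0 - y0) >= 0
        K0 = float(np.sqrt(np.min(x[x > 0]) * np.max(x)))
        if above.any():
            K0 = float(x[int(np.argmax(above))])
        params = lmfit.Parameters()
        params.add("K_app", value=max(K0, 1e-9), min=1e-12)
        params.add("k_max", value=ymax0 if ymax0 != y0 else y0 + 1e-6)

        def residual(p):
            return y0 + (p["k_max"] - y0) * x / (p["K_app"] + x) - y

        out = lmfit.minimize(residual, params, method="leastsq", **_FIT_KW)
        flags = []
        if float(np.max(x)) < 2.0 * float(out.params["K_app"].value):
            flags.append("wide-CI: no saturation within grid")
        return _result_from_lmfit(
            out,
            self.model_name,
            units={"K_app": "mM", "k_max": "min^-1"},
            flags=flags,
            metadata={"background": y0},
        )


def max_loglog_slope(xs: np.ndarray, ys: np.ndarray, floor: float = 0.0) -> float:
    """Maximum pairwise log-log slope of a titration: a model-free
    cooperativity estimator for log-linear oligomerization readouts."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    keep = (x > 0) & (y > floor)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DegenerateDataError("too few positive points for a log-log slope")
    slopes = np.diff(np.log(y)) / np.diff(np.log(x))
    return float(np.max(slopes))


class HillModel:
    """Four-parameter Hill curve: y = y0 + y_max * x^n / (EC50^n + x^n)."""

    model_name = "hill"

    def __init__(self, xs_uM: np.ndarray, ys: np.ndarray, noise_scale: float = 0.0):
        x = np.asarray(xs_uM, dtype=float)
        y = np.asarray(ys, dtype=float)
        if x.ndim != 1 or len(x) < 5 or np.any(x < 0):
            raise GridError("Hill fitting needs >= 5 nonnegative concentrations")
        self.x, self.y = x, y
        self.noise_scale = float(noise_scale)

    def fit(self) -> FitResult:
        x, y = self.x, self.y
        span = float(np.max(y) - np.min(y))
        if span <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
            raise DegenerateDataError("flat profile; no transition to fit")
        ylo, yhi = float(np.min(y)), float(np.max(y))
        half = ylo + 0.5 * span
        above = y >= half
        if not above.any() or above[0] or not above[-1]:
            raise GridError("transition not covered by the grid")
        i = int(np.argmax(above))
        ec0 = float(np.sqrt(x[i - 1] * x[i])) if x[i - 1] > 0 else float(x[i])
        # local log-log slope around the midpoint as the n guess
        lo = max(i - 2, 0)
        hi = min(i + 2, len(x) - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            n0 = (math.log(max(y[hi] - ylo, 1e-12)) - math.log(max(y[lo] - ylo, 1e-12))) / (
                math.log(x[hi]) - math.log(x[lo])
            )
        n0 = min(max(n0, 0.5), 12.0)

        flags = []
        diffs = np.diff(y)
        tol = 3.0 * self.noise_scale + 1e-12 * max(1.0, abs(yhi))
        if np.any(diffs < -tol):
            flags.append("monotonicity violation beyond noise")

        params = lmfit.Parameters()
        params.add("n_H", value=n0, min=0.05, max=50.0)
        params.add("EC50", value=ec0, min=1e-12)
        params.add("y_max", value=span, min=1e-15)
        params.add("y0", value=ylo)

        def residual(p):
            xn = np.power(x, p["n_H"])
            return p["y0"] + p["y_max"] * xn / (p["EC50"] ** p["n_H"] + xn) - y

        out = lmfit.minimize(residual, params, method="leastsq", **_FIT_KW)
        return _result_from_lmfit(
            out,
            self.model_name,
            units={"n_H": "", "EC50": "uM", "y_max": "signal", "y0": "signal"},
            flags=flags,
        )


class CompetitiveInhibitionModel:
    """Competitive inhibition of a cofactor-stimulated reaction.

    y = y_floor + (y_0 - y_floor) / (1 + x / K_i): decline of k_obs with
    inhibitor at a fixed activator concentration, corrected for the
    activator background through the floated floor.  K_i is reported as
    apparent; an optional Cheng–Prusoff-style correction
    K_i / (1 + [activator]/K_activator) can be requested and is appended
    as a separate estimate.
    """

    model_name = "competitive_inhibition"

    def __init__(
        self,
        xs_mM: np.ndarray,
        ys: np.ndarray,
        activator_mM: float = 0.2,
        activator_name: str = "ADP",
    ):
        x = np.asarray(xs_mM, dtype=float)
        y = np.asarray(ys, dtype=float)
        if x.ndim != 1 or len(x) < 5 or np.any(x < 0):
            raise GridError("competition fitting needs >= 5 nonnegative concentrations")
        self.x, self.y = x, y
        self.activator_mM = float(activator_mM)
        self.activator_name = activator_name

    def fit(self, cheng_prusoff_K_mM: float | None = None) -> FitResult:
        x, y = self.x, self.y
        y0_guess = float(y[np.argmin(x)])
        yfloor_guess = float(y[np.argmax(x)])
        drop = y0_guess - yfloor_guess
        if drop <= 1e-9 * max(1.0, abs(y0_guess)):
            raise NoResponseError("series does not inhibit; nothing to fit")
        half = yfloor_guess + 0.5 * drop
        below = y <= half
        Ki0 = float(np.sqrt(np.min(x[x > 0]) * np.max(x)))
        if below.any() and not below[0]:
            Ki0 = float(x[int(np.argmax(below))])

        params = lmfit.Parameters()
        params.add("K_i", value=Ki0, min=1e-12)
        params.add("y_0", value=y0_guess)
        params.add("y_floor", value=max(yfloor_guess, 0.0), min=0.0)

        def residual(p):
            return p["y_floor"] + (p["y_0"] - p["y_floor"]) / (1.0 + x / p["K_i"]) - y

        out = lmfit.minimize(residual, params, method="leastsq", **_FIT_KW)
        res = _result_from_lmfit(
            out,
            self.model_name,
            units={"K_i": "mM", "y_0": "min^-1", "y_floor": "min^-1"},
            metadata={
                "activator_mM": self.activator_mM,
                "activator": self.activator_name,
            },
        )
        if cheng_prusoff_K_mM is not None:
            corr = res.estimates["K_i"] / (1.0 + self.activator_mM / cheng_prusoff_K_mM)
            est = dict(res.estimates)
            se = dict(res.stderr)
            un = dict(res.units)
            est["K_i_corrected"] = corr
            se["K_i_corrected"] = se["K_i"] / (1.0 + self.activator_mM / cheng_prusoff_K_mM)
            un["K_i_corrected"] = "mM"
            res = FitResult(
                estimates=est,
                stderr=se,
                units=un,
                model_name=res.model_name,
                converged=res.converged,
                residual_norm=res.residual_norm,
                flags=res.flags,
                metadata=res.metadata,
            )
        return res


# ---------------------------------------------------------------------------
# Operation-style wrappers


def fit_single_exponential(tc: TimeCourse) -> FitResult:
    """Observed rate constant from a single-turnover cleavage time course."""
    return SingleExponentialModel(tc).fit()


def fit_isotherm(xs_mM, ys, background: float) -> FitResult:
    """Hyperbolic titration fit with the zero-ligand baseline held fixed."""
    return BindingIsothermModel(xs_mM, ys, background).fit()


def fit_hill(xs_uM, ys, noise_scale: float = 0.0) -> FitResult:
    """Cooperative (Hill) fit of an activation profile vs enzyme concentration."""
    return HillModel(xs_uM, ys, noise_scale=noise_scale).fit()


def fit_competitive_ki(
    xs_mM,
    ys,
    activator_mM: float = 0.2,
    activator_name: str = "ADP",
    cheng_prusoff_K_mM: float | None = None,
) -> FitResult:
    """Apparent K_i from inhibition of a cofactor-stimulated reaction."""
    model = CompetitiveInhibitionModel(xs_mM, ys, activator_mM, activator_name)
    return model.fit(cheng_prusoff_K_mM=cheng_prusoff_K_mM)


def estimate_pcof_from_titration(titration: FitResult, apo_kobs: float, *,
                                 E_tot_uM: float | None = None) -> float:
    """P_cof from a titration fit: saturating k_max over the apo rate.

    Both quantities must refer to the same total enzyme concentration; when
    the fit's metadata records one and ``E_tot_uM`` is supplied they are
    cross-checked.
    """
    if apo_kobs <= 0:
        raise ZeroDivisionError("apo k_obs must be > 0")
    meta_E = titration.metadata.get("E_tot_uM")
    if E_tot_uM is not None and meta_E is not None and not math.isclose(E_tot_uM, meta_E):
        raise MetadataError(
            f"titration fitted at E_tot={meta_E} uM but apo rate given for {E_tot_uM} uM"
        )
    k_max = titration.estimates.get("k_max")
    if k_max is None:
        raise MetadataError("titration FitResult lacks a k_max estimate")
    return float(k_max) / float(apo_kobs)
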