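"""Fluorescence correlation spectroscopy: simulation, fitting, calibration.

FCS records intensity fluctuations of fluorophores diffusing through a
diffraction-limited confocal volume.  The autocorrelation of a freely
diffusing species in a 3D Gaussian detection volume, with a fast triplet
(dark-state) term, is

    G(tau) = offset + (1/N) * [1 + T/(1-T) * exp(-tau/tau_T)]
             * sum_i f_i * (1 + tau/tau_Di)^-1 * (1 + tau/(S^2 tau_Di))^-1/2

where N is the mean molecule number in the volume, f_i the component
fractions (sum 1), tau_Di the diffusion times, S = z0/w0 the structure
parameter, T the triplet fraction and tau_T the triplet relaxation time.

Two-component fits resolve a free and a DNA-bound species; with equal
molecular brightness the fitted fractions are number fractions, so the slow
fraction is the bound fraction.  Calibrating with a dye of known diffusion
coefficient D (e.g. fluorescein, D = 4.25e-6 cm^2/s) pins the beam waist
through tau_D = w0^2/(4 D) and hence the effective volume
V_eff = pi^(3/2) w0^3 S, converting fitted N into absolute concentration
C = N / (N_A V_eff).

Units: lag times in seconds, D in cm^2/s, w0 in micrometres, V_eff in
litres, concentrations in nM.  All conversions happen inside this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "FcsCurve",
    "FcsModel",
    "Calibration",
    "autocorrelation",
    "fit_curve",
    "calibrate",
    "concentration",
    "diffusion_time",
    "diffusion_coefficient",
    "effective_volume",
    "read_curve_tsv",
    "write_curve_tsv",
    "AVOGADRO",
]

AVOGADRO = 6.02214076e23  # 1/mol

#: fluorescein diffusion coefficient used for 488-nm calibration, cm^2/s
FLUORESCEIN_D = 4.25e-6

_CM2_PER_UM2 = 1e-8
_L_PER_UM3 = 1e-15


@dataclass(frozen=True)
class FcsCurve:
    """Measured or simulated autocorrelation: lag times (s) and G values."""

    lags: np.ndarray
    g: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)
        if lags.ndim != 1 or lags.shape != g.shape:
            raise ValueError("lags and g must be 1-D arrays of equal length")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing and positive")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", w)
            if w.shape != lags.shape:
                raise ValueError("weights must match lags in length")


@dataclass(frozen=True)
class FcsModel:
    """Parameters of the 3D-diffusion + triplet autocorrelation model."""

    n_mean: float
    tau_d: tuple[float, ...]  # diffusion time per component, s
    fractions: tuple[float, ...] = (1.0,)
    s_param: float = 5.0
    triplet_frac: float = 0.0
    tau_t: float = 2e-6
    offset: float = 1.0

    def __post_init__(self) -> None:
        td = tuple(float(t) for t in np.atleast_1d(self.tau_d))
        fr = tuple(float(f) for f in np.atleast_1d(self.fractions))
        object.__setattr__(self, "tau_d", td)
        object.__setattr__(self, "fractions", fr)
        if self.n_mean <= 0:
            raise ValueError("n_mean must be > 0")
        if len(td) != len(fr):
            raise ValueError("tau_d and fractions must have equal length")
        if any(t <= 0 for t in td):
            raise ValueError("diffusion times must be > 0")
        if any(f < 0 for f in fr) or not math.isclose(sum(fr), 1.0, rel_tol=1e-9):
            raise ValueError("fractions must be >= 0 and sum to 1")
        if self.s_param <= 1:
            raise ValueError("structure parameter must be > 1")
        if not 0.0 <= self.triplet_frac < 1.0:
            raise ValueError("triplet fraction must lie in [0, 1)")
        if self.tau_t <= 0:
            raise ValueError("triplet time must be > 0")


@dataclass(frozen=True)
class Calibration:
    """Confocal-volume calibration from a dye of known diffusion coefficient."""

    dye_d: float  # cm^2/s
    tau_d: float  # s
    s_param: float
    w0: float = field(init=False)  # um
    veff: float = field(init=False)  # L

    def __post_init__(self) -> None:
        w0_cm = math.sqrt(4.0 * self.dye_d * self.tau_d)
        w0 = w0_cm / math.sqrt(_CM2_PER_UM2)
        object.__setattr__(self, "w0", w0)
        object.__setattr__(self, "veff", effective_volume(w0, self.s_param))


def diffusion_time(d: float, w0: float) -> float:
    """tau_D (s) of a species with D (cm^2/s) in a beam of waist w0 (um)."""
    return (w0**2 * _CM2_PER_UM2) / (4.0 * d)


def diffusion_coefficient(tau_d: float, w0: float) -> float:
    """D (cm^2/s) from a fitted tau_D (s) at known beam waist w0 (um)."""
    return (w0**2 * _CM2_PER_UM2) / (4.0 * tau_d)


def effective_volume(w0: float, s_param: float) -> float:
    """V_eff (L) = pi^(3/2) w0^3 S with w0 in um."""
    return math.pi**1.5 * w0**3 * s_param * _L_PER_UM3


def autocorrelation(model: FcsModel, lags) -> np.ndarray:
    """Evaluate G(tau) of the diffusion + triplet model at the given lags (s)."""
    tau = np.asarray(lags, dtype=float)
    diff = np.zeros_like(tau)
    for f, td in zip(model.fractions, model.tau_d):
        diff += f / ((1.0 + tau / td) * np.sqrt(1.0 + tau / (model.s_param**2 * td)))
    trip = 1.0
    if model.triplet_frac > 0:
        t = model.triplet_frac
        trip = 1.0 + t / (1.0 - t) * np.exp(-tau / model.tau_t)
    return model.offset + trip * diff / model.n_mean


def _model_from_params(p: Mapping[str, float], n_components: int) -> FcsModel:
    if n_components == 1:
        fractions: tuple[float, ...] = (1.0,)
        tau_d: tuple[float, ...] = (p["tau_d1"],)
    else:
        f2 = p["f2"]
        fractions = (1.0 - f2, f2)
        tau_d = (p["tau_d1"], p["tau_d2"])
    return FcsModel(
        n_mean=p["n_mean"],
        tau_d=tau_d,
        fractions=fractions,
        s_param=p["s_param"],
        triplet_frac=p["triplet_frac"],
        tau_t=p["tau_t"],
        offset=p["offset"],
    )


def fit_curve(
    curve: FcsCurve,
    n_components: int = 1,
    fixed: Mapping[str, float] | None = None,
    init: Mapping[str, float] | None = None,
) -> tuple[FcsModel, lmfit.minimizer.MinimizerResult]:
    """Weighted least-squares fit of the diffusion + triplet model.

    Parameters named ``n_mean, tau_d1[, tau_d2, f2], s_param, triplet_frac,
    tau_t, offset`` may be pinned through ``fixed`` (for two-component fits
    the free-species diffusion time, measured on protein alone, is normally
    fixed).  Initial guesses are derived deterministically from the curve:
    N from the short-lag amplitude, tau_d1 from the lag nearest the
    half-decay.  Returns the fitted model and the lmfit result (inspect
    ``result.params[...].stderr`` and bound flags for diagnostics).

    Raises ``ValueError`` for curves with fewer than 30 points and
    ``RuntimeError`` on non-convergence.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if len(curve.lags) < 30:
        raise ValueError("need at least 30 lag points to fit")
    fixed = dict(fixed or {})
    init = dict(init or {})
    if n_components == 2 and not ({"tau_d1", "tau_d2"} & set(fixed)):
        raise ValueError("two-component fits require one diffusion time fixed")

    g = curve.g
    offset0 = float(fixed.get("offset", init.get("offset", g[-5:].mean())))
    amp0 = max(float(g[:3].mean() - offset0), 1e-6)
    n0 = 1.0 / amp0
    # lag nearest the half-amplitude decay as the diffusion-time guess
    half = offset0 + amp0 / 2.0
    tau0 = float(curve.lags[int(np.argmin(np.abs(g - half)))])

    p = lmfit.Parameters()
    p.add("n_mean", value=init.get("n_mean", n0), min=1e-6)
    p.add("tau_d1", value=init.get("tau_d1", tau0), min=1e-9)
    if n_components == 2:
        p.add("tau_d2", value=init.get("tau_d2", 3 * tau0), min=1e-9)
        p.add("f2", value=init.get("f2", 0.5), min=0.0, max=1.0)
    p.add("s_param", value=init.get("s_param", 5.0), min=1.0 + 1e-6, max=100.0)
    p.add("triplet_frac", value=init.get("triplet_frac", 0.05), min=0.0, max=0.999)
    p.add("tau_t", value=init.get("tau_t", 2e-6), min=1e-8)
    p.add("offset", value=init.get("offset", offset0))
    for name, value in fixed.items():
        if name not in p:
            raise KeyError(f"unknown parameter {name!r}")
        p[name].set(value=value, vary=False)

    weights = curve.weights if curve.weights is not None else np.ones_like(curve.lags)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        vals = params.valuesdict()
        model = _model_from_params(vals, n_components)
        return (autocorrelation(model, curve.lags) - g) * weights

    result = lmfit.minimize(residual, p, method="leastsq")
    values = np.array(list(result.params.valuesdict().values()))
    # scipy's "tolerance too small" return codes still carry a converged
    # solution; reject only genuinely unusable fits
    if not np.all(np.isfinite(values)) or not np.all(np.isfinite(result.residual)):
        raise RuntimeError(f"FCS fit did not converge: {result.message}")
    fitted = _model_from_params(result.params.valuesdict(), n_components)
    # enforce timescale separation: the triplet must relax before diffusion
    if fitted.triplet_frac > 0 and fitted.tau_t >= min(fitted.tau_d):
        fitted = replace(fitted, triplet_frac=0.0)
    return fitted, result


def calibrate(
    curve: FcsCurve,
    dye_d: float,
    fixed: Mapping[str, float] | None = None,
) -> Calibration:
    """Derive the confocal volume from a single-dye calibration curve.

    Fits the one-component model (diffusion time and structure parameter
    free unless pinned via ``fixed``), then converts the known diffusion
    coefficient into the beam waist w0 = sqrt(4 D tau_D) and the effective
    volume V_eff = pi^(3/2) w0^3 S.
    """
    if dye_d <= 0:
        raise ValueError("dye_d must be > 0")
    model, _ = fit_curve(curve, n_components=1, fixed=fixed)
    return Calibration(dye_d=dye_d, tau_d=model.tau_d[0], s_param=model.s_param)


def concentration(n_mean: float, cal: Calibration | float) -> float:
    """Absolute concentration (nM) from molecule number and calibrated volume.

    ``cal`` may be a :class:`Calibration` or an effective volume in litres.
    C = N / (N_A * V_eff), returned in nM.
    """
    if n_mean < 0:
        raise ValueError("n_mean must be >= 0")
    veff = cal.veff if isinstance(cal, Calibration) else float(cal)
    if veff <= 0:
        raise ValueError("effective volume must be > 0")
    molar = n_mean / (AVOGADRO * veff)
    return molar * 1e9


# ---------------------------------------------------------------------------
# I/O


def read_curve_tsv(path) -> FcsCurve:
    """Read a correlation curve TSV with columns lag_s, g[, weight]."""
    df = pd.read_csv(path, sep="\t")
    if not {"lag_s", "g"}.issubset(df.columns):
        raise ValueError("curve TSV must have columns lag_s and g")
    w = df["weight"].to_numpy(float) if "weight" in df.columns else None
    return FcsCurve(df["lag_s"].to_numpy(float), df["g"].to_numpy(float), w)


def write_curve_tsv(curve: FcsCurve, path) -> None:
    df = pd.DataFrame({"lag_s": curve.lags, "g": curve.g})
    if curve.weights is not None:
        df["weight"] = curve.weights
    df.to_csv(path, sep="\t", index=False)
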