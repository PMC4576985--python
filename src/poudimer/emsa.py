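"""Band-shift quantitation: bound fractions and apparent Kd estimation.

A titration runs a dilution series of protein against a fixed, labeled DNA
probe.  In each lane the probe's fluorescence splits between the free-DNA
band and one or more shifted (protein-bound) bands; the bound fraction is
the shifted share of the DNA channel's total intensity.  Plotting bound
fraction against total protein gives a sigmoid whose 50%-crossing defines
the apparent dissociation constant (aKd).

The fitted family is a three-parameter logistic in log concentration,

    f(x) = fmax / (1 + (midpoint / x)**h),

with the lower asymptote pinned at zero.  It contains the ideal
no-depletion isotherm (fmax = 1, h = 1) and tolerates the distortions that
probe depletion, dimer stoichiometry and cooperativity introduce.  The aKd
is read off as the fitted curve's crossing of absolute bound fraction 0.5 —
not the inflection point; the two differ whenever fmax < 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .equilibrium import LanePattern

__all__ = [
    "TitrationPoint",
    "TitrationSeries",
    "SigmoidFit",
    "FitError",
    "bound_fraction",
    "fit_titration",
    "logistic3",
    "read_titration_tsv",
    "write_titration_tsv",
]


class FitError(RuntimeError):
    """Raised when a titration cannot be fitted (degenerate or invalid data)."""


@dataclass(frozen=True)
class TitrationPoint:
    protein_conc: float  # total protein, nM
    bound_fraction: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be > 0")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TitrationSeries:
    """A bound-fraction titration of one protein against one probe."""

    dna_conc: float  # probe concentration, nM
    points: Sequence[TitrationPoint]
    protein: str = ""
    probe: str = ""

    def __post_init__(self) -> None:
        if self.dna_conc <= 0:
            raise ValueError("dna_conc must be > 0")

    @property
    def n_distinct_concs(self) -> int:
        return len({p.protein_conc for p in self.points})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_conc_nM": [p.protein_conc for p in self.points],
                "bound_fraction": [p.bound_fraction for p in self.points],
                "replicate": [p.replicate for p in self.points],
            }
        )


@dataclass(frozen=True)
class SigmoidFit:
    """Result of fitting the 3-parameter logistic to a titration.

    ``akd`` is the concentration at which the fitted curve reaches bound
    fraction 0.5; it is None (with ``flag = "no-half-saturation"``) when the
    fitted plateau does not exceed 0.5.
    """

    fmax: float
    hill: float
    midpoint: float
    akd: float | None
    rss: float
    n_points: int
    flag: str | None = None

    def predict(self, conc) -> np.ndarray:
        return logistic3(np.asarray(conc, dtype=float), self.fmax, self.hill, self.midpoint)

    def to_dict(self) -> dict:
        return {
            "fmax": self.fmax,
            "hill": self.hill,
            "midpoint_nM": self.midpoint,
            "akd_nM": self.akd,
            "rss": self.rss,
            "n_points": self.n_points,
            "flag": self.flag,
        }


def logistic3(x: np.ndarray, fmax: float, h: float, midpoint: float) -> np.ndarray:
    """Bottom-anchored logistic in log concentration: fmax/(1+(mid/x)^h)."""
    return fmax / (1.0 + (midpoint / x) ** h)


def bound_fraction(lane: LanePattern, dna_channel: str) -> float:
    """Shifted-band share of the DNA channel's total intensity in one lane.

    Every band in the DNA channel other than free DNA counts as bound;
    bands from other channels are ignored.
    """
    dna_bands = [b for b in lane.bands if b.channel == dna_channel]
    total = sum(b.intensity for b in dna_bands)
    if not dna_bands or total <= 0:
        raise FitError("lane has no DNA-channel intensity; bound fraction undefined")
    shifted = sum(b.intensity for b in dna_bands if b.mobility_class != "free_dna")
    return shifted / total


_HILL_BOUNDS = (0.3, 5.0)
_FMAX_MAX = 1.05


def fit_titration(series: TitrationSeries) -> SigmoidFit:
    """Least-squares logistic fit of a titration; aKd at the 0.5 crossing.

    Replicates are pooled, not averaged, so each measured point carries its
    own residual.  Initialization is deterministic: fmax0 is the largest
    observed bound fraction, midpoint0 the concentration whose bound
    fraction lies closest to fmax0/2, h0 = 1; the optimizer is bounded
    (fmax <= 1.05, h in [0.3, 5]), making the fit reproducible and
    insensitive to point order.
    """
    if series.n_distinct_concs < 4:
        raise FitError("need at least 4 distinct concentrations to fit")
    x = np.array([p.protein_conc for p in series.points], dtype=float)
    y = np.array([p.bound_fraction for p in series.points], dtype=float)
    order = np.lexsort((y, x))  # deterministic under point permutation
    x, y = x[order], y[order]
    if np.allclose(y, y[0]):
        raise FitError("degenerate titration: all bound fractions equal")

    fmax0 = min(max(float(np.max(y)), 1e-3), _FMAX_MAX)
    mid0 = float(x[np.argmin(np.abs(y - fmax0 / 2.0))])
    p0 = (fmax0, 1.0, mid0)
    lo = (1e-6, _HILL_BOUNDS[0], x.min() / 100.0)
    hi = (_FMAX_MAX, _HILL_BOUNDS[1], x.max() * 100.0)
    popt, _ = optimize.curve_fit(
        logistic3, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
    )
    fmax, h, mid = (float(v) for v in popt)
    rss = float(np.sum((y - logistic3(x, fmax, h, mid)) ** 2))

    if fmax > 0.5:
        # f(x) = 0.5  =>  x = mid / (2*fmax - 1)**(1/h)
        akd = mid / (2.0 * fmax - 1.0) ** (1.0 / h)
        flag = None
    else:
        akd, flag = None, "no-half-saturation"
    return SigmoidFit(fmax, h, mid, akd, rss, len(x), flag)


# ---------------------------------------------------------------------------
# I/O


def read_titration_tsv(path, dna_conc: float = 5.0, protein: str = "", probe: str = "") -> TitrationSeries:
    """Read a titration table with columns protein_conc_nM, bound_fraction[, replicate]."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_conc_nM", "bound_fraction"}
    if not required.issubset(df.columns):
        raise ValueError(f"titration TSV must have columns {sorted(required)}")
    reps = df["replicate"] if "replicate" in df.columns else np.zeros(len(df), dtype=int)
    points = tuple(
        TitrationPoint(float(c), float(f), int(r))
        for c, f, r in zip(df["protein_conc_nM"], df["bound_fraction"], reps)
    )
    return TitrationSeries(dna_conc, points, protein=protein, probe=probe)


def write_titration_tsv(series: TitrationSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False)
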