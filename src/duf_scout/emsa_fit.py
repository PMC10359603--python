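"""Gel-shift (EMSA) quantitation: constant co-purified band exclusion and
least-squares fitting of the specific-binding-with-Hill-slope model

    Y = Bmax * X^h / (K_D^h + X^h)

to the bound fraction (or the raw bound/unbound ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class BindingCurve:
    concentrations: np.ndarray  # nM, one entry per lane
    bound: np.ndarray
    unbound: np.ndarray
    reps: np.ndarray
    excluded_baseline: Optional[float] = None
    clipped_lanes: int = 0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.bound = np.asarray(self.bound, dtype=float)
        self.unbound = np.asarray(self.unbound, dtype=float)
        self.reps = np.asarray(self.reps)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(self.bound < 0) or np.any(self.unbound < 0):
            raise ValueError("intensities must be non-negative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingCurve":
        return cls(concentrations=df["concentration_nM"].to_numpy(),
                   bound=df["bound"].to_numpy(),
                   unbound=df["unbound"].to_numpy(),
                   reps=df["rep"].to_numpy())

    def response(self, use_fraction: bool = True) -> np.ndarray:
        if use_fraction:
            return self.bound / (self.bound + self.unbound)
        return self.bound / self.unbound


@dataclass
class BindingFit:
    kd: float
    hill: float
    bmax: float
    rss: float
    converged: bool
    n_points: int
    diagnostics: dict = field(default_factory=dict)


def hill_model(x, bmax, kd, h):
    x = np.asarray(x, dtype=float)
    return bmax * x ** h / (kd ** h + x ** h)


def exclude_constant_unbound(
    df: pd.DataFrame,
    cv_threshold: float = 0.10,
    band: str = "copurified",
) -> BindingCurve:
    """Apply the constant co-purified band exclusion rule.

    If lane quantitations carry a designated band column whose coefficient
    of variation across lanes is below ``cv_threshold``, its mean intensity
    is subtracted from each lane's unbound signal and recorded as
    ``excluded_baseline``.  Corrections driving an unbound intensity below
    zero are clipped to zero and counted.
    """
    if len(df) < 3:
        raise ValueError("need at least 3 lanes")
    curve = BindingCurve.from_frame(df)
    if band not in df.columns:
        return curve
    values = df[band].to_numpy(dtype=float)
    mean = values.mean()
    cv = np.inf if mean == 0 else values.std(ddof=0) / mean
    if mean > 0 and cv < cv_threshold:
        corrected = curve.unbound - mean
        clipped = int((corrected < 0).sum())
        if clipped:
            warnings.warn(f"baseline subtraction clipped {clipped} lanes to 0")
        curve.unbound = np.clip(corrected, 0.0, None)
        curve.excluded_baseline = float(mean)
        curve.clipped_lanes = clipped
    return curve


def _initial_guesses(x: np.ndarray, y: np.ndarray, n_starts: int):
    ymax = max(float(np.max(y)), 1e-9)
    half = np.abs(y - ymax / 2)
    kd0 = float(x[np.argmin(half)])
    factors = np.geomspace(0.25, 4.0, max(1, n_starts // 2))
    for f in factors:
        yield (ymax, kd0 * f, 1.0)
        # a cooperative start helps steep curves
        yield (ymax, kd0 / f, 2.0)


def fit_hill(
    curve: BindingCurve,
    use_fraction: bool = True,
    n_starts: int = 8,
) -> BindingFit:
    """Multi-start least-squares Hill fit of the binding response.

    Initialization: Bmax at the maximal response, K_D at the concentration
    nearest half-max jittered geometrically over x0.25..x4, Hill slope 1
    (plus a cooperative variant per start).  ``converged`` is honest: when
    every start fails, parameters are NaN.
    """
    x = curve.concentrations
    y = curve.response(use_fraction=use_fraction)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    best = None
    failures = []
    for p0 in _initial_guesses(x, y, n_starts):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    hill_model, x, y, p0=p0,
                    bounds=([1e-12, 1e-12, 1e-3], [np.inf, np.inf, 50.0]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError) as exc:
            failures.append(str(exc))
            continue
        rss = float(np.sum((hill_model(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return BindingFit(kd=float("nan"), hill=float("nan"),
                          bmax=float("nan"), rss=float("nan"),
                          converged=False, n_points=len(x),
                          diagnostics={"failures": failures})
    (bmax, kd, h), rss = best
    return BindingFit(kd=float(kd), hill=float(h), bmax=float(bmax),
                      rss=rss, converged=True, n_points=len(x),
                      diagnostics={"n_failures": len(failures)})


def fit_report(fit: BindingFit, curve: BindingCurve) -> dict:
    return {
        "kd_nM": fit.kd,
        "hill": fit.hill,
        "bmax": fit.bmax,
        "rss": fit.rss,
        "converged": fit.converged,
        "n_points": fit.n_points,
        "excluded_baseline": curve.excluded_baseline,
        "clipped_lanes": curve.clipped_lanes,
    }
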