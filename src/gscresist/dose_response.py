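"""Dose-response curve fitting and the Drug Sensitivity Score (DSS).

The screening readout (luminescent viability) is normalized against the
plate's negative (DMSO) and positive (full-kill) controls to percent
inhibition, a four-parameter logistic (4PL) is fitted per drug per sample
on the log10 concentration axis,

    y(x) = bottom + (top - bottom) / (1 + 10^(s * (m - x))),

and DSS summarizes each fitted curve as the normalized area of drug
activity above an inhibition floor t (default 10%) across the tested
concentration window [x1, x2]:

    DSS = 100 * A / ((100 - t) * (x2 - x1)),
    A   = integral over [x1, x2] of max(0, min(y(x), 100) - t) dx.

The integral is evaluated in closed form: the logistic is monotone in x,
so the crossings with t and 100 are solved analytically and the logistic
antiderivative is applied piecewise. No extrapolation beyond the tested
range is performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import DssParams

__all__ = [
    "ViabilityScreen",
    "DoseResponseFit",
    "logistic4",
    "normalize_viability",
    "fit_4pl",
    "compute_dss",
    "dss_from_curve",
    "screen_dss",
    "build_dss_matrix",
]

LN10 = math.log(10.0)


class DegenerateControlsError(ValueError):
    """Controls do not separate (negative-control mean <= positive)."""


class UnfittableError(ValueError):
    """Fewer than two distinct doses available for curve fitting."""


@dataclass
class ViabilityScreen:
    """Per-sample raw drug-screen wells.

    ``wells`` columns: drug, dose_index, concentration, signal, well_type
    with well_type in {drug, neg_ctrl, pos_ctrl}. Control summaries are the
    plain means of the respective control wells.
    """

    sample: str
    wells: pd.DataFrame

    @property
    def neg_mean(self) -> float:
        return float(
            self.wells.loc[self.wells.well_type == "neg_ctrl", "signal"].mean()
        )

    @property
    def pos_mean(self) -> float:
        return float(
            self.wells.loc[self.wells.well_type == "pos_ctrl", "signal"].mean()
        )


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters for one (drug, sample) series.

    ``bottom`` and ``top`` are on the percent-inhibition scale;
    ``log10_ec50`` (m) and ``slope`` (s) parametrize the transition;
    ``x1``/``x2`` are log10 of the smallest/largest tested concentration.
    """

    drug: str
    sample: str
    bottom: float
    top: float
    log10_ec50: float
    slope: float
    x1: float
    x2: float
    converged: bool
    rss: float


def logistic4(x, bottom: float, top: float, log10_ec50: float,
              slope: float):
    """Evaluate the 4PL at log10-concentration ``x`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    expo = np.clip(slope * (log10_ec50 - x), -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + np.power(10.0, expo))


def normalize_viability(screen: ViabilityScreen,
                        clip_low: float = -25.0,
                        clip_high: float = 100.0) -> pd.DataFrame:
    """Convert raw drug-well signals to percent inhibition.

    inhibition = 100 * (neg_mean - signal) / (neg_mean - pos_mean), clipped
    to [clip_low, clip_high]; the mild negative allowance tolerates growth
    stimulation without letting it dominate fits.
    """
    neg, pos = screen.neg_mean, screen.pos_mean
    if not neg > pos:
        raise DegenerateControlsError(
            f"sample {screen.sample!r}: negative-control mean ({neg:.3g}) "
            f"does not exceed positive-control mean ({pos:.3g})"
        )
    drug_wells = screen.wells[screen.wells.well_type == "drug"]
    inhib = 100.0 * (neg - drug_wells["signal"]) / (neg - pos)
    out = drug_wells[["drug", "dose_index", "concentration"]].copy()
    out["inhibition"] = inhib.clip(clip_low, clip_high)
    return out.reset_index(drop=True)


def _starts(x: np.ndarray, y: np.ndarray) -> list[tuple]:
    """Four deterministic initializations for the 4PL least-squares fit."""
    b0 = float(np.min(y))
    t0 = float(np.max(y))
    mid = 0.5 * (b0 + t0)
    # x closest to the half-maximal response
    m_half = float(x[np.argmin(np.abs(y - mid))])
    m_med = float(np.median(x))
    return [
        (b0, t0, m_med, 1.0),
        (b0, t0, m_half, 1.0),
        (b0, t0, m_half, 0.3),
        (0.0, t0, m_med, 3.0),
    ]


def fit_4pl(concentrations: Sequence[float], inhibition: Sequence[float],
            drug: str = "", sample: str = "") -> DoseResponseFit:
    """Least-squares 4PL fit of percent inhibition vs log10 concentration.

    Replicate wells at the same concentration are averaged before fitting.
    Parameter bounds: bottom in [-25, 25], top in [-25, 120],
    slope in (0, 10], m in [x1 - 2, x2 + 2]. Four deterministic starts are
    tried and the best residual sum of squares kept.
    """
    conc = np.asarray(concentrations, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if not np.all(np.isfinite(y)):
        raise UnfittableError("non-finite inhibition values")
    if conc.size != y.size:
        raise UnfittableError("dose and inhibition lengths differ")
    # average replicates per distinct dose
    df = pd.DataFrame({"c": conc, "y": y}).groupby("c", sort=True).mean()
    if len(df) < 2:
        raise UnfittableError(
            f"drug {drug!r} sample {sample!r}: fewer than 2 distinct doses"
        )
    x = np.log10(df.index.to_numpy())
    yy = df["y"].to_numpy()
    x1, x2 = float(x[0]), float(x[-1])

    lo = np.array([-25.0, -25.0, x1 - 2.0, 1e-3])
    hi = np.array([25.0, 120.0, x2 + 2.0, 10.0])

    def resid(p):
        return logistic4(x, *p) - yy

    def jac(p):
        bottom, top, m, s = p
        u = np.power(10.0, np.clip(s * (m - x), -300.0, 300.0))
        f = 1.0 / (1.0 + u)
        g = u * f * f  # u / (1 + u)^2
        return np.column_stack([
            1.0 - f,
            f,
            -(top - bottom) * LN10 * s * g,
            -(top - bottom) * LN10 * (m - x) * g,
        ])

    best = None
    for p0 in _starts(x, yy):
        p0 = np.clip(np.asarray(p0, dtype=float), lo, hi)
        try:
            res = least_squares(resid, p0, jac=jac, bounds=(lo, hi),
                                xtol=1e-10, ftol=1e-10, gtol=1e-10,
                                max_nfev=300)
        except Exception:  # pragma: no cover - scipy failure path
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)
        if rss < 1e-16:  # exact fit; further starts cannot improve
            break
    if best is None:  # pragma: no cover
        return DoseResponseFit(drug, sample, 0.0, 0.0, 0.5 * (x1 + x2), 1.0,
                               x1, x2, False, float("inf"))
    rss, res = best
    bottom, top, m, s = (float(v) for v in res.x)
    # accept either scipy's own tolerance-based success or a stationary
    # point in the projected-gradient sense (series with unidentifiable
    # parameters crawl along a bound without meeting step tolerances)
    converged = (np.all(np.isfinite(res.x))
                 and (bool(res.success)
                      or float(res.optimality) <= 1e-3 * max(1.0, rss)))
    return DoseResponseFit(drug, sample, bottom, top, m, s, x1, x2,
                           converged, rss)


def _logistic_antideriv(x: float, bottom: float, top: float, m: float,
                        s: float) -> float:
    """Antiderivative of the 4PL: bottom*x + (top-bottom)/(s ln10) *
    ln(1 + 10^(s(x-m))), with an asymptotic guard for large exponents."""
    u = s * (x - m) * LN10
    if u > 700.0:
        log_term = u
    else:
        log_term = math.log1p(math.exp(u))
    return bottom * x + (top - bottom) / (s * LN10) * log_term


def _crossing(bottom: float, top: float, m: float, s: float,
              level: float) -> float | None:
    """Solve y(x) = level for the monotone 4PL; None if never attained."""
    num = top - level
    den = level - bottom
    if num == 0 or den == 0 or (num > 0) != (den > 0):
        return None
    return m - math.log10(num / den) / s


def dss_from_curve(bottom: float, top: float, log10_ec50: float,
                   slope: float, x1: float, x2: float,
                   t: float = 10.0) -> float:
    """Closed-form DSS of a 4PL curve over [x1, x2] with activity floor t.

    The inhibition curve is clipped to [0, 100] before the area above t is
    taken; the piecewise-logistic integral is exact up to floating point.
    """
    if not x1 < x2:
        raise ValueError("x1 must be < x2")
    m, s = log10_ec50, slope
    # segment the window at the (unique, monotone) crossings with t and 100
    cuts = [x1, x2]
    for level in (t, 100.0):
        xc = _crossing(bottom, top, m, s, level)
        if xc is not None and x1 < xc < x2:
            cuts.append(xc)
    cuts = sorted(cuts)
    area = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        ymid = float(logistic4(mid, bottom, top, m, s))
        if ymid <= t:
            continue
        if ymid >= 100.0:
            area += (100.0 - t) * (b - a)
        else:
            area += (_logistic_antideriv(b, bottom, top, m, s)
                     - _logistic_antideriv(a, bottom, top, m, s)
                     - t * (b - a))
    dss = 100.0 * area / ((100.0 - t) * (x2 - x1))
    return float(min(max(dss, 0.0), 100.0))


def compute_dss(fit: DoseResponseFit,
                params: DssParams | None = None) -> float:
    """DSS of a fitted curve; non-convergent fits score 0 (conservative)."""
    params = params or DssParams()
    if not fit.converged:
        warnings.warn(
            f"non-convergent fit for drug {fit.drug!r} sample "
            f"{fit.sample!r}; DSS reported as 0", stacklevel=2)
        return 0.0
    dss = dss_from_curve(fit.bottom, fit.top, fit.log10_ec50, fit.slope,
                         fit.x1, fit.x2, t=params.activity_threshold)
    if params.dss_variant == "dss2":
        # compatibility variant: additionally divide by log10(top)
        top = max(fit.top, 1.0 + 1e-9)
        dss = dss / math.log10(top) if math.log10(top) > 0 else 0.0
    return float(dss)


def screen_dss(screen: ViabilityScreen,
               params: DssParams | None = None) -> pd.Series:
    """Normalize, fit and score every drug of one sample's screen."""
    params = params or DssParams()
    inhib = normalize_viability(screen)
    out = {}
    for drug, grp in inhib.groupby("drug", sort=True):
        fit = fit_4pl(grp["concentration"], grp["inhibition"],
                      drug=drug, sample=screen.sample)
        out[drug] = compute_dss(fit, params)
    return pd.Series(out, name=screen.sample)


def build_dss_matrix(columns: Iterable[pd.Series]) -> pd.DataFrame:
    """Assemble per-sample DSS series into a drugs x samples matrix.

    Missing entries (drug not screened in a sample) become NaN. Duplicate
    (drug, sample) pairs with conflicting values raise.
    """
    cols = list(columns)
    if not cols:
        return pd.DataFrame()
    names = [c.name for c in cols]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample ids in DSS columns")
    for c in cols:
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].tolist()
            raise ValueError(
                f"sample {c.name!r}: duplicate drug entries {dup[:5]}")
    mat = pd.concat(cols, axis=1).sort_index()
    mat.index.name = "drug"
    return mat
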