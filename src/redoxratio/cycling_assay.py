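"""Enzymatic cycling quantification of the NADP(H) pool.

The destructive counterpart of biosensor imaging: an enzymatic cycle
(G6PDH / PMS / DCPIP) turns the amount of pyridine nucleotide in an extract
into a dye-reduction rate read as absorbance change at 600 nm.  Rates are
calibrated against a linear standard curve (0-400 pmol NADPH); NADPH is
measured after heat destruction of NADP+, total NADP(H) without it, and
NADP+ follows by difference.  The NADPH/NADP+ ratio converts to a pool
potential through the Nernst relation in :mod:`redoxratio.redox_core`,
enabling cross-validation of biosensor-derived potentials in single-
compartment systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import redox_core
from .redox_core import PhysicalConstants, PoolParameters

__all__ = [
    "AbsorbanceTrace",
    "StandardCurve",
    "PoolQuantification",
    "InsufficientDataError",
    "InvalidCurveError",
    "InconsistencyError",
    "rate_from_trace",
    "fit_standard_curve",
    "quantify",
    "pool_from_measurements",
    "read_standards_csv",
    "read_samples_csv",
    "quantify_samples",
]

#: Calibrated amount range of the standard curve, pmol.
STANDARD_RANGE_PMOL = (0.0, 400.0)


class InsufficientDataError(ValueError):
    """Too few points to fit a slope."""


class InvalidCurveError(ValueError):
    """Standard curve unusable for quantification (e.g. non-positive slope)."""


class InconsistencyError(ValueError):
    """NADPH exceeding total NADP(H); signals a heat-destruction artifact."""


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A600 time course of one cycling reaction."""

    time: np.ndarray
    a600: np.ndarray
    sample_id: str = ""
    dilution: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.a600, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "a600", a)
        if t.size != a.size:
            raise ValueError("time and a600 must have equal length")
        if t.size < 3:
            raise InsufficientDataError("trace needs >= 3 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.dilution <= 0:
            raise ValueError("dilution must be > 0")


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of rate vs amount over the calibration standards."""

    amounts: np.ndarray
    rates: np.ndarray
    slope: float
    intercept: float
    r_squared: float

    @property
    def rate_range(self) -> tuple[float, float]:
        return float(np.min(self.rates)), float(np.max(self.rates))


@dataclass(frozen=True)
class PoolQuantification:
    """NADPH / NADP+ / total amounts (pmol) and the derived pool potential (mV)."""

    nadph: float
    total: float
    nadp_plus: float
    e_pool: float


def rate_from_trace(
    trace: AbsorbanceTrace,
    window: tuple[float, float] | None = None,
) -> float:
    """Cycling rate as |least-squares slope| of A600 vs time (AU/s).

    Dye reduction makes A600 fall, so the raw slope is negative; the
    magnitude is returned and used throughout.
    """
    t, a = trace.time, trace.a600
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, a = t[sel], a[sel]
    if t.size < 3:
        raise InsufficientDataError(
            f"need >= 3 points in window, got {t.size}"
        )
    slope = stats.linregress(t, a).slope
    return abs(float(slope))


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """OLS standard curve (free intercept) over (amount_pmol, rate) pairs.

    r^2 is reported; an intercept above 10 % of the maximum rate draws a
    warning since the cycling blank should be small.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InsufficientDataError("need >= 3 (amount, rate) points")
    amounts, rates = pts[:, 0], pts[:, 1]
    if np.unique(amounts).size < 2:
        raise InvalidCurveError("all standard amounts identical")
    fit = stats.linregress(amounts, rates)
    r2 = float(fit.rvalue ** 2)
    if abs(fit.intercept) > 0.10 * np.max(np.abs(rates)):
        warnings.warn(
            f"standard-curve intercept {fit.intercept:.4g} exceeds 10% of the "
            "maximum rate; check the assay blank",
            stacklevel=2,
        )
    return StandardCurve(
        amounts=amounts,
        rates=rates,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
    )


def quantify(rate: float, curve: StandardCurve, dilution: float = 1.0) -> float:
    """Amount (pmol) from a sample rate via curve inversion and dilution.

    Rates outside the calibrated range draw an extrapolation warning, not an
    error.
    """
    if curve.slope <= 0:
        raise InvalidCurveError(f"standard-curve slope must be > 0, got {curve.slope}")
    lo, hi = curve.rate_range
    if not lo <= rate <= hi:
        warnings.warn(
            f"rate {rate:.4g} outside calibrated range [{lo:.4g}, {hi:.4g}]; "
            "extrapolating",
            stacklevel=2,
        )
    return (rate - curve.intercept) / curve.slope * dilution


def pool_from_measurements(
    nadph: float,
    total: float,
    ph: float = 7.0,
    *,
    e0_pool: float = -320.0,
    const: PhysicalConstants | None = None,
    clip_eps: float = 1e-6,
) -> PoolQuantification:
    """NADP+ by difference and the pool potential from the NADPH/NADP+ ratio.

    ``nadph > total`` raises :class:`InconsistencyError` (the selective heat
    destruction step failed).  Fully reduced or oxidised pools are clipped
    by ``clip_eps`` of the total before the log, mirroring the OxD policy.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if nadph < 0:
        raise ValueError("nadph must be >= 0")
    if nadph > total:
        raise InconsistencyError(
            f"NADPH ({nadph}) exceeds total NADP(H) ({total}); "
            "heat-destruction artifact suspected"
        )
    nadp_plus = total - nadph
    lo = clip_eps * total
    ratio = min(max(nadph, lo), total - lo) / max(nadp_plus, lo)
    e = redox_core.e_pool_from_ratio(
        PoolParameters(e0_pool=e0_pool, ratio_red_ox=ratio), ph, const
    )
    return PoolQuantification(nadph=nadph, total=total, nadp_plus=nadp_plus, e_pool=e)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_standards_csv(path: str | Path) -> StandardCurve:
    """Fit the standard curve from a CSV with columns amount_pmol, rate."""
    df = pd.read_csv(path)
    if not {"amount_pmol", "rate"} <= set(df.columns):
        raise ValueError("standards CSV needs columns amount_pmol, rate")
    return fit_standard_curve(list(zip(df["amount_pmol"], df["rate"])))


def read_samples_csv(path: str | Path) -> pd.DataFrame:
    """Samples CSV with columns sample_id, rate, dilution, kind in {total, nadph}."""
    df = pd.read_csv(path)
    required = {"sample_id", "rate", "dilution", "kind"}
    if not required <= set(df.columns):
        raise ValueError(f"samples CSV needs columns {sorted(required)}")
    bad = set(df["kind"]) - {"total", "nadph"}
    if bad:
        raise ValueError(f"unknown sample kind(s): {sorted(bad)}")
    return df


def quantify_samples(
    curve: StandardCurve,
    samples: pd.DataFrame,
    ph: float = 7.0,
    *,
    e0_pool: float = -320.0,
    const: PhysicalConstants | None = None,
) -> pd.DataFrame:
    """Pair total/nadph rows per sample_id into pool quantifications.

    Returns a table with columns sample_id, nadph_pmol, nadp_plus_pmol,
    total_pmol, ratio, e_pool_mV.
    """
    rows = []
    for sid, grp in samples.groupby("sample_id", sort=True):
        kinds = dict(zip(grp["kind"], zip(grp["rate"], grp["dilution"])))
        if "total" not in kinds or "nadph" not in kinds:
            raise ValueError(f"sample {sid!r} needs both a total and a nadph row")
        rate_t, dil_t = kinds["total"]
        rate_n, dil_n = kinds["nadph"]
        total = quantify(float(rate_t), curve, float(dil_t))
        nadph = quantify(float(rate_n), curve, float(dil_n))
        q = pool_from_measurements(nadph, total, ph, e0_pool=e0_pool, const=const)
        rows.append(
            {
                "sample_id": sid,
                "nadph_pmol": q.nadph,
                "nadp_plus_pmol": q.nadp_plus,
                "total_pmol": q.total,
                "ratio": q.nadph / q.nadp_plus if q.nadp_plus > 0 else np.inf,
                "e_pool_mV": q.e_pool,
            }
        )
    return pd.DataFrame(rows)
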