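"""Closed-form biophysics of roGFP2-type ratiometric redox probes.

A redox-sensitive fluorescent protein exposes two excitation maxima whose
emission intensities trade against each other as the engineered dithiol is
oxidised.  The fluorescence ratio ``R = I_short / I_long`` therefore encodes
the degree of oxidation of the probe (``OxD``), which the Nernst equation in
turn maps onto a redox potential ``E`` (in mV, negative = reducing).  This
module collects every closed-form relation in that chain:

* ``OxD`` from ``R`` and instrument calibration endpoints, and its inverse;
* ``E`` from ``OxD`` via the Nernst equation (n = 2 electrons), and inverse;
* the pool potential of a two-electron redox couple (e.g. NADPH/NADP+) from
  its reduced/oxidised concentration ratio, and inverse;
* the pH correction of midpoint potentials (2 H+ per 2 e-) and the 5-95 %
  oxidation detection window derived from it;
* the equilibrium titration forward model linking pool ratios to probe
  ratios;
* small helpers: dynamic range, relative quantum yield, Beer-Lambert.

All potentials are handled in millivolts throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PhysicalConstants",
    "ProbeCalibration",
    "RedoxState",
    "PoolParameters",
    "QuantumYieldInput",
    "SpectralConstants",
    "DegenerateCalibrationError",
    "OutOfRangeError",
    "UnboundedPotentialError",
    "oxd_from_ratio",
    "ratio_from_oxd",
    "e_from_oxd",
    "oxd_from_e",
    "ph_corrected_midpoint",
    "detection_window",
    "e_pool_from_ratio",
    "ratio_from_e_pool",
    "titration_curve",
    "dynamic_range",
    "quantum_yield",
    "concentration_from_absorbance",
    "nernst_slope_mv",
    "calibration_to_yaml",
    "calibration_from_yaml",
    "read_plate_table",
    "write_plate_table",
    "write_titration_csv",
]

PhMode = Literal["paper_rounded", "exact_nernst"]

#: Linear pH slope of the rounded convention: -6 mV per 0.1 pH unit.
PH_SLOPE_ROUNDED_MV = -60.0


class DegenerateCalibrationError(ValueError):
    """Calibration endpoints coincide or are inverted; R carries no information."""


class OutOfRangeError(ValueError):
    """A measured value lies outside the physically meaningful domain."""


class UnboundedPotentialError(ValueError):
    """OxD of exactly 0 or 1 maps to an infinite potential in strict mode."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic constants of the Nernst term.

    Parameters
    ----------
    gas_constant : float
        Molar gas constant, J mol^-1 K^-1.
    faraday : float
        Faraday constant, C mol^-1.
    temperature : float
        Absolute temperature, K.  298 K unless an experiment says otherwise.
    n_electrons : int
        Electrons exchanged by the couple; 2 for the dithiol/disulfide and
        for NADPH/NADP+.
    """

    gas_constant: float = 8.314
    faraday: float = 96485.0
    temperature: float = 298.0
    n_electrons: int = 2

    def __post_init__(self) -> None:
        if self.gas_constant <= 0 or self.faraday <= 0 or self.temperature <= 0:
            raise ValueError("physical constants must be strictly positive")
        if int(self.n_electrons) != self.n_electrons or self.n_electrons < 1:
            raise ValueError("n_electrons must be an integer >= 1")


def nernst_slope_mv(const: PhysicalConstants | None = None) -> float:
    """RT/nF in millivolts (~12.84 mV for n = 2 at 298 K)."""
    c = const or PhysicalConstants()
    return 1000.0 * c.gas_constant * c.temperature / (c.n_electrons * c.faraday)


@dataclass(frozen=True)
class ProbeCalibration:
    """Instrument-specific endpoint calibration of a ratiometric probe.

    ``r_ox`` and ``r_red`` are the fluorescence ratios of the fully oxidised
    and fully reduced probe on this instrument; ``i490_min``/``i490_max`` are
    the long-wavelength (490-type) emission intensities of the fully oxidised
    and fully reduced forms, whose quotient corrects the OxD formula for the
    oxidation dependence of the denominator channel.
    """

    r_ox: float
    r_red: float
    i490_min: float
    i490_max: float
    e0_probe: float = -280.0  # mV at pH 7
    protons_per_2e: int = 2
    lambda_short: str = "405"
    lambda_long: str = "488"

    def __post_init__(self) -> None:
        if not (self.r_ox > self.r_red > 0):
            raise DegenerateCalibrationError(
                f"require r_ox > r_red > 0, got r_ox={self.r_ox}, r_red={self.r_red}"
            )
        if not (self.i490_max >= self.i490_min > 0):
            raise ValueError(
                f"require i490_max >= i490_min > 0, got "
                f"i490_min={self.i490_min}, i490_max={self.i490_max}"
            )

    @property
    def i_ratio(self) -> float:
        """i490_min / i490_max, the denominator-channel correction factor."""
        return self.i490_min / self.i490_max

    @property
    def dynamic_range(self) -> float:
        return self.r_ox - self.r_red


@dataclass(frozen=True)
class RedoxState:
    """Paired (OxD, E, pH, T) description of a probe or pool at one condition."""

    oxd: float
    e: float
    ph: float = 7.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.oxd <= 1.0:
            raise ValueError(f"oxd must lie in [0, 1], got {self.oxd}")
        if not math.isfinite(self.e):
            raise ValueError("e must be finite")
        if not 4.0 <= self.ph <= 10.0:
            raise ValueError(f"ph must lie in [4, 10], got {self.ph}")


@dataclass(frozen=True)
class PoolParameters:
    """A two-electron redox pool (default: NADPH/NADP+, E0' = -320 mV, pH 7)."""

    e0_pool: float = -320.0
    ratio_red_ox: float = 1.0
    total_conc: float | None = None

    def __post_init__(self) -> None:
        if self.ratio_red_ox <= 0:
            raise ValueError("ratio_red_ox must be > 0")
        if self.total_conc is not None and self.total_conc <= 0:
            raise ValueError("total_conc must be > 0 when set")


@dataclass(frozen=True)
class QuantumYieldInput:
    """Integrated emissions of sample and reference standard at matched absorbance."""

    f_sample: float
    f_standard: float
    phi_standard: float = 0.89  # fluorescein in 0.1 N NaOH

    def __post_init__(self) -> None:
        if self.f_sample <= 0 or self.f_standard <= 0:
            raise ValueError("emission intensities must be > 0")
        if not 0 < self.phi_standard <= 1:
            raise ValueError("phi_standard must lie in (0, 1]")


@dataclass(frozen=True)
class SpectralConstants:
    """Molar extinction coefficients of the probe, mM^-1 cm^-1."""

    eps_488_ox: float = 13.0
    eps_488_red: float = 21.8
    eps_387_ox: float = 17.7

    def __post_init__(self) -> None:
        if min(self.eps_488_ox, self.eps_488_red, self.eps_387_ox) <= 0:
            raise ValueError("extinction coefficients must be > 0")


# ---------------------------------------------------------------------------
# OxD <-> R
# ---------------------------------------------------------------------------

def oxd_from_ratio(
    r,
    calib: ProbeCalibration,
    *,
    clip: bool = True,
    strict: bool = False,
):
    """Degree of oxidation from a fluorescence ratio.

    OxD = (R - R_red) / [ (I_min/I_max) (R_ox - R) + (R - R_red) ]

    Parameters
    ----------
    r : float or array-like
        Measured short/long emission ratio(s).
    calib : ProbeCalibration
        Endpoint calibration of the instrument.
    clip : bool
        When True (default) the result is clipped to [0, 1]; noise can push
        measured R slightly past the calibration endpoints.  A warning
        carrying the number of clipped values is emitted.
    strict : bool
        When True, R outside [r_red, r_ox] raises :class:`OutOfRangeError`
        instead of clipping.
    """
    if calib.r_ox == calib.r_red:  # unreachable through the dataclass, kept for raw use
        raise DegenerateCalibrationError("r_ox == r_red")
    arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("r must be finite")
    if strict:
        bad = (arr < calib.r_red) | (arr > calib.r_ox)
        if np.any(bad):
            offending = arr[bad] if arr.ndim else arr
            raise OutOfRangeError(
                f"ratio {offending} outside calibration range "
                f"[{calib.r_red}, {calib.r_ox}]"
            )
    num = arr - calib.r_red
    den = calib.i_ratio * (calib.r_ox - arr) + num
    with np.errstate(divide="ignore", invalid="ignore"):
        oxd = num / den
    if clip:
        n_out = int(np.sum((oxd < 0) | (oxd > 1)))
        if n_out:
            warnings.warn(
                f"{n_out} ratio value(s) outside calibration endpoints; "
                "OxD clipped to [0, 1]",
                stacklevel=2,
            )
        oxd = np.clip(oxd, 0.0, 1.0)
    return float(oxd) if np.isscalar(r) or np.ndim(r) == 0 else oxd


def ratio_from_oxd(oxd, calib: ProbeCalibration):
    """Algebraic inverse of :func:`oxd_from_ratio` on OxD in [0, 1]."""
    arr = np.asarray(oxd, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise ValueError("oxd must lie in [0, 1]")
    f = calib.i_ratio
    num = (1.0 - arr) * calib.r_red + arr * f * calib.r_ox
    den = (1.0 - arr) + arr * f
    r = num / den
    return float(r) if np.ndim(oxd) == 0 else r


# ---------------------------------------------------------------------------
# Nernst equation: OxD <-> E
# ---------------------------------------------------------------------------

def e_from_oxd(
    oxd,
    e0: float,
    const: PhysicalConstants | None = None,
    *,
    clip_eps: float = 1e-6,
    strict: bool = False,
):
    """Redox potential (mV) of a probe at degree of oxidation ``oxd``.

    E = E0' - (RT/nF) ln((1 - OxD)/OxD)

    OxD is clipped into [clip_eps, 1 - clip_eps] before the logarithm unless
    ``strict`` is set, in which case endpoint values raise
    :class:`UnboundedPotentialError`.
    """
    const = const or PhysicalConstants()
    arr = np.asarray(oxd, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("oxd must lie in [0, 1]")
    if strict and np.any((arr == 0.0) | (arr == 1.0)):
        raise UnboundedPotentialError("OxD of exactly 0 or 1 has unbounded potential")
    arr = np.clip(arr, clip_eps, 1.0 - clip_eps)
    e = e0 - nernst_slope_mv(const) * np.log((1.0 - arr) / arr)
    return float(e) if np.ndim(oxd) == 0 else e


def oxd_from_e(e, e0: float, const: PhysicalConstants | None = None):
    """Logistic inverse of :func:`e_from_oxd`; exact round trip."""
    const = const or PhysicalConstants()
    arr = np.asarray(e, dtype=float)
    # OxD = 1 / (1 + exp((e0 - E)/slope)); overflow saturates cleanly to 0
    with np.errstate(over="ignore"):
        oxd = 1.0 / (1.0 + np.exp((e0 - arr) / nernst_slope_mv(const)))
    return float(oxd) if np.ndim(e) == 0 else oxd


# ---------------------------------------------------------------------------
# pH correction and detection window
# ---------------------------------------------------------------------------

def ph_corrected_midpoint(
    e0_ph7: float,
    ph: float,
    mode: PhMode = "paper_rounded",
    const: PhysicalConstants | None = None,
) -> float:
    """Midpoint potential shifted from pH 7 to ``ph``.

    The probe exchanges 2 H+ per 2 e-, so the midpoint moves by roughly
    -59 mV per pH unit.  ``paper_rounded`` (default) applies the rounded
    field convention of exactly -6 mV per 0.1 unit (-60 mV/pH), extended
    linearly below pH 7 as well; ``exact_nernst`` uses RT ln10 / F.
    """
    if not 4.0 <= ph <= 10.0:
        raise ValueError(f"ph must lie in [4, 10], got {ph}")
    if mode == "paper_rounded":
        slope = PH_SLOPE_ROUNDED_MV
    elif mode == "exact_nernst":
        c = const or PhysicalConstants()
        slope = -1000.0 * c.gas_constant * c.temperature * math.log(10.0) / c.faraday
    else:
        raise ValueError(f"unknown pH mode {mode!r}")
    return e0_ph7 + slope * (ph - 7.0)


def _half_window_mv(const: PhysicalConstants) -> float:
    """5-95 % oxidation half-window, rounded to the nearest 10 mV per side."""
    exact = nernst_slope_mv(const) * math.log(0.95 / 0.05)
    return round(exact / 10.0) * 10.0


def detection_window(
    ph: float,
    calib: ProbeCalibration | None = None,
    const: PhysicalConstants | None = None,
    mode: PhMode = "paper_rounded",
) -> tuple[float, float]:
    """Potential interval over which 5-95 % probe oxidation is resolvable.

    Returns ``(e_lower, e_upper)`` in mV: the pH-corrected midpoint plus or
    minus the Nernst half-window rounded to the nearest 10 mV per side
    (40 mV for n = 2 at 298 K, giving the conventional 80 mV window).
    """
    const = const or PhysicalConstants()
    e0 = calib.e0_probe if calib is not None else -280.0
    mid = ph_corrected_midpoint(e0, ph, mode=mode, const=const)
    half = _half_window_mv(const)
    return (mid - half, mid + half)


# ---------------------------------------------------------------------------
# Pool potential <-> concentration ratio
# ---------------------------------------------------------------------------

def e_pool_from_ratio(
    pool: PoolParameters,
    ph: float = 7.0,
    const: PhysicalConstants | None = None,
    *,
    ph_correct_pool: bool = False,
) -> float:
    """Pool potential from the reduced/oxidised concentration ratio.

    E = E0'_pool - (RT/nF) ln([red]/[ox])

    By default ``e0_pool`` is used as given (its standard value already
    refers to pH 7 and the couple binds 1 H+ per 2 e-, a correction the
    convention here omits).  Set ``ph_correct_pool`` to apply -29.6 mV per
    pH unit above 7 instead.
    """
    const = const or PhysicalConstants()
    if pool.ratio_red_ox <= 0:
        raise ValueError("ratio_red_ox must be > 0")
    e0 = pool.e0_pool
    if ph_correct_pool:
        c = const
        # 1 H+ per 2 e-: half the full proton slope
        e0 = e0 - 0.5 * 1000.0 * c.gas_constant * c.temperature * math.log(10.0) / c.faraday * (ph - 7.0)
    return e0 - nernst_slope_mv(const) * math.log(pool.ratio_red_ox)


def ratio_from_e_pool(
    e: float, e0_pool: float = -320.0, const: PhysicalConstants | None = None
) -> float:
    """Inverse of :func:`e_pool_from_ratio`: [red]/[ox] = exp((E0' - E) nF/RT)."""
    const = const or PhysicalConstants()
    return math.exp((e0_pool - e) / nernst_slope_mv(const))


# ---------------------------------------------------------------------------
# Titration forward model
# ---------------------------------------------------------------------------

def titration_curve(
    ratios: Sequence[float] | np.ndarray,
    calib: ProbeCalibration,
    pool: PoolParameters | None = None,
    ph: float = 7.0,
    const: PhysicalConstants | None = None,
) -> pd.DataFrame:
    """Equilibrium titration of the probe against a redox pool.

    Assumes the probe equilibrates with the pool at every point
    (E_probe = E_pool), so each concentration ratio maps to a pool
    potential, a probe OxD through the pH-corrected midpoint, and a
    fluorescence ratio R.  Returns a DataFrame with columns
    ``ratio, e_pool_mV, oxd, r``; OxD decreases as the reduced fraction
    grows.
    """
    pool = pool or PoolParameters()
    const = const or PhysicalConstants()
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("all ratios must be > 0")
    e0_mid = ph_corrected_midpoint(calib.e0_probe, ph)
    e_pool = np.array(
        [
            e_pool_from_ratio(
                PoolParameters(pool.e0_pool, float(rr), pool.total_conc), ph, const
            )
            for rr in ratios
        ]
    )
    oxd = oxd_from_e(e_pool, e0_mid, const)
    r = ratio_from_oxd(oxd, calib)
    return pd.DataFrame({"ratio": ratios, "e_pool_mV": e_pool, "oxd": oxd, "r": r})


# ---------------------------------------------------------------------------
# Small helpers
# ---------------------------------------------------------------------------

def dynamic_range(r_ox: float, r_red: float) -> float:
    """Dynamic range DR = R_ox - R_red; the probe's measurement sensitivity."""
    if r_ox <= r_red:
        raise DegenerateCalibrationError(
            f"r_ox must exceed r_red, got r_ox={r_ox}, r_red={r_red}"
        )
    return r_ox - r_red


def quantum_yield(qy: QuantumYieldInput) -> float:
    """Relative fluorescence quantum yield against a matched-absorbance standard."""
    return qy.phi_standard * qy.f_sample / qy.f_standard


def concentration_from_absorbance(a: float, eps: float, path: float = 1.0) -> float:
    """Beer-Lambert: concentration (mM) = A / (eps * path)."""
    if eps <= 0 or path <= 0:
        raise ValueError("eps and path must be > 0")
    if a < 0:
        raise ValueError("absorbance must be >= 0")
    return a / (eps * path)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def calibration_to_yaml(
    calib: ProbeCalibration,
    path: str | Path,
    *,
    e0_pool_mv: float = -320.0,
    temperature_k: float = 298.0,
    ph_mode: PhMode = "paper_rounded",
) -> None:
    """Write a calibration block as YAML (keys match the run-config schema)."""
    payload = {
        "r_ox": float(calib.r_ox),
        "r_red": float(calib.r_red),
        "i490_min": float(calib.i490_min),
        "i490_max": float(calib.i490_max),
        "e0_probe_mV": float(calib.e0_probe),
        "e0_pool_mV": float(e0_pool_mv),
        "temperature_K": float(temperature_k),
        "ph_mode": str(ph_mode),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def calibration_from_yaml(path: str | Path) -> tuple[ProbeCalibration, dict]:
    """Read a YAML calibration; returns the calibration and the raw mapping."""
    raw = yaml.safe_load(Path(path).read_text())
    calib = ProbeCalibration(
        r_ox=float(raw["r_ox"]),
        r_red=float(raw["r_red"]),
        i490_min=float(raw["i490_min"]),
        i490_max=float(raw["i490_max"]),
        e0_probe=float(raw.get("e0_probe_mV", -280.0)),
    )
    return calib, raw


PLATE_COLUMNS = ["time_s", "excitation_nm", "emission_nm", "intensity", "well", "condition"]


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Read a plate-reader intensity table; validates the column set."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    return df[PLATE_COLUMNS]


def write_plate_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    df[PLATE_COLUMNS].to_csv(path, index=False)


def write_titration_csv(curve: pd.DataFrame, path: str | Path) -> None:
    """Write a titration table with columns ratio, e_pool_mV, oxd, r."""
    curve[["ratio", "e_pool_mV", "oxd", "r"]].to_csv(path, index=False)
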