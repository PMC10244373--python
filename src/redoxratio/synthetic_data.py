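"""Seeded generators for every input class the pipeline consumes.

No public raw data accompany the experiments this package models, so each
stage is exercised against synthetic inputs carrying their own ground
truth: two-channel microscope scenes with per-cell true potentials,
equilibrium titration tables, and cycling-assay standard/sample CSVs.

The image model is deliberately the same forward model the analysis
inverts: per cell, the true potential fixes OxD through the pH-corrected
midpoint; the long-wavelength channel interpolates linearly between the
calibration endpoint intensities in OxD (exactly the assumption under which
the endpoint-corrected OxD formula is exact); the short channel is defined
through R, guaranteeing self-consistency.  A low-order background plane and
Poisson-then-Gaussian noise complete the scene.  Everything is reproducible
from an integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

from . import redox_core
from .ratio_imaging import ChannelStack
from .redox_core import PhysicalConstants, PoolParameters, ProbeCalibration

__all__ = [
    "CellSpec",
    "SyntheticScene",
    "SyntheticTitration",
    "default_calibration",
    "render_scene",
    "random_scene",
    "write_scene",
    "simulate_titration",
    "fit_titration_midpoint",
    "simulate_cycling",
    "simulate_perturbation_series",
    "recover_scene",
]

#: Endpoint intensity quotient mirrors the probe's 488-nm extinction
#: coefficients (13.0 oxidised / 21.8 reduced); DR 1.4 sits at the top of
#: the range seen in bacterial imaging.
def default_calibration() -> ProbeCalibration:
    return ProbeCalibration(r_ox=1.9, r_red=0.5, i490_min=596.0, i490_max=1000.0)


@dataclass(frozen=True)
class CellSpec:
    """One elliptical cell: center (x, y), radii, true potential, expression."""

    cx: float
    cy: float
    rx: float
    ry: float
    e_true: float
    expression: float = 2000.0

    def __post_init__(self) -> None:
        if self.expression <= 0:
            raise ValueError("expression must be > 0")
        if self.rx <= 0 or self.ry <= 0:
            raise ValueError("radii must be > 0")


@dataclass(frozen=True)
class SyntheticScene:
    """Ground-truth specification from which a two-channel image is rendered."""

    shape: tuple[int, int] = (256, 256)
    cells: tuple[CellSpec, ...] = ()
    ph: float = 7.3
    calibration: ProbeCalibration = field(default_factory=default_calibration)
    background_mean: float = 50.0
    background_gradient: tuple[float, float] = (0.02, 0.03)  # counts/px in x, y
    poisson: bool = True
    read_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        for c in self.cells:
            if not (0 <= c.cx < w and 0 <= c.cy < h):
                raise ValueError(f"cell center ({c.cx}, {c.cy}) outside image {self.shape}")


@dataclass(frozen=True)
class SyntheticTitration:
    """Replicate design of a noisy titration experiment."""

    ratios: tuple[float, ...]
    total: float = 1.0  # mM
    noise_sd_r: float = 0.02
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _background_plane(scene: SyntheticScene) -> np.ndarray:
    h, w = scene.shape
    yy, xx = np.mgrid[0:h, 0:w]
    gx, gy = scene.background_gradient
    plane = scene.background_mean + gx * (xx - w / 2) + gy * (yy - h / 2)
    return np.clip(plane, 0.0, None)


def _cell_mask(scene_shape: tuple[int, int], cell: CellSpec) -> np.ndarray:
    h, w = scene_shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cell.cx) / cell.rx) ** 2 + ((yy - cell.cy) / cell.ry) ** 2 <= 1.0


def render_scene(
    scene: SyntheticScene,
    const: PhysicalConstants | None = None,
) -> tuple[ChannelStack, pd.DataFrame]:
    """Render a scene to a two-channel stack plus its ground-truth table.

    Cells whose true potential falls outside the 5-95 % detection window at
    the scene's pH are flagged ``in_window = False`` in the truth table
    (recovery there is not guaranteed); rendering itself proceeds normally.
    """
    const = const or PhysicalConstants()
    calib = scene.calibration
    e0_mid = redox_core.ph_corrected_midpoint(calib.e0_probe, scene.ph)
    lo, hi = redox_core.detection_window(scene.ph, calib, const)

    expected_short = _background_plane(scene)
    expected_long = expected_short.copy()
    truth_rows = []
    for i, cell in enumerate(scene.cells, start=1):
        oxd = redox_core.oxd_from_e(cell.e_true, e0_mid, const)
        r_true = redox_core.ratio_from_oxd(oxd, calib)
        long_i = (
            cell.expression
            * (calib.i490_max + oxd * (calib.i490_min - calib.i490_max))
            / calib.i490_max
        )
        short_i = r_true * long_i
        m = _cell_mask(scene.shape, cell)
        expected_long[m] += long_i
        expected_short[m] += short_i
        truth_rows.append(
            {
                "cell_id": i,
                "cx": cell.cx,
                "cy": cell.cy,
                "rx": cell.rx,
                "ry": cell.ry,
                "e_true_mV": cell.e_true,
                "oxd_true": oxd,
                "r_true": r_true,
                "expression": cell.expression,
                "in_window": bool(lo <= cell.e_true <= hi),
            }
        )

    rng = np.random.default_rng(scene.seed)
    short = expected_short
    long = expected_long
    if scene.poisson:
        short = rng.poisson(short).astype(float)
        long = rng.poisson(long).astype(float)
    if scene.read_sd > 0:
        short = short + rng.normal(0.0, scene.read_sd, short.shape)
        long = long + rng.normal(0.0, scene.read_sd, long.shape)
    short = np.clip(short, 0.0, None)
    long = np.clip(long, 0.0, None)

    stack = ChannelStack(
        short=short,
        long=long,
        axes="yx",
        provenance={
            "synthetic": True,
            "seed": scene.seed,
            "ph": scene.ph,
            "background_mean": scene.background_mean,
            "n_cells": len(scene.cells),
        },
    )
    truth = pd.DataFrame(truth_rows)
    return stack, truth


def random_scene(
    n_cells: int = 50,
    *,
    shape: tuple[int, int] = (256, 256),
    e_range: tuple[float, float] = (-340.0, -280.0),
    ph: float = 7.3,
    expression: float = 2000.0,
    radius_range: tuple[float, float] = (5.0, 9.0),
    calibration: ProbeCalibration | None = None,
    poisson: bool = True,
    read_sd: float = 3.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> SyntheticScene:
    """Random non-overlapping scene with per-cell potentials U(e_range).

    Cell placement uses rejection sampling against already-placed cells
    (bounding circles + 2 px margin); exceeding ``max_tries`` raises.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    calibration = calibration or default_calibration()
    placed: list[CellSpec] = []
    tries = 0
    while len(placed) < n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in {max_tries} tries"
            )
        tries += 1
        rx = rng.uniform(*radius_range)
        ry = rng.uniform(*radius_range)
        cx = rng.uniform(rx + 2, w - rx - 3)
        cy = rng.uniform(ry + 2, h - ry - 3)
        rad = max(rx, ry)
        ok = all(
            np.hypot(cx - o.cx, cy - o.cy) > rad + max(o.rx, o.ry) + 2.0
            for o in placed
        )
        if not ok:
            continue
        e_true = rng.uniform(*e_range)
        placed.append(CellSpec(cx, cy, rx, ry, e_true, expression))
    return SyntheticScene(
        shape=shape,
        cells=tuple(placed),
        ph=ph,
        calibration=calibration,
        poisson=poisson,
        read_sd=read_sd,
        seed=seed,
    )


def write_scene(
    scene: SyntheticScene,
    prefix: str | Path,
    const: PhysicalConstants | None = None,
) -> dict[str, Path]:
    """Render and write <prefix>_ch0.tif, _ch1.tif, _truth.csv, _provenance.json."""
    prefix = Path(prefix)
    stack, truth = render_scene(scene, const)
    paths = {
        "ch0": prefix.parent / f"{prefix.name}_ch0.tif",
        "ch1": prefix.parent / f"{prefix.name}_ch1.tif",
        "truth": prefix.parent / f"{prefix.name}_truth.csv",
        "provenance": prefix.parent / f"{prefix.name}_provenance.json",
    }
    tifffile.imwrite(str(paths["ch0"]), stack.short.astype(np.float32))
    tifffile.imwrite(str(paths["ch1"]), stack.long.astype(np.float32))
    truth.to_csv(paths["truth"], index=False)
    paths["provenance"].write_text(
        json.dumps(stack.provenance, indent=2, sort_keys=True, default=str)
    )
    return paths


def recover_scene(
    scene: SyntheticScene,
    *,
    bg_roi=None,
    min_cell_area: int = 20,
    statistic: str = "ratio_of_means",
    const: PhysicalConstants | None = None,
) -> pd.DataFrame:
    """Run the full pipeline on a rendered scene and pair results with truth.

    Render -> background subtract -> Otsu mask -> pixel ratio -> per-cell
    measurement -> E, then match each segmented cell to the nearest
    ground-truth cell by centroid.  Returns the truth table with appended
    measured columns (``r_meas``, ``oxd_meas``, ``e_meas_mV``,
    ``e_err_mV``); unmatched truth cells carry NaN.
    """
    from skimage.measure import regionprops

    from . import ratio_imaging as ri

    const = const or PhysicalConstants()
    if bg_roi is None:
        bg_roi = ri.Roi(0, 0, 12, 12)
    stack, truth = render_scene(scene, const)
    corr = ri.subtract_background(stack, bg_roi)
    mask, labels = ri.build_mask(corr, min_cell_area=min_cell_area)
    rmap = ri.ratio_map(corr, mask)
    cells = ri.measure_cells(
        rmap, corr, labels,
        calib=scene.calibration, ph=scene.ph,
        statistic=statistic, const=const, min_cell_area=min_cell_area,
    )
    centroids = {p.label: p.centroid for p in regionprops(labels)}
    meas = {}
    for c in cells:
        cy, cx = centroids[c.cell_id]
        d2 = (truth["cx"] - cx) ** 2 + (truth["cy"] - cy) ** 2
        tid = int(truth.loc[d2.idxmin(), "cell_id"])
        # keep the closer match if two segments map to one truth cell
        if tid not in meas or d2.min() < meas[tid][0]:
            meas[tid] = (float(d2.min()), c)
    out = truth.copy()
    out["r_meas"] = np.nan
    out["oxd_meas"] = np.nan
    out["e_meas_mV"] = np.nan
    for tid, (_, c) in meas.items():
        idx = out.index[out["cell_id"] == tid][0]
        out.loc[idx, "r_meas"] = c.r
        out.loc[idx, "oxd_meas"] = c.oxd
        out.loc[idx, "e_meas_mV"] = c.e
    out["e_err_mV"] = out["e_meas_mV"] - out["e_true_mV"]
    return out


# ---------------------------------------------------------------------------
# Titration simulation and midpoint fitting
# ---------------------------------------------------------------------------

def simulate_titration(
    spec: SyntheticTitration,
    calib: ProbeCalibration | None = None,
    pool: PoolParameters | None = None,
    ph: float = 7.0,
    const: PhysicalConstants | None = None,
) -> pd.DataFrame:
    """Noisy replicate R values over a titration design.

    Gaussian noise of sd ``noise_sd_r`` is added to the noiseless forward
    curve independently per replicate; columns are
    ``replicate, ratio, e_pool_mV, oxd_true, r_true, r``.
    """
    calib = calib or default_calibration()
    curve = redox_core.titration_curve(list(spec.ratios), calib, pool, ph, const)
    rng = np.random.default_rng(spec.seed)
    frames = []
    for rep in range(spec.replicates):
        noisy = curve["r"].to_numpy() + rng.normal(0.0, spec.noise_sd_r, len(curve))
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "ratio": curve["ratio"],
                    "e_pool_mV": curve["e_pool_mV"],
                    "oxd_true": curve["oxd"],
                    "r_true": curve["r"],
                    "r": noisy,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def fit_titration_midpoint(
    e_pool: np.ndarray,
    r: np.ndarray,
    calib: ProbeCalibration,
    const: PhysicalConstants | None = None,
) -> float:
    """Recover the probe midpoint (mV) from noisy (E_pool, R) titration data.

    Converts R to OxD with the calibration and fits the two-electron Nernst
    sigmoid OxD(E) = 1/(1 + exp((e0 - E)/slope)) by nonlinear least squares
    with e0 free.
    """
    from scipy.optimize import curve_fit

    const = const or PhysicalConstants()
    slope = redox_core.nernst_slope_mv(const)
    oxd = np.asarray(redox_core.oxd_from_ratio(np.asarray(r, dtype=float), calib))
    e_pool = np.asarray(e_pool, dtype=float)

    def model(e, e0):
        return 1.0 / (1.0 + np.exp((e0 - e) / slope))

    p0 = [float(np.median(e_pool))]
    popt, _ = curve_fit(model, e_pool, oxd, p0=p0)
    return float(popt[0])


# ---------------------------------------------------------------------------
# Cycling simulation
# ---------------------------------------------------------------------------

def simulate_cycling(
    true_nadph: float,
    true_total: float,
    *,
    curve_slope: float = 0.002,
    intercept: float = 0.0,
    noise_frac: float = 0.0,
    n_standards: int = 9,
    standard_max_pmol: float = 400.0,
    dilution: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standards and samples CSV tables from a linear rate model.

    Rates follow rate = slope * pmol + intercept, perturbed by multiplicative
    Gaussian noise of fractional sd ``noise_frac``.  Returns
    ``(standards, samples)`` DataFrames matching the cycling_assay readers.
    """
    if not 0 <= true_nadph <= true_total:
        raise ValueError("need 0 <= true_nadph <= true_total")
    rng = np.random.default_rng(seed)
    amounts = np.linspace(0.0, standard_max_pmol, n_standards)
    std_rates = curve_slope * amounts + intercept
    if noise_frac > 0:
        std_rates = std_rates * (1.0 + rng.normal(0.0, noise_frac, std_rates.shape))
    standards = pd.DataFrame({"amount_pmol": amounts, "rate": std_rates})

    def sample_rate(amount: float) -> float:
        rate = curve_slope * amount / dilution + intercept
        if noise_frac > 0:
            rate *= 1.0 + rng.normal(0.0, noise_frac)
        return rate

    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s1"],
            "rate": [sample_rate(true_total), sample_rate(true_nadph)],
            "dilution": [dilution, dilution],
            "kind": ["total", "nadph"],
        }
    )
    return standards, samples


# ---------------------------------------------------------------------------
# Perturbation time series
# ---------------------------------------------------------------------------

PerturbationEvent = Literal["oxidant", "reductant", "nox_drain"]


def simulate_perturbation_series(
    base_scene: SyntheticScene,
    event: PerturbationEvent,
    frames: int,
    *,
    event_frame: int = 1,
    const: PhysicalConstants | None = None,
) -> tuple[list[SyntheticScene], pd.DataFrame]:
    """Per-frame scenes emulating a chemical or enzymatic redox perturbation.

    ``oxidant`` steps every cell's true potential to just inside the
    oxidised edge of the detection window at ``event_frame``; ``reductant``
    steps to the reduced edge; ``nox_drain`` ramps linearly from each cell's
    baseline toward the oxidised edge over the remaining frames.  Returns
    the scene list (seeds offset per frame so noise differs) and the truth
    trajectory table (cell_id, frame, e_true_mV).
    """
    if frames < 2:
        raise ValueError("frames must be >= 2")
    const = const or PhysicalConstants()
    lo, hi = redox_core.detection_window(base_scene.ph, base_scene.calibration, const)
    margin = 5.0
    ox_target, red_target = hi - margin, lo + margin

    scenes: list[SyntheticScene] = []
    rows = []
    for f in range(frames):
        new_cells = []
        for i, cell in enumerate(base_scene.cells, start=1):
            if event == "oxidant":
                e = cell.e_true if f < event_frame else ox_target
            elif event == "reductant":
                e = cell.e_true if f < event_frame else red_target
            elif event == "nox_drain":
                frac = f / (frames - 1)
                e = cell.e_true + frac * (ox_target - cell.e_true)
            else:
                raise ValueError(f"unknown event {event!r}")
            new_cells.append(replace(cell, e_true=e))
            rows.append({"cell_id": i, "frame": f, "e_true_mV": e})
        scenes.append(
            replace(base_scene, cells=tuple(new_cells), seed=base_scene.seed + f)
        )
    return scenes, pd.DataFrame(rows)
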