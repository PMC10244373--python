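"""Two-channel ratiometric microscopy pipeline.

Implements the standard roGFP2-style workflow: load a two-channel stack
(short- and long-wavelength excitation, one shared emission band), subtract
a cell-free background ROI per channel, threshold the long-wavelength
channel with Otsu's method to mask expressing cells, divide the corrected
channels pixel by pixel inside the mask, and reduce the ratio map to
per-cell statistics that :mod:`redoxratio.redox_core` converts into degrees
of oxidation and redox potentials.  z-stacks are reduced by maximum-intensity
projection *before* any ratio arithmetic; time series are measured through
fixed per-cell ROIs.

Conventions: the ratio is short/long, so R rises with oxidation; images are
row-major with 0-based (x, y, width, height) half-open ROIs; pixels whose
corrected long-channel intensity is not positive are removed from the mask
rather than patched with an epsilon.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

from . import redox_core
from .redox_core import PhysicalConstants, ProbeCalibration

__all__ = [
    "Roi",
    "ChannelStack",
    "RatioMap",
    "CellMeasurement",
    "FormatError",
    "EmptyMaskResult",
    "load_stack",
    "max_project",
    "subtract_background",
    "estimate_background",
    "build_mask",
    "ratio_map",
    "measure_cells",
    "measurements_to_frame",
    "track_timeseries",
    "determine_dynamic_range",
    "render_pseudocolor",
    "load_fire_lut",
    "measure_intensiometric",
    "write_ratio_tiff",
    "write_cell_csv",
]

CellStatistic = Literal["ratio_of_means", "mean_of_ratios"]


class FormatError(ValueError):
    """Input image does not match the expected channel layout."""


class EmptyMaskResult(Exception):
    """Signals that thresholding found no foreground; distinct from an error."""


@dataclass(frozen=True)
class Roi:
    """Axis-aligned rectangle, 0-based, half-open: pixels [y, y+h) x [x, x+w)."""

    x: int
    y: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI must have area >= 1")
        if self.x < 0 or self.y < 0:
            raise ValueError("ROI offsets must be non-negative")

    def validate_within(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.y + self.height > h or self.x + self.width > w:
            raise ValueError(
                f"ROI {self} exceeds image bounds {shape}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y, self.y + self.height), slice(self.x, self.x + self.width))

    @classmethod
    def parse(cls, text: str) -> "Roi":
        """Parse 'X,Y,W,H'."""
        parts = [int(p) for p in text.split(",")]
        if len(parts) != 4:
            raise ValueError("ROI must be X,Y,W,H")
        return cls(*parts)


@dataclass
class ChannelStack:
    """Raw or corrected two-channel image data.

    ``short`` and ``long`` are (y, x) frames or (z|t, y, x) stacks of equal
    shape with non-negative intensities.  ``extra`` optionally carries a
    third, intensiometric channel.  ``provenance`` accumulates processing
    metadata (background values subtracted, projections applied).
    """

    short: np.ndarray
    long: np.ndarray
    extra: np.ndarray | None = None
    axes: str = "yx"
    timestamps: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.short = np.asarray(self.short, dtype=float)
        self.long = np.asarray(self.long, dtype=float)
        if self.short.shape != self.long.shape:
            raise FormatError(
                f"channel shapes differ: {self.short.shape} vs {self.long.shape}"
            )
        if self.axes not in ("yx", "zyx", "tyx"):
            raise ValueError(f"axes must be yx, zyx or tyx, got {self.axes!r}")
        expected_ndim = 2 if self.axes == "yx" else 3
        if self.short.ndim != expected_ndim:
            raise FormatError(
                f"axes {self.axes!r} implies {expected_ndim}D data, got {self.short.ndim}D"
            )
        if np.any(self.short < 0) or np.any(self.long < 0):
            raise ValueError("intensities must be >= 0 after load")
        if self.extra is not None:
            self.extra = np.asarray(self.extra, dtype=float)
            if self.extra.shape != self.short.shape:
                raise FormatError("extra channel shape differs from ratio channels")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.short.shape[-2:]

    @property
    def n_planes(self) -> int:
        return 1 if self.short.ndim == 2 else self.short.shape[0]


@dataclass
class RatioMap:
    """Masked pixel-wise short/long ratio image.

    ``values`` is float with NaN outside ``mask``; ``provenance`` records the
    background levels subtracted from each channel.
    """

    values: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CellMeasurement:
    """Per-cell, per-frame background-corrected measurement."""

    cell_id: int
    frame: int
    mean_short: float
    mean_long: float
    r: float
    area: int
    oxd: float | None = None
    e: float | None = None
    time_s: float | None = None
    valid: bool = True


# ---------------------------------------------------------------------------
# I/O and geometry
# ---------------------------------------------------------------------------

def load_stack(
    path: str | Path,
    layout: str = "cyx",
    channels: dict | None = None,
) -> ChannelStack:
    """Load a TIFF into a :class:`ChannelStack`.

    ``layout`` names the file's axes with characters from {c, z, t, y, x};
    ``channels`` maps {"short": i, "long": j, "extra": k} onto the channel
    axis (default short=0, long=1).  8/16-bit integer and 32-bit float data
    are accepted.
    """
    channels = dict(channels or {})
    channels.setdefault("short", 0)
    channels.setdefault("long", 1)
    arr = tifffile.imread(str(path))
    layout = layout.lower()
    if arr.ndim != len(layout):
        raise FormatError(
            f"file has {arr.ndim} axes but layout {layout!r} names {len(layout)}"
        )
    if "c" not in layout:
        raise FormatError("layout must include a channel axis 'c' (>=2 channels required)")
    c_axis = layout.index("c")
    if arr.shape[c_axis] < 2:
        raise FormatError(
            f"need >=2 channels, file has {arr.shape[c_axis]} on axis {c_axis}"
        )
    arr = np.moveaxis(arr, c_axis, 0)
    rest = layout.replace("c", "")
    if rest not in ("yx", "zyx", "tyx"):
        raise FormatError(f"unsupported non-channel layout {rest!r}")

    def pick(key: str) -> np.ndarray | None:
        idx = channels.get(key)
        if idx is None:
            return None
        if idx >= arr.shape[0]:
            raise FormatError(f"channel {key}={idx} not present ({arr.shape[0]} channels)")
        return np.asarray(arr[idx], dtype=float)

    return ChannelStack(
        short=pick("short"),
        long=pick("long"),
        extra=pick("extra") if "extra" in channels else None,
        axes=rest,
        provenance={"source": str(path), "layout": layout, "channels": channels},
    )


def max_project(stack: ChannelStack) -> ChannelStack:
    """Per-channel maximum-intensity projection over the z axis."""
    if stack.axes != "zyx":
        raise ValueError(f"max_project requires a z-stack, got axes {stack.axes!r}")
    prov = dict(stack.provenance)
    prov["max_projected_z"] = stack.n_planes
    return ChannelStack(
        short=stack.short.max(axis=0),
        long=stack.long.max(axis=0),
        extra=None if stack.extra is None else stack.extra.max(axis=0),
        axes="yx",
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Background correction
# ---------------------------------------------------------------------------

def estimate_background(frame: np.ndarray) -> float:
    """Automatic fallback background: mode of the lowest-decile pixels.

    Used only when no cell-free ROI is supplied; the estimate is recorded as
    automatic in provenance by the caller.
    """
    flat = np.sort(frame.ravel())
    decile = flat[: max(1, flat.size // 10)]
    # mode via histogram over the decile's own range
    hist, edges = np.histogram(decile, bins=min(64, decile.size))
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def subtract_background(
    stack: ChannelStack,
    bg_roi: Roi | None,
    mask: np.ndarray | None = None,
) -> ChannelStack:
    """Subtract the mean of a cell-free ROI from each channel; clamp at 0.

    With ``bg_roi`` None, falls back to :func:`estimate_background` per
    channel (flagged ``automatic`` in provenance).  If a foreground ``mask``
    is already known and overlaps the ROI, a warning is emitted.
    """
    def bg_of(chan: np.ndarray) -> float:
        frame = chan if chan.ndim == 2 else chan[0]
        if bg_roi is None:
            return estimate_background(frame)
        bg_roi.validate_within(frame.shape)
        return float(np.mean(frame[bg_roi.slices()]))

    if bg_roi is not None and mask is not None:
        sl = bg_roi.slices()
        if np.any(mask[sl]):
            warnings.warn("background ROI overlaps the foreground mask", stacklevel=2)

    bg_short = bg_of(stack.short)
    bg_long = bg_of(stack.long)
    prov = dict(stack.provenance)
    prov["background"] = {
        "short": bg_short,
        "long": bg_long,
        "roi": None if bg_roi is None else (bg_roi.x, bg_roi.y, bg_roi.width, bg_roi.height),
        "automatic": bg_roi is None,
    }
    out = ChannelStack(
        short=np.clip(stack.short - bg_short, 0.0, None),
        long=np.clip(stack.long - bg_long, 0.0, None),
        extra=None
        if stack.extra is None
        else np.clip(stack.extra - bg_of(stack.extra), 0.0, None),
        axes=stack.axes,
        timestamps=stack.timestamps,
        provenance=prov,
    )
    return out


# ---------------------------------------------------------------------------
# Masking and ratio
# ---------------------------------------------------------------------------

def build_mask(
    stack: ChannelStack,
    channel: Literal["long", "short", "sum"] = "long",
    min_cell_area: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Otsu mask of positive expression plus 8-connected labels.

    Thresholds the chosen channel (default long: best SNR in both redox
    states) by maximising between-class variance over the intensity
    histogram, then drops connected components below ``min_cell_area``.
    A constant image yields no foreground and raises
    :class:`EmptyMaskResult` — a signal, not an error.
    """
    if stack.axes != "yx":
        raise ValueError("build_mask expects a single background-corrected frame")
    img = {
        "long": stack.long,
        "short": stack.short,
        "sum": stack.long + stack.short,
    }[channel]
    if np.all(img == img.flat[0]):
        raise EmptyMaskResult("constant image: no foreground found")
    thr = threshold_otsu(img)
    mask = img > thr
    if min_cell_area > 1 and mask.any():
        labels0 = sk_label(mask, connectivity=2)
        areas = np.bincount(labels0.ravel())
        keep = areas >= min_cell_area
        keep[0] = False
        mask = keep[labels0]
    if not mask.any():
        raise EmptyMaskResult("no region survived thresholding and size filtering")
    labels = sk_label(mask, connectivity=2)
    return mask, labels


def ratio_map(stack: ChannelStack, mask: np.ndarray) -> RatioMap:
    """Pixel-wise short/long ratio inside the mask; NaN elsewhere.

    Pixels with non-positive corrected long intensity are excluded from the
    mask (no epsilon patching, which would bias the ratio).
    """
    if stack.axes != "yx":
        raise ValueError("ratio_map expects a single frame")
    mask = np.asarray(mask, dtype=bool) & (stack.long > 0)
    values = np.full(stack.long.shape, np.nan, dtype=np.float32)
    values[mask] = (stack.short[mask] / stack.long[mask]).astype(np.float32)
    return RatioMap(values=values, mask=mask, provenance=dict(stack.provenance))


# ---------------------------------------------------------------------------
# Per-cell measurement
# ---------------------------------------------------------------------------

def measure_cells(
    ratio: RatioMap,
    stack: ChannelStack,
    labels: np.ndarray,
    calib: ProbeCalibration | None = None,
    ph: float | None = None,
    *,
    statistic: CellStatistic = "ratio_of_means",
    frame: int = 0,
    time_s: float | None = None,
    const: PhysicalConstants | None = None,
    min_cell_area: int = 1,
) -> list[CellMeasurement]:
    """Reduce a labeled ratio map to per-cell measurements.

    Default statistic is the ratio of background-corrected channel means
    over each cell's pixels (robust to photon noise); ``mean_of_ratios``
    averages the pixel-wise ratio instead.  With a calibration and pH, OxD
    and E (via the pH-corrected midpoint) are appended.
    """
    const = const or PhysicalConstants()
    out: list[CellMeasurement] = []
    for cid in np.unique(labels):
        if cid == 0:
            continue
        sel = (labels == cid) & ratio.mask
        area = int(np.sum(sel))
        if area < max(1, min_cell_area):
            continue
        mean_short = float(np.mean(stack.short[sel]))
        mean_long = float(np.mean(stack.long[sel]))
        valid = mean_long > 0
        if not valid:
            out.append(
                CellMeasurement(int(cid), frame, mean_short, mean_long,
                                float("nan"), area, time_s=time_s, valid=False)
            )
            continue
        if statistic == "ratio_of_means":
            r = mean_short / mean_long
        elif statistic == "mean_of_ratios":
            r = float(np.nanmean(ratio.values[sel]))
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        oxd = e = None
        if calib is not None and ph is not None:
            oxd = redox_core.oxd_from_ratio(r, calib)
            e0 = redox_core.ph_corrected_midpoint(calib.e0_probe, ph)
            e = redox_core.e_from_oxd(oxd, e0, const)
        out.append(
            CellMeasurement(int(cid), frame, mean_short, mean_long, r, area,
                            oxd=oxd, e=e, time_s=time_s, valid=True)
        )
    return out


def measurements_to_frame(cells: Sequence[CellMeasurement]) -> pd.DataFrame:
    """Tabulate measurements with the standard per-cell CSV columns."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "frame": [c.frame for c in cells],
            "time_s": [c.time_s for c in cells],
            "area_px": [c.area for c in cells],
            "mean_short": [c.mean_short for c in cells],
            "mean_long": [c.mean_long for c in cells],
            "R": [c.r for c in cells],
            "OxD": [c.oxd for c in cells],
            "E_mV": [c.e for c in cells],
            "flags": ["" if c.valid else "invalid" for c in cells],
        }
    )


def track_timeseries(
    stacks: Sequence[ChannelStack],
    rois: Sequence[Roi],
    calib: ProbeCalibration | None = None,
    ph: float | None = None,
    *,
    times: Sequence[float] | None = None,
    statistic: CellStatistic = "ratio_of_means",
    const: PhysicalConstants | None = None,
) -> pd.DataFrame:
    """Fixed-ROI cell-by-cell tracking across a time series.

    Each ROI is one cell held fixed across all frames; per frame the
    background-corrected channel means inside the ROI give R (and OxD/E
    when calibrated).  Output is ordered by (cell_id, frame).
    """
    rows = []
    for fi, stack in enumerate(stacks):
        if stack.axes != "yx":
            raise ValueError(f"frame {fi}: expected single-frame stacks")
        for ci, roi in enumerate(rois, start=1):
            try:
                roi.validate_within(stack.frame_shape)
            except ValueError as exc:
                raise ValueError(f"frame {fi}: {exc}") from exc
            sl = roi.slices()
            mean_short = float(np.mean(stack.short[sl]))
            mean_long = float(np.mean(stack.long[sl]))
            if mean_long <= 0:
                r = oxd = e = float("nan")
            else:
                r = mean_short / mean_long
                oxd = e = float("nan")
                if calib is not None and ph is not None:
                    oxd = redox_core.oxd_from_ratio(r, calib)
                    e0 = redox_core.ph_corrected_midpoint(calib.e0_probe, ph)
                    e = redox_core.e_from_oxd(oxd, e0, const)
            rows.append(
                {
                    "cell_id": ci,
                    "frame": fi,
                    "time_s": None if times is None else float(times[fi]),
                    "R": r,
                    "OxD": oxd if calib is not None else None,
                    "E_mV": e if calib is not None else None,
                }
            )
    df = pd.DataFrame(rows).sort_values(["cell_id", "frame"]).reset_index(drop=True)
    return df


def determine_dynamic_range(
    reduced_measurements: Sequence[CellMeasurement],
    oxidized_measurements: Sequence[CellMeasurement],
) -> tuple[float, float, float]:
    """Calibration endpoints from reductant- and oxidant-treated scenes.

    ``r_red`` is the mean cell R after full chemical reduction (DTT),
    ``r_ox`` after full oxidation (H2O2/diamide); DR is their difference.
    """
    red = [c.r for c in reduced_measurements if c.valid]
    ox = [c.r for c in oxidized_measurements if c.valid]
    if not red or not ox:
        raise ValueError("need at least one valid cell per condition")
    r_red = float(np.mean(red))
    r_ox = float(np.mean(ox))
    dr = redox_core.dynamic_range(r_ox, r_red)  # raises if r_ox <= r_red
    return r_red, r_ox, dr


# ---------------------------------------------------------------------------
# Rendering and intensiometric channel
# ---------------------------------------------------------------------------

def load_fire_lut() -> np.ndarray:
    """The packaged 256-entry fire-style LUT as a (256, 3) uint8 array."""
    ref = importlib.resources.files("redoxratio") / "data" / "fire_lut.csv"
    table = pd.read_csv(str(ref))
    return table[["r", "g", "b"]].to_numpy(dtype=np.uint8)


def render_pseudocolor(
    ratio: RatioMap,
    display_min: float,
    display_max: float,
    lut: np.ndarray | None = None,
) -> np.ndarray:
    """Map defined ratio pixels through the fire LUT; undefined pixels black.

    Values are scaled linearly from [display_min, display_max] to LUT
    indices 0..255 with floor rounding; out-of-range values saturate.
    """
    if not display_min < display_max:
        raise ValueError("display_min must be < display_max")
    lut = load_fire_lut() if lut is None else np.asarray(lut, dtype=np.uint8)
    if lut.shape != (256, 3):
        raise ValueError("LUT must be a (256, 3) table")
    vals = ratio.values
    scaled = (vals - display_min) / (display_max - display_min) * 255.0
    with np.errstate(invalid="ignore"):
        idx = np.floor(scaled)
    idx = np.where(np.isnan(idx), 0, np.clip(idx, 0, 255)).astype(np.intp)
    rgb = lut[idx]
    rgb[~ratio.mask] = 0
    return rgb


def measure_intensiometric(
    stack: ChannelStack,
    labels: np.ndarray,
    *,
    frame: int = 0,
    time_s: float | None = None,
) -> pd.DataFrame:
    """Mean background-corrected intensity of the extra channel per region.

    For intensity-only reporters (e.g. a red H2O2 sensor) that share the
    field of view but have no ratiometric readout.
    """
    if stack.extra is None:
        raise FormatError("stack has no extra (intensiometric) channel")
    rows = []
    for cid in np.unique(labels):
        if cid == 0:
            continue
        sel = labels == cid
        rows.append(
            {
                "cell_id": int(cid),
                "frame": frame,
                "time_s": time_s,
                "FI": float(np.mean(stack.extra[sel])),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_ratio_tiff(ratio: RatioMap, path: str | Path) -> None:
    """32-bit float TIFF of the ratio map, NaN outside the mask."""
    tifffile.imwrite(str(path), ratio.values.astype(np.float32))


def write_cell_csv(cells: Sequence[CellMeasurement], path: str | Path) -> None:
    measurements_to_frame(cells).to_csv(path, index=False)


def write_pseudocolor_png(rgb: np.ndarray, path: str | Path) -> None:
    iio.imwrite(str(path), rgb.astype(np.uint8))


def write_provenance_json(provenance: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(provenance, indent=2, sort_keys=True, default=str))
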