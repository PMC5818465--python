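"""Starch densitometry and ovary morphometry on stained-section images.

Starch granules stained blue-black with I2KI are isolated by a per-channel
RGB box threshold (the way interactive image analyzers define a "color"),
giving a binary mask. The mask is overlaid on the grayscale version of the
image and the optical density ``OD = log10(255 / I)`` of every masked pixel
inside a fixed-area measurement frame (default 1337 um^2) is summed; four
frames per section are averaged into one value per ovary.

Threshold calibration reproduces the interactive procedure ("raise the
detection levels until the binary image matches the granules") as a
deterministic search: the RGB box on a quantization grid maximizing
intersection-over-union with a user-supplied reference mask.

Ovary growth is measured on calcofluor-stained sections: cell layers are
counted as intensity peaks (bright cellulose walls) along an annotated
transect, and the ovary diameter is the transect's physical length.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from skimage.measure import profile_line

from .errors import GeometryError, InputError, ThresholdError

__all__ = [
    "SectionImage",
    "ThresholdSpec",
    "MeasurementFrame",
    "StarchMeasurement",
    "CalibrationResult",
    "segment_starch",
    "calibrate_threshold",
    "optical_density",
    "starch_content",
    "measure_ovary",
    "count_cell_layers",
    "ovary_diameter",
    "load_section_image",
    "read_annotations",
]

DEFAULT_FRAME_AREA_UM2 = 1337.0
MAX_OD = math.log10(255.0)

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class SectionImage:
    """RGB raster of a stained section with its physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float
    ovary_id: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"expected an RGB (H, W, 3) raster, got shape {px.shape}")
        if px.dtype == np.uint16:
            warnings.warn("16-bit image rescaled to 8-bit", stacklevel=3)
            px = (px.astype(np.float64) / 257.0).round().astype(np.uint8)
        elif px.dtype != np.uint8:
            arr = np.asarray(px, dtype=np.float64)
            if arr.min() < 0 or arr.max() > 255:
                raise InputError("channel intensities must lie in [0, 255]")
            px = arr.round().astype(np.uint8)
        if not self.pixel_size_um > 0:
            raise InputError("pixel_size_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ThresholdSpec:
    """Inclusive per-channel intensity bounds defining the "starch" color."""

    red: tuple[int, int]
    green: tuple[int, int]
    blue: tuple[int, int]

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 255):
                raise ThresholdError(f"{name} bounds ({lo}, {hi}) violate 0 <= min <= max <= 255")
            object.__setattr__(self, name, (int(lo), int(hi)))

    @property
    def bounds(self) -> tuple[tuple[int, int], ...]:
        return (self.red, self.green, self.blue)

    @property
    def total_range(self) -> int:
        return sum(hi - lo for lo, hi in self.bounds)


@dataclass(frozen=True)
class MeasurementFrame:
    """Square frame of fixed physical area centered on an anchor pixel.

    ``anchor`` is (x, y) = (column, row). The side length in pixels is
    ``round(sqrt(area) / pixel_size)``.
    """

    anchor: tuple[int, int]
    area_um2: float = DEFAULT_FRAME_AREA_UM2

    def __post_init__(self) -> None:
        if not self.area_um2 > 0:
            raise InputError("frame area must be > 0")
        object.__setattr__(self, "anchor", (int(self.anchor[0]), int(self.anchor[1])))

    def side_px(self, pixel_size_um: float) -> int:
        return max(1, round(math.sqrt(self.area_um2) / pixel_size_um))

    def slices(self, image: SectionImage) -> tuple[slice, slice]:
        """(row, col) slices of the frame; raises if it leaves the image."""
        side = self.side_px(image.pixel_size_um)
        x, y = self.anchor
        r0, c0 = y - side // 2, x - side // 2
        r1, c1 = r0 + side, c0 + side
        h, w = image.shape
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise GeometryError(
                f"frame at {self.anchor} (side {side} px) exceeds image bounds {h}x{w}"
            )
        return slice(r0, r1), slice(c0, c1)


@dataclass(frozen=True)
class StarchMeasurement:
    """Per-frame summed OD values and their per-ovary aggregate."""

    per_frame: tuple[float, ...]
    ovary_value: float
    mask_area_um2: float
    ovary_id: str = ""
    date: str = ""


def segment_starch(image: SectionImage, thr: ThresholdSpec) -> np.ndarray:
    """Binary starch mask: pixels whose R, G and B all fall in their bounds."""
    px = image.pixels
    mask = np.ones(image.shape, dtype=bool)
    for c, (lo, hi) in enumerate(thr.bounds):
        chan = px[:, :, c]
        mask &= (chan >= lo) & (chan <= hi)
    return mask


def optical_density(image: SectionImage) -> np.ndarray:
    """Per-pixel OD of the luma grayscale image.

    ``I = 0.299 R + 0.587 G + 0.114 B`` (not rounded); ``OD = log10(255 /
    max(I, 1))`` so white is 0 and OD is capped at log10(255) ~ 2.407.
    """
    luma = image.pixels.astype(np.float64) @ _LUMA
    return np.log10(255.0 / np.maximum(luma, 1.0))


def starch_content(image: SectionImage, mask: np.ndarray, frame: MeasurementFrame) -> float:
    """Summed OD (OD*pixel) over masked pixels inside the frame."""
    if mask.shape != image.shape:
        raise InputError("mask shape must match image shape")
    rows, cols = frame.slices(image)
    od = optical_density(image)
    sub = od[rows, cols]
    return float(sub[mask[rows, cols]].sum())


def measure_ovary(
    image: SectionImage,
    thr: ThresholdSpec,
    frames: list[MeasurementFrame],
    *,
    require_four: bool = True,
) -> StarchMeasurement:
    """Starch content of one ovary: four frame measures and their mean."""
    if require_four and len(frames) != 4:
        raise InputError(f"exactly 4 measurement frames expected, got {len(frames)}")
    if not frames:
        raise InputError("at least one measurement frame required")
    mask = segment_starch(image, thr)
    per_frame = tuple(starch_content(image, mask, f) for f in frames)
    return StarchMeasurement(
        per_frame=per_frame,
        ovary_value=float(np.mean(per_frame)),
        mask_area_um2=float(mask.sum()) * image.pixel_size_um**2,
        ovary_id=image.ovary_id,
        date=image.date,
    )


# --- threshold calibration -------------------------------------------------


@dataclass(frozen=True)
class CalibrationResult:
    spec: ThresholdSpec
    iou: float
    method: str
    step: int


class _BoxCounter:
    """O(1) pixel counts inside RGB boxes via a 3-D integral histogram.

    Counts are exact for boxes whose bounds lie on the calibration grid:
    the histogram is binned at every grid value v and v - 1, the only cut
    points inclusive box queries need.
    """

    def __init__(self, pixels: np.ndarray, ref: np.ndarray, grid: np.ndarray):
        cuts = np.unique(np.concatenate([grid - 1, grid]).astype(np.int64))
        self.cuts = cuts
        self._cut_index = {int(v): i for i, v in enumerate(cuts)}
        flat = pixels.reshape(-1, 3).astype(np.int64)
        idx = [np.searchsorted(cuts, flat[:, c], side="left") for c in range(3)]
        n = len(cuts)
        hist_all = np.zeros((n, n, n), dtype=np.int64)
        hist_ref = np.zeros((n, n, n), dtype=np.int64)
        np.add.at(hist_all, tuple(idx), 1)
        rf = ref.reshape(-1)
        np.add.at(hist_ref, tuple(i[rf] for i in idx), 1)
        for h in (hist_all, hist_ref):
            h.cumsum(axis=0, out=h)
            h.cumsum(axis=1, out=h)
            h.cumsum(axis=2, out=h)
        self.C_all = hist_all
        self.C_ref = hist_ref
        self.n_ref = int(rf.sum())

    def hi_index(self, v: int) -> int:
        return self._cut_index[int(v)]

    def lo_index(self, v: int) -> int:
        """Index of the cut v - 1; -1 encodes 'count nothing' for v = min."""
        return self._cut_index.get(int(v) - 1, -1)

    @staticmethod
    def _corner(C, i, j, k):
        if np.ndim(k) == 0:
            if i < 0 or j < 0 or k < 0:
                return 0
            return C[i, j, k]
        if i < 0 or j < 0:
            return np.zeros(np.shape(k), dtype=np.int64)
        out = np.where(np.asarray(k) < 0, 0, C[i, j, np.maximum(k, 0)])
        return out

    def _count(self, C, r0, r1, g0, g1, b0, b1):
        c = self._corner
        return (
            c(C, r1, g1, b1) - c(C, r0, g1, b1) - c(C, r1, g0, b1) + c(C, r0, g0, b1)
            - c(C, r1, g1, b0) + c(C, r0, g1, b0) + c(C, r1, g0, b0) - c(C, r0, g0, b0)
        )

    def iou(self, r0, r1, g0, g1, b0, b1):
        """IoU between the box mask and the reference; b-indices may be arrays."""
        inter = self._count(self.C_ref, r0, r1, g0, g1, b0, b1)
        inbox = self._count(self.C_all, r0, r1, g0, g1, b0, b1)
        union = self.n_ref + inbox - inter
        return np.where(union > 0, inter / np.maximum(union, 1), 0.0)


def _calibration_grid(step: int) -> np.ndarray:
    grid = np.arange(0, 256, step, dtype=np.int64)
    if grid[-1] != 255:
        grid = np.append(grid, 255)
    return grid


def calibrate_threshold(
    image: SectionImage,
    reference_mask: np.ndarray,
    *,
    step: int = 5,
    exhaustive_limit: int = 200_000,
) -> CalibrationResult:
    """Recover the ThresholdSpec best matching a reference starch mask.

    Searches RGB boxes with bounds on a grid of spacing ``step`` for the
    maximum intersection-over-union with ``reference_mask``. When the number
    of candidate boxes is at most ``exhaustive_limit`` the search is
    exhaustive (guaranteed global optimum on the grid); otherwise a
    deterministic coordinate ascent is started from the tightest grid box
    enclosing the reference pixel colors. Ties are broken toward the
    tightest bounds, then lexicographically smallest bounds.
    """
    ref = np.asarray(reference_mask, dtype=bool)
    if ref.shape != image.shape:
        raise InputError("reference mask shape must match image shape")
    if not ref.any():
        raise InputError("reference mask is empty")
    if step < 1:
        raise InputError("step must be >= 1")

    grid = _calibration_grid(step)
    counter = _BoxCounter(image.pixels, ref, grid)
    m = len(grid)
    n_pairs = m * (m + 1) // 2
    if n_pairs**3 <= exhaustive_limit:
        bounds, iou = _search_exhaustive(counter, grid)
        method = "exhaustive"
    else:
        bounds, iou = _search_coordinate_ascent(counter, grid, image.pixels, ref)
        method = "coordinate_ascent"
    spec = ThresholdSpec(red=bounds[0], green=bounds[1], blue=bounds[2])
    return CalibrationResult(spec=spec, iou=float(iou), method=method, step=step)


def _pairs(grid: np.ndarray) -> list[tuple[int, int]]:
    return [(int(lo), int(hi)) for i, lo in enumerate(grid) for hi in grid[i:]]


def _key(iou: float, bounds) -> tuple:
    """Sort key: higher IoU, then tighter, then lexicographically smaller."""
    tightness = sum(hi - lo for lo, hi in bounds)
    flat = tuple(v for b in bounds for v in b)
    return (-iou, tightness, flat)


def _search_exhaustive(counter: _BoxCounter, grid: np.ndarray):
    pairs = _pairs(grid)
    lo_idx = np.array([counter.lo_index(lo) for lo, _ in pairs])
    hi_idx = np.array([counter.hi_index(hi) for _, hi in pairs])
    best_key, best = None, None
    for pi, (rlo, rhi) in enumerate(pairs):
        r0, r1 = lo_idx[pi], hi_idx[pi]
        for pj, (glo, ghi) in enumerate(pairs):
            g0, g1 = lo_idx[pj], hi_idx[pj]
            ious = counter.iou(r0, r1, g0, g1, lo_idx, hi_idx)
            # only the max-IoU b-pairs of this (r, g) slice can win globally,
            # but exact ties must all be compared under the full key
            for pk in np.nonzero(ious == ious.max())[0]:
                blo, bhi = pairs[pk]
                bounds = ((rlo, rhi), (glo, ghi), (blo, bhi))
                key = _key(float(ious[pk]), bounds)
                if best_key is None or key < best_key:
                    best_key, best = key, (bounds, float(ious[pk]))
    return best


def _search_coordinate_ascent(counter, grid: np.ndarray, pixels: np.ndarray, ref: np.ndarray):
    # shrink-wrap the reference colors outward to the grid
    colors = pixels[ref]
    bounds = []
    for c in range(3):
        lo = int(grid[np.searchsorted(grid, colors[:, c].min(), side="right") - 1])
        hi = int(grid[np.searchsorted(grid, colors[:, c].max(), side="left")])
        bounds.append((lo, hi))

    def evaluate(b) -> float:
        (rlo, rhi), (glo, ghi), (blo, bhi) = b
        return float(
            counter.iou(
                counter.lo_index(rlo), counter.hi_index(rhi),
                counter.lo_index(glo), counter.hi_index(ghi),
                counter.lo_index(blo), counter.hi_index(bhi),
            )
        )

    best_key = _key(evaluate(tuple(bounds)), bounds)
    for _ in range(100):
        improved = False
        for c in range(3):
            for side in (0, 1):
                current = bounds[c]
                for v in grid:
                    cand = (int(v), current[1]) if side == 0 else (current[0], int(v))
                    if cand[0] > cand[1]:
                        continue
                    trial = list(bounds)
                    trial[c] = cand
                    key = _key(evaluate(tuple(trial)), trial)
                    if key < best_key:
                        best_key, bounds = key, trial
                        improved = True
        if not improved:
            break
    return tuple(tuple(b) for b in bounds), -best_key[0]


# --- ovary morphometry -----------------------------------------------------


def count_cell_layers(
    image: SectionImage,
    transect: tuple[tuple[float, float], tuple[float, float]],
    *,
    min_peak_distance_um: float = 2.0,
    peak_threshold: float = 0.2,
) -> int:
    """Count cell layers along a transect of a calcofluor-stained section.

    Bright cellulose walls appear as intensity peaks along the sampled
    profile; n wall peaks delimit n - 1 cell layers. ``peak_threshold`` is
    the required peak prominence relative to the profile's intensity range.
    """
    (x0, y0), (x1, y1) = transect
    length_um = math.hypot(x1 - x0, y1 - y0) * image.pixel_size_um
    if length_um < 2 * min_peak_distance_um:
        raise GeometryError("transect shorter than twice the minimum peak distance")
    _check_inside(image, transect)
    luma = image.pixels.astype(np.float64) @ _LUMA
    profile = profile_line(luma, (y0, x0), (y1, x1), mode="reflect")
    rng = profile.max() - profile.min()
    if rng == 0:
        return 0
    dist_px = max(1, round(min_peak_distance_um / image.pixel_size_um))
    peaks, _ = find_peaks(profile, distance=dist_px, prominence=peak_threshold * rng)
    return max(len(peaks) - 1, 0)


def ovary_diameter(
    transect: tuple[tuple[float, float], tuple[float, float]], pixel_size_um: float
) -> float:
    """Physical length (um) of a diameter transect."""
    (x0, y0), (x1, y1) = transect
    length = math.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise GeometryError("zero-length transect")
    return length * pixel_size_um


def _check_inside(image: SectionImage, transect) -> None:
    h, w = image.shape
    for x, y in transect:
        if not (0 <= x < w and 0 <= y < h):
            raise GeometryError(f"transect endpoint ({x}, {y}) outside image {h}x{w}")


# --- I/O -------------------------------------------------------------------


def load_section_image(path, pixel_size_um: float, ovary_id: str = "", date: str = "") -> SectionImage:
    import imageio.v3 as iio

    return SectionImage(
        pixels=iio.imread(path), pixel_size_um=pixel_size_um, ovary_id=ovary_id, date=date
    )


def read_annotations(path) -> dict:
    """Per-image annotation JSON: pixel size, frame anchors, optional transect
    and reference-mask path."""
    with open(path) as fh:
        ann = json.load(fh)
    if "pixel_size_um" not in ann:
        raise InputError(f"{path}: annotation missing pixel_size_um")
    ann.setdefault("frames", [])
    return ann
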