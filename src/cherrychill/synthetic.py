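"""Seeded synthetic seasons with known ground truth.

The generator emulates the structure of a two-winter sweet cherry study:

* an hourly station temperature record (annual trend + diurnal cycle +
  AR(1) weather noise), where a "mild" winter delays the onset of chilling
  by a configurable ~20 days relative to a "cold" winter;
* weekly forcing tests whose forced/field weight ratio stays near 1.05
  until a planted chilling requirement is met and then rises logistically
  past the 30% classification threshold;
* stained-section images in which dark blue-black starch granules (a
  distinct RGB band) cover an area fraction theta that rises linearly with
  cumulative chill units up to fulfillment and falls linearly with growing
  degree hours after it;
* calcofluor-like ovary-wall images with a planted number of cell layers.

Every generator is bit-reproducible for a fixed seed, and the emitted
``ground_truth.json`` carries everything needed to score recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

from .dormancy import ForcingTest
from .errors import InputError
from .imaging import MeasurementFrame, SectionImage
from .thermal import HourlyTemperatureSeries, accumulate

__all__ = [
    "SeasonSpec",
    "StarchTrajectorySpec",
    "SeasonDataset",
    "GRANULE_BAND",
    "gen_temperature_series",
    "gen_forcing_tests",
    "gen_section_image",
    "gen_ovary_wall_image",
    "gen_season_dataset",
]

#: RGB band of the painted starch granules (separable from the pale
#: background, whose channels all stay >= 140).
GRANULE_BAND = ((40, 90), (30, 70), (60, 110))

_SEASON_YEAR = 2014  # nominal season: Sep 2014 - Apr 2015


@dataclass(frozen=True)
class SeasonSpec:
    """Climate scenario for one dormant season."""

    year_type: str = "cold"  # "cold" | "mild"
    chill_onset_shift_days: float | None = None  # default 0 cold, +20 mild
    planted_cu_requirement: float = 1000.0
    ar_coeff: float = 0.8
    noise_sd: float = 1.5  # stationary sd of the AR(1) component, degC
    seed: int = 0
    autumn_temp_c: float = 14.25   # plateau before cooling onset (Utah dead band)
    winter_min_c: float = 2.0      # seasonal minimum, reached mid-January
    diurnal_amplitude_c: float = 3.4  # peak at 14:00; keeps the autumn plateau CU-neutral
    onset_base_day: float = 20.0   # cold-year cooling onset, days after Sep 1 (~Sep 21)
    days_to_coldest: float = 115.0  # onset -> coldest day (~Jan 15 in the cold year)

    def __post_init__(self) -> None:
        if self.year_type not in ("cold", "mild"):
            raise InputError("year_type must be 'cold' or 'mild'")
        if not self.planted_cu_requirement > 0:
            raise InputError("planted_cu_requirement must be > 0")
        if not 0 <= self.ar_coeff < 1:
            raise InputError("AR(1) coefficient must be in [0, 1)")
        if self.chill_onset_shift_days is None:
            shift = 0.0 if self.year_type == "cold" else 20.0
            object.__setattr__(self, "chill_onset_shift_days", shift)


@dataclass(frozen=True)
class StarchTrajectorySpec:
    """Planted ovary starch trajectory: linear in CU up, linear in GDH down.

    ``gdh_decay`` (GDH over which starch vanishes) defaults to None, meaning
    it is calibrated per season so that the relative decline over the half
    sampling interval after fulfillment equals the relative rise over the
    half interval before it. That balance makes the sampled starch maximum
    fall on the date nearest chilling fulfillment, whichever side of it the
    nearest date lies.
    """

    theta_max: float = 0.2          # peak granule area fraction
    ovary_noise_sd: float = 0.02    # per-ovary sd of theta (10% of theta_max)
    gdh_decay: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.theta_max <= 0.5:
            raise InputError("theta_max must be in (0, 0.5]")
        if self.ovary_noise_sd < 0 or (self.gdh_decay is not None and self.gdh_decay <= 0):
            raise InputError("invalid trajectory noise/decay")


def seasonal_mean_curve(days: np.ndarray, spec: SeasonSpec) -> np.ndarray:
    """Daily-mean temperature: autumn plateau, then a sinusoidal cold season.

    Before the cooling onset (``onset_base_day`` + the year's shift) the mean
    holds at ``autumn_temp_c``, chosen inside the Utah dead band so the
    pre-onset period contributes ~0 CU; afterwards it follows half a
    sine-squared cycle down to ``winter_min_c`` and back up into spring.
    """
    onset = spec.onset_base_day + spec.chill_onset_shift_days
    dd = np.maximum(np.asarray(days, dtype=float) - onset, 0.0)
    depth = spec.autumn_temp_c - spec.winter_min_c
    return spec.autumn_temp_c - depth * np.sin(
        np.pi * np.minimum(dd, 2 * spec.days_to_coldest) / (2 * spec.days_to_coldest)
    ) ** 2


def gen_temperature_series(spec: SeasonSpec) -> HourlyTemperatureSeries:
    """Hourly Sep 1 - Apr 30 temperatures for the scenario.

    A mild winter's seasonal curve is the cold winter's with the cooling
    onset delayed by ``chill_onset_shift_days``; because the pre-onset
    plateau is CU-neutral, the date any cumulative-CU threshold is reached
    moves by ~ that shift (exactly, with noise off).
    """
    times = pd.date_range(
        f"{_SEASON_YEAR}-09-01 00:00", f"{_SEASON_YEAR + 1}-04-30 23:00", freq="h"
    )
    hours = np.arange(len(times), dtype=float)
    days = hours / 24.0
    seasonal = seasonal_mean_curve(days, spec)
    hod = times.hour.to_numpy(dtype=float)
    diurnal = spec.diurnal_amplitude_c * np.cos(2 * np.pi * (hod - 14.0) / 24.0)
    temps = seasonal + diurnal
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar_coeff**2)
        eps = rng.normal(0.0, innov_sd, size=len(times))
        noise = np.empty(len(times))
        noise[0] = rng.normal(0.0, spec.noise_sd)
        for i in range(1, len(times)):
            noise[i] = spec.ar_coeff * noise[i - 1] + eps[i]
        temps = temps + noise
    return HourlyTemperatureSeries(times=times, temps=temps)


def _forced_field_ratio(cu: float, requirement: float, *, floor: float, ceiling: float,
                        scale_cu: float) -> float:
    return floor + (ceiling - floor) / (1.0 + np.exp(-(cu - requirement) / scale_cu))


def gen_forcing_tests(
    series: HourlyTemperatureSeries,
    spec: SeasonSpec,
    *,
    cadence_days: int = 7,
    n_buds: int = 10,
    seed: int | None = None,
    start: str | None = None,
    end: str | None = None,
    ratio_floor: float = 1.05,
    ratio_ceiling: float = 1.6,
    ratio_scale_cu: float = 40.0,
    field_mu0_mg: float = 60.0,
    field_slope_mg_per_day: float = 0.05,
    bud_sd_mg: float = 4.0,
) -> list[ForcingTest]:
    """Weekly forcing tests tied to the season's actual CU accumulation.

    The expected forced/field ratio follows a logistic in cumulative CU
    centered on the planted requirement, rising from ``ratio_floor`` to
    ``ratio_ceiling``; per-bud weights are normal around the date's means.
    """
    if cadence_days < 1:
        raise InputError("cadence_days must be >= 1")
    rng = np.random.default_rng(spec.seed + 1_000_003 if seed is None else seed)
    start = pd.Timestamp(start) if start else pd.Timestamp(f"{_SEASON_YEAR}-11-30")
    end = pd.Timestamp(end) if end else pd.Timestamp(f"{_SEASON_YEAR + 1}-03-10")
    end = min(end, series.times[-1])
    acc = accumulate(series, (series.season_start, series.times[-1]), "chill")

    tests = []
    date = start
    while date <= end:
        cu = acc.value_at(date)
        ratio = _forced_field_ratio(
            cu, spec.planted_cu_requirement,
            floor=ratio_floor, ceiling=ratio_ceiling, scale_cu=ratio_scale_cu,
        )
        days_in = (date - series.times[0]).days
        mu_field = field_mu0_mg + field_slope_mg_per_day * days_in
        field_w = np.maximum(rng.normal(mu_field, bud_sd_mg, n_buds), 1.0)
        forced_w = np.maximum(rng.normal(ratio * mu_field, bud_sd_mg, n_buds), 1.0)
        tests.append(ForcingTest(date=date, field_weights=field_w, forced_weights=forced_w))
        date = date + pd.Timedelta(days=cadence_days)
    return tests


def gen_section_image(
    theta: float,
    *,
    size: tuple[int, int] = (96, 96),
    pixel_size_um: float = 1.0,
    seed: int = 0,
    band=GRANULE_BAND,
    ovary_id: str = "",
    date: str = "",
) -> tuple[SectionImage, np.ndarray]:
    """Synthetic stained section: pale textured tissue + dark granules.

    Elliptical granules with per-pixel colors drawn uniformly from ``band``
    are painted until they cover fraction ``theta`` of the image (the final
    granule may overshoot by well under 2%). Returns the image and the
    exact ground-truth granule mask.
    """
    if not 0.0 <= theta <= 0.5:
        raise InputError("theta must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    h, w = size

    base = np.array([225.0, 205.0, 185.0])
    img = base[None, None, :] + rng.normal(0.0, 6.0, size=(h, w, 3))
    # faint cell-outline texture (circles of slightly darker tissue tone)
    for _ in range(max(4, h * w // 600)):
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        rad = int(rng.integers(4, 10))
        rr, cc = disk((cy, cx), rad, shape=(h, w))
        ring = np.zeros((h, w), dtype=bool)
        ring[rr, cc] = True
        rr2, cc2 = disk((cy, cx), max(rad - 1, 1), shape=(h, w))
        ring[rr2, cc2] = False
        img[ring] -= 35.0
    img = np.clip(img, 140.0, 255.0)  # keep tissue out of the granule band

    mask = np.zeros((h, w), dtype=bool)
    target_px = theta * h * w
    guard = 0
    while mask.sum() < target_px and guard < 100_000:
        guard += 1
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        ry, rx = rng.uniform(1.5, 4.0), rng.uniform(1.5, 4.0)
        ang = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=ang)
        mask[rr, cc] = True

    npix = int(mask.sum())
    for c, (lo, hi) in enumerate(band):
        img[:, :, c][mask] = rng.integers(lo, hi + 1, size=npix)

    image = SectionImage(
        pixels=np.clip(img, 0, 255).round().astype(np.uint8),
        pixel_size_um=pixel_size_um,
        ovary_id=ovary_id,
        date=date,
    )
    return image, mask


def gen_ovary_wall_image(
    n_layers: int,
    *,
    layer_width_um: float = 6.0,
    pixel_size_um: float = 1.0,
    seed: int = 0,
    height: int = 48,
    margin_px: int = 8,
) -> tuple[SectionImage, tuple[tuple[int, int], tuple[int, int]]]:
    """Calcofluor-like wall image: n_layers + 1 bright walls on dark tissue.

    Returns the image and a horizontal transect crossing all walls, so
    counting wall peaks minus one recovers ``n_layers``.
    """
    if n_layers < 1:
        raise InputError("n_layers must be >= 1")
    rng = np.random.default_rng(seed)
    step_px = max(3, round(layer_width_um / pixel_size_um))
    width = 2 * margin_px + n_layers * step_px + 1
    img = rng.normal(30.0, 3.0, size=(height, width))
    xs = margin_px + step_px * np.arange(n_layers + 1)
    for x in xs:
        img[:, x] += 190.0
        if x - 1 >= 0:
            img[:, x - 1] += 80.0
        if x + 1 < width:
            img[:, x + 1] += 80.0
    img = np.clip(img, 0, 255)
    rgb = np.repeat(img[:, :, None], 3, axis=2).round().astype(np.uint8)
    image = SectionImage(pixels=rgb, pixel_size_um=pixel_size_um)
    y = height // 2
    transect = ((2, y), (width - 3, y))
    return image, transect


def _default_frames(size: tuple[int, int], pixel_size_um: float, area_um2: float):
    """Four frames at the quarter points of the image."""
    h, w = size
    side = max(1, round(np.sqrt(area_um2) / pixel_size_um))
    if side > min(h, w) // 2:
        raise InputError("image too small for four frames of the requested area")
    qx, qy = w // 4, h // 4
    anchors = [(qx, qy), (3 * qx, qy), (qx, 3 * qy), (3 * qx, 3 * qy)]
    return [MeasurementFrame(anchor=a, area_um2=area_um2) for a in anchors]


@dataclass
class SeasonDataset:
    """One cultivar-year input bundle plus its ground truth."""

    season: SeasonSpec
    trajectory: StarchTrajectorySpec
    series: HourlyTemperatureSeries
    forcing_tests: list
    dates: list
    images: dict              # date str -> list of (SectionImage, mask, frames)
    wall_images: dict         # date str -> (SectionImage, transect)
    ground_truth: dict

    def write(self, out_dir) -> Path:
        """Materialize the bundle in the on-disk formats the pipeline reads."""
        import imageio.v3 as iio

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        self.series.as_frame().to_csv(out / "temperature.csv", index=False)

        rows = []
        for t in self.forcing_tests:
            for cond, weights in (("field", t.field_weights), ("forced", t.forced_weights)):
                for bud_id, wgt in enumerate(weights):
                    rows.append(
                        {"date": t.date.date(), "condition": cond,
                         "bud_id": bud_id, "weight_mg": round(float(wgt), 3)}
                    )
        pd.DataFrame(rows).to_csv(out / "forcing.csv", index=False)

        annotations = {}
        for date_str, ovaries in self.images.items():
            for i, (image, mask, frames) in enumerate(ovaries):
                stem = f"{date_str}_ov{i}"
                iio.imwrite(out / "images" / f"{stem}.png", image.pixels)
                iio.imwrite(
                    out / "images" / f"{stem}_ref.png",
                    (mask.astype(np.uint8) * 255),
                )
                annotations[f"{stem}.png"] = {
                    "pixel_size_um": image.pixel_size_um,
                    "ovary_id": stem,
                    "date": date_str,
                    "frames": [list(f.anchor) for f in frames],
                    "frame_area_um2": frames[0].area_um2,
                    "reference_mask": f"{stem}_ref.png",
                }
        for date_str, (image, transect) in self.wall_images.items():
            stem = f"{date_str}_wall"
            iio.imwrite(out / "images" / f"{stem}.png", image.pixels)
            annotations[f"{stem}.png"] = {
                "pixel_size_um": image.pixel_size_um,
                "ovary_id": stem,
                "date": date_str,
                "frames": [],
                "transect": [list(transect[0]), list(transect[1])],
                "kind": "wall",
            }
        with open(out / "annotations.json", "w") as fh:
            json.dump(annotations, fh, indent=1)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, default=str)
        return out


def gen_season_dataset(
    season: SeasonSpec | None = None,
    trajectory: StarchTrajectorySpec | None = None,
    *,
    dates=None,
    n_ovaries: int = 6,
    image_size: tuple[int, int] = (96, 96),
    pixel_size_um: float = 1.0,
    frame_area_um2: float = 1337.0,
    with_images: bool = True,
) -> SeasonDataset:
    """Full synthetic cultivar-year bundle.

    Starch fractions are driven by the season's *actual* CU and GDH
    accumulation: theta rises as ``theta_max * CU/requirement`` until the
    planted requirement is met and then falls as GDH accumulates. Cell
    layers hold at 13 through endodormancy and rise toward 20 afterwards.
    Sampling defaults to every 14 days, Oct 1 - Mar 30.
    """
    season = season or SeasonSpec()
    trajectory = trajectory or StarchTrajectorySpec()
    series = gen_temperature_series(season)
    forcing = gen_forcing_tests(series, season)

    if dates is None:
        dates = list(
            pd.date_range(f"{_SEASON_YEAR}-10-01", f"{_SEASON_YEAR + 1}-03-30", freq="14D")
        )
    dates = [pd.Timestamp(d) for d in dates]

    chill = accumulate(series, (series.season_start, series.times[-1]), "chill")
    req = season.planted_cu_requirement
    reached = np.nonzero(chill.cumulative >= req)[0]
    fulfillment = chill.times[reached[0]] if reached.size else None
    heat = (
        accumulate(series, (fulfillment, series.times[-1]), "heat")
        if fulfillment is not None and fulfillment < series.times[-1]
        else None
    )

    gdh_decay = trajectory.gdh_decay
    if gdh_decay is None and fulfillment is not None and heat is not None:
        # balance decline against rise over half a sampling interval, so the
        # sampled maximum falls on the date nearest fulfillment
        half = (dates[1] - dates[0]) / 2 if len(dates) > 1 else pd.Timedelta(days=7)
        cu_half = chill.value_at(fulfillment) - chill.value_at(fulfillment - half)
        gdh_half = heat.value_at(fulfillment + half)
        if cu_half > 0 and gdh_half > 0:
            gdh_decay = gdh_half * req / cu_half
    if gdh_decay is None:
        gdh_decay = np.inf  # no heat-driven decline can be defined

    def theta_at(date) -> float:
        cu = chill.value_at(date)
        if fulfillment is None or date <= fulfillment:
            return trajectory.theta_max * min(cu / req, 1.0)
        gdh = heat.value_at(date) if heat is not None else 0.0
        return trajectory.theta_max * max(0.0, 1.0 - gdh / gdh_decay)

    last = dates[-1]
    def layers_at(date) -> int:
        if fulfillment is None or date <= fulfillment:
            return 13
        frac = (date - fulfillment) / (last - fulfillment) if last > fulfillment else 1.0
        return int(round(13 + 7 * min(max(float(frac), 0.0), 1.0)))

    ss = np.random.SeedSequence(season.seed)
    child_seeds = iter(ss.generate_state(2 * len(dates) * (n_ovaries + 2)) % (2**31))
    ov_rng = np.random.default_rng(season.seed + 77)

    images: dict[str, list] = {}
    wall_images: dict[str, tuple] = {}
    theta_by_date: dict[str, float] = {}
    theta_ovary: dict[str, list[float]] = {}
    layers_by_date: dict[str, int] = {}
    for date in dates:
        key = str(date.date())
        th = theta_at(date)
        theta_by_date[key] = th
        layers_by_date[key] = layers_at(date)
        if not with_images:
            continue
        ovaries = []
        thetas = []
        for i in range(n_ovaries):
            th_o = float(np.clip(ov_rng.normal(th, trajectory.ovary_noise_sd), 0.0, 0.5))
            thetas.append(th_o)
            image, mask = gen_section_image(
                th_o, size=image_size, pixel_size_um=pixel_size_um,
                seed=int(next(child_seeds)), ovary_id=f"{key}_ov{i}", date=key,
            )
            frames = _default_frames(image_size, pixel_size_um, frame_area_um2)
            ovaries.append((image, mask, frames))
        images[key] = ovaries
        theta_ovary[key] = thetas
        wall_images[key] = gen_ovary_wall_image(
            layers_by_date[key], pixel_size_um=pixel_size_um, seed=int(next(child_seeds))
        )

    ground_truth = {
        "planted_cu_requirement": req,
        "fulfillment_date": str(fulfillment) if fulfillment is not None else None,
        "chill_onset_shift_days": season.chill_onset_shift_days,
        "theta_max": trajectory.theta_max,
        "gdh_decay": None if not np.isfinite(gdh_decay) else float(gdh_decay),
        "theta_by_date": theta_by_date,
        "theta_by_ovary": theta_ovary,
        "n_layers_by_date": layers_by_date,
        "granule_band": [list(b) for b in GRANULE_BAND],
        "seed": season.seed,
    }
    return SeasonDataset(
        season=season, trajectory=trajectory, series=series, forcing_tests=forcing,
        dates=dates, images=images, wall_images=wall_images, ground_truth=ground_truth,
    )
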