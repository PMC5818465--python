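"""End-to-end orchestration of one cultivar-year analysis.

Given a config pointing at an hourly temperature CSV, a forcing-test CSV
and a directory of annotated section images, the pipeline (i) accumulates
chill units and dates the break of endodormancy, yielding the chilling
requirement, (ii) accumulates growing degree hours from the break, (iii)
measures starch (summed OD in four 1337-um^2 frames per ovary, six ovaries
per date) and ovary growth, and (iv) runs the inference layer: per-date
ANOVA with Duncan letters and the pre-/post-fulfillment Pearson windows.
All tables are written as TSV plus a JSON report with provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dormancy import (
    DEFAULT_BREAK_THRESHOLD_PCT,
    estimate_break_date,
    chilling_requirement,
    read_forcing_csv,
    write_break_tsv,
)
from .errors import CherryChillError, GeometryError, InputError, StageError
from .imaging import (
    DEFAULT_FRAME_AREA_UM2,
    MeasurementFrame,
    ThresholdSpec,
    calibrate_threshold,
    count_cell_layers,
    load_section_image,
    measure_ovary,
    ovary_diameter,
    read_annotations,
)
from .stats import (
    GroupedMeasurements,
    duncan_mrt,
    one_way_anova,
    significance_stars,
    windowed_correlations,
)
from .thermal import (
    UTAH_TABLE,
    accumulate,
    read_temperature_csv,
    write_daily_tsv,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_inputs", "ValidationReport"]

log = logging.getLogger("cherrychill")


@dataclass
class RunConfig:
    """Configuration for one cultivar-year run."""

    temperature_csv: str
    forcing_csv: str
    image_dir: str
    annotation_json: str
    cultivar: str = "synthetic"
    year: str = "0"
    season_start: str | None = None
    chill_table: str = "utah"
    break_threshold_pct: float = DEFAULT_BREAK_THRESHOLD_PCT
    frame_area_um2: float = DEFAULT_FRAME_AREA_UM2
    alpha_groups: float = 0.05
    alpha_correlation: float = 0.01
    bloom_date: str | None = None
    threshold: dict | None = None  # fixed RGB bounds; else calibrated
    floor_chill_at_zero: bool = False
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    cultivar: str
    year: str
    break_date: str | None
    ratio_at_break: float | None
    chilling_requirement_cu: float | None
    gdh_at_end: float | None
    starch_by_date: pd.DataFrame
    growth_by_date: pd.DataFrame
    anova_table: pd.DataFrame
    correlations: dict
    warnings: list[str]
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "schema_version": 1,
            "cultivar": self.cultivar,
            "year": self.year,
            "break_date": self.break_date,
            "ratio_at_break": self.ratio_at_break,
            "chilling_requirement_cu": self.chilling_requirement_cu,
            "gdh_at_end": self.gdh_at_end,
            "correlations": self.correlations,
            "warnings": self.warnings,
            "provenance": self.provenance,
        }


def _chill_table(name: str):
    if name != "utah":
        raise InputError(f"unknown chill table {name!r}")
    return UTAH_TABLE


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Run the full analysis for one cultivar-year; write tables if out_dir."""
    warnings: list[str] = []

    # --- thermal accumulation ---------------------------------------------
    log.info("stage thermal_models: reading %s", config.temperature_csv)
    if not Path(config.temperature_csv).exists():
        raise StageError("thermal_models", f"temperature CSV not found: {config.temperature_csv}")
    series = read_temperature_csv(config.temperature_csv, season_start=config.season_start)
    table = _chill_table(config.chill_table)
    chill = accumulate(
        series, (series.season_start, series.times[-1]), "chill",
        table=table, floor_at_zero=config.floor_chill_at_zero,
    )
    warnings += [f"thermal_models: {w}" for w in chill.metadata["warnings"]]
    log.info("stage thermal_models: %d hours, total CU %.1f", len(chill.times), chill.total)

    # --- dormancy break ----------------------------------------------------
    if not Path(config.forcing_csv).exists():
        raise StageError("dormancy_break", f"forcing CSV not found: {config.forcing_csv}")
    tests = read_forcing_csv(config.forcing_csv)
    log.info("stage dormancy_break: %d forcing tests", len(tests))
    det = estimate_break_date(tests, config.break_threshold_pct)
    cu_req = None
    heat = None
    if det.break_date is not None:
        cu_req, _ = chilling_requirement(
            series, det, table=table, floor_at_zero=config.floor_chill_at_zero
        )
        end = pd.Timestamp(config.bloom_date) if config.bloom_date else series.times[-1]
        if det.break_date < end:
            heat = accumulate(series, (det.break_date, end), "heat")
    else:
        warnings.append("dormancy_break: no test reached the threshold; no break date")

    # --- starch imaging ----------------------------------------------------
    if not Path(config.annotation_json).exists():
        raise StageError("starch_imaging", f"annotation JSON not found: {config.annotation_json}")
    annotations = read_annotations_file(config.annotation_json)
    image_dir = Path(config.image_dir)
    threshold, thr_meta = _resolve_threshold(config, image_dir, annotations)
    warnings += thr_meta

    starch_rows, growth_rows = [], []
    for fname, ann in sorted(annotations.items()):
        path = image_dir / fname
        if not path.exists():
            raise StageError("starch_imaging", f"image not found: {path}")
        image = load_section_image(
            path, ann["pixel_size_um"], ovary_id=ann.get("ovary_id", fname),
            date=ann.get("date", ""),
        )
        if ann.get("frames"):
            frames = [
                MeasurementFrame(anchor=tuple(a), area_um2=ann.get("frame_area_um2",
                                                                   config.frame_area_um2))
                for a in ann["frames"]
            ]
            meas = measure_ovary(image, threshold, frames)
            starch_rows.append(
                {"date": ann.get("date", ""), "ovary_id": meas.ovary_id,
                 **{f"frame_{i + 1}": v for i, v in enumerate(meas.per_frame)},
                 "ovary_value": meas.ovary_value}
            )
        if ann.get("transect"):
            transect = tuple(tuple(p) for p in ann["transect"])
            layers = count_cell_layers(image, transect)
            growth_rows.append(
                {"date": ann.get("date", ""), "ovary_id": ann.get("ovary_id", fname),
                 "cell_layers": layers,
                 "diameter_um": ovary_diameter(transect, image.pixel_size_um)}
            )
    if not starch_rows:
        raise StageError("starch_imaging", "no annotated measurement frames found")
    starch_df = pd.DataFrame(starch_rows).sort_values(["date", "ovary_id"]).reset_index(drop=True)
    growth_df = pd.DataFrame(
        growth_rows, columns=["date", "ovary_id", "cell_layers", "diameter_um"]
    )
    log.info("stage starch_imaging: %d ovaries measured", len(starch_df))

    # --- statistics --------------------------------------------------------
    anova_df, correlations = _inference(
        starch_df, chill, heat, det.break_date, config, warnings
    )

    provenance = {
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "version": __version__,
        "chill_table": table.name,
        "threshold": {
            "red": list(threshold.red), "green": list(threshold.green),
            "blue": list(threshold.blue),
        },
    }
    report = RunReport(
        cultivar=config.cultivar,
        year=config.year,
        break_date=str(det.break_date.date()) if det.break_date is not None else None,
        ratio_at_break=det.ratio_at_break,
        chilling_requirement_cu=cu_req,
        gdh_at_end=heat.total if heat is not None else None,
        starch_by_date=starch_df,
        growth_by_date=growth_df,
        anova_table=anova_df,
        correlations=correlations,
        warnings=warnings,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_outputs(report, chill, heat, det, config, Path(out_dir))
    return report


def read_annotations_file(path) -> dict:
    with open(path) as fh:
        ann = json.load(fh)
    if not isinstance(ann, dict) or not ann:
        raise InputError(f"{path}: expected a non-empty image -> annotation mapping")
    return ann


def _resolve_threshold(config: RunConfig, image_dir: Path, annotations: dict):
    """Fixed bounds from config, else calibrate on the first reference mask."""
    import imageio.v3 as iio

    if config.threshold is not None:
        t = config.threshold
        return ThresholdSpec(red=tuple(t["red"]), green=tuple(t["green"]),
                             blue=tuple(t["blue"])), []
    for fname, ann in sorted(annotations.items()):
        ref = ann.get("reference_mask")
        if not ref:
            continue
        image = load_section_image(image_dir / fname, ann["pixel_size_um"])
        mask = iio.imread(image_dir / ref) > 0
        if not mask.any():
            continue
        cal = calibrate_threshold(image, mask)
        note = (f"starch_imaging: threshold calibrated on {fname} "
                f"(IoU {cal.iou:.3f}, {cal.method})")
        return cal.spec, [note]
    raise StageError(
        "starch_imaging",
        "no threshold in config and no reference mask available for calibration",
    )


def _inference(starch_df, chill, heat, break_date, config, warnings):
    by_date = starch_df.groupby("date")["ovary_value"]
    anova_rows = []
    letters = {}
    counts = by_date.count()
    usable = counts[counts >= 2]
    if len(usable) >= 2:
        g = GroupedMeasurements.from_frame(
            starch_df[starch_df["date"].isin(usable.index)], "date", "ovary_value"
        )
        try:
            anova = one_way_anova(g)
            duncan = duncan_mrt(g, config.alpha_groups, anova=anova)
            letters = duncan.letters
        except CherryChillError as exc:
            warnings.append(f"stats_inference: ANOVA skipped ({exc})")
    else:
        warnings.append("stats_inference: fewer than 2 dates with n >= 2; ANOVA skipped")
    for date, grp in by_date:
        anova_rows.append(
            {"date": date, "mean": grp.mean(), "sd": grp.std(ddof=1), "n": grp.size,
             "letters": letters.get(date, "")}
        )
    anova_df = pd.DataFrame(anova_rows)

    correlations = {}
    if break_date is not None:
        per_date = [(d, v) for d, v in by_date.mean().items()]
        results, notes = windowed_correlations(per_date, chill, heat, break_date)
        warnings += [f"stats_inference: {n}" for n in notes]
        for window, res in results.items():
            correlations[window] = (
                None if res is None else
                {"r": res.r, "p": res.p, "n": res.n, "stars": res.stars}
            )
    else:
        warnings.append("stats_inference: no break date; correlation windows skipped")
    return anova_df, correlations


def _write_outputs(report: RunReport, chill, heat, det, config: RunConfig, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    write_daily_tsv(out / "cu_gdh_daily.tsv", chill, heat)
    write_break_tsv(
        out / "break_dates.tsv",
        [{"cultivar": report.cultivar, "year": report.year,
          "break_date": report.break_date, "ratio_at_break": report.ratio_at_break,
          "chilling_requirement_CU": report.chilling_requirement_cu}],
    )
    starch = report.starch_by_date.copy()
    starch.insert(0, "year", report.year)
    starch.insert(0, "cultivar", report.cultivar)
    starch.to_csv(out / "starch_by_date.tsv", sep="\t", index=False, float_format="%.4f")
    report.growth_by_date.to_csv(out / "ovary_growth.tsv", sep="\t", index=False,
                                 float_format="%.2f")
    report.anova_table.to_csv(out / "anova_groups.tsv", sep="\t", index=False,
                              float_format="%.4f")
    corr_rows = []
    for window, res in report.correlations.items():
        corr_rows.append(
            {"cultivar": report.cultivar, "year": report.year, "window": window,
             "r": None if res is None else res["r"],
             "p": None if res is None else res["p"],
             "n": None if res is None else res["n"],
             "stars": "" if res is None else res["stars"]}
        )
    pd.DataFrame(corr_rows, columns=["cultivar", "year", "window", "r", "p", "n", "stars"]) \
        .to_csv(out / "correlations.tsv", sep="\t", index=False, float_format="%.5f")
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=1, default=str)


# --- validation ------------------------------------------------------------


@dataclass
class ValidationReport:
    failures: list[str] = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Schema-check every input without running the analysis."""
    rep = ValidationReport()

    try:
        df = pd.read_csv(config.temperature_csv)
        if not {"timestamp", "temp_c"}.issubset(df.columns):
            rep.failures.append("temperature CSV: missing timestamp/temp_c columns")
        else:
            times = pd.to_datetime(df["timestamp"])
            if times.duplicated().any():
                rep.failures.append("temperature CSV: duplicated hour(s)")
            if not times.is_monotonic_increasing:
                rep.failures.append("temperature CSV: timestamps not increasing")
            deltas = times.diff().dropna()
            rep.stats["hour_coverage"] = float(
                (deltas == pd.Timedelta(hours=1)).mean()
            ) if len(deltas) else 0.0
            if not np.isfinite(df["temp_c"]).all():
                rep.failures.append("temperature CSV: non-finite temperature")
    except Exception as exc:  # noqa: BLE001 - report, never raise
        rep.failures.append(f"temperature CSV unreadable: {exc}")

    try:
        fdf = pd.read_csv(config.forcing_csv)
        missing = {"date", "condition", "weight_mg"} - set(fdf.columns)
        if missing:
            rep.failures.append(f"forcing CSV: missing columns {sorted(missing)}")
        elif (fdf["weight_mg"] <= 0).any():
            rep.failures.append("forcing CSV: non-positive bud weight")
    except Exception as exc:  # noqa: BLE001
        rep.failures.append(f"forcing CSV unreadable: {exc}")

    try:
        annotations = read_annotations_file(config.annotation_json)
        image_dir = Path(config.image_dir)
        n_paired = 0
        for fname, ann in annotations.items():
            path = image_dir / fname
            if not path.exists():
                rep.failures.append(f"annotation refers to missing image {fname}")
                continue
            n_paired += 1
            if "pixel_size_um" not in ann:
                rep.failures.append(f"{fname}: missing pixel_size_um")
                continue
            image = load_section_image(path, ann["pixel_size_um"])
            for anchor in ann.get("frames", []):
                frame = MeasurementFrame(
                    anchor=tuple(anchor),
                    area_um2=ann.get("frame_area_um2", config.frame_area_um2),
                )
                try:
                    frame.slices(image)
                except GeometryError as exc:
                    rep.failures.append(f"{fname}: {exc}")
        rep.stats["images_paired"] = n_paired
    except Exception as exc:  # noqa: BLE001
        rep.failures.append(f"annotations unreadable: {exc}")

    return rep
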