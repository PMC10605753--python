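"""Orchestration: simulate -> analyze -> summarize.

Each stage is runnable on its own: `analyze` consumes any directory of
multi-page TIFF recordings (real or synthetic), produces one strength
record per recording, and `summarize` turns a records table into the
group-comparison report.  Failures on individual recordings are logged
and skipped, never fatal.  Outputs carry the config hash and seed so that
equal configurations give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import morphometrics, simulate, stats, tracking
from .geometry import DeviceGeometry

logger = logging.getLogger("nemaflex")

__all__ = [
    "AnalysisSettings",
    "PipelineConfig",
    "analyze_recording",
    "run_analyze",
    "run_summarize",
]


@dataclass(frozen=True)
class AnalysisSettings:
    """Tunables of the measurement stages."""

    noise_floor_multiplier: float = 4.0
    min_frames: int = 20
    adult_length_threshold_um: float = 900.0
    morphometry_frames: int = 8
    expected_length_um: float = 1050.0
    expected_diameter_um: float = 46.0


@dataclass(frozen=True)
class PipelineConfig:
    """Bundled geometry, simulation design and analysis settings."""

    geometry: DeviceGeometry = field(default_factory=DeviceGeometry)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    simulation: simulate.CohortDesign = field(
        default_factory=simulate.default_cohort_design
    )
    noise_sd: float = 5.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        geometry = DeviceGeometry.from_dict(raw.get("geometry", {}))
        analysis = AnalysisSettings(**raw.get("analysis", {}))
        sim_raw = dict(raw.get("simulation", {}))
        groups_raw = sim_raw.pop("groups", None)
        seed = int(raw.get("seed", 0))
        if groups_raw:
            groups = tuple(simulate.GroupSpec(**g) for g in groups_raw)
            design = simulate.CohortDesign(groups=groups, seed=seed, **sim_raw)
        else:
            design = dataclasses.replace(
                simulate.default_cohort_design(seed=seed), **sim_raw
            )
        return cls(
            geometry=geometry,
            analysis=analysis,
            simulation=design,
            noise_sd=float(raw.get("noise_sd", 5.0)),
            seed=seed,
        )

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [encode(o) for o in obj]
            return obj

        payload = json.dumps(encode(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze_recording(
    stack: np.ndarray,
    geometry: DeviceGeometry,
    settings: AnalysisSettings | None = None,
) -> dict:
    """Full measurement chain on one image stack.

    Detects the reference lattice, measures deflections, measures the
    worm, converts per-frame maximal deflections to forces at the
    *measured* diameter, and computes f95.  Returns a flat dict of the
    per-animal quantities.
    """
    settings = settings or AnalysisSettings()
    if not np.issubdtype(stack.dtype, np.floating):
        stack = stack.astype(np.float32)  # one conversion for all stages
    grid = tracking.detect_reference_grid(stack, geometry)
    track = tracking.measure_deflections(
        stack, grid, geometry, noise_floor_multiplier=settings.noise_floor_multiplier
    )
    n_frames = stack.shape[0]
    morpho_idx = np.unique(
        np.linspace(0, n_frames - 1, min(settings.morphometry_frames, n_frames)).astype(int)
    )
    measurement = morphometrics.measure_worm(
        [stack[i] for i in morpho_idx],
        grid,
        geometry,
        expected_length_um=settings.expected_length_um,
        expected_diameter_um=settings.expected_diameter_um,
        adult_length_threshold_um=settings.adult_length_threshold_um,
    )
    frames, argmax_pillars, delta_max, n_dropped = tracking.max_deflection_per_frame(track)
    forces = stats.per_frame_forces(delta_max, geometry, measurement.diameter_um)
    f95 = stats.compute_f95(forces, min_frames=settings.min_frames)
    return {
        "diameter_um": measurement.diameter_um,
        "length_um": measurement.length_um,
        "is_adult": measurement.is_adult,
        "morpho_frames_used": measurement.frames_used,
        "f95_uN": f95,
        "n_frames_used": int(len(frames)),
        "n_frames_dropped": n_dropped,
        "noise_floor_um": track.noise_floor_um,
    }


def run_analyze(
    path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Analyze a recording file or a directory of recordings.

    Group labels are taken from a ``manifest.csv`` sitting next to the
    recordings when present, else parsed from ``strain_environment_id``
    file names.  Failed recordings are logged and reported with an
    ``error`` column, not raised.
    """
    config = config or PipelineConfig()
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not files:
            raise FileNotFoundError(f"no recordings found in {path}")
        manifest = None
        mpath = path / "manifest.csv"
        if mpath.exists():
            manifest = pd.read_csv(mpath).set_index("animal_id")
    else:
        files = [path]
        manifest = None

    rows = []
    for f in files:
        animal_id = f.stem
        strain, environment = _labels_for(animal_id, manifest)
        try:
            stack = tifffile.imread(f)
            result = analyze_recording(stack, config.geometry, config.analysis)
            rows.append(
                {"animal_id": animal_id, "strain": strain, "environment": environment,
                 **result, "error": ""}
            )
            logger.info("analyzed %s: f95=%.2f uN", animal_id, result["f95_uN"])
        except Exception as exc:  # per-recording failures are data, not crashes
            logger.warning("failed %s: %s", animal_id, exc)
            rows.append(
                {"animal_id": animal_id, "strain": strain,
                 "environment": environment, "error": str(exc)}
            )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(df, out / "strength_records.csv", config)
    return df


def run_summarize(
    records: pd.DataFrame | str | Path,
    out_dir: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> stats.CohortComparison:
    """Group comparison report from a records table (or its CSV path).

    Writes a group-summary CSV (the mean +/- SD table), an ANOVA/Tukey
    JSON report, and a plain-text summary with percent declines.
    """
    config = config or PipelineConfig()
    if not isinstance(records, pd.DataFrame):
        records = pd.read_csv(records)
    required = {"strain", "environment", "f95_uN", "diameter_um", "length_um"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")
    if "error" in records.columns:
        records = records[records["error"].fillna("") == ""]
    group_sizes = records.groupby(["strain", "environment"]).size()
    if (group_sizes < 2).any():
        # degenerate pass-through: report percent declines from the group
        # means, skip inference (undefined below n = 2)
        logger.warning("groups with n < 2: ANOVA/Tukey skipped")
        comparison = _means_only_comparison(records)
    else:
        comparison = stats.compare_cohort(records)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(comparison.summary, out / "group_summary.csv", config)
        report = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_records": comparison.n_records,
            "normality_shapiro_p": comparison.normality.to_dict(orient="records"),
            "anova": {
                var: tab.reset_index(names="effect").to_dict(orient="records")
                for var, tab in comparison.anova.items()
            },
            "tukey": {
                var: tab.to_dict(orient="records")
                for var, tab in comparison.tukey.items()
            },
            "percent_declines": comparison.declines.to_dict(orient="records"),
        }
        (out / "comparison.json").write_text(json.dumps(report, indent=1, default=str))
        (out / "summary.txt").write_text(_text_summary(comparison))
    return comparison


def _means_only_comparison(records: pd.DataFrame) -> stats.CohortComparison:
    variables = ("f95_uN", "diameter_um", "length_um")
    rows = []
    for (strain, env), grp in records.groupby(["strain", "environment"]):
        row = {"strain": strain, "environment": env, "n": len(grp)}
        for var in variables:
            row[f"{var}_mean"] = float(grp[var].mean())
            row[f"{var}_sd"] = float(grp[var].std(ddof=1)) if len(grp) > 1 else float("nan")
        rows.append(row)
    summary = pd.DataFrame(rows)
    decl_rows = []
    for strain in records["strain"].unique():
        for var in variables:
            sub = summary[summary.strain == strain].set_index("environment")
            if {"ground", "flight"} <= set(sub.index):
                decl_rows.append(
                    {
                        "strain": strain,
                        "variable": var,
                        "percent_decline": stats.percent_decline(
                            sub.loc["ground", f"{var}_mean"],
                            sub.loc["flight", f"{var}_mean"],
                        ),
                    }
                )
    return stats.CohortComparison(
        summary=summary,
        normality=pd.DataFrame(),
        anova={},
        tukey={},
        declines=pd.DataFrame(decl_rows),
        n_records=len(records),
    )


def _text_summary(comparison: stats.CohortComparison) -> str:
    lines = ["Group summary (mean +/- SD):"]
    for _, row in comparison.summary.iterrows():
        lines.append(
            f"  {row.strain:>6} {row.environment:<7} n={row.n:>3}  "
            f"f95 = {row.f95_uN_mean:6.2f} +/- {row.f95_uN_sd:5.2f} uN  "
            f"diameter = {row.diameter_um_mean:6.2f} +/- {row.diameter_um_sd:4.2f} um  "
            f"length = {row.length_um_mean:7.1f} +/- {row.length_um_sd:5.1f} um"
        )
    lines.append("")
    lines.append("Percent declines, flight vs ground:")
    for _, row in comparison.declines.iterrows():
        lines.append(
            f"  {row.strain:>6} {row.variable:<12} {row.percent_decline:5.1f} %"
        )
    lines.append("")
    for var, tab in comparison.anova.items():
        p_env = tab.loc["environment", "PR(>F)"]
        p_strain = tab.loc["strain", "PR(>F)"]
        lines.append(
            f"Two-way ANOVA on {var}: environment p={p_env:.3g} "
            f"({stats.significance_stars(p_env)}), strain p={p_strain:.3g} "
            f"({stats.significance_stars(p_strain)})"
        )
    return "\n".join(lines) + "\n"


def _labels_for(animal_id: str, manifest: pd.DataFrame | None):
    if manifest is not None and animal_id in manifest.index:
        row = manifest.loc[animal_id]
        return str(row["strain"]), str(row["environment"])
    parts = animal_id.split("_")
    if len(parts) >= 3 and parts[-2] in stats.ENVIRONMENTS:
        return "_".join(parts[:-2]), parts[-2]
    return "unknown", "unknown"


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    df = df.copy()
    df["config_hash"] = config.config_hash()
    df["seed"] = config.seed
    df.to_csv(path, index=False, float_format="%.6f")
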