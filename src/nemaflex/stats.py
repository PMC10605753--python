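"""The f95 strength statistic and cohort-level group comparisons.

Per animal, strength is summarised as f95: the pillar with the maximal
deflection is identified in every frame, deflections are converted to
forces using the animal's own mid-section diameter, and f95 is the 95th
percentile of the resulting per-frame maximal-force distribution.

At the cohort level the analysis mirrors a 2x2 strain-by-environment
design: per-group mean +/- SD tables, an advisory Shapiro-Wilk normality
check, a two-way ANOVA (Type II sums of squares, appropriate for the
unbalanced group sizes) with Tukey HSD pairwise comparisons, and percent
strength/size declines of flight relative to ground.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .geometry import DeviceGeometry, deflection_to_force

__all__ = [
    "StrengthRecord",
    "CohortComparison",
    "compute_f95",
    "per_frame_forces",
    "summarize_groups",
    "percent_decline",
    "significance_stars",
    "compare_cohort",
]

STRAINS = ("wt", "dys-1")
ENVIRONMENTS = ("ground", "flight")


@dataclass
class StrengthRecord:
    """One animal's morphometrics and strength summary."""

    animal_id: str
    strain: str
    environment: str
    diameter_um: float
    length_um: float
    f95_uN: float
    n_frames_used: int

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"strain must be one of {STRAINS}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"environment must be one of {ENVIRONMENTS}")
        if self.f95_uN < 0:
            raise ValueError("f95_uN must be non-negative")


@dataclass
class CohortComparison:
    """Group summaries plus the inferential results for one cohort."""

    summary: pd.DataFrame                 # per group x variable: mean, sd, n
    normality: pd.DataFrame               # Shapiro-Wilk p per group x variable
    anova: dict[str, pd.DataFrame]        # variable -> two-way ANOVA table
    tukey: dict[str, pd.DataFrame]        # variable -> pairwise Tukey table
    declines: pd.DataFrame                # per strain x variable: percent decline
    n_records: int = 0


def compute_f95(forces_uN, min_frames: int = 20) -> float:
    """95th percentile of the per-frame maximal-force sample (uN).

    Uses linear interpolation between order statistics (the "type 7"
    convention, position h = 0.95 (n - 1) + 1 on the sorted sample), which
    makes the statistic permutation-invariant and positively
    scale-equivariant.
    """
    forces = np.asarray(forces_uN, dtype=float)
    if forces.ndim != 1:
        forces = forces.ravel()
    if forces.size < min_frames:
        raise ValueError(
            f"insufficient frames: need >= {min_frames}, got {forces.size}"
        )
    if np.any(forces < 0):
        raise ValueError("forces must be non-negative")
    return float(np.percentile(forces, 95.0, method="linear"))


def per_frame_forces(
    max_deflections_um,
    geometry: DeviceGeometry,
    worm_diameter_um: float,
) -> np.ndarray:
    """Convert per-frame maximal deflections (um) to forces (uN).

    Force is strictly increasing in deflection at fixed diameter, so the
    argmax-deflection pillar and the argmax-force pillar coincide.
    """
    deltas = np.asarray(max_deflections_um, dtype=float)
    forces = deflection_to_force(deltas, geometry, worm_diameter_um)
    return np.asarray(forces, dtype=float)


def summarize_groups(
    records: list[StrengthRecord] | pd.DataFrame,
    variables: tuple[str, ...] = ("f95_uN", "diameter_um", "length_um"),
) -> pd.DataFrame:
    """Per-group sample mean and SD (n-1 denominator) for each variable."""
    df = _records_frame(records)
    rows = []
    for (strain, env), grp in df.groupby(["strain", "environment"], sort=False):
        if len(grp) < 2:
            raise ValueError(
                f"group ({strain}, {env}) has n={len(grp)} < 2; "
                "group statistics undefined"
            )
        row = {"strain": strain, "environment": env, "n": len(grp)}
        for var in variables:
            row[f"{var}_mean"] = float(grp[var].mean())
            row[f"{var}_sd"] = float(grp[var].std(ddof=1))
        rows.append(row)
    out = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(STRAINS)}
    eorder = {e: i for i, e in enumerate(ENVIRONMENTS)}
    out = out.sort_values(
        ["strain", "environment"],
        key=lambda c: c.map(order if c.name == "strain" else eorder),
    ).reset_index(drop=True)
    return out


def percent_decline(ground_mean: float, flight_mean: float, decimals: int | None = 1) -> float:
    """Percent decline of the flight mean relative to the ground mean.

    Reported at one-decimal precision by truncation toward zero, the
    convention under which the published group means reproduce the printed
    decline figures exactly.  Pass ``decimals=None`` for the untruncated
    value.
    """
    if ground_mean <= 0:
        raise ValueError("ground_mean must be positive")
    value = 100.0 * (ground_mean - flight_mean) / ground_mean
    if decimals is None:
        return value
    scale = 10.0**decimals
    return float(math.trunc(value * scale) / scale)


def significance_stars(p: float) -> str:
    """Star annotation used in the study's figures.

    Mapping as printed there: '*' p<0.05, '**' p<0.01, '****' p<0.001
    (the four-star tier is the source's own labelling for p<0.001).
    """
    if p < 0.001:
        return "****"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_cohort(
    records: list[StrengthRecord] | pd.DataFrame,
    variables: tuple[str, ...] = ("f95_uN", "diameter_um", "length_um"),
) -> CohortComparison:
    """Full group comparison: summaries, normality, two-way ANOVA, Tukey.

    The ANOVA models strain, environment and their interaction with Type II
    sums of squares so unbalanced group sizes are handled sensibly.  The
    Shapiro-Wilk check is advisory (reported, never used to switch tests).
    """
    df = _records_frame(records)
    if df.empty:
        raise ValueError("no records")
    groups = df.groupby(["strain", "environment"])
    if any(len(g) < 2 for _, g in groups):
        raise ValueError("every group needs n >= 2")
    if df["strain"].nunique() < 2 or df["environment"].nunique() < 2:
        missing = "strain" if df["strain"].nunique() < 2 else "environment"
        raise ValueError(f"need both levels of factor '{missing}' for a 2x2 comparison")

    summary = summarize_groups(df, variables)

    norm_rows = []
    for (strain, env), grp in groups:
        row = {"strain": strain, "environment": env}
        for var in variables:
            x = grp[var].to_numpy(dtype=float)
            row[var] = float(sps.shapiro(x).pvalue) if len(x) >= 3 else np.nan
        norm_rows.append(row)
    normality = pd.DataFrame(norm_rows)

    anova: dict[str, pd.DataFrame] = {}
    tukey: dict[str, pd.DataFrame] = {}
    work = df.rename(columns={v: v.replace("-", "_") for v in variables}).copy()
    work["strain_c"] = work["strain"]
    work["env_c"] = work["environment"]
    work["group"] = work["strain"] + ":" + work["environment"]
    for var in variables:
        model = smf.ols(f"{var} ~ C(strain_c) * C(env_c)", data=work).fit()
        table = sm.stats.anova_lm(model, typ=2)
        table.index = [
            {"C(strain_c)": "strain", "C(env_c)": "environment",
             "C(strain_c):C(env_c)": "strain:environment"}.get(i, i)
            for i in table.index
        ]
        anova[var] = table
        hsd = pairwise_tukeyhsd(work[var], work["group"], alpha=0.05)
        tukey[var] = pd.DataFrame(
            hsd.summary().data[1:], columns=hsd.summary().data[0]
        )

    decl_rows = []
    for strain in df["strain"].unique():
        for var in variables:
            means = {
                env: summary.loc[
                    (summary.strain == strain) & (summary.environment == env),
                    f"{var}_mean",
                ]
                for env in ENVIRONMENTS
            }
            if any(m.empty for m in means.values()):
                continue
            g, f = float(means["ground"].iloc[0]), float(means["flight"].iloc[0])
            decl_rows.append(
                {
                    "strain": strain,
                    "variable": var,
                    "percent_decline": percent_decline(g, f),
                }
            )
    declines = pd.DataFrame(decl_rows)

    return CohortComparison(
        summary=summary,
        normality=normality,
        anova=anova,
        tukey=tukey,
        declines=declines,
        n_records=len(df),
    )


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    required = {"strain", "environment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    return df
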