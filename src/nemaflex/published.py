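"""Reference group summaries from the ISS spaceflight strength experiment.

These are the published per-group sample sizes and mean +/- SD values for
mid-section diameter, centerline length and the f95 strength statistic of
wild-type (N2) and dystrophin-mutant (dys-1, BZ33) adults cultured on the
ground or aboard the ISS.  They serve two purposes here: the percent-decline
arithmetic can be reproduced from them directly, and the synthetic cohort
generator uses them as the default study design it emulates.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REFERENCE_GROUPS", "reference_table", "GROUP_KEYS"]

GROUP_KEYS = [
    ("wt", "ground"),
    ("wt", "flight"),
    ("dys-1", "ground"),
    ("dys-1", "flight"),
]

# (strain, environment) -> n, diameter um, length um, f95 uN (mean, sd each)
REFERENCE_GROUPS: dict[tuple[str, str], dict[str, float]] = {
    ("wt", "ground"): dict(
        n=30, diameter_mean=46.97, diameter_sd=1.92,
        length_mean=1077.0, length_sd=60.0,
        f95_mean=22.34, f95_sd=5.67,
    ),
    ("wt", "flight"): dict(
        n=30, diameter_mean=44.35, diameter_sd=1.88,
        length_mean=1062.0, length_sd=42.0,
        f95_mean=18.62, f95_sd=4.05,
    ),
    ("dys-1", "ground"): dict(
        n=25, diameter_mean=48.24, diameter_sd=1.87,
        length_mean=1110.0, length_sd=43.0,
        f95_mean=21.38, f95_sd=5.39,
    ),
    ("dys-1", "flight"): dict(
        n=29, diameter_mean=44.41, diameter_sd=2.29,
        length_mean=1080.0, length_sd=45.0,
        f95_mean=14.23, f95_sd=3.87,
    ),
}


def reference_table() -> pd.DataFrame:
    """The reference summaries as a tidy DataFrame (one row per group)."""
    rows = []
    for (strain, env), vals in REFERENCE_GROUPS.items():
        rows.append({"strain": strain, "environment": env, **vals})
    return pd.DataFrame(rows)
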