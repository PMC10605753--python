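"""f95 statistic, group summaries, percent declines and the two-way ANOVA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nemaflex.geometry import DeviceGeometry, deflection_to_force
from nemaflex.published import REFERENCE_GROUPS
from nemaflex.stats import (
    StrengthRecord,
    compare_cohort,
    compute_f95,
    per_frame_forces,
    percent_decline,
    significance_stars,
    summarize_groups,
)


def brute_force_percentile95(values) -> float:
    """Oracle: type-7 95th percentile straight from the definition.

    Position h = 0.95 (n - 1) + 1 on the 1-based sorted sample, linear
    interpolation between the bracketing order statistics.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    h = 0.95 * (n - 1) + 1
    k = int(np.floor(h))
    frac = h - k
    if k >= n:
        return float(x[-1])
    return float(x[k - 1] + frac * (x[k] - x[k - 1]))


class TestComputeF95:
    def test_constant_sample(self):
        assert compute_f95([7.0] * 300) == 7.0

    def test_worked_sequence(self):
        """1..300 uN has its 95th percentile at 285.05 under type-7."""
        assert compute_f95(np.arange(1.0, 301.0)) == pytest.approx(285.05, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=60.0), min_size=20, max_size=400)
    )
    def test_matches_brute_force_oracle(self, values):
        assert compute_f95(values) == pytest.approx(
            brute_force_percentile95(values), rel=1e-12, abs=1e-12
        )

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=60.0), min_size=25, max_size=200),
        st.floats(min_value=0.01, max_value=50.0),
        st.randoms(use_true_random=False),
    )
    def test_scale_equivariance_and_permutation_invariance(self, values, c, rnd):
        base = compute_f95(values)
        assert compute_f95([c * v for v in values]) == pytest.approx(
            c * base, rel=1e-9, abs=1e-12
        )
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert compute_f95(shuffled) == base

    def test_insufficient_frames(self):
        with pytest.raises(ValueError, match="insufficient"):
            compute_f95([1.0] * 19)


class TestPerFrameForces:
    def test_zero_track(self):
        geom = DeviceGeometry()
        forces = per_frame_forces(np.zeros(30), geom, 45.0)
        assert np.all(forces == 0.0)
        assert compute_f95(forces) == 0.0

    def test_linearity_in_deflection(self):
        geom = DeviceGeometry()
        d = np.linspace(0.1, 2.0, 25)
        f1 = per_frame_forces(d, geom, 45.0)
        f2 = per_frame_forces(2 * d, geom, 45.0)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_argmax_preserved(self):
        """Force is strictly increasing in deflection at fixed diameter."""
        geom = DeviceGeometry()
        d = np.array([0.3, 1.7, 0.9, 1.1])
        f = per_frame_forces(d, geom, 45.0)
        assert np.argmax(f) == np.argmax(d)


class TestPercentDecline:
    @pytest.mark.parametrize(
        "ground,flight,expected",
        [
            (22.34, 18.62, 16.6),   # wt strength
            (21.38, 14.23, 33.4),   # dys-1 strength
            (46.97, 44.35, 5.5),    # wt diameter
            (48.24, 44.41, 7.9),    # dys-1 diameter
            (10.0, 10.0, 0.0),
        ],
    )
    def test_reported_one_decimal(self, ground, flight, expected):
        assert percent_decline(ground, flight) == expected

    def test_untruncated_value_available(self):
        assert percent_decline(22.34, 18.62, decimals=None) == pytest.approx(
            100 * (22.34 - 18.62) / 22.34
        )

    def test_rejects_nonpositive_ground(self):
        with pytest.raises(ValueError):
            percent_decline(0.0, 1.0)


class TestSignificanceStars:
    def test_mapping(self):
        assert significance_stars(0.0005) == "****"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"


def _records_from_groups(spec: dict, noise_sd=0.0, seed=0) -> list[StrengthRecord]:
    rng = np.random.default_rng(seed)
    records = []
    for (strain, env), (n, f95, dia, length) in spec.items():
        for i in range(n):
            records.append(
                StrengthRecord(
                    animal_id=f"{strain}_{env}_{i}",
                    strain=strain,
                    environment=env,
                    diameter_um=dia + rng.normal(0, noise_sd),
                    length_um=length + rng.normal(0, noise_sd),
                    f95_uN=max(f95 + rng.normal(0, noise_sd), 0.01),
                    n_frames_used=300,
                )
            )
    return records


class TestSummarizeGroups:
    def test_degenerate_replicates_reproduce_reference_means(self):
        spec = {
            key: (ref["n"], ref["f95_mean"], ref["diameter_mean"], ref["length_mean"])
            for key, ref in REFERENCE_GROUPS.items()
        }
        table = summarize_groups(_records_from_groups(spec))
        for (strain, env), ref in REFERENCE_GROUPS.items():
            row = table[(table.strain == strain) & (table.environment == env)].iloc[0]
            assert row["f95_uN_mean"] == pytest.approx(ref["f95_mean"])
            assert row["f95_uN_sd"] == pytest.approx(0.0, abs=1e-12)
            assert row["n"] == ref["n"]

    def test_hand_checkable_sd(self):
        spec = {("wt", "ground"): (2, 10.0, 45.0, 1000.0)}
        recs = _records_from_groups(spec)
        recs[1].f95_uN = 20.0
        table = summarize_groups(recs)
        assert table["f95_uN_mean"].iloc[0] == pytest.approx(15.0)
        assert table["f95_uN_sd"].iloc[0] == pytest.approx(np.sqrt(50.0))

    def test_single_animal_group_rejected(self):
        spec = {("wt", "ground"): (1, 10.0, 45.0, 1000.0)}
        with pytest.raises(ValueError, match="n=1"):
            summarize_groups(_records_from_groups(spec))


def two_way_anova_by_hand(df: pd.DataFrame, value: str):
    """Oracle for the balanced case: textbook sums of squares."""
    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    n_cell = df.groupby(["strain", "environment"])[value].count().iloc[0]
    ss_a = sum(
        len(g) * (g[value].mean() - grand) ** 2 for _, g in df.groupby("strain")
    )
    ss_b = sum(
        len(g) * (g[value].mean() - grand) ** 2 for _, g in df.groupby("environment")
    )
    ss_cells = sum(
        len(g) * (g[value].mean() - grand) ** 2
        for _, g in df.groupby(["strain", "environment"])
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((g[value] - g[value].mean()) ** 2).sum()
        for _, g in df.groupby(["strain", "environment"])
    )
    df_err = len(y) - 4
    return (
        (ss_a / 1) / (ss_err / df_err),
        (ss_b / 1) / (ss_err / df_err),
        (ss_ab / 1) / (ss_err / df_err),
    )


class TestCompareCohort:
    def test_balanced_toy_anova_matches_hand_computation(self):
        rng = np.random.default_rng(42)
        rows = []
        means = {("wt", "ground"): 20.0, ("wt", "flight"): 17.0,
                 ("dys-1", "ground"): 19.0, ("dys-1", "flight"): 13.0}
        for (strain, env), mu in means.items():
            for i in range(8):
                rows.append(
                    dict(
                        strain=strain, environment=env,
                        f95_uN=mu + rng.normal(0, 2.0),
                        diameter_um=45.0 + rng.normal(0, 1.0),
                        length_um=1080.0 + rng.normal(0, 30.0),
                    )
                )
        df = pd.DataFrame(rows)
        comparison = compare_cohort(df)
        f_a, f_b, f_ab = two_way_anova_by_hand(df, "f95_uN")
        table = comparison.anova["f95_uN"]
        assert table.loc["strain", "F"] == pytest.approx(f_a, rel=1e-8)
        assert table.loc["environment", "F"] == pytest.approx(f_b, rel=1e-8)
        assert table.loc["strain:environment", "F"] == pytest.approx(f_ab, rel=1e-8)

    def test_reference_cohort_shape_and_declines(self):
        spec = {
            key: (ref["n"], ref["f95_mean"], ref["diameter_mean"], ref["length_mean"])
            for key, ref in REFERENCE_GROUPS.items()
        }
        comparison = compare_cohort(_records_from_groups(spec, noise_sd=0.5, seed=7))
        decl = comparison.declines
        wt = decl[(decl.strain == "wt") & (decl.variable == "f95_uN")]
        dys = decl[(decl.strain == "dys-1") & (decl.variable == "f95_uN")]
        assert abs(wt.percent_decline.iloc[0] - 16.6) < 1.5
        assert abs(dys.percent_decline.iloc[0] - 33.4) < 1.5
        assert set(comparison.summary.n) == {30, 25, 29}
        assert comparison.n_records == 114

    def test_power_under_designed_effect(self):
        """Flight multiplier 0.7, n = 30/group, CV 0.25: the environment
        main effect is detected in >= 80% of repetitions."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 200
        for _ in range(reps):
            rows = []
            for strain in ("wt", "dys-1"):
                for env, mult in (("ground", 1.0), ("flight", 0.7)):
                    mu = 20.0 * mult
                    for i in range(30):
                        rows.append(
                            dict(strain=strain, environment=env,
                                 f95_uN=max(rng.normal(mu, 0.25 * mu), 0.01),
                                 diameter_um=45.0, length_um=1080.0)
                        )
            df = pd.DataFrame(rows)
            comparison = compare_cohort(df, variables=("f95_uN",))
            if comparison.anova["f95_uN"].loc["environment", "PR(>F)"] < 0.05:
                hits += 1
        assert hits / reps >= 0.80

    def test_single_factor_level_rejected(self):
        spec = {("wt", "ground"): (3, 10.0, 45.0, 1000.0),
                ("dys-1", "ground"): (3, 11.0, 46.0, 1010.0)}
        with pytest.raises(ValueError, match="environment"):
            compare_cohort(pd.DataFrame([vars(r) for r in _records_from_groups(spec)]))

    def test_normality_reported_not_gating(self):
        spec = {
            key: (ref["n"], ref["f95_mean"], ref["diameter_mean"], ref["length_mean"])
            for key, ref in REFERENCE_GROUPS.items()
        }
        comparison = compare_cohort(_records_from_groups(spec, noise_sd=1.0, seed=5))
        assert comparison.normality.shape[0] == 4
        assert np.isfinite(comparison.normality["f95_uN"]).all()


class TestStrengthRecord:
    def test_closed_vocabularies(self):
        with pytest.raises(ValueError):
            StrengthRecord("a", "n2", "ground", 45.0, 1000.0, 20.0, 300)
        with pytest.raises(ValueError):
            StrengthRecord("a", "wt", "orbit", 45.0, 1000.0, 20.0, 300)
        with pytest.raises(ValueError):
            StrengthRecord("a", "wt", "ground", 45.0, 1000.0, -1.0, 300)
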