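"""Group comparison of the measured cohort.

Builds the group mean +/- SD table, runs the Shapiro-Wilk normality
check, the two-way ANOVA (strain x environment, Type II) with Tukey HSD
comparisons, and reports percent strength/size declines of flight
relative to ground — the same summary shape the flight study reported.

Reads results/strength_records.csv; writes group_summary.csv,
comparison.json and summary.txt under results/.
"""

from pathlib import Path

from nemaflex.pipeline import run_summarize

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = ROOT / "strength_records.csv"
    if not records.exists():
        raise SystemExit("run 03_measure_strength.py first")
    run_summarize(records, out_dir=ROOT)
    print((ROOT / "summary.txt").read_text())
    print(f"full report in {ROOT / 'comparison.json'}")


if __name__ == "__main__":
    main()
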