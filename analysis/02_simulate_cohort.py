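"""Simulate a demonstration cohort of micropillar-arena recordings.

Generates synthetic videos for a reduced 2x2 cohort (strain x
environment, 4 animals per group) whose body sizes and group strength
ratios mirror the flight study, and writes multi-page TIFFs plus a
ground-truth manifest under scratch/recordings/ (image stacks are bulky
scratch data; the derived tables land in results/).  Pass ``--full`` for
the complete 30/30/25/29 design (longer run).

The arena is rendered at a quarter-size field of view (640 x 480 px at
the same 1.6 um/px scale) with 24 s recordings; see docs/methods.md for
the reasoning behind these analysis-scale sizes.
"""

import argparse
import dataclasses
from pathlib import Path

from nemaflex.geometry import DeviceGeometry
from nemaflex.simulate import default_cohort_design, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "scratch" / "recordings"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--full", action="store_true",
                        help="full 30/30/25/29 design instead of 4/group")
    args = parser.parse_args()

    geometry = DeviceGeometry(image_width_px=640, image_height_px=480)
    design = default_cohort_design(seed=args.seed, duration_s=24.0)
    if not args.full:
        design = dataclasses.replace(
            design,
            groups=tuple(
                dataclasses.replace(g, n=4) for g in design.groups
            ),
        )
    count = 0
    for rec in generate_cohort(design, geometry, noise_sd=5.0, out_dir=OUT):
        count += 1
        print(
            f"{rec.animal_id}: true f95 = {rec.ground_truth.true_f95_uN:.2f} uN, "
            f"diameter = {rec.worm.diameter_um:.2f} um"
        )
    print(f"\nwrote {count} recordings and manifest.csv to {OUT}")


if __name__ == "__main__":
    main()
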