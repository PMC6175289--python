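#!/usr/bin/env python
"""Full single-sample quantification run with all artifacts and figures.

Executes the end-to-end workbench pipeline (simulate → fit → fat-water
separation → clustering → fraction report → resolution study → agreement)
on the default configuration.  The run directory with maps, class volumes,
figures and the manifest goes to scratch/run_seed1/; the fraction tables are
copied to results/.
"""

import shutil
from pathlib import Path

from lamap import phantom as ph
from lamap import workbench as wb

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
RUN_DIR = ROOT / "scratch" / "run_seed1"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = wb.RunConfig(
        phantom_spec=ph.PhantomSpec(noise_sigma=1.0 / 40.0, seed=1),
        seed=1,
    )
    manifest = wb.run_pipeline(cfg, RUN_DIR)
    for name in ("fractions.csv", "ground_truth.csv",
                 "resolution_variation.csv", "agreement_slices.csv"):
        shutil.copy(RUN_DIR / name, RESULTS / name)

    s = manifest["summary"]
    print("volumetric fractions (3-slice fibrosis / 5-slice fat):")
    for k, v in s["fractions_volume"].items():
        truth = s["truth_volume"].get(k)
        extra = f" (truth {truth:.2f}%)" if truth is not None else ""
        print(f"  {k:22s} {v:6.2f}%{extra}")
    print(f"fat volume fraction (mean Dixon FF): "
          f"{s['fat_volume_fraction_mean_ff_pct']:.2f}%")
    print(f"3- vs 4-class reclassified pixels: "
          f"{s['reclassification_pct']:.2f}%")
    print("variation at 2 mm:",
          {k: round(v, 1) for k, v in s["variation_at_coarsest_pct"].items()})
    print(f"run directory: {RUN_DIR} ({len(manifest['artifacts'])} artifacts,"
          f" {len(manifest['figures'])} figures)")


if __name__ == "__main__":
    main()
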