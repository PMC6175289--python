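#!/usr/bin/env python
"""Eight-phantom fraction-recovery study.

Renders eight phantoms (seeds 1-8) whose composition targets span the
observed tissue ranges (total fibrosis 6-23%, fat 4-43%), quantifies each,
and compares recovered against true fractions per component: per-phantom
errors, cross-phantom Spearman correlation, regression and Bland-Altman
limits.  Tables go to results/.
"""

from pathlib import Path

from lamap import workbench as wb

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    batch = wb.batch_fraction_study(seeds=(1, 2, 3, 4, 5, 6, 7, 8))
    agree = wb.batch_agreement(batch)
    batch.to_csv(RESULTS / "batch_fractions.csv", index=False,
                 float_format="%.6g")
    agree.to_csv(RESULTS / "batch_agreement.csv", float_format="%.6g")

    err3 = (batch["recovered_3d"] - batch["truth_3d"]).abs()
    print(f"8 phantoms x 4 components: max |error| "
          f"{err3.max():.2f} pp (3D), "
          f"{(batch['recovered_2d'] - batch['truth_2d']).abs().max():.2f} pp "
          f"(2D)")
    print(agree[["spearman_r_3d", "max_abs_error_3d_pp", "bias_pp",
                 "slope"]].to_string(float_format=lambda v: f"{v:.3f}"))
    print(f"wrote {RESULTS/'batch_fractions.csv'} and batch_agreement.csv")


if __name__ == "__main__":
    main()
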