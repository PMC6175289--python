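#!/usr/bin/env python
"""Resolution-degradation experiment: 200 µm → 2 mm.

Quantifies the seed-1 phantom at 200/400/1000/2000 µm in both degradation
modes (map-domain block-averaging of the fitted maps, and signal-domain
block-averaging of the raw series followed by re-fitting) and reports the
percentage of variation of each tissue component relative to the 200 µm
reference.  Table goes to results/.
"""

from pathlib import Path

import pandas as pd

from lamap import phantom as ph
from lamap import pipeline as pl

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = ph.PhantomSpec(noise_sigma=1.0 / 40.0, seed=1)
    series = pl.render_sample(spec)
    maps = pl.fit_sample_maps(series)
    quant = pl.quantify(series, maps, seed=1)

    rows = []
    for mode in ("map-domain", "signal-domain"):
        for v in pl.run_variation_study(
                series, maps, quant,
                resolutions_um=(200.0, 400.0, 1000.0, 2000.0), mode=mode,
                seed=1):
            rows.append({"mode": mode, "component": v.component,
                         "test_um": v.test_um,
                         "reference_pct": v.reference_pct,
                         "test_pct": v.test_pct,
                         "variation_pct": v.variation_pct})
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "resolution_variation_modes.csv", index=False,
                 float_format="%.6g")
    at_2mm = frame[frame["test_um"] == 2000.0]
    print("percentage of variation at 2 mm (vs 200 µm reference):")
    print(at_2mm.pivot(index="component", columns="mode",
                       values="variation_pct")
          .to_string(float_format=lambda v: f"{v:+.1f}%"))
    print("fibrosis components fall, fat rises — partial volume dilutes "
          "sub-voxel strands and septa while lobule borders bleed outward")
    print(f"wrote {RESULTS/'resolution_variation_modes.csv'}")


if __name__ == "__main__":
    main()
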