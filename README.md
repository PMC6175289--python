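# lamap — ex vivo left-atrial tissue mapping

Atrial fibrosis and fatty infiltration remodel the thin (~2 mm) wall of the
left atrium, but in vivo T1 mapping cannot resolve them: the wall is only a
few voxels thick and partial volume mixes every tissue. `lamap` implements
the ex vivo analysis chain that quantifies this remodelling at 200 µm
resolution on fixed left-atrial samples — and, because such specimens are
not publicly available, validates every stage end-to-end on digital
phantoms whose tissue composition is known exactly.

The pipeline, for each sample:

1. **T1 mapping.** A fat-saturated saturation-recovery series (nine
   repetition delays, 0.15–6.5 s) is fitted per voxel with the
   three-parameter model *S(t) = A(1 − B·e^(−t/T1))* by variable
   projection (the linear subproblem is solved in closed form, leaving a
   1-D golden-section search over T1).
2. **Fat imaging.** Two-point Dixon: the fat-water chemical shift (~600 Hz
   at 4 T) makes the 3.356 ms echo in-phase and the 4.194 ms echo opposed,
   so *FF = (IP − OP)/(2·IP)* after correcting both magnitudes for shared
   T2\* decay. The decay map comes from a 48-echo spin-echo series fitted
   with a Rician-noise-aware monoexponential (the expected-magnitude
   objective removes the noise-floor bias of plain least squares).
3. **Tissue clustering.** T1 values are clustered with 1-D Gaussian
   mixtures fitted by EM; classes get roles purely by T1 ordering
   (fat < myocardium < fibrosis < PFA bath). Three classes give total
   fibrosis, four give interstitial fibrosis, and a two-class fit on the
   fat-masked T1 map ("T1-fat map") separates fat from fatty fibrosis.
   Per-slice and volumetric percentages are reported over tissue voxels
   (3-slice average for fibrosis, 5-slice for fat).
4. **Resolution experiment.** Data are block-averaged from 200 µm toward
   the 2 mm scale achievable in vivo and re-quantified; the percentage of
   variation per component shows fibrosis being underestimated and fat
   overestimated as structures fall below the voxel size.
5. **Agreement statistics.** Spearman rank correlation, linear regression,
   Bland-Altman limits (±1.96 SD) and the Hotelling–Steiger test for
   dependent correlations.

See `docs/methods.md` for models, parameter defaults and numerical choices.

## Worked example

```python
from lamap import phantom as ph, pipeline as pl

spec = ph.PhantomSpec(noise_sigma=1/40, seed=1)   # SNR 40 phantom
series = pl.render_sample(spec)                   # T1 + Dixon + MSME stacks
maps = pl.fit_sample_maps(series)                 # T1, decay, fat maps
quant = pl.quantify(series, maps, seed=1)         # GMM clustering + report

for comp in ("total_fibrosis", "interstitial_fibrosis",
             "fatty_fibrosis", "fat"):
    print(f"{comp:22s} recovered {quant.report.volume[comp]:5.2f}%"
          f"  truth {series.truth.loc['volume', comp]:5.2f}%")
```

prints (exactly reproducible for this seed):

```
total_fibrosis         recovered 14.73%  truth 14.00%
interstitial_fibrosis  recovered 10.75%  truth 10.00%
fatty_fibrosis         recovered  4.04%  truth  4.00%
fat                    recovered 15.58%  truth 15.00%
```

i.e. every tissue component of the phantom is recovered to within ~0.8
percentage points. The fitted four-class mixture puts its myocardium
component at 966 ms against a generating T1 of 962 ms, and pure fibrotic
voxels fit at 1139 ± 57 ms against a generating 1131 ms. Degrading the same sample's maps to 2 mm and re-quantifying gives
variation percentages of −32% (total fibrosis), −31% (interstitial), −35%
(fatty) and +81% (fat): sub-voxel fibrotic strands and septa dilute away
while fat lobules bleed outward across the fat-fraction threshold.

The numbered scripts under `analysis/` run the full study — phantom
rendering, map fitting, quantification, the eight-phantom recovery batch,
the resolution experiment in both degradation modes, and the agreement
statistics — writing tables to `results/` and volumes/figures to
`scratch/`.

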