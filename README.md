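# trackdose

CR-39 etch-pit microdosimetry for alpha-particle autoradiography of tissue
sections, aimed at targeted alpha therapy (e.g. ²¹¹At-labelled antibodies in
tumour-bearing tissue). The package takes per-pit geometry measured on a
CR-39 solid-state nuclear track detector and produces per-track LET,
efficiency-corrected fluence spectra, cell-scale (10 μm) absorbed-dose maps,
decay-corrected total doses, and the tumour-to-normal track-density ratio
("concentration efficiency") with Poisson counting errors. A synthetic
tissue-phantom simulator with full ground truth makes the whole chain
testable end to end.

## The physics in brief

Each alpha particle crossing the detector leaves a conical etch pit whose
elliptical aperture (major axis *D_A*, minor axis *D_B*) encodes its LET and
dip angle. With bulk removal thickness *B* (3.3 ± 0.7 μm for a 2 h etch in
7 M NaOH at 70 °C), the detector response is

    S = sqrt(16 B² D_A² / (4B² − D_B²)² + 1) − 1,

the track-to-bulk etch-velocity ratio minus one. A monotone calibration maps
*S* to LET in water over 3.5–600 keV/μm. The response also fixes the critical
dip angle sin θ_c = 1/(S+1); tracks shallower than θ_c are never revealed,
so an isotropic flux is detected with efficiency η = 1 − sin²θ_c and every
observed track is counted with weight 1/η. The fluence φ_i (cm⁻²) per LET
bin gives the absorbed dose

    D [Gy] = (1.6×10⁻⁹ / ρ) Σ_i φ_i L_i ,

with ρ the specific gravity. Because the tissue sits on the detector only
from mount (t₁ = 12 h after injection) to removal (t₂ = 43 h), the observed
dose is scaled by 1 + D₀/D, where

    D₀/D = (1 − e^{−λt₁}) / (e^{−λt₁} − e^{−λt₂}),   λ = ln2 / 7.2 h,

the ratio of decays missed before mounting to decays recorded in the window.
Tissue/tumour/normal regions are segmented from the pre-etch micrograph by
fixed 8-bit thresholds (tissue: gray < 138; eosin-pink tumour: R 123–177,
G 42–84, B 94–139), registered onto the detector frame through an affine
transform fitted to four scratched markers.

## Worked example

Simulate the default desk-scale phantom (2 × 2 mm field, 6:1 tumour/normal
activity contrast, ²¹¹At kinetics) and analyse it:

```bash
$ trackdose simulate --seed 1 --outdir demo
simulated 84510 decays (21400 registered in window) -> demo/pits.csv [1.3 s]
$ trackdose analyze --config demo/run_config.yaml
analyzed 21400 tracks; concentration efficiency 5.95 +/- 0.08; spectrum mode 128.5 keV/um [2.1 s] -> demo/analysis/report.json
```

The report says: of 84 510 simulated decays, 21 400 formed etch pits during
the 12–43 h recording window. The pipeline re-derived their LET from the pit
axes — the efficiency-corrected spectrum peaks in the 123.5–133.5 keV/μm bin
(the simulator's true source peaks at 130) — counted tracks per segmented
region (12 015 in 0.449 mm² of tumour, 9 385 in 2.088 mm² of normal tissue),
and recovered a concentration efficiency of 5.95 ± 0.08 against the
simulated contrast of 6.0. The decay-window factor D₀/D = 2.29 scales each
observed cell dose to the full 0–43 h total (e.g. the observed per-cell dose
range 0.18–2.9 Gy becomes 0.59–9.6 Gy). All intermediates (derived track
table, masks, LET spectrum, 10-μm dose maps, 50-μm density map) are written
next to `report.json`, and every report number is recomputable from them.

The same `analyze` subcommand runs on real data: a pit table CSV
(`x_um, y_um, major_axis_um, minor_axis_um`), an RGB tissue micrograph, a
four-marker registration file, and optionally a measured calibration knot
file in place of the packaged synthetic power-law stand-in
(`S = (L/100)^1.5`).

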