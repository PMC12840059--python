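# panoce

Compression optical coherence elastography (C-OCE) quantification of
pancreatic tissue, from phase-sensitive OCT frame pairs to
stress-standardized Young's-modulus maps, stiffness spectra, four-class
morphological classification, and islet-yield prediction.

## The problem

After total pancreatectomy, islets of Langerhans can be isolated from the
resected pancreas and autotransplanted to prevent brittle diabetes — but
only if the sampled parenchyma actually contains islets and digests well.
Fibrosis and tumour invasion (PDAC) stiffen the tissue and ruin the yield;
islet-poor acinar tissue is soft but equally unproductive. Quantitative
stiffness imaging at histological scale (30–50 µm) can grade a specimen
intraoperatively. `panoce` implements the full quantification chain for a
phase-sensitive compression-OCE system (1.3 µm central wavelength), and a
synthetic phantom generator that stands in for clinical specimens so every
stage is testable end to end.

## The method

1. **Phase-sensitive strain.** For consecutive complex B-scans under
   incremental compression, the interframe phase is
   `φ = 4π·n·u/λ₀` (wrapped); local axial strain ε is the least-squares
   slope of the locally unwrapped phase over a sliding window
   (default 48 µm × 50 µm), computed by vector (complex) averaging —
   never averaging raw angles.
2. **Reference-layer stress calibration.** The specimen is compressed
   through a calibration silicone layer of known stiffness (100 kPa).
   The silicone's strain reports the applied stress σ via its
   stress–strain curve.
3. **Stress standardization.** Because pancreas is nonlinear, the tangent
   modulus `E = Δσ/Δε` is evaluated over the run of increments whose
   cumulative stress lies in a standardized window (2 ± 1 kPa), making
   moduli comparable across samples.
4. **Stiffness spectra.** Normalized histograms of E over an analysis ROI
   (~350 × 3200 µm), with band fractions below 100 kPa (soft acinar
   tissue), 100–250 kPa (mid), and above 250 kPa (islets / tumour-grade
   stiffness).
5. **Classification and yield.** Ordered rules map the band fractions to
   {islet-poor, islet-rich, fibrotic, PDAC}; mean ROI stiffness in
   75–150 kPa predicts a high islet yield (≥ 120 pcs/g), outside that
   range a low yield (≤ 110 pcs/g).

Group statistics (Mann–Whitney U with exact enumeration for small
samples, 1.5×IQR box summaries) mirror the comparisons made between
morphological groups.

## Worked example

```python
from panoce import run_preset, PipelineConfig

r = run_preset("islet_rich", seed=1, config=PipelineConfig())
f = r["features"]
print(f"label            : {r['tissue'].label}")
print(f"p_soft / p_mid / p_stiff : {f.p_soft:.3f} / {f.p_mid:.3f} / {f.p_stiff:.3f}")
print(f"mean / median kPa : {f.mean_kpa:.1f} / {f.median_kpa:.1f}")
print(f"achieved stress   : {r['map'].standardization_stress_kpa:.2f} kPa")
print(f"yield prediction  : {r['yield'].category} (bound {r['yield'].bound_pcs_per_g:.0f} pcs/g)")
```

prints (values from an actual run):

```
label            : islet_rich
p_soft / p_mid / p_stiff : 0.361 / 0.558 / 0.082
mean / median kPa : 133.7 / 112.7
achieved stress   : 2.00 kPa
yield prediction  : high (bound 120 pcs/g)
```

A phantom of islet-rich parenchyma (soft background with ~9 % stiff
disc-shaped inclusions emulating islets) was simulated, reconstructed at
a standardized stress of 2 kPa, and analyzed: 36 % of ROI pixels are
below 100 kPa and 8 % above 250 kPa — the signature of islet-rich
tissue — and the mean stiffness of 134 kPa falls in the 75–150 kPa
optimal isolation range, so the predicted yield category is *high*.

The same flow is available from the shell:

```sh
panoce simulate --preset islet_rich --seed 1 --out stream.h5
panoce reconstruct --in stream.h5 --target-stress 2 --half-window 1 --out map.tif
panoce analyze --in map.tif --out analysis/
panoce run pdac --seed 1 --out out/          # all-in-one
panoce classify --features features.csv --out classified.csv
panoce report --features per_sample.csv --out report/
```

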