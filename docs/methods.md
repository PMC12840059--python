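# Methods

This note documents the models, numerical choices and limitations of
`panoce` at the level of detail a user needs to interpret its output.

## Mechanical and optical model of the simulator

The phantom simulator (`panoce.phantom`) models quasi-static compression
of a layered sample — calibration silicone (default 300 µm, 100 kPa) on
top of tissue — imaged by a phase-sensitive spectral-domain OCT system
with central wavelength λ₀ = 1.3 µm.

**Mechanics.** Each compression step applies a uniform uniaxial stress
increment σ_step to every image column (stress-controlled compression;
columns are independent stacks of springs in series). Per-pixel
incremental strain is ε(z,x) = σ_step / E(z,x) and axial displacement is
the depth integral of strain from the probe surface downward. The
acquisition parameter is the per-step surface displacement `d` averaged
over columns; σ_step = d / mean(C_x) with C_x = Σ_z Δz/E(z,x) the column
compliance, so each column's surface displacement equals the depth
integral of its strain exactly. Lateral mechanical coupling and Poisson
effects are ignored — the simplest model consistent with reference-layer
stress calibration. Real tissue shows stress redistribution around stiff
inclusions that this model does not produce.

**Optics.** Interframe phase at depth z is 4π·n·u(z)/λ₀, wrapped to
(−π, π], with refractive index n = 1.4 (typical soft tissue; the value is
configurable — it is a property of the sample, not the instrument).
Speckle is a complex circular-Gaussian reflectivity held fixed across
frames (fully correlated; no decorrelation with strain). Phase noise is
additive Gaussian per pixel per frame (default sd 0.1 rad), independent
of speckle amplitude. Both are simplifications: real speckle decorrelates
under strain, and real phase noise scales inversely with signal
amplitude. Consequences: (i) passing tests do not demonstrate robustness
to speckle decorrelation; (ii) amplitude-weighted vector averaging of
the complex product — optimal when phase noise ∝ 1/amplitude — is not
variance-optimal under this noise model, which is why the
noise-monotonicity test uses uniform-amplitude frames. The simulator
refuses configurations whose per-step phase gradient would exceed π per
axial pixel (aliasing) or whose per-step strain would exceed 0.1
(linearization limit).

**No wave-optics effects** (confocal gating, sensitivity roll-off,
refraction) and only 2D B-scan geometry.

## Ground-truth stiffness fields

The four presets encode the morphological groups' stiffness signatures
as log-normal background fields (strictly positive, right-skewed) plus,
for islet-rich tissue, stiff disc inclusions:

| preset | background law (solved from) | inclusions | band targets (soft/mid/stiff) |
|---|---|---|---|
| islet_poor | P(E<100)=0.93, P(E>250)=0.002 | — | 0.93 / 0.07 / 0.00 |
| islet_rich | P(E<100)=0.38/0.91, P(E>250)=0.005 | 9 % area, 250–450 kPa, ⌀60–200 µm | 0.38 / 0.53 / 0.09 |
| fibrotic | P(E<100)=0.10, P(E>250)=0.10 | — | 0.10 / 0.80 / 0.10 |
| pdac | P(E>250)=0.97, median 400 kPa | — | 0.00 / 0.03 / 0.97 |

Log-normal parameters are solved from two quantile constraints in closed
form. The published percentages fix only the band fractions, not the
full per-pixel distribution, so these laws are a reverse-engineered
choice; the islet-poor soft-band target is set at 0.93 (slightly above
the printed "90 %") so the defining ≥ 90 %-soft property holds per
realization under ROI sampling variation.

Numerics that matter:

* **Exact marginals.** The background is a white Gaussian field smoothed
  to a 35 µm correlation length (comparable to the 30–50 µm resolution
  cell) and then rank-mapped onto the target log-normal quantiles, so
  every realization's band fractions match the targets to ~1 pixel. This
  is what makes the ±2 pp generator self-check deterministic rather than
  statistical.
* **Inclusions** are non-overlapping ellipses in pixel space (discs in
  physical units), painted until the pixel-counted area fraction reaches
  the target; each disc carries one modulus drawn uniformly from its
  range. Diameters of 60–200 µm span several resolution cells, as
  islets must to be detectable.
* Moduli are clamped to [10, 1000] kPa. The floor keeps the softest
  pixels inside the aliasing limit at the default step stress and
  affects ≈1 % of islet-poor pixels (all of which stay in the soft
  band); the ceiling affects ≈0.01 % of PDAC pixels.
* Default grid: 2 mm depth × 4 mm width at 4 µm × 10 µm pixels
  (500 × 400); 17 frames at 0.25 kPa per step (cumulative 4 kPa).

## Strain estimation

`interframe_phase_difference` computes arg of the window-averaged
complex product b·ā (vector averaging) with a coherence-style quality
map. The default averaging window is 1×1: at the per-step strains used
here (10⁻³–10⁻²) the cumulative interframe phase at depth differs by
more than a radian between adjacent columns of heterogeneous tissue, so
lateral phase averaging decoheres; spatial averaging is applied to
strain instead. Multi-pixel vector averaging remains available (and is
appropriate for smaller step strains or homogeneous samples).

`estimate_axial_strain` fits the quality-weighted least-squares slope of
the locally unwrapped phase versus physical depth. The implementation
expresses the LS slope as a tent-weighted sum of wrapped adjacent-pixel
phase differences — valid because the generator guarantees per-pixel
gradients below π — followed by a lateral quality-weighted boxcar.
Default window 48 µm (axial) × 50 µm (lateral), inside the system's
resolution band; windows below 30 µm (one resolution cell) are rejected.
Estimates are masked where windowed quality falls below 0.3, |ε| ≥ 0.1,
or the window leaves the image.

## Elastogram reconstruction

The silicone/tissue boundary row is located by maximizing the log-ratio
contrast of mean strain in 20-row bands above/below candidate rows
within a configurable search band (100–600 µm). If no candidate reaches
a 10 % strain contrast — homogeneous samples, or tissue with silicone-like
stiffness (the islet-rich preset's background averages ≈100 kPa) — the
nominal layer thickness is used with a warning. On clean two-layer
phantoms the detector is within 2 pixels of truth; on noisy
heterogeneous phantoms it can drift several rows, which downstream
stages tolerate because the analysis ROI starts one processing window
below the boundary.

Cumulative stress after increment k is the silicone stress–strain curve
evaluated at the running sum of masked mean reference-layer strain
(guard bands exclude boundary-blurred rows). The silicone is linear by
default (σ = 100·ε kPa); a nonlinear curve can be supplied since stress
standardization exists precisely because tissue is nonlinear.
Decompression raises an error naming the offending increment.

The tangent modulus is the endpoint difference E = Δσ/Δε across the
contiguous run of increments whose cumulative stresses lie in the
closed window [target − half, target + half] (default [1, 3] kPa);
endpoint differencing avoids the division-by-small-strain instability of
per-increment averaging. Pixels with Δε ≤ 0, poor quality, or E outside
[1, 1000] kPa are masked out, not clamped, so spectra are not distorted
(the ceiling comfortably exceeds the >400 kPa values PDAC reaches). The
achieved standardization stress is recorded as the midpoint of the
stress span of the run; with default steps it lands at ≈1.9–2.0 kPa.
Pixels failing standardization are excluded from all statistics via the
mask (how the published analysis handled them is not stated).

## Spectra, classification, yield

Spectra are normalized histograms over the masked ROI pixels (≥ 100
pixels required), default 25 kPa bins from 0 to 1000 kPa; bin widths
must place 100 and 250 kPa on edges, so band fractions are exact bin
sums at any refinement. Mean and median are computed from the raw
masked pixels, never bin centres. The default ROI is 350 µm × 3200 µm,
laterally centred, starting 48 µm (one axial processing window) below
the detected boundary to skip the boundary transition zone. Stitching
concatenates 2–4 maps laterally, averaging overlap columns where both
maps are valid. Per-patient aggregation is the mean of per-image ROI
means (three images per patient in the acquisition protocol this
mirrors).

Classification applies ordered rules (first match wins):

1. p_stiff > 0.95 → **pdac**
2. p_soft ≥ 0.90 → **islet_poor**
3. 0.02 ≤ p_stiff ≤ 0.20 and p_soft ≥ 0.25 → **islet_rich**
4. otherwise → **fibrotic**

The thresholds operationalize the printed group spectra and are
configurable. Yield: mean ROI stiffness within [75, 150] kPa (inclusive)
→ high (≥ 120 pcs/g), otherwise low (≤ 110 pcs/g). The published lower
cut-off appears once as 75 kPa and once as "<70 kPa"; this package uses
75 kPa (the abstract's value) and exposes the bounds as parameters
rather than silently merging the two. Both per-image and per-patient
mean stiffness can be fed to the rule.

## Statistics

`mann_whitney_u` returns U = min of the two one-sided statistics and a
two-sided p. For pooled sizes ≤ 12 the null distribution is enumerated
exactly (a subset-sum dynamic program over doubled midranks, so ties are
handled exactly); otherwise a tie-corrected normal approximation with
continuity correction is used. Both routes can be forced via `method=`;
note that at n = m = 10 the approximation cannot produce p below
≈1.8×10⁻⁴ even for complete separation, so strong-significance checks
on small groups should request the exact route. Box summaries use
linear-interpolation ("type 7") quartiles and 1.5×IQR whiskers placed at
the most extreme data values inside the fences. Raw p-values are always
reported; a Bonferroni column is optional and off by default (whether
the original analysis corrected for multiplicity is unstated).

## Problem sizes used in tests and the acceptance script

Band-fraction recovery averages 10 phantoms per preset at the full
default grid (500 × 400, 16 increments); end-to-end classification
consistency uses 20 phantoms per preset. These sizes give ≈2 pp standard
error on ROI band fractions, well inside the ±5 pp acceptance margin,
and each full pipeline run takes under a second.

## Known limitations

* The stress field is uniform per column; no load redistribution around
  stiff inclusions, so inclusion-adjacent moduli are more accurate here
  than they would be in reality.
* Partial-volume smoothing by the strain window erodes the stiff-band
  fraction of disc inclusions by roughly a third at default sizes
  (reconstructed islet-rich stiff fraction ≈6–7 % for a 9 % truth); the
  same effect exists in real OCE at matched resolution.
* Speckle does not decorrelate and phase noise is amplitude-independent.
* Boundary detection assumes a strain contrast at the silicone/tissue
  interface; silicone-like tissue falls back to the nominal thickness.
* Classification thresholds are fixed rules, not learned; they inherit
  the ROI's ≈2 pp sampling noise, so samples near a band threshold can
  flip class between acquisitions.
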