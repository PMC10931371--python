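# Methods

## Scope and model

The package quantifies polystyrene nanoparticle uptake two ways: a
fluorescence-based per-cell bead-load statistic, and label-free Raman
unmixing that localizes polystyrene inside cells by its vibrational
fingerprint. Both chains are exercised end-to-end on synthetic scenes with
planted ground truth; no microscope data ships with the package.

## Fluorescence chain

Each field of view is a multi-channel 8-bit confocal z-stack. Analysis runs
on 2-D projections (maximum-intensity by default: beads are sparse bright
puncta and the maximum preserves a punctum regardless of its in-focus
plane; a sum projection is available by flag).

**Nuclei.** DAPI channel → Gaussian blur (σ = 3 px, smoothing nucleus
edges before thresholding) → threshold (Otsu by default; an explicit 8-bit
value reproduces a manually matched capture) → watershed split of touching
nuclei on the distance transform, seeded by local maxima at least one
minimum-nucleus equivalent diameter apart → filter by area in µm²
(≥ 20 µm² for THP-1, ≥ 10 µm² for A549/CaCo-2) and circularity 4πA/P²,
clamped at 1.0 because discrete perimeter estimates can push a disk above
1; the default inclusive 0–1 window is therefore a configurable no-op.
Auto-thresholding requires at least 5 gray levels of post-blur dynamic
range; below that the field is treated as empty rather than letting Otsu
hallucinate foreground from noise.

**Cell area.** Actin (IF555) channel thresholded, closed and hole-filled.
If that mask covers less than 80 % of the nuclei area it is deemed
insufficient and the brightfield fallback is used: 2–98 percentile
contrast stretch → Canny edges (σ = 2 px) → maximum filter (radius 3 px)
→ binary closing and opening (radius 5 px) → hole filling → erosion by
the maximum-filter radius (the maximum filter thickened the edge outward
by exactly that much) → removal of regions smaller than one minimum
nucleus. Fluorescence outside the cell area (residual extracellular beads)
is excluded from counting.

**Beads.** The bead threshold is calibrated as the 99.95th percentile of
within-cell intensity on unexposed control fields, rounded up (floor 1),
and can be overridden. The bead mask is binarized to {0, 255} and counted
through the mean-gray identity `n_pixels × mean / 255`, which equals the
foreground count exactly; dividing by the nuclei count gives bead pixels
per cell. Fields with zero detected nuclei are flagged invalid and
excluded with a warning.

## Raman chain

Spectra are processed per pixel, in order:

1. **Despiking.** Modified z-score of first differences
   (0.6745·(d−med)/MAD), threshold 6; flagged channels are replaced by the
   mean of unflagged channels within ±5 channels. A single-channel cosmic
   spike produces one extreme positive and one extreme negative
   difference, so the spike channel and its successor are both flagged.
2. **SNIP baseline.** Iterative clipping
   v(i) ← min(v(i), (v(i−w)+v(i+w))/2), w = 1…60, in the compressive
   log-log-sqrt (LLS) domain, back-transformed and subtracted. The
   clipping only ever lowers the working sequence, so the corrected signal
   is non-negative up to transform round-off. The LLS domain is not
   homogeneous: recovered peak amplitudes are exact at order-1 intensity
   scales but overshoot by several percent at raw-count scales, and
   preprocessing is consequently only approximately invariant to a
   positive rescaling of the input spectrum (tested at 5 % relative RMS).
3. **Silent region.** Channels strictly inside 1800–2700 cm⁻¹ are
   removed (bound channels retained); the window carries no bands of the
   scene components. A region that does not overlap the axis is a no-op;
   removing every channel is an error.
4. **Mean normalization.** Each retained spectrum is scaled to mean 1
   on the working (cut) axis, removing per-pixel intensity scale before
   unmixing; normalizing on the working axis (rather than before the cut)
   is what makes a repeated pass through the chain almost a no-op. Pixels
   with non-positive mean after baseline removal are degenerate: zeroed,
   flagged, and excluded from endmember search.

**Unmixing.** Pixels from all z-planes are pooled (one endmember set spans
the stack). N-FINDR: project spectra to the (k−1) leading principal
components, start from k random pixels, and repeatedly replace one vertex
by the pixel that most increases the simplex volume, accepting only strict
increases — the volume sequence is strictly increasing, so the search
terminates; the best of `n_restarts` seeded restarts wins, and the
returned endmembers are actual pixel spectra (pure-pixel assumption). The
restart seed is mandatory and echoed in logs. Abundances are per-pixel
non-negative least squares without a sum-to-one constraint (none is
imposed by the physics of uncalibrated intensities); per-pixel residual
norms are kept for QC. Endmember identity is assigned automatically by
cosine similarity against the band-library references (threshold 0.5,
below which an endmember stays "unassigned"); several endmembers may share
a label, as a strongly scattering inclusion can reappear as a second,
more intense endmember of the same material. Univariate band imaging
(default 1000 ± 12.5 cm⁻¹, the polystyrene ring-breathing window) provides
the model-free counterpart.

## Synthetic scenes

**Raman.** Default geometry mirrors a single-cell scan: 25 µm × 25 µm at
0.5 µm step (50 × 50 pixels — area divided by step, not step count + 1),
three z-planes 1.5 µm apart, axis 600–3100 cm⁻¹ every 2 cm⁻¹. The scene
is bulk water with round lipid droplets and polystyrene clusters; regions
mix only over a one-pixel boundary (3 × 3 box average with exact integer
sums), so component interiors stay exactly pure and pure pixels exist for
every component. Band lists: eight polystyrene bands (621, 1001, 1031,
1201, 1450, 1604, 2913, 3057 cm⁻¹), five lipid bands (1302, 1442, 1656,
2882, 2929 cm⁻¹), one broad water band (1644 cm⁻¹, fwhm 200 cm⁻¹).
Relative intensities and widths are model choices (fingerprint 1001 at
1.0, other polystyrene bands 0.25–0.6 at fwhm 12–14 cm⁻¹, pseudo-Voigt);
recovery checks depend only on positions. Component emission scales are
water 1.0, lipid 1.2, polystyrene 1.6 (beads are strong Raman
scatterers). Nuisance terms: a per-pixel degree-3 polynomial baseline
(amplitude 0.3 of the clean peak; degree 0 disables the baseline so the
noiseless limit is exactly the planted mixture), Poisson shot noise scaled
so the sd at the clean-signal peak is peak/SNR (default SNR 20) plus
Gaussian read noise of 1 % of peak, and single-channel positive spikes of
25× the pixel's peak signal on a configurable fraction of pixels
(default 0.5 %).

**Confocal.** Default field 512 × 512 px at 0.684 µm/px (≈ 350 µm field),
z-planes 1 µm apart. Cells are disks (radius 16–22 px) placed with
generous spacing; each carries an elliptical nucleus (45–110 µm²,
rendered at intensity 200, blurred σ 1.5), an actin body with a bright
cortical rim, a textured brightfield appearance and Gaussian bead puncta
(σ ≈ 1 px, amplitude 180) planted uniformly inside the cell body with a
3 px margin so the above-threshold halo stays inside. The expected bead
count is Poisson(bead_rate × concentration × n_cells); the bead rate
(default 0.2 beads per cell per µg/cm²) is a free model parameter, not an
estimate of the real uptake rate, because no bead-density calibration
exists. The ground-truth bead mask is the noise-free maximum projection
of the puncta plus background, thresholded at the default bead threshold.
Optional confounders (never part of the truth): bright sub-threshold
debris specks in the nuclear channel, placed clear of nuclei and of each
other so merged specks cannot exceed the planted area, and extracellular
beads to exercise the cell-mask exclusion rule.

**Dose-response.** Values are intercept + slope·concentration + N(0, σ²),
truncated at zero, at the three study concentrations.

What the generators do **not** emulate: optical point-spread functions
beyond Gaussian puncta, photobleaching, instrument noise spectra, spectral
crosstalk, cell-shape heterogeneity, or out-of-focus haze. Passing
recovery tests therefore demonstrate correctness of the algorithms under
the stated model, not performance on real micrographs.

## Statistics

Two-sided unpaired t-tests (Welch by default — robust to unequal
variances — with Welch–Satterthwaite degrees of freedom; the pooled
variant is available and agrees exactly for balanced equal-variance
groups). Identical degenerate groups return t = 0, p = 1. Dose-response
is unweighted OLS with 95 % slope CIs from the t distribution (n − 2 df)
and mean-response confidence bands, narrowest at the mean concentration.
Raw pairwise p-values are reported, matching common practice for these
small designs; a Holm step-down flag is available. Whether tests run on
field-of-view-level or replicate-level values is left to how records are
grouped before the call.

## Numerical choices and degenerate inputs

- Problem sizes in the validation suite are scaled to the method, not the
  data volume: 100 seeded fields for nuclei-count recovery, 30 fields per
  concentration for dose monotonicity, 20 seeds for noiseless unmixing
  recovery, 10,000 null pairs / 500 regressions for calibration.
- N-FINDR rejects a rank-deficient projection (fewer distinct components
  than k) and k larger than the usable pixel count; k = 1 degenerates to
  the pixel nearest the data mean.
- NNLS abundances of the zero spectrum are zero; linearly dependent
  endmember sets are rejected.
- The bead-threshold calibration floor is 1 (an all-zero control still
  yields a usable threshold).
- Seeds: every generator and every stochastic stage takes an explicit
  seed; identical seed ⇒ identical output, byte for byte.

## Known limitations

- The maximum of the broad water band (fwhm 200 cm⁻¹) cannot be located
  to one or two 2 cm⁻¹ channels from a single unmixed pixel spectrum at
  peak SNR 20: the band's intensity deficit within ±4 cm⁻¹ of center
  (~0.1 % of amplitude) is far below the per-channel noise, so the
  recovered position scatters by a few tens of cm⁻¹ around 1644 cm⁻¹.
  Narrow bands (polystyrene 1001/621, lipid 1656) do not suffer from
  this and are recovered to within one channel.
- Absolute bead-pixel magnitudes depend on the manual/calibrated
  threshold; only relative (dose-response) statements are meaningful.
- Abundance maps are qualitative: uncalibrated intensities do not allow
  particle counting from abundances.
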