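# nanouptake

Quantification of polystyrene (PS) nanoparticle uptake by cultured cells
(THP-1 macrophages, A549, CaCo-2) from two complementary imaging modalities:

1. **Confocal fluorescence** — a semi-quantitative pipeline that reduces a
   multi-channel z-stack (green bead fluorescence, DAPI nuclei, phalloidin
   actin, brightfield) to a single per-field statistic, *bead pixels per
   cell*:

   N_bead = (n_pixels × mean gray value of the binary bead mask) / 255

   bead pixels per cell = N_bead / n_nuclei

   Sub-resolution beads cannot be counted individually, so the area of
   above-threshold bead fluorescence inside the segmented cell area stands
   in for particle load. Dose-response across exposure concentrations
   (7.81, 15.63, 31.25 µg/cm²) is analyzed with two-sided unpaired t-tests
   and OLS regression with 95% confidence intervals.

2. **Label-free Raman hyperspectral imaging** — per-pixel spectra over
   600–3100 cm⁻¹ are despiked (modified z-score of first differences),
   baseline-corrected (SNIP in the log-log-sqrt domain), stripped of the
   biologically silent 1800–2700 cm⁻¹ region, mean-normalized, and unmixed
   under the linear mixing model: N-FINDR extracts the pixel spectra
   spanning the maximum-volume simplex (pure-pixel assumption) and
   non-negative least squares maps their abundances. Intracellular
   polystyrene is identified by its vibrational fingerprint (aromatic ring
   breathing at 1001 cm⁻¹, ring deformation at 621 cm⁻¹, …), lipid droplets
   by the C=C stretch at 1656 cm⁻¹, bulk water by the broad H-O-H bending
   hump near 1644 cm⁻¹.

A synthetic-data module generates both kinds of scene with known ground
truth (planted nuclei, bead masks, component layouts and endmember
spectra), so every stage is testable without microscope data.

## Worked example

```python
import nanouptake as nu

# --- fluorescence: one synthetic field of view at 15.63 µg/cm²
fx = nu.make_confocal_fixture(n_cells=20, concentration=15.63, seed=3)
rec = nu.quantify_fov(fx.stack, cell_line="THP-1",
                      concentration=15.63, bead_threshold=50)
print(rec.n_nuclei, rec.bead_pixels, round(rec.bead_px_per_cell, 2))
# 20 558 27.9

# --- Raman: unmix a noisy synthetic cell scan (50×50 px, 3 z-planes)
cube_fx = nu.make_raman_fixture(seed=1)
pre, degenerate = nu.preprocess(cube_fx.cube)
ems = nu.nfindr_extract(pre, k=3, n_restarts=5, seed=1,
                        degenerate_mask=degenerate)
ems = nu.classify_endmembers(ems)
print(ems.labels)
# ['lipid', 'polystyrene', 'water']
```

The fluorescence record says: 558 pixels of above-threshold bead signal
were found inside the cell area of a field containing 20 nuclei, i.e.
27.9 bead pixels per cell. The Raman run shows that the three extracted
endmembers are automatically recognized as lipid, polystyrene and water by
cosine similarity against the band library.

The scikit-learn-style estimators (`nu.RamanPreprocessor`, `nu.NFINDR`,
`nu.DoseResponseLinear`) expose the same functionality for matrix inputs
and compose with sklearn pipelines; a `nanouptake` console script provides
`synth-fluor`, `synth-raman`, `fluor-quantify`, `raman-unmix` and `report`
subcommands over TIFF/CSV/HDF5 containers.

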