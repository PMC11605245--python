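# qdf — quadrant darkfield imaging of intracellular puncta

Label-free darkfield microscopy resolves both wavelength-scale intracellular
puncta (melanosomes, lysosome-related organelles, other granular content) and
much larger refracting structures — but the bright signal that cell edges
refract into the objective routinely obscures the puncta. **Quadrant darkfield
(QDF)** removes the edge signal optically rather than digitally: the darkfield
LED annulus is split into four quadrants (top-left, top-right, bottom-left,
bottom-right), one image is captured per quadrant, and the four images are
combined pixel-wise:

```
DF  = TL + TR + BL + BR            (conventional darkfield)
E   = |TL − BR| + |BL − TR|        (edge image)
QDF = c·DF − E
```

Large features refract light directionally (Snell's law), so an edge appears
only under the illumination quadrant opposing its outward normal and survives
in the diagonal differences `E`. Sub-wavelength puncta scatter into a broad
Mie cone, appear nearly equally in all four images, cancel in `E`, and survive
in QDF. The scaling factor `c` (system-specific, typically 0.8–1.0) matches
darkfield edge intensity to `E` before subtraction; here it is calibrated by
least squares on bright edge pixels.

The package is aimed at quantitative live-cell imaging groups who want to
analyse quadrant-darkfield acquisitions — or evaluate the method — without a
microscope in the loop. It provides:

- `qdf.phantom` — a parametric forward model (beads, cells, flat→round shape
  series, cell populations) with pixel-exact ground truth;
- `qdf.preprocess` — bit rescaling, empty-reference subtraction, masked
  order-8 polynomial background removal;
- `qdf.core` — DF/E/QDF reconstruction and `c` calibration;
- `qdf.cells` — watershed segmentation of quantitative-phase images, Crocker–
  Grier-style tracking, dry mass via the specific refractive increment
  (1.8×10⁻⁴ m³/kg), per-cell DF/QDF totals, debris filtering, puncta SNR;
- `qdf.baselines` — the Sobel/Canny digital edge-detection comparison;
- `qdf.stats` — regression with an F-test against a flat line, binned means,
  histogram Kullback–Leibler divergence, two-sample t-test;
- `qdf.pipeline` + a `qdf` command line — end-to-end orchestration.

## Worked example

Simulate a cell rounding up (conserved puncta content), run the analysis, and
compare how darkfield and QDF totals respond to the shape change:

```python
from qdf.phantom import shape_change_base_scene, make_shape_sequence
from qdf.pipeline import analyze_scene

base = shape_change_base_scene(seed=2)
seq = make_shape_sequence(base, n_frames=5, shape_range=(0.1, 0.9), seed=10)
c, df_tot, qdf_tot = None, [], []
for frame in seq.frames:
    res = analyze_scene(frame, background_order=2, c=c)
    c = res["c"]
    df_tot.append(float(res["table"]["total_df"].iloc[0]))
    qdf_tot.append(float(res["table"]["total_qdf"].iloc[0]))
print(f"c = {c:.3f}")
print(f"DF change  {100*(df_tot[-1]-df_tot[0])/df_tot[0]:+.1f}%")
print(f"QDF change {100*(qdf_tot[-1]-qdf_tot[0])/qdf_tot[0]:+.1f}%")
```

Output:

```
c = 0.902
DF change  +42.8%
QDF change +0.9%
```

The darkfield total rises by ~43% purely because the rounded edge acts as a
stronger lens, while the QDF total — tracking the conserved puncta content —
moves by under 1%. The calibrated `c` of 0.90 reflects the scene's residual
symmetric edge diffraction.

The same flow runs from the shell on simulated or real data:

```
qdf simulate --name shape_change --seed 2 --out data/
qdf run --config run.json        # input_dir/output_dir + parameters
qdf stats --cells out/cells.csv --x mass_per_area_pg_per_um2 --y qdf_per_mass
```

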