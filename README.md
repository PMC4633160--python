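# colonyscreen

Analysis and simulation pipeline for **FACS matrix-deposited colony plates** —
a high-throughput protein-library screening format in which a flow sorter
prints single bacterial cells onto dark charcoal agar at fixed lattice
positions (~500 µm pitch, up to ~195 colonies/cm²). After overnight growth,
every colony is imaged through a set of optical bandpass filters, and the
per-band intensities form a normalised multi-point emission spectrum that
lets rare spectrally shifted clones (e.g. a red-shifted firefly luciferase at
0.5% of the population) be called and located on a pick map.

The package is for people building or evaluating such screening platforms:
it contains the full computational side of the screen, plus a calibrated
synthetic-plate generator so every stage is testable without instrument data.

## What it does

* **`plate_layout`** — deposition-matrix geometry: `make_layout(n, 1.5)`
  factors a point count into the grid whose column:row ratio best matches
  the 1:1.5 plate aspect (384 → 16×24, 3 750 → 50×75, 25 350 → 130×195),
  block sub-formatting, densities, viability bookkeeping.
* **`synth_plate`** — ground-truth plate sampler (94% occupancy, doublet
  rate, variant mix, log-normal brightness with mean 0.14 / SD 0.03) and a
  renderer producing one 16-bit image per filter band with PSF, shot and
  read noise.
* **`colony_quant`** — Otsu segmentation on the max-projection,
  aperture photometry with local-median background, and lattice fitting /
  node snapping with merge- and conflict-flagging.
* **`spectral_screen`** — bandpass integrals of parametric emission models,
  max-normalised 6-point spectra, nearest-reference variant calling
  (x5_FLuc, peak ~550 nm vs x5_FLuc_red, peak ~615 nm), hit lists and pick
  maps.
* **`coincidence`** — two-colour (eGFP/mCherry) singlet-purity analysis
  with exact binomial CIs and the correction for optically invisible
  same-colour doublets.
* **`deposition_sched`** — stop/translation scheduling and the linear
  timing model for conventional single-stream printing versus the
  sort-stream multiplexer, including its attenuation-factor geometry.

The spectral model at the core: a colony of variant $v$ with brightness $B$
contributes band intensity $I_b = B \int_{\lambda_b^-}^{\lambda_b^+}
S_v(\lambda)\,d\lambda$, where $S_v$ is the unit-area emission spectrum;
the normalised spectrum $\hat I_b = I_b / \max_b I_b$ is brightness-free,
and a colony is called as the variant whose reference vector minimises
$\lVert \hat I - \hat R_v \rVert_2$, with a confidence margin over the
runner-up. Singlet purity from a 1:1 two-colour print uses
$\hat\delta_{\text{total}} = \hat\delta_{\text{2-colour}} / (2m(1-m))$.
Plate print time is $T = N_{\text{stops}} \cdot t_{\text{stop}} +
N_{\text{particles}} \cdot t_{\text{drop}}$ with
$N_{\text{stops}} = R\,\lceil C/n_{\text{streams}} \rceil$.

## Worked example

Simulate a 3 750-point plate (50×75) with a 0.5% x5_FLuc_red spike, quantify
it, and screen for the spiked clones:

```python
import colonyscreen as cs

layout = cs.make_layout(3750, 1.5)                 # 50 rows x 75 cols
gt = cs.sample_ground_truth(layout, seed=1)        # defaults: 94%, 0.5% spike
rendered = cs.render_plate(gt, seed=1)             # six bands, noise on
records, unocc, tr, qc = cs.quantify_plate(rendered.images, layout, pixel_um=25.0)
result = cs.call_plate(records, layout=layout)
print("occupied:", gt.occupied_count)
print("qc:", qc)
print("majority:", result.majority_variant, "| hits:", len(result.hits))
print(result.hits.head(2).to_string())
```

prints

```
occupied: 3511
qc: {'n_detected': 3511, 'n_assigned': 3511, 'n_flagged': 0, 'n_unoccupied': 239,
     'n_positions': 3750, 'viability_estimate': 0.9362666666666667,
     'median_residual_px': 0.09903913915229216}
majority: x5_FLuc | hits: 14
  block  row  col      variant  distance  red_ratio
0  None    6   66  x5_FLuc_red  0.036611   2.018959
1  None    7   13  x5_FLuc_red  0.021714   2.040932
```

All 3 511 colonies that grew are detected and snapped to their lattice nodes
(residual ~0.1 px), and the 14 red-shifted singles present in the ground
truth are exactly the 14 hits: their `red_ratio` (590–640 nm over
550–600 nm intensity) is ~2, versus ~0.2 for the x5_FLuc majority.

The same run is available from the shell
(`colonyscreen run-all --seed 1 --out run/`), and the scheduler report for
the 4 050-point multiplexer comparison is:

```sh
$ colonyscreen schedule --rows 50 --cols 81 --streams 9 --t-stop 0.3859
{
  "n_points": 4050,
  "n_streams": 9,
  "stops": 450,
  "x_translations_per_row": 9,
  "y_translations": 50,
  "predicted_time_s": 173.7,
  "rate_per_s": 23.32,
  "improvement_pct_vs_1_stream": 88.9
}
```

i.e. with the per-stop dead time calibrated from the conventional run
(1563 s / 4050 stops ≈ 0.386 s), the 9-stream multiplexer is predicted to
finish the plate in ~174 s — an ~89% throughput gain.

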