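# Methods

## The screening platform being modelled

A fluorescence-activated cell sorter deposits single bacterial cells onto
solid charcoal-agar medium at defined lattice positions ("matrix
deposition"). Plates follow a 1:1.5 row:column aspect at ~500 µm pitch;
large matrices are sub-formatted into blocks so hits can be retrieved by
(block, row, col). Deposition viability is ~94%, so a 3 750-point matrix
grows ~3 525 colonies. After induction, colonies expressing firefly
luciferase are imaged through six optical bandpass filters spanning
510–750 nm; the per-colony band intensities form a 6-point emission spectrum
used to call spectral variants — in the flagship scenario, a red-shifted
luciferase (peak ~615 nm vs ~550 nm) spiked in at 0.5%.

This package implements the computational pipeline of that platform:
simulation, quantification, spectral screening, two-colour coincidence
analysis, and deposition scheduling. Wet-lab steps (vector construction,
sorter gating, substrate kinetics) and instrument electronics are out of
scope; only their measurable consequences (viability, doublet rate, stream
count, dead time) enter as parameters.

## Synthetic plates

There is no public deposited-plate image data for this platform, so the
simulator is the test bed for everything downstream.

**Ground truth.** Each node is independently empty with probability
`1 − viability` (default 0.94); occupied nodes are doublets with probability
`doublet_rate` (default 0.004, consistent with a sub-0.4% coincidence
level). Cell variants are i.i.d. draws from `variant_mix` (default: 0.5%
x5_FLuc_red in x5_FLuc). Brightness is log-normal parameterised by mean and
CV, defaulting to mean 0.14 and SD 0.03 (CV ≈ 0.214) — the calibration of a
~10⁴-colony clonal plate in arbitrary imager units (only relative statistics
are meaningful; the simulator makes no radiometric claim). All draws come
from one seeded generator in a fixed order (occupancy, doublet flags,
variants, brightnesses), so plates are bit-reproducible from the seed.

**Colony size.** Colony radius follows `r = r_ref (d_ref/d)^α` in matrix
density `d` (defaults `r_ref` = 5 px at `d_ref` = 400 cm⁻², α = 1/3): a
gentle monotone shrink with crowding. Only the monotone trend is asserted
anywhere — the true area–density curve of the platform is not tabulated, so
no quantitative fit is attempted.

**Emission spectra.** Variant emission is a Gaussian in wavelength,
unit-normalised over 400–800 nm, peaks 550 nm (x5_FLuc) and 615 nm
(x5_FLuc_red), common FWHM 70 nm. Firefly luciferase emission is a broad
unimodal peak, and the classification contract depends only on peak
position, not exact line shape; the FWHM is configurable. The band fraction
is a trapezoidal integral at ≤ 0.5 nm steps (error ~10⁻⁵).

**Rendering.** Each colony stamps a soft-edged disc whose pixel weights are
normalised to unit mass, so the pre-noise, pre-blur summed signal in band
`b` equals exactly `Σ_cells brightness × gain × band_fraction` — signal
conservation is by construction, and tests hold it to ≤ 0.5% through
rasterisation. The stack is then Gaussian-PSF-blurred (σ = 1 px default),
offset by a flat background (100 counts), Poisson shot noise and Gaussian
read noise (SD 2) applied, and clipped to the 8/16-bit range; per-colony
saturation is recorded in the truth table. The default `gain`
(2×10⁵ counts per brightness unit) puts a median colony at ~160 counts/px
above background — integrated per-band SNR well above 10 — representative
of an image-intensified camera run at reasonable exposure.

**What the simulator does not emulate.** Illumination gradients, vignetting,
non-circular colony morphology, satellite colonies, agar texture, substrate
(D-luciferin) kinetics and the post-spray stabilisation transient, and
spatial correlation of brightness. Passing tests therefore demonstrate the
pipeline's correctness under controlled geometry and noise, not robustness
to every artefact of real plates; the quantification defaults (local-median
background, relative threshold) are chosen to degrade gracefully on such
artefacts but are untested against them.

## Quantification

**Segmentation.** Otsu threshold on the max-projection across bands
(relative: invariant to global linear rescaling), with a robust noise floor
of median + 5·(1.4826·MAD) so an empty, noise-only plate yields zero
components rather than a bisected noise field. Connected components below
`min_area_px` (default 5) are dropped. An absolute numeric threshold may be
supplied instead.

**Photometry.** Integrated intensity per band is the pixel sum over the
label *expanded by 2 px* (`expand_labels`; expansion never crosses into a
neighbour) minus aperture-area × background. The expansion matters: the
threshold mask clips the soft disc edge and PSF tail, which otherwise costs
a few percent of flux and breaks 1%-level photometry. Reported `area_px`
remains the thresholded component size (the biologically meaningful colony
area). Background defaults to the median of a 3-px annulus outside the
aperture (robust to plate-level gradients); a global unlabelled-pixel median
is the alternative. Band-identical apertures mean any residual aperture loss
cancels in the normalised spectrum.

**Grid assignment.** A per-axis scale + translation from lattice µm to
image px is fitted by iterated nearest-node least squares (4 rounds),
initialised at the nominal pixel scale. The fitted scale is clipped to ±10%
of nominal — the pixel scale is known hardware geometry, and the bound
prevents a degenerate fit from collapsing the lattice onto a structureless
centroid cloud. Colonies snap to their nearest node within pitch/2; when two
colonies contend for one node the nearer wins and the loser is flagged
`conflict`; components whose bounding-box long side exceeds 1.2× the pitch
are flagged `merged`. The fit is rejected (error) when the median
nearest-node residual over all in-range colonies — conflict losers included,
so near-misses cannot masquerade as fits — exceeds pitch/4. Rotation is not
fitted: the imaged plate is mechanically registered; small rotations within
the snap radius are absorbed, larger ones fail the residual check loudly.

## Spectral screening

Spectra are normalised by their maximum (not their sum): the peak band then
reads 1.0 and peak *position* becomes the dominant feature. Reference
vectors are computed from the emission models, not learned — no training
data exists, and a model-derived reference keeps the caller deterministic.
Classification is nearest reference in Euclidean distance; a call is
`confident` when the distance is ≤ 0.35 *and* the runner-up is ≥ 1.2× as
far. The distance cap rejects junk spectra (the two references are ~1.3
apart, and band-level noise at SNR ≥ 10 perturbs a normalised spectrum by
≲ 0.05); the margin rejects genuinely ambiguous spectra such as the
midpoint of the two references (e.g. balanced mixed doublets). `red_ratio`
(590–640 over 550–600 intensity, ~0.2 for x5_FLuc vs ~2 for x5_FLuc_red) is
carried on every call as a scalar, threshold-free shift index. Hits are
confident calls to any non-majority variant; merged/conflicted colonies are
excluded from calling, mirroring the treatment of coincident depositions as
unidentifiable. Four of the six filter bands are not fixed by the screening
protocol; the default set (510–560, 550–600, 590–640, 630–680, 670–720,
700–750 nm) tiles the stated 510–750 nm range with 50 nm windows and
contains both protocol-named bands verbatim.

## Two-colour coincidence

With channel calls in hand (double iff both channels exceed their cuts),
singlet purity is `100 (1 − n_double/n)` with an exact Clopper–Pearson 95%
CI. The total doublet rate is estimated as
`observed_two_colour_rate / (2 m (1 − m))` for mix fraction `m`, correcting
for same-colour doublets that no imager can see; at a 1:1 mix the correction
is exactly ×2 (0.2% observed → 0.4% total), and since `2m(1−m) ≤ 1/2` the
corrected estimate always bounds the observed rate from above.

Default channel thresholds are noise-referenced Otsu cuts: Otsu first
separates the off/on populations, then the threshold is set at the
off-population mean + 6 SD. A raw Otsu cut sits roughly midway to the
on-population mean, i.e. inside the dim tail of the log-normal colony
brightnesses, and silently discards real colonies (biasing purity
downward); referencing the cut to the measured off-channel noise keeps
every genuine colony countable while leaving a false double ~5σ improbable.
Below-threshold colonies are excluded from the purity denominator and
reported separately.

The purity calibration uses a statistical simulation (ground-truth draw +
ideal photometry per channel, Gaussian noise SD 0.005) rather than full
image rendering: the statistic under test is a counting property, and the
imaging path is already covered by the spectral-screen tests.

## Deposition scheduling

One burst of `n_streams` droplets is deposited per stop, so a row of `C`
columns needs `ceil(C/n_streams)` stops and a plate `R·ceil(C/n_streams)`;
rows are visited serpentine-fashion. The published translation counts ("50
y-axis and 81 x-axis translations") are read as 81 x-stops per row over 50
rows: 1563 s over 4 050 stops gives a consistent ~0.39 s per stop, whereas
reading them as 131 total translations is irreconcilable with the measured
time. `t_drop` defaults to 0 — in-burst deposition runs at the sort rate,
negligible against electromechanical dead time, which the platform
identifies as the rate limit. Calibrating `t_stop = 1563/4050 s` predicts
the 9-stream plate at 450 × 0.386 ≈ 173.7 s versus the measured 169 s
(within 3%); whether the measured time excludes some per-burst settling is
not resolvable, so both numbers are surfaced rather than reconciled.
Attenuation factors for the multiplexer use a linear charge→deflection
model, `(full − i·pitch)/full` for stream `i`; a geometry whose last factor
would reach zero is rejected as infeasible. Real electrostatics (charge
decay, stream fanning) are out of scope.

## Problem sizes and numerical choices

The behavioural checks run at the platform's own scales where that is cheap
(50×75 plates for spike-in recovery over 10 seeds; ~12 700 colonies × 20
seeds for purity; 50 seeds for estimator bias) and at reduced scale where
only a structural property is asserted (8×12 plates for conservation and
round-trip identities) — sizes chosen so the full suite completes in about
a minute while keeping every statistical band meaningful. Ties in
`make_layout` factorisation are resolved by exact rational arithmetic
(`Fraction`), not floating-point log distances — the 4 050-point format is
a genuine tie between 50×81 and 54×75 that the documented more-columns rule
breaks toward 50×81. Degenerate inputs error loudly rather than guess:
all-zero spectra, infeasible stream geometry, unresolvable pixel scales,
sub-4-colony grid fits.

## Known limitations

* The caller's distance/margin rule is this package's explicit
  formalisation of "any colony with a spectral shift was identified"; no
  published threshold exists to compare against.
* Merged-colony handling flags and excludes; no declumping/watershed split
  is attempted at matrix densities where merging is rare by design.
* The area–density and intensity–density curves are enforced only as
  monotone trends.
* Manual picking error rates involve a human operator and are not modelled.
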