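# Methods

This note documents the models implemented in `halofoci`, the default
parameters and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## Imaging model and modalities

Two acquisition modes are modelled as `ImagingConfig` presets:

| parameter | wide-field | SIM | unit | rationale |
|---|---|---|---|---|
| lateral PSF FWHM | 260 | 100 | nm | diffraction-limited vs structured-illumination resolution |
| pixel size | 160 | 40 | nm | wide-field: Nyquist for a 260 nm PSF (< FWHM/1.6); SIM: the 2× oversampled grid that SI reconstruction outputs (raw SI frames are acquired at 80 nm) |
| z-step × slices | 250 × 30 | 125 × 9 | nm | the acquisition geometries of the modelled experiments |
| photon scale | 2.0 | 0.2 | photons/A.U. | see "camera model" below |
| read noise | 3 | 15 | A.U. | same |

The SIM pixel size deserves a note: quantification of SI data runs on
*reconstructed* images, which standard reconstruction software writes on a
grid twice as fine as the raw 80 nm acquisition.  An 80 nm grid cannot even
represent two maxima 150 nm apart under 8-connected peak detection
(separation < 2 px), whereas reconstructed SIM data resolves such pairs;
the simulator therefore renders SIM images directly at 40 nm.  The PSF is
an isotropic Gaussian laterally, with axial FWHM fixed at twice the lateral
FWHM — adequate because all quantification here operates on 2D projections
or single planes.

**Camera model.**  Rendered intensity is camera A.U.; shot noise is Poisson
on `photon_scale × signal`, plus Gaussian read noise, quantized to integer
A.U. and clipped to the 16-bit range.  The two gains are set 10× apart
(0.5 vs 5 A.U./photon), matching the ~10× ratio between the standard
noise-tolerance settings for the two modalities (35 vs 400).  Both gains
put the default tolerance ≥ 5σ above in-cell noise.  This is deliberate: a
"find maxima" noise tolerance is useful precisely when it does not fire on
noise, so the camera model is calibrated to the regime in which such a
tolerance is chosen in practice.

## Synthetic cells and foci

Cells are non-overlapping ellipses (semi-major axis 1.25–2.25 µm, aspect
ratio 1.2–2.5, uniform priors) — the simplest segmentable approximation to
pleomorphic haloarchaeal cells; no published shape or intensity statistics
exist for the modelled experiments, so all priors are explicit and
configurable rather than claimed faithful.  Placement is rejection
sampling on bounding circles with a 0.5 µm margin; an overcrowded request
fails with the limiting parameters named.

Per-cell focus counts are i.i.d. Poisson(λ) — the structure the counting
analysis assumes — and are drawn *before* placement and never altered by
it.  Focus positions are uniform in the 0.8-inset ellipse with z within
one z-step of mid-stack, subject to a hard-core minimum separation of
500 nm (configurable).  The hard core encodes that the analysis treats
foci as discrete, individually resolvable replication factories; with a
few foci in a ~5 µm² cell the typical nearest-neighbour distance is of
this order, and a workflow that counts foci by wide-field microscopy at
~260 nm resolution presupposes separations at or above it.  Without the
hard core, ~10% of uniformly placed pairs fall below the resolution limit
and are physically uncountable in the projection — a regime the
two-point-resolution experiment probes explicitly instead.  If a crowded
cell cannot host its drawn count at 500 nm, the separation is relaxed for
that cell (logged), never the count.

True focus diameters are uniform on 50–300 nm.  A rendered spot is the
object ⊗ PSF in the Gaussian approximation: lateral σ =
√(σ²_PSF + σ²_object) with σ = FWHM/2.355, and the same broadening
axially.  Peak amplitude is normalized so the flux integrated over the
stack equals the focus's `amplitude` regardless of modality.  The default
flux makes the *largest* (dimmest-peaked, 300 nm) foci stand 2.5 noise
tolerances above the cytoplasm — about peak SNR 10 in both modalities —
so every focus in the prior is detectable with margin while the image
histogram stays dominated by cells rather than foci.

The diffuse cytoplasmic GFP pool defaults to 60 photons/pixel, dim enough
that its within-cell contrast (interior minus the segmentation threshold)
stays below the noise tolerance: in the emulated workflow the published
tolerances evidently did not report the cytoplasm maximum of focus-free
cells, so the simulator reproduces that operating point.

**Hoechst channel.**  Non-compacted cells spread their total DNA intensity
uniformly over the cell; compacted cells concentrate the *same* total into
a concentric ellipse of `compaction_fraction` × cell area (axes scaled by
√fraction).  The fill is exactly uniform (no PSF smoothing) so per-cell
integrated intensity is conserved *exactly* between diffuse and compacted
noiseless renders — the invariant that licenses reading a higher maximum
at equal mean as compaction rather than a DNA-content change.
`compaction_fraction = 1` reproduces the diffuse render bit-for-bit; 0 is
rejected as a degenerate point mass.

**FRAP traces.**  101 frames at 500 ms including 10 pre-bleach frames
(50 s total).  The bleach is an instantaneous drop; recovery is imposed as
the target A − B·exp(−k·t) — the simulator exercises the *fitting*
procedure, not reaction–diffusion physics.  The whole-cell reference
decays exponentially (acquisition photobleaching, default 0.002 s⁻¹) over
a constant camera background, so three-ROI normalization recovers the
target exactly in the noiseless case.  Default kinetics are control-like:
plateau 0.95, amplitude 0.75, τ½ = 8.4 s.

## Segmentation

Cells are segmented on the maximum-intensity z-projection: Otsu's
threshold (between-class variance maximization) times a recorded
`adjust_factor` — the reproducible stand-in for "adjusting the threshold
manually" — then 8-connected components, border-touching components
removed first, then components under 40 px.  Otsu is computed exactly over
native integer levels (256 equal bins for float input), ties broken toward
the lower level; `adjust_factor = 1` is plain Otsu.

An optional `clip_percentile` (the pipeline default is 99) caps
intensities before histogramming.  Otsu assumes a bimodal
background/cell histogram; a fraction of a percent of very bright focus
pixels can otherwise dominate the between-class variance and pull the
threshold above the cytoplasm — the failure mode that forces manual
adjustment in interactive use.  Clipping the top percentile restores the
bimodal regime without moving either mode; the pure unclipped operation
remains available and is what the oracle-equivalence test checks.

Conventions: 0-based (row, col) indices, pixel-center coordinates, areas
in the half-open pixel model, `area_um2 = area_px × (pixel_size/1000)²`.
Touching cells are not split (the generator avoids overlaps; no watershed
is described for the emulated workflow).  Empty segmentation results are
logged, not raised.

## Focus detection ("find maxima")

The detector reports a regional-maximum plateau of value *v* iff flooding
from it over pixels strictly greater than *v − h* (8-connected, restricted
to the mask) reaches neither a strictly higher pixel nor the entire mask
component — equivalently, its topological persistence (dynamics) is ≥ *h*,
with the component maximum's persistence defined as *v* − component
minimum (hence a constant image has no maxima).  Equal-valued accepted
plateaus whose floods connect merge into one report.  The reported
position is the plateau pixel nearest the plateau centroid, ties broken by
smallest (row, col); reported peaks therefore always lie inside the mask.

The implementation uses grayscale morphological reconstruction
(`rec = reconstruction(image − h, image)`; a candidate survives iff `rec`
equals `image − h` on its plateau), which is exactly the flood criterion
but runs in C.  A pure-Python per-candidate BFS oracle freezes these
semantics in the test suite; the two agree on hundreds of randomized
masked images, and the accepted count is non-increasing in *h*.

Edge semantics worth noting: at *h* = 0 the flood set excludes the plateau
itself, so equal maxima never merge and every regional maximum is
reported; suppression chains propagate because a flood passes through
suppressed territory to higher ground.

## Morphometry

Focus area is the 8-connected component, containing the peak, of pixels ≥
background + (peak − background)/2; the local background is the median
in-cell intensity excluding all focus contours (one refinement pass).
If a contour contains another detected peak the component is split by the
midline (each pixel to its nearest contained peak, tie-break by sorted
peak order so the split is query-independent) and flagged.  Diameter is
D = 2√(A/π), reported in nm.  Both the mean of diameters and the diameter
of the mean area are reported; they differ under size heterogeneity and
are never equated.  On wide-field data areas are PSF-limited and biased;
the pipeline measures areas by default only in SIM mode.

## Count statistics

Three estimators of the Poisson mean: `mle_full` (sample mean, the
analytic MLE), `histogram_ls` (least squares between empirical relative
frequencies and the pmf over a support, default 1–9, unweighted), and
`mle_truncated` (zero-truncated MLE via root-finding of
λ/(1 − e^−λ) = mean of positive counts).  The default pipeline reports
the truncated fit over support 1–9 alongside the full MLE, because the
zero class is assessed separately: an exact one-sided binomial test of the
observed zero count against n·e^−λ̂.  Standard errors are seeded
500-replicate nonparametric bootstraps — distribution-free, and agreeing
with √(λ/n) within 15% on Poisson data.

Group comparisons use Welch's unequal-variance t-test
(Welch–Satterthwaite df) with the conventional star levels
0.05/0.01/0.001/0.0001 and no multiplicity correction (raw p-values are
reported, as is standard for these comparisons).  Diameter summaries give
mean, SD, a t-based 95% CI (mean ± t₀.₉₇₅,ₙ₋₁·SD/√n) and the empirical
CDF; a single observation yields a degenerate CI at the value.

Goodness of fit uses a chi-square test with Poisson-unimodal bin folding
(both tails merged inward until every expected count ≥ 5) and one df
charged for an estimated mean.

## Compaction metrics

For each cell the optical slice carrying the most GFP foci is selected
(ties toward mid-stack, then the lower index; all-zero cells fall back to
mid-stack with a warning), and per-cell mean and maximum Hoechst
intensities are measured over the GFP-derived cell mask (registration is
assumed perfect, matching sequential same-stage acquisition).  Cells are
stratified by GFP focus count 1–4; Welch tests compare arms per stratum
and pooled, skipping strata with fewer than 2 cells per arm.  Visual
co-localization is replaced by a defined proxy: the distance from each GFP
peak to the nearest Hoechst local maximum.

## FRAP analysis

Normalization is I_n = (I − I_b)/(I_sb − I_b), then rescaling so the
pre-bleach mean equals 1, making A and B interpretable as fractions of the
pre-bleach signal.  Subtracting the background from the reference is the
default because the raw I_sb denominator biases the plateau low by the
camera offset; the literal (I − I_b)/I_sb form is available via a flag for
strict replication.  The fit is bounded nonlinear least squares of
A − B·exp(−k·t) on post-bleach frames (t re-zeroed at the first
post-bleach frame; ≥ 10 post-bleach frames required), initialized at
A₀ = mean of the last 5 frames, B₀ = A₀ − first post-bleach value,
k₀ = 1/(0.3 × span), with B ≥ 0, k > 0; up to three seeded jittered
restarts, after which a non-converged fit is returned with diagnostics.

Derived quantities follow the conventional symbol usage: τ½ = ln 2/k
(τ½·k = ln 2 holds identically), mobile fraction = B, immobile
fraction = 1 − A.  These need not sum to 1; the bleach-depth-normalized
alternative B/(1 − (A − B)) is reported alongside, clearly labelled.
The lowercase a, b sometimes seen in the fraction formulas are taken to
denote the same fitted A, B.

## Pipeline and reproducibility

A `RunConfig` serializes every result-affecting parameter; runs write CSV/
JSON outputs plus a manifest (config, config hash, seed, package and
dependency versions).  Per-stage randomness derives from the single global
seed via a SHA-256 counter scheme (`stage_seed`), so stages can be rerun
independently yet reproducibly; reruns of the same config are
bit-identical.  Intensities stay in A.U. throughout; px ↔ nm/µm
conversions happen only where geometry requires them.

## Validation experiment sizes

The canned experiments in `halofoci.experiments` use study-scale but
desk-sized problems: 400 cells across four 1700² px SIM fields for count
recovery; 391 cells × 200 replicates per rate for Poisson recovery; 25
noiseless pairs per modality for two-point resolution (50 nm objects — the
smallest of the prior, probing the PSF rather than object size); 100
noisy traces for FRAP recovery; 100 cells per arm for compaction; 5000
replicates for Welch calibration.

## Known limitations

- The simulator is a statistical emulator, not an optical model: no SIM
  reconstruction artifacts, no photophysics beyond one acquisition-bleach
  term, no DIC channel, Gaussian (not Airy/vectorial) PSFs.  Passing tests
  demonstrate that the *analysis* recovers known structure under these
  conditions, not that real data meets them.
- Detection is 2D (projections or single planes); axially stacked foci
  closer than the axial PSF merge, and 3D detection is out of scope.
- Cell geometry and intensity priors are plausible, configurable choices,
  not measurements; conclusions that depend on absolute intensity scales
  should treat A.U. as arbitrary.
- Focus areas measured on wide-field images are PSF-dominated and should
  not be interpreted as structure sizes; the package flags but does not
  forbid this use.
- The zero-truncated MLE degenerates as the truncated sample mean
  approaches 1 (λ → 0); it is intended for rates ≳ 1.
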