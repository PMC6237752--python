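# halofoci

Quantitative live-cell fluorescence imaging of replication/repair foci in
archaea, as a tested, reusable Python pipeline.

In live *Haloferax volcanii* cells, GFP-tagged single-stranded-DNA-binding
protein (RPA/SSB) marks discrete replication foci (RF).  Characterizing
them quantitatively requires a chain of image-analysis steps — cell
segmentation on maximum-intensity projections, per-cell focus counting with
a prominence ("noise tolerance") criterion, Poisson modelling of the
counts, focus morphometry on super-resolution (3D-SIM) images, Hoechst
DNA-compaction metrics, and FRAP recovery fitting.  `halofoci` implements
that chain for anyone analyzing punctate fluorescence in small cells
(archaea, bacteria, yeast), together with a ground-truthed synthetic
microscopy generator so every stage can be verified without raw microscope
data.

## The models at the core

- **Focus detection.** A pixel is a reported maximum iff it is a regional
  maximum whose *prominence* exceeds the noise tolerance *h*: flooding from
  a maximum of value *v* over pixels > *v − h* must reach neither a
  strictly higher pixel nor cover the whole cell region (topological
  persistence ≥ *h*).  Defaults: *h* = 35 (wide-field), 400 (SIM).
- **Counting model.** Per-cell focus counts *N* ~ Poisson(λ), fitted with λ
  as the only parameter: analytic MLE (sample mean), histogram least
  squares over counts 1–9, or the zero-truncated MLE; the zero class is
  tested separately with an exact binomial test against e^−λ.
- **Morphometry.** Focus area *A* by the half-maximum contour; diameter
  *D* = 2√(*A*/π).  A rendered spot is the true structure ⊗ PSF, so the
  measured lateral FWHM is √(FWHM²_PSF + d²_true).
- **Compaction.** With per-cell integrated Hoechst intensity conserved,
  compaction raises the per-cell *maximum* DNA intensity while leaving the
  *mean* unchanged; arms are compared with Welch's unequal-variance t-test.
- **FRAP.** Three-ROI normalization I_n = (I − I_b)/(I_sb − I_b), rescaled
  to a unit pre-bleach plateau, then A − B·exp(−k·t) fitted post-bleach;
  τ½ = ln 2/k, mobile fraction = B, immobile fraction = 1 − A.

## Worked example

`examples/01_simulate_and_count.py` simulates a wide-field field of 60
cells with Poisson(2.76) focus counts and runs the counting pipeline:

```
threshold (Otsu, top-1% clipped): 19.0 A.U.
cells segmented: 60 of 60 simulated
mean detected foci/cell: 2.58 (ground truth 2.72, lambda 2.76)
```

Every simulated cell is recovered as one ROI and the detected mean count
agrees with the generator's truth to a few percent.  `examples/05_frap.py`
fits a simulated control-like FRAP trace (τ½ = 8.4 s, 2% noise):

```
fitted A = 0.956, B = 0.761, k = 0.0817 1/s
half-time tau_1/2 = ln(2)/k = 8.48 s (true 8.40 s)
mobile fraction (B): 0.76
immobile fraction (1 - A): 0.04
```

i.e. ~76% of molecules exchange into the bleached spot with a ~8.5 s
half-time, and ~4% remain immobile over the acquisition.  The other
examples cover the Poisson model and zero-class deficit (`02`), SIM focus
sizing (`03`), and the DNA-compaction contrast (`04`).

A thin CLI mirrors the library:

```bash
halofoci simulate --modality widefield --n-cells 60 --lambda-foci 2.76 -o field/
halofoci poisson field/gfp.tif --modality widefield -o run/
halofoci frap field/frap_000.csv -o run/
```

## Layout

```
src/halofoci/
  config.py       acquisition geometry and camera model per modality
  simulate.py     ground-truthed synthetic fields, Hoechst mode, FRAP traces
  segment.py      projection, Otsu (+ manual adjust factor), CellROI stats
  foci.py         prominence maxima, per-cell counts, half-max morphometry
  stats.py        Poisson fits, zero-class test, Welch test, summaries
  compaction.py   focal-plane selection and DNA-intensity metrics
  frap.py         trace normalization and recovery fitting
  experiments.py  canned study-scale validation experiments
  pipeline.py     RunConfig, seeded end-to-end runs, manifests
  cli.py          thin command-line layer
```

Methodological details, parameter defaults and known limitations are in
`docs/methods.md`.
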