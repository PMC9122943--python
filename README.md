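# fixclust

Chemical fixation is supposed to freeze a cell in place — but on the
nanometre scale it rewrites the cell surface. High-resolution AFM of living
cell membranes shows protein-sized protrusions (FWHM well under 10 nm) that
grow markedly larger after paraformaldehyde, glutaraldehyde or methanol
fixation, while two-colour fluorescence shows unrelated membrane proteins
(e.g. E-cadherin and EpCAM) ending up significantly closer together. Both
observations are explained by a simple model: once the fixative acts,
membrane proteins that touch can no longer move apart, so freely diffusing
proteins aggregate irreversibly into clusters.

`fixclust` is a Python library for quantifying this effect end to end. It is
aimed at AFM and fluorescence microscopists who want to measure what
fixation does to their samples, and at method developers who need a fully
synthetic, ground-truth-labelled testbed for such pipelines.

## What it computes

- **AFM preprocessing** (`fixclust.afm`) — the standard flattening chain:
  2-D polynomial plane fit (degree 2), per-scan-line polynomial levelling
  (degree 3), median filter (width 3), each with robust trimming
  (tolerance 0.5) so protrusions do not bias the baseline.
- **Protrusion recognition** (`fixclust.protrusions`) — each protrusion is
  delimited by the subpixel iso-contour at half its peak height above the
  local background; for an isotropic Gaussian bump of width σ the enclosed
  area is the closed form `A½ = 2π ln2 · σ²`, which the detector reproduces
  within a few percent. Also: profile FWHM (`2√(2 ln2)·σ` for a Gaussian),
  nearest-neighbour distances, persistence filtering across drift-corrected
  consecutive frames (a feature present in ≥ 3 frames is real, not a scan
  artefact), and Mann–Whitney U condition comparisons.
- **Stiffness** (`fixclust.mechanics`) — Hertz–Sneddon fit for a pyramidal
  tip, `F = F₀ + κ tanθ · E/(1−ν²) · δ²` with face half-angle θ = 17.5°,
  three-sided-pyramid front factor κ = 0.7453 and ν = 0.5, recovering the
  Young's modulus E from approach force–distance curves.
- **Fluorescence spots** (`fixclust.spots`) — LoG spot detection (spot size
  0.5 μm, quality threshold 0.2 on an ideal-spot-normalised scale), channel
  density equalisation, per-cell mean cross-channel nearest distances,
  Student's t condition comparison, single-spot time-lapse tracking and
  aggregation-onset detection.
- **Registration** (`fixclust.registration`) — similarity transform between
  AFM and fluorescence frames estimated from the microporous support
  membrane's hole lattice (5 μm holes at 10 μm pitch) via mutual-nearest
  matching and a closed-form least-squares fit.
- **Synthetic data** (`fixclust.synthetic`) — a sticky-diffusion simulator
  of the fixation model (Brownian particles of two species; after fixative
  addition any pair within a capture radius bonds permanently; clusters slow
  as D/n and arrest over a ~10 s ramp) plus renderers producing AFM
  topographs, two-channel spot images, force curves and hole-lattice image
  pairs, all with ground-truth labels and bit-reproducible from a seed.
- **Workflows & pipeline** (`fixclust.workflows`, `fixclust.pipeline`,
  `fixclust` CLI) — end-to-end simulated condition studies and a YAML-config
  runner with reproducible, provenance-stamped outputs.

## A worked example

```sh
python examples/02_hertz_fit.py
```

```
 condition  true E (kPa)  fitted E (kPa)     SEM
    living         27.21           27.37    0.23
      MeOH        165.30          166.28    1.41
       PFA        449.00          451.65    3.82
        GA        534.80          537.96    4.55
```

Twenty-five noisy synthetic approach curves per condition (5% force noise)
are fitted each; the recovered moduli track the generating stiffness, i.e.
the 6–20× stiffening that fixatives produce is read out faithfully. The
other examples are equally short: `01_flatten_and_detect.py` (flatten a
tilted topograph and measure half-max protrusion areas),
`03_fluorescence_nn.py` (living vs fixed cross-channel distances with a
t-test; prints ~0.60 μm living vs ~0.38 μm fixed), `04_registration.py`
(recovers a 7°/1.02×/(3, −2) μm transform to ~0.006 μm RMSE) and
`05_fixation_simulation.py` (tracks one molecule through fixation and
prints its arrest time).

## Layout

```
src/fixclust/     library (afm, protrusions, mechanics, spots,
                  registration, synthetic, workflows, pipeline, cli)
examples/         one short narrative script per capability
tests/            pytest suite incl. property-based acceptance checks
docs/methods.md   models, parameters, numerical choices, limitations
scripts/          acceptance.py
```
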