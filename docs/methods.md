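# Methods

`holomass` measures the 3D position and dry mass of individual
microplankton from time-lapse inline holograms. This note records the
models it implements, the constants and defaults that matter, what the
synthetic-data generator does and does not emulate, and the numerical and
design choices that were genuinely open.

## Dry mass and optical contrast

Dry mass is the non-water mass of a cell, `m = V (c_obj − c_med)` with `c`
the solute mass concentration. Since the refractive index of a dilute
solution rises linearly with concentration — the specific refractive-index
increment `dn/dc`, for the average planktonic solute composition
0.21 ml/g — the same quantity is optically accessible:

```
m = V · Δn / (dn/dc)
```

With lengths in µm, masses in pg and dn/dc in ml/g the unit factors cancel
exactly (`1 µm³ = 1e-12 ml`, `1 g = 1e12 pg`), so
`mass_pg = V_µm³ · Δn / dndc`. All conversions are centralized in
`holomass.optics`; `refractive_index_from_dry_mass` is the exact algebraic
inverse (round-trip error < 1e-9 pg).

Forward scattering at small angles is proportional to the integrated
contrast `V·Δn`, which is why a single inline hologram encodes dry mass.
Two conventional comparison estimators are provided as thin utilities with
caller-supplied coefficients: the volume-to-carbon allometry
`log10 C = log_a + b·log10 V` (coefficients differ per trophic group and
come from the literature, not from this package) and the carbon→total dry
mass extrapolation by an extended Redfield multiplier.

**Coherence length.** `λ²/(2Δλ)` — the convention that yields ~200 µm for a
632.8 nm source behind a 1 nm line filter, matching the instrument this
package models. The λ²/Δλ convention (twice this) also appears in the
literature; we document it and use the factor-½ form throughout.

## Hologram formation model

A unit-amplitude plane wave illuminates spherical scatterers above a bare
sensor (no lenses). Each particle is a thin phase object: integrated phase
`φ = (2π/λ_vac) · Δn · chord(x, y)`, area-averaged onto the pixel grid with
8–16× supersampling so sub-pixel particles contribute the correct
integrated phase (the quantity that carries dry mass). The scattered field
`exp(iφ) − 1` of each particle is propagated to the detector with the
band-limited angular-spectrum transfer function for its own axial distance
`z`, the per-particle fields are summed (first order in scattering), and
the intensity `|1 + Σ s_k|²` is normalized by the unscattered intensity
(identically 1 here), so an empty scene is exactly 1.

Validity: the weak-scattering/first-order assumptions underlying the
dry-mass law fail for the largest, densest draws of the training
distribution (Δn·diameter is not ≪ λ there). This is accepted: the
networks learn the simulated map, and the same forward model generates
train and test data.

**Axial sampling limit.** The sampled angular-spectrum kernel aliases when
its phase gradient exceeds π per frequency sample; for an N-px grid at
pitch Δx this caps the propagation distance at
`z_max = N·Δx²·sqrt(1/λ'² − 1/(4Δx²))` (λ' the in-medium wavelength) —
about 1.7 mm for a 64-px grid at 3.6 µm pitch and 3.5 mm for 128 px.
Scenes beyond the limit raise an error naming it. A Matsushima-style band
limit is also applied inside the kernel.

**Noise model.** Optional additive Gaussian noise (default σ = 0.01 of the
unit background) plus a zero-mean low-order polynomial illumination
gradient (default amplitude 0.02). Both are applied after the interference
intensity is formed; negative values are clamped at the sensor floor 0.

## Training data

The scene sampler draws, per particle, an equivalent spherical diameter
uniform on [1.5, 10] µm and an index contrast Δn uniform on the range the
dry-mass endpoints imply (0.119–0.399 for 1–995 pg with dn/dc = 0.21), so
dry mass — the derived quantity — spans [1, 995] pg with physically coupled
size/contrast values. Sampling mass and size independently instead would
require index contrasts far above anything aqueous biology produces
(Δn > 1 for the smallest, heaviest draws) and, empirically, makes the mass
channel unlearnable. Positions are uniform with a margin,
and z is uniform over a configurable range (default [500, 2000] µm on
128-px grids — the observation well sits ≈1.5 mm above the sensor; the
64-px desk-scale configuration uses [500, 1500] µm because of the grid's
axial sampling limit). Default particle count is 1–8 per 128² image; the
desk-scale 64² configuration uses 1–3, matching areal density.

Crop sequences for the mass-refinement network contain 15 frames of
64×64 px centered on a main particle whose global lateral step is uniform
in ±1 px/frame (the crop re-centers on it each frame, so only the sub-pixel
residual remains) and whose axial step is uniform in ±100 µm/frame.
With probability 0.3 a distractor particle crosses the crop on a fixed
random heading at 1–7 px/frame with the same axial motion.

What the generator does *not* emulate: non-spherical morphologies (diatom
frustules, chains), internal structure, partial coherence and chromatic
effects, sensor Bayer patterns/vignetting, and motion blur. Passing the
synthetic recovery tests therefore demonstrates that the pipeline is
self-consistent on the simulated image formation physics, not that it
reaches the same accuracy on arbitrary real recordings.

## The detection network

A U-Net variant whose upsampling path splits into two parallel arms. Six
downsampling blocks (8, 16, 32, 64, 32, 32 filters by default); the first
four are followed by 2×2 max-pooling and feed skip connections; the last
two operate at bottleneck resolution (this reconciles six down blocks with
four up blocks). Each arm has four upsampling blocks (128, 64, 32, 16
filters), nearest-neighbour ×2 upsampling, skip concatenation, and
3×3/stride-1/same convolutions — two per block by default; block depth and
kernel size are declared defaults, chosen as the lightest standard choice.
Arm 1 ends in a sigmoid (segmentation); arm 2 ends in a ReLU and produces
z, mass, Δx, Δy. Outputs concatenate to H×W×5.

**Encodings** (`MapCodec`, stored in every checkpoint): z/1000; mass either
/100 (linear, full-scale default) or log10(1 + m) (`mass_encoding="log"`,
used at desk scale — with an absolute-error loss over a 1–995 pg range the
linear encoding rewards predicting the range median, whereas an error in
log space is a *relative* mass error, which is the quantity that matters);
offsets are shifted by +16 px, clipped to [0, 32] and divided by 16 so a
ReLU head can represent them; the hologram input has its unit background
subtracted. Decoding inverts all of these.

**Loss.** Binary cross-entropy on segmentation (positive-class weight 10,
because foreground disks cover ~1% of a tile) plus mean absolute error on
each regression channel restricted to the pixels where that channel is
defined — the owning particle's disk for z/mass, the 16-px neighbourhood of
a center for the offsets — with default weights seg 1, z 1, mass 1,
Δx/Δy 0.5 (the desk-scale schedule raises z and mass to 3, since those are
its hardest channels). The loss form is this package's declared
construction.

**Training.** AMSGrad Adam; streamed scene generation with a pre-buffer
(half the pool before the first epoch, the rest added as epochs proceed).
Full-scale defaults: lr 1e-4, batch 16, 300 epochs, 4000 images. The
desk-scale configuration used by the test suite trains a narrower net
(8-16-32-48 down; 48-32-16-8 regression arm; 16-12-8-6 segmentation arm —
segmentation needs far less capacity than the regressions, so the arms are
deliberately asymmetric) on 500 64² images with batch 4 and cosine-decayed
lr 3e-3 for 32 epochs — sized to fit the package's single-threaded numpy
engine into roughly ten minutes of one CPU. A master seed fans out to data
stream, weight init and shuffling; all constants land in the checkpoint.

**Decoding detections.** Every pixel with segmentation probability > 0.5
casts a vote at `pixel + (Δx, Δy)`; votes are splatted bilinearly,
smoothed (Gaussian σ = 1 px), and local maxima at least 5 px apart with at
least 5 supporting votes become detections. (x, y) is the vote centroid
within 3 px of the peak; z and mass are medians of the corresponding maps
over pixels near the center (the regression channels are supervised only on
the particle disk, so far pixels carry noise; medians resist fringe-edge
outliers). Ties in peak ordering break by row then column. A plain
segmentation-blob decoder is available as `decoder="blob"`; it is the right
operating point when the offset channels are not yet converged — on the
desk-scale checkpoints the offsets reach only ~3 px MAE, which scatters the
votes, while the segmentation channel alone already localizes reliably, so
the desk-scale evaluations use the blob decoder. The vote decoder is exact
on ideal maps and is the default.

## The mass-refinement network

A weighted-average CNN: each crop passes through a shared trunk (four conv
blocks of 32, 64, 128, 256 filters by default — one conv per block, as the
crops are small — each conv→ReLU→max-pool, then two dense-128 layers) to a
latent vector; a weight head (dense 128 → dense 1 per frame) scores each
latent, a softmax over the sequence axis produces convex weights, and the
weighted mean latent feeds a dense 32-32-2 head. Because the softmax
normalizes over however many frames are present, any sequence length ≥ 1
works at inference; training uses 15 frames.

The two outputs are trained in encoded units: optical volume `V·Δn`
(scaled by 1/20) and radius (µm). Optical volume — not mass — is what a
hologram physically encodes, so the division by dn/dc happens at decode
time; decoding the same network with a different dn/dc rescales masses
exactly inversely (tested), and the mass label never depends on an assumed
solute composition during training. Loss is joint MAE; training matches
the detection network's scheme (full-scale: lr 1e-4, batch 32, 200 epochs,
4000 sequences; desk scale: 500 sequences, narrower trunk (8-16-32-48 filters, 64-node latents), 16 epochs, cosine-decayed lr 1e-3).

Sliding-window inference (stride 1) produces a mass/radius series; the
window length is recorded with the output. Feeding analyses use window 1
(temporal resolution); division analyses use window 15 (accuracy).

## Tracking and events

Frame-to-frame linking solves the assignment problem optimally per frame
pair (cell counts are small). Cost: Euclidean distance with the axial term
down-weighted by 0.3 (z estimates are noisier), plus 10 µm per unit
relative dry-mass change — mass is what disambiguates crossing cells.
Links are gated at 50 µm per elapsed frame; gaps up to 3 frames bridge.

**Feeding events.** A candidate is two tracks approaching within 20 µm
(same axial down-weight) where the lighter track terminates during the
contact. At desk scale the contact test runs laterally (axial weight 0)
with a 60 µm radius: two cells merge into a single detected blob at
roughly 13 px ≈ 47 µm separation, so the prey's track always ends before
a literal 20 µm approach could be observed, and desk z estimates carry
~35 µm noise that would mask real contacts. Predator mass is averaged over up to 100 frames before first
contact and up to 100 after last contact (windows truncate at track
boundaries, never extend; fewer than 10 usable frames on either side drops
the event); the increment must exceed twice the pooled SEM. Per-frame
window-1 estimates are treated as independent samples when computing SEMs
— a simplification, since consecutive estimates share fringe content.

**Division events.** A candidate is a track that ends while exactly two
tracks begin within 30 µm and ≤ 3 frames later (three-way splits are
logged and skipped). Masses are taken at isolation-satisfying frames —
the first frame (searching backward for the parent, forward for each
daughter) at which the nearest neighbour is at least 40 px away — as
mean ± SEM over ±5 frames. The quoted isolation figure "3.6 µm (40 px)" is
internally inconsistent with the 3.6 µm/px pitch; the pixel number is
taken as authoritative (it is what governs crop contamination), so the
default is 144 µm. The conservation ratio is Σ(daughters)/parent. The
desk-scale analysis measures at a stricter 216 µm (60 px) isolation and
tracks division recordings with a tighter step gate (25 µm, axial weight
0.1), because the desk-scale refinement network is more sensitive to
neighbour fringes than a fully trained one and the scripted split is
abrupt.

## Numerical and engineering choices

- **Engine.** Both networks run on a compact reverse-mode autodiff over
  numpy arrays (im2col convolutions on BLAS matmul, float32), written for
  this package and gradient-checked against central differences. It is
  single-threaded and bit-deterministic: same seeds → identical training
  histories and predictions.
- **Indexing.** 0-based pixels, centers on integer coordinates,
  x = column, y = row. Offsets point from pixel toward particle center.
- **Checkpoints.** Single `.npz` holding weights, architecture config,
  encode/decode constants and provenance (seed, schedule); reload is
  bit-identical.
- **Determinism.** All stochastic stages take explicit seeds; the pipeline
  stamps artifacts with a config hash, and re-running a stage from
  persisted inputs is idempotent.
- **Degenerate inputs.** Empty scenes render as exactly 1; an empty vote
  map decodes to no detections; tracks shorter than the window refuse a
  mass series; fewer than two regression pairs is an error.

## Desk-scale study sizes

The test suite trains at desk scale: detection on 500 simulated 64² images
(~10 min on one CPU), mass refinement on 500 sequences (~6 min), and the
end-to-end analyses on scripted movies of a few hundred 96² frames. These
sizes are the package's declared desk conditions; the full-scale defaults
above reproduce the original training regime and are configuration, not
code changes.

## Known limitations

- The formation model is scalar, first-order, monochromatic and thin-object;
  real high-contrast cells violate weak scattering, and real sources have
  finite coherence (the package reports the coherence length but does not
  model partial coherence).
- Spheres only; no species identity; no behavioral classification.
- The desk-scale networks are far smaller and far less trained than the
  full-scale defaults; their recovery numbers bound what the pipeline can
  do at that budget, not what the method achieves when fully trained.
- In the strong-phase regime (peak phase ≫ 1 rad) the pattern→(mass,
  radius) mapping is locally non-smooth: small changes in Δn·diameter shift
  the internal ring structure by large fractions of a cycle. The desk-scale
  refinement network consequently shows mass-dependent error pockets of
  ±25% — stable for one cell over time (noise SEMs are a few pg) but
  systematic between different optical states. This is why the desk-scale
  event analyses recover mass *changes* less accurately than mass *noise*
  statistics suggest; the full-scale training budget is what removes these
  pockets.
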