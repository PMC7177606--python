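# Methods

## Problem

EEG electrodes are metallic objects on the scalp; when the head is exposed to
an RF source (here 900 MHz), small uncertainties in where each electrode sits
change the electromagnetic field inside the head and therefore the specific
absorption rate (SAR = σ|E|²/2ρ, W/kg) in the brain. Quantifying that
uncertainty by brute-force Monte Carlo over a full-wave solver is intractable
— one solve of the coupled electrode/head scattering problem takes tens of
hours — so this package implements the neural-surrogate alternative: compress
the high-dimensional SAR field with an autoencoder, learn a map from the
discrete electrode-position variables to the latent codes, and run the Monte
Carlo ensemble through the cheap surrogate instead of the solver.

## Geometry and design of experiments

The head is a three-layer sphere (brain/skull/skin; the shipped dielectric
table is a four-year-old child at 900 MHz: brain ε_r 55.5, σ 0.94 S/m,
ρ 1030 kg/m³, outer radius 68 mm; skull 12.5/0.14/1850/71.1; skin
35.2/0.6/1110/74.7). L = 64 electrode centres sit on the scalp sphere
(r = 74.7 mm) at spherical coordinates (θ_p, φ_p). Each electrode moves
independently on the 3×3 offset grid {−Δ, 0, +Δ}² in (θ, φ); the nine grid
cells carry 1-based indices, with index 9 the unperturbed position, so a cap
configuration is a length-64 vector over {1,…,9} and the design space has
9⁶⁴ members. Index values are kept 1-based end to end so the offset table
stays traceable.

Choices the source material leaves open:

* **Δ (angular step).** Default 2° ≈ 0.0349 rad — larger than the surface
  mesh edge of a 13 mm cap on this sphere, so all nine positions are
  physically distinct. Configurable.
* **Electrode coordinates.** No coordinate table is published; the default
  layout is a deterministic Fibonacci lattice on the upper hemisphere,
  quasi-uniform in solid angle, starting 2Δ below the pole so every
  perturbed θ stays inside [0, π].
* **Azimuth wrap / polar clamp.** φ offsets wrap modulo 2π. θ offsets that
  would leave [0, π] raise an error rather than clamp: clamping would merge
  two discrete positions and silently corrupt the nine-position model.

## Synthetic forward model

The full-wave volume–surface integral solver is out of scope; a parametric
generator stands in for it behind the single `generate_field` contract, so a
real solver could be swapped in without touching the pipeline. The generator
produces a non-negative SAR vector on a 30³ Cartesian grid of half-width
68 mm (D = 27,000 voxels; x varies fastest in the flattened order), zero
outside the brain sphere:

* a baseline field magnitude decaying exponentially with depth from the
  scalp (default decay scale 30 mm, the order of tissue attenuation at
  900 MHz), modulated by a smooth seeded angular pattern standing in for the
  unspecified incident source;
* one localized non-negative kernel per electrode (Gaussian, default width
  14 mm ≈ electrode size, amplitude 0.6× the base field), centred at the
  perturbed electrode direction scaled to 0.9× the brain radius — moving an
  electrode moves its kernel. Kernels are truncated to compact support at
  4× their width so an electrode's influence is exactly local;
* voxelwise SAR via σ|E|²/2ρ with the tissue shell of the voxel centre.

What this emulates: smooth non-negative fields on a low-dimensional manifold
parameterized by the 64 discrete variables, concentrated under the cap, with
spatially heterogeneous std/mean at the few-percent level. What it does not
emulate: wave interference, electrode–electrode electromagnetic coupling,
resonances, anatomical heterogeneity. Passing tests therefore demonstrate
that the surrogate machinery recovers the uncertainty structure of fields
*like* these, not that it reproduces any particular solver's physics.

### Rank-limited mode

For oracle tests the generator can instead emit an **exact** linear
combination of `rank` fixed smooth basis fields (wide overlapping Gaussians
masked to the brain) with coefficients affine in the normalized index
vector. Two realism constraints matter, and both were chosen to mirror how
ensembles of smooth physical fields actually behave:

* **Decaying mode spectrum.** Mode strengths decay geometrically (factor
  0.75 per mode). Field ensembles driven by many small local perturbations
  have a steep spectrum — a few dominant smooth modes and a weak tail — and
  a network trained on 70 samples can only generalize such a spectrum; a
  flat 40-mode spectrum is information-theoretically out of reach of any
  estimator from 70 examples, independent of architecture.
* **Few-percent variability.** Coefficient swings are bounded (sup 0.2 on
  the leading mode) so per-voxel std/mean sits at the sub-percent to
  percent level, consistent with the coefficient-of-variation maps the
  method targets.

The data matrix still has numerical rank exactly `rank` (singular values
beyond it are < 1e−10 of the leading one), so the truncated-SVD
reconstruction floor for any bottleneck ≥ `rank` is exactly zero, and every
unit of held-out autoencoder error is attributable to the network.

## Networks

Both networks are fully-connected MLPs with ReLU hidden units, linear input
and output activations, trained by backpropagation with Adam under the MSE
loss; no early stopping (the 30% validation split is held out for reporting
only, and reported MSEs are recomputed from the final weights so they are
exactly reproducible). Full-scale hyperparameters: autoencoder hidden stack
3000·3000·3000·100·3000·3000·3000 (bottleneck d = 100), 100 training
samples, batch 25, 8000 epochs; regressor hidden stack 500·500·100 with a
d-wide linear output, 200 training samples, batch 50, 6000 epochs. The
desk-scale benchmark specs are the same structures at one-tenth width with a
50-wide bottleneck.

Electrode indices enter the regressor ordinally: (i − 1)/8 ∈ [0, 1] per
electrode, S = L inputs (one-hot would inflate S 9-fold and contradicts
min–max normalization of the indices). SAR matrices are normalized by one
global min–max over all entries — the columns share physical units — and
codes are used as the encoder emits them.

### Initialisation and optimisation

The source material specifies activations, optimizer and loss but not
initialisation or learning-rate schedule. Those defaults are load-bearing
here, and the shipped scheme was chosen after the standard one failed
reproducibly:

* **Data-dependent (LSUV-style) init.** One forward pass of the training
  data sets every hidden unit's preactivation to unit variance, centred at
  `activation_margin` (default 4, benchmarks use 6) standard deviations
  above zero, and the output layer is scaled to the target's standard
  deviation with its bias at the target mean. The network therefore starts
  well inside the active, locally linear regime of every ReLU — the regime
  in which a deep network can represent the optimal linear (PCA-like)
  reconstruction, and from which training need not kill units to make
  progress. With plain He or Glorot initialisation on this data — a large
  shared mean with few-percent fluctuations — a third of all units are born
  dead, the optimizer kills most bottleneck units within a few hundred
  epochs (47/50 observed), the effective code rank collapses, and held-out
  MSE plateaus orders of magnitude above the achievable floor.
* **Per-tensor scale reparameterisation (muP-style).** Each weight tensor
  is stored at unit RMS with a fixed scalar `scale` carried separately, so
  Adam's scale-free per-parameter steps are proportionate for every layer
  no matter how the data-dependent init conditioned the effective weights.
  Without it, layers whose effective weights are small (e.g. the 2744-input
  encoder layer after variance normalisation) are randomised by the
  optimizer noise.
* **Adam β₂ = 0.99, ε = 1e−10** (β₁ = 0.9). The faster second-moment decay
  tracks the rapidly shrinking gradients in the late, fine-convergence
  phase of an interpolation-capable model.
* **Hold-then-cosine schedule.** Constant learning rate (default 1e−3) for
  the first 75% of epochs, then a cosine decay to `lr_final_fraction` of
  the base rate. The constant phase does the structural learning; the
  anneal removes the minibatch-noise floor. Annealing earlier trades
  structural progress for noise reduction and measured worse on the
  shipped benchmarks.

All randomness — weight init, minibatch shuffling, data generation, splits,
Monte-Carlo draws — flows from explicit integer seeds through NumPy
Generators; single-threaded NumPy arithmetic makes runs bit-reproducible on
one machine.

### Numerical conventions

* Min–max normalization maps constant columns to 0 and records the constant
  for exact inversion; `denormalize(normalize(x)) = x` to 1e−12.
* The validation split is `round(0.3 n)` samples, at least 1, from a seeded
  shuffle (200 → 60/140, 100 → 30/70).
* Training aborts with an error if the epoch loss ever becomes non-finite.
* Degenerate inputs (empty ensembles, mismatched dimensions, out-of-range
  indices, unfitted normalizers) raise typed errors naming the offending
  quantity; nothing is silently coerced.

## Uncertainty quantification

`run_uq` chains dataset generation → normalization → autoencoder training →
encoding → regressor training → Monte-Carlo prediction → per-voxel
statistics, with stage-labelled failure propagation and a manifest of seeds
and content hashes. The Monte-Carlo ensemble (default 500 configurations,
freshly sampled and seeded) is pushed through regressor + decoder; per-voxel
sample mean, sample standard deviation (n−1 denominator) and the
coefficient-of-variation map 100·std/mean are computed on both the
normalized and the physical (W/kg) scale. Voxels with zero mean — those
outside the brain — are masked (NaN), not reported as 0/0. Decoder outputs
are clipped at zero and zeroed outside the brain sphere before statistics:
the SAR support is known geometry, and the decoder's ~1e−4-level residuals
there are artefacts of the reconstruction, not physics.

## Problem sizes in the shipped benchmarks

The full-scale protocol (27,000-dim fields, 3000-wide layers, 8000 epochs)
is faithful to the method but is not what the automated benchmarks run; they
use one-tenth-width networks on a 14³ = 2744-voxel grid (the closest cube to
one tenth of 27,000), bottleneck 50, rank-40 data, 100 training / 400 test
samples for the autoencoder and 200/200 for the regressor — sizes at which
the whole suite trains in minutes on one CPU while preserving the
sample-to-dimension ratios of the full protocol. The scaled epoch budgets
(5000 for the autoencoder, 3000 for the regressor, with the batch sizes of
the full protocol) are the package's own choice: large enough for the
regressor to land within 1e-6 of its least-squares floor and for the
autoencoder to come within the same band of its SVD floor, small enough
that both benchmarks and the surrounding tests run comfortably on one CPU.
On the autoencoder benchmark the held-out error continues to fall roughly
inversely with the number of optimizer steps, so a larger epoch budget
buys further accuracy at proportional cost. The `tiny` fixture (2
electrodes, 5³ grid, 81-configuration design space) exercises every pipeline
stage in seconds and supports exhaustive-enumeration cross-checks.

## Known limitations

* The forward generator is a stand-in: its fields are physically plausible
  but not solutions of Maxwell's equations; agreement of surrogate UQ with
  generator truth does not validate the method against a real solver.
* ReLU unit death is mitigated by initialisation, not eliminated; a
  bottleneck wider than the data's effective rank is still advisable.
* Training-time regularisation is implicit (architecture + schedule); there
  is no weight decay or early stopping, matching the source protocol.
* The min–max normalization state is fitted on the autoencoder's training
  fields and reused everywhere; fields far outside that range denormalize
  accordingly.
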