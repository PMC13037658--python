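# Methods

This note documents the models implemented in `cortexbench`, the parameter
defaults and why they were chosen, the numerical choices that affect
results, and what the synthetic fixtures can and cannot demonstrate.

## Latent shape space and distortion trajectories

A cortical surface is represented by a fixed triangulation whose vertex
order never changes, so "distortion" is always measured between
corresponding vertices. Surrogate anatomies are produced by a latent code
`z ∈ R^K` acting through a basis of per-vertex displacement fields
`W = {f_1 … f_K}`:

    v' = v + g · Σ_i δz_i f_i(v)

with a single global calibration constant `g`. The deformation is **linear**
in the code. A trained population shape model would instead integrate a
velocity field (a diffeomorphism); linearity is a deliberate simplification
that keeps the interface (latent vector → deformed mesh) while making
`δz = 0` an exact identity, `±δz` exact mirror images, and successive
deformations additive. Consequences: the undistorted surface sits exactly
at the trajectory midpoint (no residual re-parameterization error), and
very large codes could in principle self-intersect (the default range never
does on the packaged fixtures).

**The synthetic basis.** The first seven components are global affine
fields — three axis scalings, three symmetric shears, one rotation — the
modes that change head size or are shape-irrelevant. Trajectories clamp
them to zero, which structurally mirrors the constant-brain-volume
constraint: because the remaining components are orthonormalized *against*
the affine fields, their first-order volume change vanishes, and the
measured volume change across a default trajectory is < 0.2% on the
packaged fixtures (tested bound 2%). The other `K − 7` components start as
i.i.d. Gaussian per-vertex 3-vectors, are smoothed by repeated
half-self/half-neighbour averaging on the mesh graph, and are then
orthonormalized by modified Gram–Schmidt (affine fields first) under the
flat vertex-displacement inner product.

Parameters and defaults:

| parameter | default | meaning / rationale |
|---|---|---|
| `K` | 100 | latent dimensionality of the shape space |
| size components | 1–7 | affine modes clamped by every trajectory |
| `Z` | 3 | trajectory half-range in z-scores |
| `N` | 17 | surfaces per trajectory (odd, midpoint = truth) |
| `smoothness` | 20 mm | diffusion length of the random fields; population shape components are global, low-frequency modes, and 20 mm keeps them clearly smoother than the coarsest (10.6 mm-edge) fixture mesh can alias |
| `calibration_target_mm` | 3.5 | mean vertex displacement at a default trajectory endpoint |

The trajectory step formula is implemented exactly as

    δz_{i,j} = 2 Z (j − (N+1)/2) s_i / N,

so the endpoint magnitude is `Z (N−1)/N ≈ 2.82` for the defaults (not `Z`
itself); the calibration is defined at that endpoint. `g` is set so that
the endpoint of the trajectory built from the *calibration seed* (seed 1,
the first default trajectory seed) yields exactly the target mean
displacement; endpoints of other seeds land within ~2% because the mean
per-vertex norm concentrates over 93 orthonormal fields. Sign vectors are
drawn componentwise from a fair coin (`s_i = 2r − 1`), seeded; distinct
seeds give near-orthogonal trajectories (mean pairwise squared correlation
≈ 0.01 for 93 free components, tested bound 0.1).

## Forward model

The conductor is a homogeneous sphere, for which the external magnetic
field of a current dipole has a closed form that includes volume currents.
Its only parameter is the centre, taken as the vertex centroid of the
*undistorted* mesh and held fixed across a trajectory, so that sweeping a
trajectory varies the source model only. (Refitting the sphere per surface
is possible by passing a different `SphereModel`; the default keeps the
comparison clean.) Dipoles sit at mesh vertices, oriented along outward
area-weighted vertex normals; sensors are radial magnetometers (no
gradiometers, no coil integration). Units: positions mm, moments nAm,
fields fT; gains are fT/nAm. Radial dipoles are exactly silent in this
model — a property used as a numerical test (silence to 1e−10 of a
tangential dipole's gain).

The null model row-permutes the gain matrix with a seeded permutation:
the data are untouched, the gain distribution is untouched, but the
channel-to-anatomy assignment is destroyed.

## Inversion engine

All three schemes share one generative model, `Y = L J + ε`, with source
and sensor covariances expressed as scaled sums of fixed components,
`Q_α = Σ exp(λ_k) Q_k`. Hyperparameters live on a log scale with Gaussian
priors (`v = 0`, `Π = I/256` — weak enough that Nt ≥ 100 data dominate) and
are optimized by Fisher scoring with Levenberg–Marquardt damping (max 128
iterations, convergence at |ΔF| < 0.01; non-convergence returns the best
iterate with a warning). The free energy is

    F = −Nt/2 log|Σ| − Nt/2 tr(Σ_Y Σ⁻¹) − Nt·Nc·log(2π)/2
        − (λ̂−v)ᵀΠ(λ̂−v)/2 − log|Σ_λ Π|/2

whose first three terms equal the Gaussian log likelihood of the data
(verified against a direct log-density sum). The sign of the final
(hyperposterior) term is implemented as written above; some
variational-Laplace presentations carry `+½ log|Σ_λ Π|` instead. Across
surfaces of a sweep the component count is constant, so the choice shifts
every F by a similar amount and does not affect peak locations. `Σ_λ` is
the inverse of the expected curvature plus prior precision. An exactly
zero `Π` is treated as an improper flat prior (both prior terms dropped) —
used in closed-form recovery tests.

Posterior currents use `Ĵ = Q_α Lᵀ Σ⁻¹ Y` via Cholesky solves (no explicit
inverse); the identity with the source-space form
`(Lᵀ Q_ε⁻¹ L + Q_α⁻¹)⁻¹ Lᵀ Q_ε⁻¹ Y` is tested to 1e−10.

- **IID**: unit diagonal source component → regularized minimum norm
  (equals Tikhonov ridge at matched regularization).
- **EBB**: diagonal source variances `q_i = (l̃_iᵀ Σ_Y⁻¹ l̃_i)⁻¹` with
  column-normalized lead fields — unit-gain beamformer power under an
  uncorrelated-source assumption. Conventions not fixed by theory: a ridge
  of 1e−6 × mean diagonal on Σ_Y before inversion, and unit-trace
  normalization of the component.
- **GS**: a library of `Np = 64` rank-1 patch priors (seed vertices by
  farthest-point sampling on graph geodesics; profiles `exp(−d/σ)` with
  `σ = 10 mm`), grown greedily from a noise-only model, adding the patch
  whose inclusion most increases F after full re-optimization; stop at
  improvement < 0.01 or 8 patches. This forward-greedy scheme over a fixed
  discrete library is intentionally simple and can be sub-optimal; ARD
  pruning and multi-start variants are out of scope.
- **LCMV** weights (for the projected-power metric):
  `w_i = Σ⁻¹ l_i (l_iᵀ Σ⁻¹ l_i)⁻¹`, ridge 5% of the mean diagonal by
  default; the unit-gain constraint holds exactly by construction.

Temporal SVD projection (retain 99% variance, Nt = retained modes) is
available but **off** by default: Nt is the raw sample count.
Tie-breaking everywhere is "first index wins"; every stochastic step takes
an explicit seed. Hyperparameters are re-estimated per surface — each
surrogate anatomy is a distinct model and gets a fresh empirical-Bayes fit.

## Metrics and scoring

- **Free energy**: from the inversion itself.
- **Variance explained**: residual-based, `R² = 1 − ‖Y−Ŷ‖²_F/‖Y‖²_F`
  (this equals a squared correlation only for unbiased predictions; the
  residual form is what is implemented).
- **Cross-validation error**: per run, a seeded 10% of channels is held
  out, the inversion is *fully re-optimized* on the rest (the honest
  generalization test — hyperparameters included), and held-out channels
  are predicted through their own lead-field rows; the per-channel RMS (fT)
  is averaged over channels and over 10 independent runs.
- **Max normalized projected power**: `Γ = max_θ (w_θᵀ Σ_Y w_θ)/(w_θᵀ Σ_ε w_θ)`
  from the LCMV scan, with Σ_ε defaulting to the optimized sensor noise.

`find_peak` takes the argmax (argmin for CV error) over the N surfaces and
returns that surface's distortion in mm — unsigned, since ±j pairs are
equidistant from the truth; ties break toward smaller distortion. The
distortion score is the mean peak over trajectory seeds; the chance level
is the mean score of permuted-lead-field runs, and significance against
chance (or between methods) is a paired one-tailed t-test across datasets
(df = n−1), with a zero-variance guard.

The true surface is trajectory step `(N+1)/2` — no extra appended surface
is needed because the linear model makes `δz = 0` exact.

## Simulation fixtures

The toy cortex is an icosphere (tiny: 642 vertices; standard: 2562;
radius 70 mm) with a deterministic sinusoidal radial "gyral" modulation
(±~8%), giving spatially varying dipole orientations on a closed genus-0
manifold. Sensors: 96/120 radial magnetometers on a 110 mm Fibonacci cap
(105° polar coverage). Evoked data: 336 trials of a single fixed dipole
(20 Hz Hann-windowed sinusoid — mid-band for a 5–90 Hz evoked bandwidth —
100 samples at 250 Hz, 10 nAm), white sensor noise scaled to a −1.77 dB
single-trial SNR at the peak channel; trials are averaged and the realized
peak/median channel SNRs recorded. The default benchmark uses 8 trajectory
seeds and 3 simulated datasets (different source vertices) per run.

**What passing tests show — and what they do not.** The fixtures prove the
machinery: calibration, forward/inverse consistency, selectivity of a
matched prior for the generating anatomy, and chance-level behaviour of
permutation nulls. They do not emulate real cortical geometry (folding
statistics, sulcal depth), realistic noise (correlated sensor noise,
physiological background, co-registration error), multi-source activity,
or a trained population shape model — so absolute distortion scores here
do not predict scores on empirical head-cast recordings; only the
*relative* behaviour of methods and metrics is meaningful at this scale.
Problem sizes throughout (vertex counts, trajectory counts, dataset
counts) are the package's fixture-scale defaults, chosen so the full suite
runs on a laptop core in minutes.

## Numerical notes and known limitations

- Composite covariances stay positive definite because the sensor noise
  component is full rank and scales are exponentials; damped retries guard
  the line search, and a failed Cholesky in the posterior raises a named
  rank-deficiency error.
- OFF files are written at %.17g so write→read round-trips are bit-exact;
  GIFTI surfaces store float64 pointsets (nibabel "force" mode) for the
  same reason, which nominally departs from the GIFTI standard's float32.
- The linear shape model cannot reproduce the residual distance a
  diffeomorphic round trip leaves at δz = 0; mean pairwise trajectory
  correlations are asserted only qualitatively (< 0.1), not at any
  particular value.
- GS runtime grows as (library size × active patches) ReML fits; the
  defaults keep it desk-scale but it is the slowest path.
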