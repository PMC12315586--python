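# Methods

`probinitio` implements probabilistic single- and multi-volume *ab initio*
3D reconstruction for single-particle cryo-EM: given a stack of noisy,
CTF-affected particle images and 2D-class metadata, it simultaneously
estimates per-particle orientations (and optionally discrete structural
state labels) and reconstructs regularized 3D density map(s). This note
records the model, the concrete numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Model and objective

Particles are treated as central sections of the 3D Fourier transform `V`
(projection-slice theorem), modulated by a per-particle CTF `H_i` and
degraded by additive Gaussian noise. An orientation is `φ = (o, s)` with
`o ∈ SO(3)` discretized on an `N_m × N_n` grid over `S² × S¹`
(Fibonacci-sphere directions restricted to the point-group asymmetric unit,
uniform in-plane angles) and a continuous 2D origin shift `s`.

The matching objective is a noise-weighted Euclidean distance normalized to
[0, 1]:

    d(φ) = Σ_k w_k Σ_{h∈ring k} |P̃(h) − H(h) R(h)|²
           ───────────────────────────────────────────────,  w_k = 1/σ²_k
           2 Σ_k w_k Σ_{h∈ring k} (|P̃(h)|² + |H(h) R(h)|²)

where `R = ℘(V, o)` is the reference reprojection and `P̃` the particle
transform recentered by `s` (phase ramp `exp(+i c h·s)`, `c = 2π/L`). By the
parallelogram bound `0 ≤ d ≤ 1` with `d = 0` iff `P̃ = HR` and `d = 1` iff
`P̃ = −HR`; the normalization removes the dependence on image size. The
per-ring noise powers `σ²_k` are re-estimated once per iteration from the
residual at each particle's current orientation and then frozen for that
iteration's searches. Because a residual estimated at a *wrong* orientation
can collapse on accidentally matching rings and invert the cost ranking,
`σ²_k` is floored at 5% of the ring power; at realistic SNR the residual is
noise-dominated and the floor is inactive.

Shifts are optimized continuously with bounded L-BFGS-B using the analytic
gradient `∂P̃/∂s_j = +i c h_j P̃` (the normalization denominator is
shift-invariant). In the pipeline the optimizer is started both from the
previous estimate and from zero — the second start lets particles escape
self-consistent wrong (orientation, shift) pairs — and the per-iteration
update is relaxed halfway (`s ← s + 0.5 (s* − s)`) to suppress the jitter
injected by stochastic orientation resampling.

## Orientation search

Matching runs in polar Fourier coordinates: reference polar sections are
extracted from the (gridding-corrected, 2× oversampled) Fourier volume for
every grid direction, and the cost against every in-plane rotation is
evaluated at once with FFT cross-correlations along the angular axis. The
grid is sized to the current resolution — the angular step is
`k / r_lp` radians (`r_lp` the low-pass ring, undersampling factor
`k = 1.25` by default), capped at the per-stage maximum number of
directions — and is rebuilt whenever the dynamic low-pass limit moves, so
the search never pays for finer sampling than the data currently supports.

*Probabilistic assignment.* Affinities `a = 1 − d` form the probability
table: rows are normalized by their sums and a single global min–max maps
the table into [0, 1]. Per particle, the ε-neighborhood is the set of
top-Q affinity cells, `Q` being the expected number of grid cells in a
geodesic cap of radius ε (times the number of states). One cell is drawn
multinomially; the draw combines the table probability with the Gaussian
likelihood `exp(−(num − num_min)/2)` implied by the noise-weighted squared
residual. The likelihood factor is essential: the linear affinities alone
are nearly flat within a neighborhood and the sampler then never
concentrates (measured: orientations resample almost uniformly within the
neighborhood and the error plateaus at tens of degrees). Assignments are
sequentially coupled: each accepted direction increments an occupancy
counter that damps the effective probability of crowded directions for all
subsequent particles (`1/(1 + occupancy/expected)`), discouraging collapse
onto few views. The very last iteration reports the maximum-probability
cell instead of a draw (the MAP estimate; sampling is for optimization,
not for reporting).

*Hybrid SHC.* The first four stages use stochastic hill climbing over
projection directions — visit directions in a fresh random order, accept
the first one improving on the incumbent cost, fall back to the best seen —
with the in-plane angle sampled within the in-plane ε-neighborhood.

*Angular threshold.* ε starts at 10° and is updated each iteration to the
90th percentile of the particles' geodesic direction changes, clamped
between the grid spacing and its previous value (monotone non-increasing).

*Trial-shift rescue.* With shift search enabled, the worst-cost 15% of
sampled particles are re-matched over a small absolute shift grid (current
value, origin, and two rings of the shift box — 10 candidates); the
globally best (cell, shift) replaces the assignment when it improves the
cost. Without this, particles whose true shift exceeds ~2 px deadlock:
their true direction never ranks well at the wrong shift, and the shift is
never refined at the right direction (measured: stuck fraction 19% → 5%).
In the final two stages the rescue runs every third iteration.

## Sampling schedule and frequency marching

The run is divided into eight stages (hybrid SHC search without/with ML
regularization for stages 1–4, global probabilistic search with ICM
regularization for 5–8; shift search from stage 3; 500/1000/2500 maximum
directions; 20/20/17/17/17/17/15/30 iterations). Particles are selected
evenly across the 2D classes each iteration: stages 1–3 take each class's
best-scoring members deterministically, stages 4–6 sample among each
class's top 50%, stages 7–8 among the top 85%; per-class quotas differ by
at most one, with shortfalls redistributed round-robin.

Per-stage low-pass limits derive from the class FRC curves: the start is
the all-class mean-FRC 0.8 crossing (30 Å default if never reached), the
final limit the 0.143 crossing of the three best-resolved classes clamped
into [4.5, 6.0] Å (user override may only coarsen), and the six
intermediate limits step linearly along the mean-FRC values in between.
Each stage is Fourier-crop downscaled so the pixel size is one third of its
limit (boxes rounded to even 5-smooth sizes, floor 16). In stages 7–8 the
limit moves dynamically: each iteration an order-8 Butterworth cutoff
minimizing the masked distance between the filtered even map and the raw
odd map is estimated from the half-set pair and clamped between the planned
stage-7 and final limits.

## Reconstruction and regularization

Particles are inserted into even/odd half-accumulators by index parity
(fixed across iterations; the halves serve regularization and the automatic
low-pass limit, not gold-standard validation), CTF-premultiplied:
numerator `Σ kernel·H·P̃`, weights `Σ kernel·H²`. Gridding uses a
Kaiser–Bessel window of width 3 on a 2× oversampled grid (β from the
Beatty formula); extraction pre-divides the real-space map by the window
transform, reconstruction divides the weighted quotient by the
shape-normalized window transform after the inverse FFT. Insertion is the
exact adjoint of extraction (verified to ~1e−7).

ML (Wiener) regularization divides the accumulator by
`weights + 1/(τ·SSNR)` per shell with `SSNR = FSC/(1−FSC)` from the half
maps and τ = 3; a floor of `1e−4·max(weights)` bounds the division on
empty cells even when the FSC claims infinite SSNR.

ICM regularization models the map as a Gibbs random field over quantized
voxel values (64-level 1-D Lloyd quantizer, quantile-seeded): raster-scan
sweeps set each voxel to the level nearest the conditional optimum of
`(v − obs)²/(2σ_i²) + λ Σ_{j∈N6} (v − v_j)²` until no voxel changes or 10
sweeps. Per-voxel noise sd `σ_i` comes from the local standard deviation of
the odd−even difference (window 5, scaled by 1/√2 to one half map). The
pairwise term carries map-value units, so λ = 1 is only meaningful at a
defined scale: the map is implicitly expressed in units where the mean
noise sd equals 0.5, which weights the neighbor mean at ~0.75 against the
data term. Even and odd maps are regularized independently with a shared
quantizer and averaged for the next reference. The global energy (pair
terms counted once) is non-increasing by construction; the final map is
soft-mask limited (cosine edge) and never B-factor sharpened.

## Multi-volume mode

`nstates = K` appends `K − 1` further reference sets: the probability row
spans `K·N_m·N_n` cells and the drawn cell yields both orientation and
state. In `independent` mode particles are partitioned uniformly at random
from the start; in `docked` mode a single volume is refined until just
before the final stage, which then splits randomly. Per-state
reconstructions use only that state's particles; states falling under four
members are re-seeded from the largest state's worst-scoring particles.
`K = 1` is literally the same code path as the single-volume pipeline.

Stable state separation needs four safeguards against the feedback loops
of joint estimation, each measurably necessary on the two-state benchmark:

- *Stratified neighborhoods.* The top-Q cells are taken per state block
  (Q/K each). A global ranking, once ε has contracted, contains only the
  better-reconstructed state's cells, and labels can never flip.
- *Reference-noise compensation.* A state rebuilt from fewer particles has
  a noisier reference, inflating every particle's residual against it and
  collapsing the labels onto the larger state. The expected inflation —
  the reference power times `1/(1 + SSNR)` with SSNR from that state's
  half-map FSC — is subtracted from the residual.
- *State-neutral noise spectra.* σ²_k is estimated against the
  state-averaged reference section. Estimated against the particle's own
  assigned state, the residual inflates exactly on the discriminative
  rings for mislabeled particles, locking them in.
- *Confidence-weighted insertion and MAP annealing.* Particles enter their
  state's reconstruction weighted by the posterior odds of their label
  (bounded below at 0.05), and the last five iterations of the final stage
  assign the minimum-residual cell deterministically. The trial-shift
  rescue never changes a label (it repairs shifts and orientations only).

## Ensemble analysis

Maps from repeated runs have arbitrary orientation and hand. Pairs are
docked by exhaustive coarse search (SO(3) grid at ≤15° spacing, closed
under inversion, both hands via z-flip; correlations on a low-passed,
Fourier-cropped working box) followed by deterministic pattern-search
refinement of the rotation vector with a sign-symmetric stencil; the score
is the masked correlation symmetrized over both application directions, so
`score(a, b) = score(b, a)`. The medoid maximizes the similarity row sum;
members scoring below `median − 2·MAD` of the others against the medoid are
flagged as outliers. Volumes are never averaged.

## Synthetic data generator

Phantoms are sums of 20–25 3D Gaussian blobs (σ 1.2–3 voxels) placed
uniformly in a sphere of 0.3·box radius, with amplitudes `∝ σ⁻³` so sharp
blobs keep measurable high-frequency power (the spectrum then falls off
like a small protein's rather than collapsing beyond the blob scale).
State variants delete or displace ~30% of the blobs. Particles are
central-slice projections (via the gridding operator), CTF-multiplied
(defocus 0.8–2 µm, 300 kV, Cs 2.7 mm, 10% amplitude contrast, astigmatism
up to 10%), randomly translated, plus white Gaussian noise calibrated so
the measured in-mask signal-to-noise power ratio equals the requested SNR.
An independent real-space projector (trilinear rotate-and-sum, no shared
code with the Fourier machinery) serves as the oracle for the
projection-slice tests.

2D-class metadata emulates the *output* of a converged 2D analysis:
particles group by nearest of `n` template directions, and each member's
registered image is its state's template view plus the member's own noise
realization. Class FRC curves are therefore noise- and class-size-limited,
like the twofold cross-validated curves a register-and-average 2D pipeline
reports; optional registration-error parameters can degrade them. This is
an idealization — real classes also carry angular spread and
misclassification — and it matters: the class curves set the frequency
march, and the blob phantom has too little low-resolution asymmetry to
bootstrap from a 20–30 Å start, so the benchmarks operate in the regime the
method requires (start ≈ 12–14 Å), mirroring the real prerequisite of
high-quality class averages.

## Benchmark conditions and what they show

The standard benchmarks (also recomputed by `scripts/acceptance.py`):

- *Single-volume recovery*: 2000 particles, box 48 at 2.0 Å/px, SNR 0.1,
  shifts σ = 1.5 px, 50 classes, random initialization, full eight-stage
  schedule. Reported: median angular error after global alignment with
  hand freedom, and the FSC between the final map and the phantom at the
  frequency limit the run itself settled on.
- *Two-state recovery*: 3000 particles of a two-state phantom (a coherent
  domain around the most massive blob deleted in state 2), box 40 at
  2.0 Å/px, SNR 0.3, docked mode, K = 2; best-permutation label accuracy
  over the particles the method classified. The box was chosen inside the
  regime where the consensus search bootstraps reliably (the search needs
  roughly seven starting rings; see limitations).
- *Component checks*: operator adjointness and projection-slice consistency
  (64³), analytic vs numerical shift gradients, ICM denoising at SNR 0.5,
  ensemble docking/medoid selection, and the automatic low-pass limit
  falling between the half-map FSC 0.5 and 0.143 resolutions.

Problem sizes were chosen so the full sweep runs in tens of minutes on one
CPU. Passing them shows the estimator works under the generator's
assumptions (white noise, ideal CTF, converged classes, rigid particles);
it does not demonstrate robustness to structural heterogeneity beyond
discrete states, colored noise, contamination, or poor 2D classes.

## Known limitations

- The class-FRC march inherits the generator's idealized class model; with
  genuinely coarse starts (fewer than about six or seven Fourier rings at
  stage 1, e.g. a 16 Å start for a 96 Å particle, or any start for a 72 Å
  particle at these noise levels) the search settles into a
  self-consistent wrong basin — the classic failure mode that
  class-average-based initialization (not implemented; out of scope)
  addresses on real data.
- Half-sets share orientation errors (one search, index-parity split), so
  the half-map FSC and the automatic low-pass limit are optimistic
  relative to a map-to-truth comparison.
- The ICM energy is non-increasing per sweep, but the per-iteration
  interleaving with reconstruction carries no global convergence guarantee
  (standard for fixed-point refinement schemes).
- Thread-level parallelism only; all benchmarks are single-process.
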