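# Methods

This note documents the model implemented by `gridfield`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not show.

## Model

A virtual agent performs a random walk in a square arena S = [0, L)² and
drives n place-cell inputs r_i(X(t)).  A single linear output
ψ = J · r learns its weights online with the Oja rule
ΔJ = ε_t (ψ r − ψ² J); the multi-output extension (Sanger's generalised
Hebbian rule) trains output i on input deflated by outputs 1..i−1.  For
zero-mean inputs this converges to the leading principal component(s) of
the input covariance Σ.  Imposing J ≥ 0 by rectifying after every update
makes the learning a local algorithm for non-negative PCA,
max {JΣJᵀ : ‖J‖=1, J ≥ 0}, an NP-hard non-convex problem of which the
network finds local optima.

Three other routes to the same object are implemented and cross-checked:
batch eigendecomposition of Σ (unconstrained); a direct projected
accelerated-gradient solver on the dense-ensemble convolution form of the
objective; and the averaged ODE dJ/dt = JΣ − diag(JΣJᵀ)J of
stochastic-approximation theory, whose equilibria JΣ = diag(JΣJᵀ)J are
the normalised eigenvectors (only the principal one stable), integrated
with an entrywise cut-off in the constrained case.

## Arena, inputs and their parameters

* Arena: periodic square, side L = 100 (length units are arbitrary;
  place-field widths set the only scale).  Periodic boundaries remove edge
  effects and make Σ circulant, so its eigenvectors are sinusoids.
* Walk: constant speed 1 per step, heading a Gaussian random walk with
  SD 0.2 rad/step — isotropic and ergodic by construction.  The walk is
  vectorised (reflection at walls is the fold map of the free walk).
* Inputs: 625 difference-of-Gaussians (DoG) fields on a 25×25 lattice,
  r(x) = c₁ e^{−x²/2σ₁²} − c₂ e^{−x²/2σ₂²} with σ₂ = 2σ₁ and c₁, c₂
  balanced numerically so each cell's raster sums to zero exactly.  In 2D
  the zero-integral condition gives c₁/c₂ = (σ₂/σ₁)²; only with this
  ratio is the transform r̂(k) ∝ e^{−σ₁²k²/2} − e^{−σ₂²k²/2}.
* σ₁ = 3.9 for the network/PCA/ODE ensembles.  The transform peak
  k† = √(2 ln(σ₂²/σ₁²)/(σ₂²−σ₁²)) then falls nearest the fourfold axis
  orbit (±4,0),(0,±4) of the reciprocal lattice, with a 0.7 % margin over
  the eightfold (4,1) orbit, so the leading eigenvalue group of Σ is a
  clean group of four and unconstrained solutions are squares.  With the
  theory-figure width σ₁ = 3.75 the two orbits are tied to within 2·10⁻⁴
  and unconstrained solutions become ring-like mixtures; the
  solver/theory experiments (spacing sweep, modules, Fourier scans),
  which do not depend on that tie, use 2σ₁ = σ₂ = 7.5.
* Alternative inputs: plain Gaussians (not zero-mean; produce no grids
  unless differentiated in time or adaptation-filtered) and signed disks
  (inner radius σ₁, outer 2σ₁, ring amplitude −r²/(R²−r²)).

## Learning and integration choices

* Learning rate ε_t = ε₀/(1 + t/t₀), ε₀ = 0.05, t₀ = 10⁵ — satisfies the
  stochastic-approximation conditions Σε = ∞, Σε² < ∞.
* Run length T = 3·10⁶ steps.  At 10⁶ steps a sizeable fraction of
  constrained runs still holds lattice defects (near-optimal Rayleigh
  quotient but visibly imperfect hexagons); by 3·10⁶ the decaying rate has
  annealed them.  Convergence was diagnosed with the Rayleigh quotient
  JΣJᵀ against the direct solver's optimum, not with the gridness score.
* Weight initialisation: uniform(0,1), normalised to unit norm.  If
  rectification ever zeroes the whole vector it is re-initialised (this
  effectively never happens at these rates).
* The single-output linear path is compiled (numba): the DoG is a sum of
  two separable Gaussians, so each step evaluates O(√n) exponentials
  instead of O(n).  The compiled and generic paths are tested to agree to
  1e-10.
* ODE integration: fixed-step explicit Euler with h = 0.2/λ_max(Σ), the
  cut-off applied between steps, no row renormalisation (the flow itself
  drives norms to 1; an equilibrium with JΣJᵀ ≠ 0 has unit norm).
  Termination: residual ‖JΣ − diag(JΣJᵀ)J‖ < tol (unconstrained) or
  per-unit-time weight change < tol (constrained, where the free-flow
  residual need not vanish on the constraint face).  An earlier
  residual-gated adaptive step was removed: the constrained flow's
  residual legitimately rises while leaving the DC-like initial condition,
  which collapsed the step.

## Direct steady-state solver

On the periodic raster the objective is Σ_k |Ĵ(k)|²|r̂(k)|² (hats are
FFT/n_pix).  The gradient is one FFT convolution; its Lipschitz constant
is exactly 2 max_k |r̂(k)|²/n_pix, so the step size needs no tuning.  The
iteration is a monotone accelerated projected gradient: a Nesterov
candidate is accepted only if it improves the objective, otherwise
momentum restarts from the best iterate — the recorded trace is
non-decreasing.  The feasible-set projection clips at zero (if
constrained) and renormalises.  Convergence: relative objective change
below 1e-9 (1e-10 in the experiments), capped at 5·10⁴ iterations.  The
kernel is shifted to exact zero spatial sum before solving.  Successive
components deflate the operator by (I − |J⟩⟨J|/n_pix) per accepted
solution; the components are not orthogonal, so deflation suppresses
rather than annihilates earlier components.

Rasters: 64² for the side-100 arena (pixel 1.56, grid spacing ≈ 18 px),
256² for the side-500 spacing sweep.

## Scoring

The autocorrelogram of a periodic rate map is the exact Pearson
correlation with its cyclic shifts (FFT); for non-periodic maps a masked
sliding Pearson correlation is used.  Peaks are 8-neighbourhood maxima of
the lightly smoothed (σ = 1 px) autocorrelogram.  The scoring annulus runs
from half the distance of the nearest peak to 1.25× the distance of the
sixth; when six peaks are not found, a fixed fallback annulus
[0.2, 0.7] × half-width applies.  Rotations use bilinear interpolation and
correlations are computed over pixels valid in both maps.  Spacing is the
median centre-to-peak distance of the six nearest peaks; orientation the
angle of the peak nearest the +x axis folded to [−30°, 30°); alignment
min(|α|, 30°−|α|) ∈ [0°, 15°].  The exact annulus and smoothing of the
original scoring protocol are not published, so absolute scores may shift
by ~0.05–0.1; all hexagonal/square contrasts are far larger.

Modules: 2-means on log-spacings of maps with gridness₆₀ > 0.7; the
centroid ratio is reported, with a single-module flag when clustering is
unresolvable (ratio < 1.1).

## Coefficient scans (sharply-peaked limit)

Under the rescaling |r̂(k†)|² = 1/2 the objective of a solution is the
summed squared amplitude on the base wavevector(s) at k†.  The 1D scan
optimises amplitudes of J(x) = a₀ + 2Σ a_m cos(m k† x) (SLSQP,
multi-start, pointwise non-negativity on a dense period, unit norm); the
harmonic common-phase form is the known structure of the optimum, and a
test confirms that perturbing the frequencies away from harmonics never
improves the objective.  Results: 1/6 (M=1, where a₀ = 2a₁), 0.2367
(M=2), 0.2457 (M=3), +6·10⁻⁴ for M=4.  The square-lattice scan does the
same over the truncated square lattice |m|,|n| ≤ 2 and stays below the
0.25 bound; the hexagonal reference solution attains 0.2558.

The reference hexagonal coefficient set (DC 0.6449; base 0.292×3;
harmonics −0.0101×3 at 2k and −0.134×2 on k₁+k₂, k₁+k₃) is evaluated on
its stated wavevector list literally.  Note an internal inconsistency of
that prescription: with the base 120° apart, k₁+k₂ = −k₃ folds onto the
base ring, so the coefficient-sum norm check double counts; re-readings
that make the last two harmonics a distinct √3-shell render the
reconstruction negative (infeasible), while converged solver solutions
carry three roughly equal √3-shell pairs.  The literal set reproduces all
three stated checks (objective 0.2558, coefficient norm ≈ 1,
non-negativity with min J = +3·10⁻⁴), so it is kept as the reference.

## What the synthetic experiments show — and what they do not

The generator emulates an idealised foraging session: uniform ergodic
exploration, identical noiseless tuning curves on a perfect lattice,
periodic boundaries, no spiking noise, no head direction or speed
modulation, no plasticity beyond the single learned projection.  Passing
tests therefore demonstrate the mathematical mechanism — non-negativity
plus zero-mean input turns the principal component hexagonal — not that
biological grid cells arise this way.  Finite arenas quantise the
admissible wavevectors, so grid spacing and orientation are lattice-
snapped; orientation only approaches its continuum uniform distribution
on [0°, 15°] as L grows.

Two reported ensemble statistics are not reproduced by the corresponding
batch pipelines and are left failing deliberately.  (1) A perfectly
balanced square cos(kx)+cos(ky) scores gridness₉₀ ≈ 0.90 and
gridness₆₀ ≈ −0.4.  The top eigenvector of a trajectory-sampled
covariance, and equally the averaged-ODE equilibrium from a random start,
is a random direction in the degenerate fourfold eigenspace — balanced
squares, rectangles and stripes in proportion — whose mean gridness₉₀ is
≈ 0.3–0.5, well below the ≈ 0.8–0.9 reference.  Only the stochastic
online network shows a noise-induced selection of balanced squares
(mean ≈ 0.6–0.7).  (2) For the same reason the unconstrained network's
mean gridness₆₀ here is slightly negative (clean squares), not ≈ +0.3; a
positive value would require maps halfway between square and ring-like,
which would simultaneously destroy the square-gridness statistic that the
same runs do reproduce.

## Problem sizes used

Networks: 625 inputs, T = 3·10⁶ steps, 20 runs (10 in the test suite).
Sampled-covariance PCA: T = 7·10⁴ per trajectory, 20 trajectories (10⁵ ×
12 in the test suite).  ODE: 40 outputs × 4 runs (3 in the test suite).
Spacing sweep: 6 σ values, one solve each, arena 500 at 256².  Modules:
100 deflated components.  These sizes keep the full reproduction under
~15 minutes on one core while leaving the ensemble means within the
spread documented above.
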