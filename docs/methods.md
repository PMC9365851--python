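# Methods

## Model

HURP intensity H(x, t) on one kinetochore-fibre is modelled as a linear
advection–diffusion–reaction field on the segment x ∈ (0, L), with x the
distance from the kinetochore toward the pole:

    ∂H/∂t + v ∂H/∂x = D ∂²H/∂x² + λ(x) g(x) − µ H.

Binding requires RanGTP-activated HURP, encoded by the stationary gradient
g(x) = exp(−x/s).  The binding rate λ(x) reflects the nucleotide state of
the lattice: on the trailing (polymerising) side it ramps linearly from
λ/r at the kinetochore, through the GTP-cap and mixed-nucleotide zone of
total length l, to the full GDP-lattice rate λ at x ≥ l; on the leading
(depolymerising) side the zone is absent and λ(x) ≡ λ.  The advection
speed is the rate of change of a lattice site's distance from the
kinetochore: +ν₊ on the trailing side (new lattice appears at x = 0, old
lattice recedes) and −ν₋ on the leading side.  Because the coordinate is
kinetochore-anchored, poleward microtubule flux does not enter.

Both ends carry partially absorbing (Robin / radiation) boundaries: the
outward diffusive flux at boundary i equals γᵢ·H(boundary).  γ = 0 is a
reflecting wall, γ → ∞ an absorbing one.  At the kinetochore (x = 0) this
is γ₁H(0) − D ∂H(0)/∂x = 0; at x = L the outward normal points the other
way, so the absorbing form is γ₂H(L) + D ∂H(L)/∂x = 0.  (The same
expression with a minus sign at x = L would feed mass *into* the domain
and could not drive the boundary value to zero at large γ₂; we use the
orientation consistent with a partially adsorbing wall at both ends.)

The leading/trailing alternation around a directional switch is produced
by an initial-condition chain: the trailing side is equilibrated from an
empty fibre; that equilibrium starts a leading-side run; its final state
starts the trailing-side run on which the HURP-gap develops.

### Parameters, units, defaults

| name | meaning | unit | fixture default |
|------|---------|------|-----------------|
| l | GTP-cap + mixed-nucleotide zone length | µm | 1.5 |
| D | HURP lattice diffusion | µm²/s | 0.024 |
| λ (`lam`) | maximal binding rate | intensity/s | 0.1 |
| µ | unbinding rate | 1/s | 0.1 |
| ν₊, ν₋ | advection speed magnitudes | µm/s | 0.02 |
| γ₁, γ₂ | boundary interaction strengths | µm/s | 0.01 |
| s | RanGTP gradient scale | µm | 3.0 |
| r | GDP/cap binding ratio | — | 4.0 |
| σ | observation noise | intensity | 5% of trailing-equilibrium max |
| L | modelled fibre length | µm | 3.0 |

Intensities are arbitrary units carried through unscaled; λ = 0.1 makes
the equilibrium amplitude λ/µ of order one.  The fixture values match the
scales measured for this system (zone length ≈ 1.5 µm, single-molecule
diffusion 0.024 µm²/s, turnover ≈ 10 s, kinetochore speeds ≈ 0.02 µm/s, a
fourfold GDP/GTP-analogue binding preference); they are test fixtures,
not fitted values.

## Numerics

Space is discretised on a cell-centred finite-volume grid (default 300
cells over L = 3 µm, dx = 10 nm; inference uses 90 cells = 33 nm, still
finer than the 104 nm observation pixel).  Diffusion uses second-order
central differences, advection first-order upwinding with the direction
set by the sign of v.  The Robin relations are closed by one-sided
extrapolation of the boundary value: H(0) = H₁ / (1 + γ₁dx/2D), giving an
effective boundary loss rate that interpolates smoothly between the
reflecting (γ = 0) and Dirichlet (γ → ∞, flux 2D/dx·H₁) limits.  The
advective flux at an inflow face uses the same Robin-implied boundary
value; for D = 0 the Robin relation pins the boundary value to zero.

The semi-discrete system is linear, dH/dt = A·H + b, so time stepping is
an exact exponential integrator: one matrix exponential of the augmented
operator per (parameter set, step size), then a matrix–vector recursion
per output frame.  This has no CFL restriction, no temporal truncation
error, and preserves non-negativity exactly because A is a Metzler matrix
(all off-diagonal entries non-negative).  A periodic-boundary variant of
the operator exists purely as a test harness for pure-transport checks.

Equilibria are found by integrating from an empty fibre in 25 s chunks
until the maximum change per unit time falls below 10⁻⁶ of the profile
maximum (horizon 2000 s; non-convergence raises an error carrying the
last residual — during MCMC such parameter points are treated as zero
posterior mass and rejected).

The HURP-gap of a profile is the smallest x at which the profile first
reaches half its maximum (threshold fraction configurable), located by
linear interpolation between cell centres; 0 if the first cell already
meets the threshold.

## Inference

The observation model treats every y±(xᵢ, tⱼ) as Gaussian around the PDE
solution evaluated on the observation grid (linear interpolation in
space; output frames are generated at the data's frame interval) with
fixed σ.  When σ is unknown it is estimated as the standard deviation of
spatial first differences divided by √2; synthetic pipelines pass the
known value.

Priors are independent log-normals on all dynamic parameters.  Defaults
are weakly informative (log-scale sd 1) around order-of-magnitude centres
(l ~ 1 µm, D ~ 0.02 µm²/s, λ ~ 0.1/s, µ ~ 0.1/s, ν ~ 0.02 µm/s,
γ ~ 0.01 µm/s, s ~ 3 µm); the binding ratio r carries a tight prior
(log-sd 0.1) centred at 4, encoding the in-vitro fourfold GDP/GTP-analogue
preference, because the profile data alone constrain it poorly.

Sampling is Random Walk Metropolis on η = log(δ + θ) with δ = 10⁻⁸: the
proposal draws ξ ~ N(0, Σ) jointly and maps back to the natural scale.
The map is asymmetric, so the exact Metropolis–Hastings correction is
applied (the change-of-variables Jacobian Πθ′ᵢ/θᵢ plus the δ-shift
asymmetry, the latter numerically negligible at the default δ); a switch
disables it for a plain-Metropolis protocol.  The protocol is: a pilot
chain (1,000 iterations, started at the prior medians) tunes Σ; then
n_chains independent chains (default 4 × 10,000) start from prior draws;
the first half of each chain is discarded as burn-in.  Σ for the main
chains is the pilot's empirical covariance of η scaled by the standard
optimal-RWM factor 2.38²/d.

Two warm-up refinements, frozen before any retained draw, make short
chains usable from overdispersed prior initialisations: during the pilot
and during each chain's burn-in half, (i) the proposal shape is
re-estimated every 50 iterations from the most recent 300 draws (scaled
2.38²/d, anchored to the pilot estimate as a floor), and (ii) a global
scale factor follows a Robbins–Monro recursion toward the optimal
acceptance rate ≈ 0.234.  After burn-in the kernel is fixed, so the
retained draws come from a valid time-homogeneous Metropolis chain.
Prior draws landing where the forward model cannot be solved are redrawn
(bounded retries); solver failures at proposed points are treated as
−∞ posterior and rejected with a warning, never aborting a run.

Summaries report pooled post-burn-in medians and central 95% intervals,
per-chain acceptance rates and the split-chain R̂ diagnostic (via arviz).

### Scaled-down recovery experiments

Desk-scale validation fits 4 chains × 2,000 iterations (pilot 1,000) at
90-cell solver resolution and infers the three scientifically central
parameters — the zone length l, the diffusion coefficient D and the
turnover rate µ — with the remaining parameters held at their generating
values.  At this iteration budget, full 10-parameter RWM from prior-draw
initialisations does not mix (strong λ–µ amplitude ridges dominate);
3-parameter inference converges (R̂ ≈ 1.0–1.6) and its 95% intervals
cover the generating values at close to the nominal rate.  The full
parameter set remains available through the same interface for
full-length runs.

## Synthetic data

The generator reproduces the kinetochore-tracking observation design: one
sample per 104 nm pixel over [0, 3] µm and per 4.1 s frame over a 60 s
window on each side of a directional switch, with i.i.d. Gaussian noise
of fixed σ (default 5% of the trailing-equilibrium maximum) added to the
noiseless model evaluation; negative noisy values are kept.  Particle
traces are 1-D Brownian walks with increment variance 2·D·dt; raw FRAP
series have a mono-exponential bleach-ROI recovery with known timescale
and mobile fraction, constant reference and background channels, and
optional Gaussian noise.  Every generator is a pure function of its
arguments and seed.

What the generator does *not* emulate: averaging over many sister pairs
aligned to switches (one alternation cycle per dataset; averaging across
replicates is the caller's choice), photobleaching during acquisition,
spatial correlation of noise, kymograph/image formation, and kinetochore
trajectory variability.  Passing tests therefore demonstrate internal
consistency of model, solver and sampler under the stated observation
design — not robustness to the real data's unmodelled structure.

## Analyses

* **Gap sensitivity** — for each value of l or ν₊, the trailing side is
  run for 300 s from the base parameters' trailing equilibrium (all other
  parameters untouched) and the half-maximum gap of the final profile is
  reported.  Demonstrations use an analysis base with γ₁ = 0.1 µm/s and
  s = 6 µm (other values at the fixture): there the trailing steady state
  exhibits a clear half-maximum gap that grows monotonically with l and
  ν₊.  At the fixture parameters the near-kinetochore depression does not
  reach half maximum and the estimator reports 0 throughout; with the
  domain-limited (L = 3 µm) window and s = 3 µm the measured gap is also
  not monotone beyond l ≈ 2 µm because the profile maximum migrates into
  the decayed RanGTP region.
* **Simulated FRAP** — the trailing equilibrium is bleached to zero for
  x > 1.5 µm, evolved forward, and the mean intensity over the bleached
  region (normalised to its pre-bleach equilibrium mean) is fitted with a
  mono-exponential to extract a recovery timescale.
* **FRAP normalisation** — the double normalisation divides the
  background-subtracted bleach signal by its pre-bleach mean and corrects
  for acquisition photobleaching with the inverse evolution of the
  background-subtracted whole-spindle reference.  The mono-exponential
  fit is F₀ + A(1 − exp(−(t − t_bleach)/τ)) on post-bleach points; the
  mobile fraction is A/(1 − F₀), the recovered share of the bleached
  depth relative to the pre-bleach level (the pre-bleach-normalised
  plateau F₀ + A is also available from the fit).
* **MSD** — time- and ensemble-averaged over all traces and overlapping
  start points; D is half the OLS slope through the first 5 non-zero
  lags (1-D diffusion, MSD = 2Dℓ; intercept free).  A constant MSD
  returns D = 0 with a warning.

## Design choices and limitations

* The exponential integrator replaces generic stiff time stepping because
  the model is linear; it is exact in time, so accuracy is governed
  entirely by the spatial grid (first-order upwind smears sharp advected
  fronts; the analytic-oracle tests bound the error at defaults).
* The paper-facing boundary condition at x = L is implemented in the
  absorbing orientation (see Model); the literal mirrored sign is
  unstable under grid refinement and contradicts the partially adsorbing
  interpretation.
* Leading and trailing sides share all parameters except the advection
  magnitude (ν₊ vs ν₋) and the zone length (l vs 0), including γ₂.
* The pilot run is discarded; only main-chain post-burn-in draws enter
  summaries.
* Observation positions at x = 0 lie half a cell outside the first cell
  centre; evaluation uses constant extrapolation over that half-cell
  (≤ 17 nm at inference resolution).
* The model is deterministic and mean-field: no microtubule-level
  stochasticity, no 2-D/3-D spindle geometry, no poleward-flux term, and
  a single θ for one averaged dataset (no hierarchical pooling).
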