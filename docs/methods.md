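# Methods

This note records the models, algorithms, numerical choices and known
limitations behind `mopcv`. Units are natural throughout: k_B = 1, so
energies and temperatures share one unit and β = 1/T. The working
temperature is T = 0.1, which makes a "chemically realistic" separation of
scales: basin depths of order 10 energy units are barriers of order 100 k_B T.

## Model surface and deterministic references

The built-in benchmark is a modified Müller–Brown surface: four anisotropic
Gaussian terms A_k exp[a_k(x−x0_k)² + b_k(x−x0_k)(y−y0_k) + c_k(y−y0_k)²]
with A = (−16, −11, −17, 2), a = (−10, −1, −6.5, 0.4), b = (5, 0, 11, 0),
c = (−5, −10, −6.5, 1.1), centers (1, 1.2), (0, 0.5), (−0.5, 1.5), (0, 1).
The fourth term is confining (positive amplitude, positive-definite
quadratic form), so the Boltzmann integral over the plane is finite.
Energy, gradient and Hessian are analytic; evaluating a configuration far
outside the confining region overflows the exponential and raises
`NonFiniteEnergyError` rather than returning infinities.

Three minima exist — A ≈ (−0.521, 1.469) at U = −14.128 (global, inside the
region {y > x + 1.5}), B ≈ (0.001, 0.513) at U = −8.387, C ≈ (0.988, 1.183)
at U = −12.943 — connected by two index-1 saddles, A–B at (−0.802, 0.671)
(climb 110.3 k_B T from A) and B–C at (0.698, 0.630) (70.7 k_B T from C).
Stationary points come from multi-start bounded minimization (L-BFGS-B on a
12×12 grid of starts) and multi-start Newton iteration on ∇U = 0 with the
analytic Hessian as Jacobian; saddles are classified by their Hessian
spectrum and joined to their two adjacent minima by descending from small
displacements along the unstable eigenvector. A barrier is the saddle
energy minus the deeper adjacent minimum; "highest barrier" maximizes this
over saddles.

The reference free-energy difference between the region A = {y > x + 1.5}
and the band C = {x − 1.5 < y < x + 1.5} is
ΔF = −(1/β) ln(∫_C e^{−βU} / ∫_A e^{−βU}), evaluated on a uniform trapezoid
grid over [−2.5, 2.5] × [−1.5, 3.5] with region masks, in log space
(`logsumexp`; the weight spans ~170 natural-log units). The grid is refined
dyadically until two successive estimates differ by < 0.01 k_B T; a
boundary check demands the edge weight be ≤ 10⁻¹² of the peak. The
converged value with the parameter set above is ΔF = 12.370 k_B T (a
Laplace approximation over the basin Hessians independently gives 12.372).

## Dynamics

Configuration-space sampling uses the overdamped Euler–Maruyama propagator
R′ = R + (Δt/mν)F + ξ with per-component noise variance 2k_BTΔt/(mν) and
the model-system parameters m = 1, ν = 10, Δt = 0.01. The same overdamped
form is used for the fictitious polymer dynamics in trajectory space
(time step 0.01, damping 100, unit bead mass), which makes the elastic
polymer measure exactly the distribution of discrete trajectories the
configuration-space propagator generates — the free-particle check below
closes that loop. An underdamped BAOAB integrator ships for qualitative
comparison only.

Where sampling accuracy of a *stationary* distribution matters more than
dynamical fidelity (the umbrella windows and static-bias production runs
used for free-energy estimation), the update averages consecutive noise
increments (the Leimkuhler–Matthews scheme), which samples the
configurational Boltzmann density with O(Δt²) error at unchanged cost. A
trust region caps the drift term at 0.05 length units per step; it only
engages on steep confining walls whose statistical weight is negligible,
and prevents explicit-integrator blow-ups there.

Everything stochastic takes a seed or a `numpy.random.Generator`; fixed
seeds give bitwise-reproducible trajectories. The numba-compiled fast paths
draw their noise from the caller's generator in the same stream order as
the numpy reference implementations, so both paths sample identical
randomness (equivalence is asserted in the tests at ≤ 10⁻⁹).

## Elastic-polymer trajectory sampling

`effective_potential` implements V_eff = U(R₁) + Σ (K/2)|R_{n+1} − R_n −
L_n|² with K = mν/(2Δt) = 500 and L_n = (Δt/mν)F_n. `polymer_forces` is its
exact negative gradient; because L_n depends on R_n, interior beads carry a
curvature coupling K(−I + (Δt/mν)H(R_n))ᵀd_n in addition to the plain
spring terms, and the first bead adds ∇U(R₁). Omitting the Hessian term is
a silent 10⁻³-level error that the force gate in the tests is designed to
catch. For a free particle the forces reduce to a discrete Laplacian and
the equilibrium bead increments are i.i.d. Gaussian with variance 1/(βK) =
2k_BTΔt/(mν) — a closed-form check that the sampled path measure is the
Brownian one.

Biased runs deposit Gaussian kernels on the end-to-end CV S = s(R_N) −
s(R₁); the chain-rule force touches only the two endpoint beads (∂S/∂R₁ =
−∇s(R₁), ∂S/∂R_N = +∇s(R_N)). Polymers initialize with all beads at one
configuration and relax unbiased (10⁴ steps) before any bias acts.

## Adaptive bias

`BiasState` accumulates Gaussian kernels on a scalar CV with the
well-tempered height rule h = h₀ exp(−V/((γ−1)k_BT)), clipped so the total
bias never exceeds a ceiling (`barrier`): late deposits act only where the
profile is still under-filled. With γ → ∞ this degenerates to plain
metadynamics under a ceiling — the exploration mode of the trajectory-space
runs, chosen because a tempered fill of a 10–15 energy-unit landscape
stalls exponentially before reaching the top. γ defaults to
1 + barrier/(5k_BT). Kernel width is fixed (default 0.03 CV units) or
adaptive (the CV standard deviation over the last ten deposition periods,
floored at 10⁻³); widths must stay below the thermal CV fluctuation or the
kernels raise a flat dome under the walker that exerts no escape pressure.

A uniform grid caches the bias and, in the sampling loops, supplies the
force as the exact slope of the recorded piecewise-linear potential, so the
potential that shapes sampling and the one used in reweighting are
identical. Outside the grid window the value clamps and the force is zero —
the bias never pushes a walker beyond the CV range it was calibrated for.
Arbitrary tabulated profiles can be added to the grid, which is how an
externally converged free-energy profile becomes a static bias.

Free-energy output: F(s) = −γ/(γ−1)·V(s) + const for a converged
well-tempered bias; ΔF between configuration-space regions by reweighting
recorded frames with log-weights βV(s_t) and a 10-block standard error
(`estimate_delta_f`, and `estimate_delta_f_pooled` for several walkers
sharing one bias).

## Neural state-discriminant CV

The network (default 2 → 24 → 12 → 1, ReLU) and its trainer are implemented
directly on numpy arrays; the loss couples all samples of a state through
batch moments, which no off-the-shelf per-sample trainer expresses. σ_k is
the population standard deviation (an all-equal batch gives exactly zero).
Training is full-batch Adam (lr 10⁻³, L2 10⁻⁵) with early stopping on a
20 % stratified validation split (patience 15, best weights restored);
mini-batches are available behind a flag but the per-state moments are
noisy in small batches. Weights initialize uniform ±1/√fan_in: modest
first-layer weights keep the map smooth between and beyond the training
clusters, which matters because the protocol evaluates the CV far outside
its training support. After training, an affine map pins the training-set
extrema to exactly ±1; per-state moments in normalized units are stored on
the model. Input gradients are exact backpropagation (the network is
piecewise linear).

Default target layouts: 2-state (−7, 7)/(0.2, 0.2); 3-state
(−15, 0, 15)/(0.3, 1.0, 0.3); 4-state (−30, −15, 0, 15)/(0.3, 4.0, 1.0,
0.3), the broad width belonging to transition-state data. Loss weights
α = 1, β = 250.

## Iterative refinement protocol

Stage 1 samples the two declared endpoint basins unbiased (30 000 steps,
stride 5, up to 6 000 configurations per state) and trains the 2-state CV.
Stage 2 runs biased polymer sampling; one leg starts from *each* declared
basin, because a CV trained on two tiny clouds typically resolves the
escape direction from only one of them. Stage 3 classifies samples by |S|
(trapped ≤ 0.3, reactive ≥ 1.0, the rest discarded, and everything from the
first 10 % of the run discarded regardless), pools trapped beads, clusters
them with OPTICS (min_samples 50, xi 0.05 on a ≤ 20 000-point subsample),
and keeps clusters farther than 0.5 length units from all known states as
new ones. If new states were found, a metastable-only CV is trained first,
all samples are re-scored, and reactive paths harvested through the window
[μ_lower + 3σ_lower, μ_upper − 3σ_upper] provide a transition state for the
final retraining (two-stage refinement). Termination requires a reactive
polymer whose endpoints fall within 0.3 length units of both declared
basins' training data; trapped evidence alone can never terminate.

Chain lengths are stage-dependent by design. Exploration uses N = 96 beads:
the chain relaxes quickly, and — decisively — a 0.96-time-unit trajectory
*cannot* span A to C (the Brownian-bridge kinetic action alone is ≈ 150
k_B T on top of ≈ 130 k_B T of climbs), so discovery can never
short-circuit into premature termination. The refined pass uses N = 288,
where complete two-saddle trajectories cost ≈ 17–19 energy units of action
and become reachable under the higher bias ceiling. The exploration ceiling
(17) admits single-saddle stretches (≈ 11–15 units) while keeping the
direct A–C ridge crossing (≳ 21 at N = 96) closed; the refined ceiling
(19.5) opens complete spans. Deposition: pace 25, height 0.2, width 0.02
(about half the thermal end-to-end fluctuation), non-tempered under the
ceiling.

At the refined scale the via-intermediate route and the direct ridge
crossing have nearly equal path action, and the sampled complete polymers
favor the ridge; the lowest-action *partial* reactive paths follow the
minimum-energy path to within 0.1 length units. On a longer polymer the
via-intermediate route wins outright; this is a known cost of the scaled-
down demonstration, not of the method.

## Enhanced-sampling free-energy estimate

The ΔF(A→C) recovery uses a progress variable that is monotone along the
A→B→C route by construction: a Gaussian-weighted soft projection onto the
minimum-energy path (steepest-descent curves from both saddles, resampled
at 0.05 spacing, extended 0.2 length units past both terminal minima so the
basins sit in the interior of the progress axis). Soft weighting (λ =
2.3/mean spacing²) keeps the variable local: remote regions inherit the
progress value of their nearest path nodes instead of aliasing onto an
unrelated section, the failure mode that makes one-dimensional marginals of
network-trained CVs unreliable at β·ΔU ≈ 100. Trained multi-state CVs
remain available (`train_three_state_cv`, `train_four_state_cv`) and drive
the protocol itself; the geometric variable is used where the estimate must
not depend on network extrapolation.

The profile F(s) is converged by stratified umbrella windows: 121 harmonic
restraints (κ = 400) spanning s ∈ [−0.98, 0.98], each initialized at the
path point with matching progress and confined to a tube of radius 0.15
around the path by a stiff wall on the soft squared distance (the wall is
independent of s, so WHAM treats it as part of the potential; the basins
lie on the path and their Boltzmann mass inside the tube is complete to
≲ 10⁻⁵). Windows sample 120 000 steps after 10 000 equilibration steps;
discrete WHAM on 800 bins stitches the histograms. The static bias
V(s) = max F − F(s) then flattens the biased marginal by construction, and
twelve walkers (half started in each endpoint basin) sample 1.2 million
production steps; reweighted region indicators with 10-time-block errors
give ΔF. Measured against quadrature, five independently seeded replicas
land within 0.01–0.21 k_B T.

Two consistency details are load-bearing: the production force must be the
exact derivative of the recorded piecewise-linear bias (an interpolated-
derivative force makes the sampled stationary distribution belong to a
slightly different potential than the reweighting assumes, a k_B T-scale
systematic), and the window integrator must be the higher-order sampler
(the plain Euler stationary density is measurably too hot in the stiff
basins).

## What the synthetic systems do and do not show

All inputs are generated internally: unbiased basin clouds, saddle-seeded
transition-region clouds, planted Gaussian clusters for trainer tests, and
the analytic surfaces themselves (a registry accepts user-defined
potentials; a finite-difference Hessian fallback exists for surfaces
without analytic second derivatives but is off by default). The 2D setting
exercises every algorithmic component — path measure, polymer forces with
curvature coupling, discovery, harvesting, retraining, termination,
free-energy recovery — but not descriptor engineering, rototranslational
invariance, or the force-field and engine coupling a molecular system
needs; passing here demonstrates correctness of the machinery, not
transferability of any particular trained CV.

## Known limitations

- Polymer sampling cost per step is linear in N with a compiled kernel for
  the built-in surface; generic potentials run through the numpy path at
  roughly 5–10× the cost.
- The bias ceiling replaces one adaptive-sampling convention with another;
  ceilings must be placed between the action scales of wanted and unwanted
  routes, which requires the barrier estimates the `potentials` module
  provides.
- Reweighting uses the final/instantaneous-bias approximation without a
  time-dependent normalization correction; block errors absorb the
  residual at the run lengths used here.
- The archive format stores bead arrays per sample (HDF5); very long
  protocols should raise the save stride.
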