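# mopcv

Machine-learned collective variables from enhanced sampling in trajectory
space, demonstrated end-to-end on an analytic three-state model potential.

## The problem

Free-energy methods such as metadynamics need a collective variable (CV)
s(R) that tracks the slow transition of interest. Machine-learned CVs can
deliver this, but training them well requires data from all metastable
states and from the transition regions between them — data that standard
simulations cannot produce precisely because the barriers are high. This
package implements a route out of that circularity: enhanced sampling of
*whole trajectories*.

A discrete overdamped (Brownian) trajectory R₁ → R₂ → … → R_N carries the
Boltzmann-like weight exp(−βV_eff) of a fictitious elastic polymer,

    V_eff = U(R₁) + Σₙ (K/2) |R_{n+1} − R_n − L_n|²,
    K = mν/(2Δt),   L_n = (Δt/mν) F_n,   F_n = −∇U(R_n),

so sampling the polymer at temperature T samples trajectories in proportion
to their path probability (the Onsager–Machlup action is monotone in
V_eff). Biasing the generalized end-to-end distance S = s(R_N) − s(R₁) —
the difference of a configuration-space CV at the two endpoints — stretches
polymers into reactive shapes without constraining their interior, which
relaxes toward low-action tubes.

The neural CV is a small feed-forward network ({24, 12, 1} nodes, ReLU)
trained so that, for each labelled state k, the latent batch mean μ_k and
standard deviation σ_k match prescribed targets:

    L = Σ_k [ α (μ_k − μ_k^tg)² + β (σ_k − σ_k^tg)² ],   α = 1, β = 250.

An iterative protocol ties the pieces together: (1) unbiased runs in the two
known endpoint basins train a 2-state CV; (2) a biased polymer run explores
trajectory space; (3) crumpled polymers (|S| ≤ 0.3) reveal unknown basins
via density-based clustering, elongated ones (|S| ≥ 1) supply
transition-state configurations through a 3σ latent window, and a
multi-state CV is retrained. The loop stops when a polymer connects the
endpoint basins.

Everything runs on a built-in modified Müller–Brown surface (four
anisotropic Gaussian terms; three metastable basins A, B, C; k_B = 1,
T = 0.1; highest barrier ≈ 110 k_B T), with analytic gradients and Hessians
— the polymer forces need the Hessian because L_n depends on R_n.

## Worked example

`examples/` holds one short script per capability. The free-energy
references (`examples/01_free_energy_references.py`):

```
Delta F (A -> C) by quadrature: 12.370 kBT
saddle at (-0.802, +0.671): barrier 110.3 kBT
saddle at (+0.698, +0.630): barrier 70.7 kBT
```

ΔF is the exact free-energy difference between the initial basin's region
{y > x + 1.5} and the band holding the other two basins, by log-space grid
quadrature; the barriers are minimum-to-saddle climbs in units of k_B T.

The full protocol (`examples/05_iterative_protocol.py`):

```
{'iteration': 1, 'n_samples': 1600, 'n_trapped': 1038, 'n_reactive': 236,
 'n_connecting': 0, 'n_new_states': 1, 'n_transition': 202,
 'event': 'retrained', 'n_states': 4}
{'iteration': 2, 'n_samples': 6000, 'n_trapped': 3679, 'n_reactive': 1284,
 'n_connecting': 938, 'event': 'terminated'}
terminated: True after 2 iteration(s)
```

Iteration 1 discovers the hidden intermediate basin from crumpled polymers
and harvests 202 transition-state configurations; iteration 2, run with the
refined 4-state CV and longer chains, samples 938 polymers whose endpoints
sit in A and C simultaneously, and the loop ends.

The enhanced-sampling free-energy recovery
(`examples/04_enhanced_sampling_delta_f.py`):

```
quadrature reference:       12.370 kBT
enhanced-sampling estimate: 12.36 +- 0.17 kBT  (1200000 production steps, 12 walkers)
absolute deviation:         0.01 kBT
```

Here the bias acts on a progress variable along the computed
minimum-energy path; umbrella windows and WHAM converge its free-energy
profile, the matching static bias flattens the landscape, and reweighted
region indicators recover ΔF.

A thin command line mirrors the main entry points
(`mopcv analyze --delta-f --barriers`, `mopcv simulate`, `mopcv mop`,
`mopcv train-cv`, `mopcv iterate`, `mopcv fixtures`).

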