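"""Sample whole trajectories as elastic polymers on the model surface.

A discrete Brownian trajectory of N steps is isomorphic to an N-bead
polymer whose Boltzmann weight equals the path probability; biasing the
end-to-end CV stretches polymers into reactive shapes.
"""

import numpy as np

from mopcv import (BiasConfig, MullerBrown, StateDataset, TDATargets,
                   TrainingConfig, effective_potential, relax_polymer,
                   run_mop, train_cv)

potential = MullerBrown()
rng = np.random.default_rng(3)

# a 2-state CV from tiny clouds at the A and C minima
X = np.concatenate([rng.normal([-0.52, 1.47], 0.03, (300, 2)),
                    rng.normal([0.99, 1.18], 0.03, (300, 2))])
cv = train_cv(StateDataset(X, np.repeat([0, 1], 300)),
              TDATargets.two_state(), TrainingConfig(seed=2, max_epochs=400))

beads0 = np.tile([0.99, 1.18], (96, 1))       # all beads at the C minimum
polymer = relax_polymer(beads0, potential, n_steps=10_000, rng=rng)
print(f"relaxed polymer: V_eff = {effective_potential(polymer, potential):.2f}, "
      f"bead spread = {polymer.beads.std(axis=0).round(3)}")

bias = BiasConfig(barrier=17.0, pace=25, sigma=0.02, height=0.2,
                  bias_factor=1e6)
samples, _ = run_mop(polymer, potential, cv, bias, n_steps=100_000,
                     stride=500, rng=rng)
S = np.array([s.S for s in samples])
print(f"{len(samples)} path samples; end-to-end CV range "
      f"[{S.min():+.2f}, {S.max():+.2f}]")

# Without bias the end-to-end CV stays near zero (crumpled, trapped paths);
# the adaptive bias stretches the polymer until its free end explores
# across the nearest saddle, which is how unknown basins are found.
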