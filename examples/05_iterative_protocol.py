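"""The full iterative CV-refinement loop on the three-state model surface.

Starting from unbiased data in the two known endpoint basins only, the loop
finds the hidden intermediate basin from crumpled path-polymers, harvests
transition-state configurations from elongated ones, retrains the CV, and
stops once a polymer connects the endpoints.
"""

import numpy as np

from mopcv import MullerBrown, ProtocolConfig, ProtocolSystem, run_protocol

system = ProtocolSystem(
    potential=MullerBrown(),
    initial_point=np.array([-0.52, 1.47]),   # basin A
    final_point=np.array([0.99, 1.18]),      # basin C
    seed=7,
)
state = run_protocol(system, ProtocolConfig())

for record in state.history:
    print(record)
print(f"terminated: {state.terminated} after {state.iteration} iteration(s)")
print("training states:",
      [(s.name, s.kind, len(s.data)) for s in state.states])

# Iteration 1 discovers the intermediate basin (a new 'discovered' state
# near (0.0, 0.5)) and harvests transition-state data; iteration 2, run
# with the refined 4-state CV and longer polymers, samples complete
# reactive paths between the declared basins and stops.
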