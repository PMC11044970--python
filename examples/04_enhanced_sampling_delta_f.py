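"""Recover the A-to-C free-energy difference by enhanced sampling.

Builds a progress variable along the computed minimum-energy path, converges
its free-energy profile with umbrella windows, freezes the matching bias,
and reweights region indicators from the biased production run.
"""

from mopcv.workflows import biased_delta_f, quadrature_reference

ref = quadrature_reference()
out = biased_delta_f(seed=1)

print(f"quadrature reference:       {ref:.3f} kBT")
print(f"enhanced-sampling estimate: {out['delta_f_kT']:.2f} "
      f"+- {out['stderr_kT']:.2f} kBT  "
      f"({out['n_steps']} production steps, 12 walkers)")
print(f"absolute deviation:         {abs(out['delta_f_kT'] - ref):.2f} kBT")

# Agreement within a fraction of kBT shows the biased run visits both
# basins in proportion to their true Boltzmann weights once the bias
# flattens the ~110 kBT landscape along the transition path.
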