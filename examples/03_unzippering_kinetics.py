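"""First-passage kinetics: how fast does a protofilament peel?

The mean first-passage time integral over F(Rx) (reflecting at A = 0,
absorbing at B) with the Stokes-Einstein tip diffusion coefficient
converts the landscape into unzippering velocities v_AB = 125 nm/tau_AB
and v_AC = 250 nm/tau_AC, comparable against the 0.5 um/s shrinkage
velocity of GDP microtubules.
"""

import ramshorn as rh
from ramshorn.landscape import (
    diffusion_coefficient,
    free_energy_from_distribution,
    unzippering_velocities,
)
from ramshorn.sampling import MCConfig, sample_landscape_distribution

D = diffusion_coefficient(a=40.0, eta=1e-3, temperature=298.0)
print(f"tip diffusion coefficient D = {D:.3g} nm^2/s (a = 40 nm)")

comp = rh.Composition("D" * 32)
for deltaE in (-2.0, 1.4):
    params = rh.params_from_energies(8.0, 8.0 - deltaE, rh.ModelParams(N=32))
    dist = sample_landscape_distribution(
        comp, params, MCConfig(n_steps=2_000_000, seed=7)
    )
    kin = unzippering_velocities(free_energy_from_distribution(dist), D)
    print(f"deltaE = {deltaE:+.1f} kBT: tau_AC = {kin.tau_AC:.3g} s, "
          f"v_AC = {kin.v_AC / 1000:.3g} um/s "
          f"({kin.v_AC / 500:.0f}x the 0.5 um/s reference)")
# Bending-dominated chains (deltaE < 0) unzip thousands of times faster
# than microtubules actually shrink; near the transition the landscape's
# barriers slow peeling to the experimental scale.
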