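"""Umbrella-sample the tip free-energy landscape F(Rx) and find its minima.

At deltaE = Ems - Emb = 1.2 kBT the chain is near its stability transition
and F(Rx) = -kBT ln P(Rx) develops minima that repeat on the intrinsic-
curvature scale 2*pi*rc ~ 126 nm: tubular, one-circle and two-circle
ram's-horn states.  (A few minutes of sampling; reduce n_steps for a
quicker, noisier look.)
"""

import ramshorn as rh
from ramshorn.landscape import find_minima, free_energy_from_distribution
from ramshorn.sampling import MCConfig, sample_landscape_distribution

params = rh.params_from_energies(8.0, 6.8, rh.ModelParams(N=32))
comp = rh.Composition("D" * 32)

dist = sample_landscape_distribution(
    comp, params, MCConfig(n_steps=2_000_000, seed=42)
)
land = free_energy_from_distribution(dist)

print(f"sampled {dist.n_samples} states; <Rx> = {dist.mean():.1f} nm")
print("free-energy minima (prominence >= 1 kBT):")
for rx, f in find_minima(land, prominence=1.0):
    print(f"  Rx = {rx:6.1f} nm   F = {f:5.2f} kBT")
# Expect three: near 0 (tubular), near 126 nm (one circle) and near the
# fully peeled end (~240-250 nm, two circles).
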