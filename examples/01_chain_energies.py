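"""Build the chain model and inspect its energy scales and geometry.

A GDP protofilament of N subunits (b = 8 nm each) prefers to curl with
0.4 rad per subunit; lateral springs to the microtubule wall resist that.
The straight (tubular) chain stores N*Emb of bending strain; the fully
curled chain pays N*Ems of broken lateral bonds.
"""

import numpy as np

import ramshorn as rh

params = rh.params_from_energies(Ems=8.0, Emb=7.0, base=rh.ModelParams(N=32))
comp = rh.Composition("D" * 32)

print(f"ks = {params.ks:.3f} kBT/nm^2, kb = {params.kb:.2f} kBT")
print(f"Ems = {params.Ems:.1f} kBT, Emb = {params.Emb:.1f} kBT, "
      f"deltaE = {params.deltaE:.1f} kBT")

straight = rh.build_geometry(np.zeros(32), params)
curled = rh.build_geometry(np.full(32, params.thetaD), params)

print(f"straight: Rx = {straight.Rx:.1f} nm, "
      f"E = {rh.total_energy(straight, comp, params):.1f} kBT "
      f"(= N*Emb, all bending strain)")
print(f"curled:   Rx = {curled.Rx:.1f} nm, "
      f"E = {rh.total_energy(curled, comp, params):.1f} kBT "
      f"(= N*Ems, all lateral bonds broken)")
print(f"peeled subunits in the curled state: Nc = {curled.Nc} "
      f"(Lc = {curled.Lc:.0f} nm)")
# The curled tip follows a circle of radius rc = b/thetaD = 20 nm: one full
# turn of that circle is 2*pi*rc ~ 126 nm, the repeat length of the
# free-energy minima seen in the landscape example.
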