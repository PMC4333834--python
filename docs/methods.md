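# Methods

## Model

A protofilament (PF) is a planar chain of N rigid subunits of length
b = 8 nm, clamped at the minus end along the microtubule axis (+x). Its
conformation is the set of bond angles {θᵢ}: θ₀ is the clamp angle of
subunit 1 against the wall direction and θᵢ (i ≥ 1) the relative angle
between subunits i and i+1. Node k (the distal end of subunit k) sits at
node k−1 plus b·(cos Θₖ, sin Θₖ) with Θₖ the cumulative angle.

Each bond carries a bending energy kᵇ(1 − cos(θᵢ − θᵢ°)) with the
preferred angle set by the nucleotide of the subunit on its plus side:
θᴰ = 0.4 rad for GDP, θᵀ = 0 for GTP. Each subunit is attached to the
rigid neighbor through a breakable spring: the distal node of subunit i
bonds to the fixed site (i·b, −l°), so the straight chain has every bond
exactly at its rest length l° = 6.5 nm, and curling away from the wall
(+y) stretches the bonds. The spring is harmonic, ½kˢ(lᵢ − l°)², up to
l_max = 1.2 l°, and constant (Eₘₛ) beyond — broken bonds re-form freely
because the energy is history-free. Energies are expressed in k_BT at the
reference temperature; a dimensionless temperature factor scales the
simulation temperature (→0 recovers the quenched two-state limit).

Parameter conversions: kˢ = 2Eₘₛ/(l_max − l°)², kᵇ = Eₘᵦ/(1 − cos θᴰ).
The defaults Eₘₛ = 8 k_BT, Eₘᵦ = 7 k_BT give kˢ ≈ 9.47 k_BT/nm² and
kᵇ ≈ 88.7 k_BT; the reaction coordinate is the tip excursion
Rx = L − x_N ∈ [0, 2L].

Two consequences of the clamp convention are worth noting. The clamp bond
still carries a bending term, so the straight all-GDP chain stores exactly
N·Eₘᵦ; but subunit 1 itself never peels, so the fully-bound/fully-peeled
energy gap is (N−1)·ΔE. And the all-curled chain is an inscribed polygon
of circumradius b/(2 sin(θᴰ/2)) = 20.07 nm rather than the continuum arc
radius r_c = b/θᴰ = 20 nm; the discrete tip therefore matches the
continuum relation Rx⁰(L_c) = L_c − r_c sin(L_c/r_c) to ~0.15 nm only
after the θᴰ/2 phase correction, and to a few nm otherwise. All landscape
comparisons in this package use tolerances far above that discretization
scale.

## Sampling

Moves are pivots: one free bond angle (j ≥ 1) is incremented by a uniform
draw in ±1.5 rad and all distal subunits rotate rigidly; acceptance is
standard Metropolis, min(1, e^{−βΔE}). Acceptance rates at the default
parameters are a few percent. Energy changes are evaluated incrementally
(one bending term plus the downstream lateral terms), and the inner loop
is a numba kernel (~0.5 µs/step), which is what makes desk-scale budgets
of 10⁶–10⁷ steps per window practical; the reference study used ~10¹⁰
steps. Histograms accumulate every post-burn-in step (default burn-in 10%,
trace thinning every 100 steps, 2 nm bins).

Direct Metropolis mixes poorly in the bistable transition zone at these
budgets, so landscapes are produced by umbrella sampling: harmonic windows
½k_b(Rx − c)² every 10 nm with k_b = 0.05 k_BT/nm², each initialized from
a peeled-arc configuration near its center and given an independent child
seed (numpy SeedSequence). Windows are recombined by standard
self-consistent histogram reweighting (WHAM) iterated until the window
free-energy shifts change by <10⁻⁸ k_BT, with an explicit connectivity
check that adjacent windows share occupied bins. The reference study used
a modified energy-paving weight scheme for the same purpose; harmonic
windows + WHAM is this package's equivalent, and the two estimates here
(WHAM vs long direct Metropolis at ΔE = 1.2) agree to ~0.1 k_BT RMS.
⟨Rx⟩-versus-ΔE transition curves default to the umbrella estimator for
the same reason; the direct estimator remains available.

## Landscape and kinetics

F = −ln P on occupied bins, min-shifted to zero, cubic-spline
interpolated, with evaluation outside the sampled support an error (never
extrapolation). Minima are detected on a 4 nm Gaussian-smoothed copy with
a 1 k_BT prominence threshold; boundary bins may count as minima. The mean
first-passage time from A (reflecting) to B (absorbing) is evaluated on a
dense grid of the spline by one cumulative-trapezoid pass (the
Fubini-swapped form of the double integral), mean-shifted against
overflow; it is exact to <10⁻³ relative on closed-form cases and invariant
to additive constants. The tip diffusion coefficient is Stokes–Einstein
with a = 40 nm (the size of one curled circle; a conservative lower
bound), η = 10⁻³ Pa·s, T = 298 K, giving D ≈ 5.46×10⁶ nm²/s. Pulling
forces tilt the landscape, F(Rx, f) = F(Rx, 0) + f·Rx, with
1 k_BT/nm ≈ 4.114 pN at 298 K.

## Shrinkage dynamics

Euler–Maruyama integration of dRx = −D F′(Rx) dt + √(2D dt) ξ with
dt = 10⁻⁷ s, mirror reflection at both support ends, and a start-time
check that drift per step stays below one histogram bin. Dissociation is a
Poisson process with rate k_off per step while Rx exceeds the gate
rx_gate = b = 8 nm ("no dissociation from the tubular state"); each event
removes one subunit and remaps the tip by shortening the peeled arc
through the zero-temperature relation, L_c ↦ L_c − b, Rx ↦ Rx⁰(L_c − b) —
switching to a same-shaped, shorter landscape without resampling. The
defaults k_off = 75 s⁻¹ (so that b·k_off = 0.6 µm/s brackets the
experimental shrinkage scale) and the geometric factor l_d = 1 are
explicit tunables surfaced in every report, not fitted values. The
observable length ℒ(t) = ℒ(0) − Rx·l_d − b·N_d holds exactly at every
recorded sample by construction. Ram's-horn statistics (Tu, Nu) count
maximal excursions of Rx above 10 nm, with excursions or gaps shorter than
10 recorded samples merged as integrator chatter; zero excursions report
Tu as missing, not zero.

## Three protofilaments

Three chains, each confined to the plane spanned by the tube axis and its
own radial direction (planes at 120°), springing from an equilateral
cross-section of side l° so the straight tube has zero lateral energy
(tube radius l°/√3). Lateral bond i of seam α connects node i of PF α to
node i of PF α+1 (cyclic) through the full 3-D distance; bending is
in-plane and identical to the single-PF model. Only bendable PFs are
moved; frozen PFs stay bit-identical. With 4 k_BT per bond, the effective
lateral energy per bendable PF is 8, 6, 4 k_BT for p = 1, 2, 3 bendable
PFs (two private bonds; three bonds shared by two; three shared by three).

Destabilization thresholds (smallest Eₘᵦ with ⟨Rx⟩ ≥ L/2 at L = 15b)
are found by bisection to ±0.25 k_BT. Near the threshold the finite-budget
Metropolis estimate is hysteretic, so each ⟨Rx⟩ is the average of two
replicas started from the straight and the fully peeled configurations;
away from the threshold the two starts agree and the average is the
converged value.

## Semi-analytic reference

P(Rx) ≈ Σ_{N_c} e^{−ΔE·N_c} 𝒩(Rx; Rx⁰(N_c b), σ(N_c)) with exact
per-bin Gaussian mass (erf differences) so that the σ→0 limit degenerates
cleanly to atoms. σ(N_c) = σ₀√N_c with σ₀ = 2 nm by default — thermal
width grows with peeled length; only peak positions, not widths, are
quantitative. Because the weights carry only the energy bias (not the
peeled-segment entropy), this reference reproduces peak positions and the
fold pile-up near 2πr_c, but not the depth of the sampled minima.

## Configuration and reproducibility

One YAML config drives the pipeline (sample → landscape → kinetics →
dynamics); every run writes a resolved-config snapshot, stage
subdirectories, and a manifest of output checksums. A single global seed
expands to per-stage and per-window child seeds by fixed offsets, so
reruns are bit-identical and partial reruns agree with full ones. All
tables are TSV with unit-suffixed columns; summaries are JSON;
conformations export as XYZ text.

## Scales used in the shipped checks

The test suite and the acceptance script run at desk scale, chosen as the
smallest budgets at which the split checks above (WHAM vs direct,
two-start threshold replicas, seed-to-seed scatter) converge: 10⁶–4×10⁶
steps per umbrella window (27 windows for N = 32, 15 for N = 19), 12–20
Langevin trajectories of 0.5–1 s at dt = 10⁻⁷ s, and 4×10⁶-step 3-PF
runs per bisection point. At these scales the landscape minima positions
are stable to ~2 nm and threshold estimates to ~0.25 k_BT between seeds.

## Known limitations

* Polymerization, rescue and re-attachment are out of scope; the model
  only shrinks.
* The single-PF model's rigid neighbor ignores correlated neighbor
  fluctuations; the 3-PF model restores them only for a triangular
  mini-tube, not the 13-PF lattice with seam and helical offsets.
* Lateral springs attach at single points per subunit; alternative
  potential shapes (Lennard-Jones/Morse) and quadratic bending are
  equivalent in spirit but not implemented.
* The dissociation rate and the geometric factor l_d are order-of-
  magnitude tunables, not measured constants; conclusions that depend on
  their precise values should sweep them.
* Synthetic landscapes used by the oracle tests (flat, cosine, tilted
  wells) emulate the shape but not the sampling noise of real landscapes;
  passing those tests validates the integrators and estimators, not the
  convergence of any particular Monte Carlo run.
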