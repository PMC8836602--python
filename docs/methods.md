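# Methods

## The two-state EVB model

The rate-limiting hydride abstraction is described by two diabatic valence
states. State 1 is the reactant pair (neutral substrate, oxidized flavin);
state 2 is the product pair after the α-CH hydrogen has transferred to the
flavin N5 as a hydride — a charge-separated configuration whose stability is
strongly environment-dependent. Each state carries a classical potential
over two dynamical coordinates:

* `r` — donor–hydride distance (Å), mass 1 amu;
* `s` — a dimensionless collective solvent coordinate, mass 10 amu;

with the donor–acceptor distance fixed at R = 2.6 Å. Per state the potential
is a Morse well for the state's own bond (C–H in state 1 along `r`; N5–H in
state 2 along `R − r`; D = 90 kcal/mol, β = 3 Å⁻¹, r₀ = 1.09 / 1.03 Å), an
r⁻¹² repulsion against the opposite heavy site (0.02 kcal Å¹²/mol), a
harmonic solvent term ½k(s − s_eq)², the calibrated gas shift α (state 2
only), a static environment shift (state 2 only), and an optional
transition-state-region well added identically to both states (below). The
ground-state surface is the lower 2×2 EVB eigenvalue with constant coupling
H12 (a distance-decaying variant exists but defaults off — the standard
choice absent evidence for a particular functional form). These reduced
functional forms are the minimal set producing two wells and a barrier along
the energy-gap coordinate; they stand in for a full force field.

Units are kcal/mol, Å, amu, fs, elementary charge, Debye throughout;
kB = 1.987204×10⁻³ kcal/(mol K); the Eyring prefactor uses CODATA kB/h.

## Sampling protocol

FEP mapping: εₘ = (1−λ)ε₁ + λε₂ over 51 uniformly spaced windows
(Δλ = 0.02). Each window runs 20,000 BAOAB Langevin steps of 0.5 fs (10 ps)
at 300 K with friction 1 ps⁻¹, recording every 10th step and discarding the
first 10 % of recorded samples; this is the desk-scale image of a
100 ps/window protocol, chosen so a full 51-window, 10-replica run finishes
in seconds while the profile estimator stays converged on this surface
(checked against dense-grid integration, below). Equilibration at λ = 0 runs
50,000 steps by default. Ten replicas start from the shared equilibrated
configuration with Maxwell–Boltzmann-redrawn velocities and a short
relaxation (2,000 steps); the reported quantity is the replica mean with
SEM = sd/√10. Weak harmonic restraints (0.5 kcal/(mol Å²)) tether `r` at the
midpoint between the bond minima — across the ~0.5 Å well separation this
biases energies by ~0.01 kcal/mol — and, in the gas phase only, tether the
otherwise decoupled `s` at zero. All randomness derives from one base seed
via `SeedSequence` spawn keys (equilibration, per-replica velocities, per
(replica, window) noise), so a run is bit-reproducible; derived seeds stay
below 2³¹.

The BAOAB inner loop is JIT-compiled with numba; energies of recorded
configurations are re-evaluated vectorized in the plain-Python energy model,
so the integrator and the energy/estimator paths stay independently
testable (forces are checked against finite differences of the energies).

## Free-energy estimation

Window-to-window increments use the Zwanzig formula evaluated with
log-sum-exp, averaged bidirectionally (forward/backward), and accumulated
into ΔG(λ) with ΔG(0) = 0. Profiles along Δε = ε₁ − ε₂ use the standard EVB
umbrella decomposition: per window and bin,
ΔG(bin) = ΔG_FEP(λ) − kBT ln⟨1{Δε∈bin} e^{−(Eg−εₘ)/kBT}⟩, combined across
windows weighted by bin sample count. Defaults: 50 bins over the sampled gap
range, bins under 10 samples excluded rather than extrapolated (declared
choices; common post-processing practice). The transition state is the
highest bin with a strictly lower bin on each side (first bin on ties —
a determinism tie-break); the reactant/product minima are the lowest bins on
either side, and the reactant minimum is shifted to zero, matching how
barriers are quoted. Pooling frames from several replicas is supported; each
replica's windows are anchored by its own FEP curve.

On systems where dense-grid Boltzmann integration over the adiabatic
surface is tractable, the 10-replica FEP estimate agrees with the grid to
well under 0.2 kcal/mol (test-enforced); the grid oracle in the test suite
re-implements the energies term by term and never calls the estimator code.

## Calibration

The gas shift α and coupling H12 are fitted so the gas-phase profile
reproduces reference activation and reaction free energies, by damped Newton
iteration (steps clipped to 2 kcal/mol per parameter) on a finite-difference
Jacobian estimated once under common random numbers. Near the solution
∂ΔG°/∂α ≈ 1 and ∂ΔG‡/∂H12 < 0, so the 2×2 system is well-conditioned.
Iterations keep the full window length but use a thinned replica batch (3);
once that converges the iteration continues on the full 10-replica
objective, whose converged residual doubles as the confirmation run
(tolerance 0.1 kcal/mol in the pipeline default, 0.15 at the API default).
Window length is *not* shortened during iterations because the FEP protocol
carries a length-dependent hysteresis bias (~0.4 kcal/mol at half length on
this surface); thinning replicas preserves the bias exactly and only raises
noise, so the fitted parameters transfer consistently to the production
protocol.

Reference gas-phase targets are plain configuration values
(`REFERENCE_GAS_TARGETS`): HIS (ΔG‡ 33.00, ΔG° 25.00) and NMH (31.94,
25.00) kcal/mol, encoding a 1.06 kcal/mol barrier advantage for NMH and a
strongly endergonic gas-phase step of ~25 kcal/mol for both substrates, with
the absolute barrier anchored ~12 kcal/mol above the aqueous one. Once
calibrated, (α, H12) are frozen for all condensed-phase runs.

## Environment surrogates

The gas/water/enzyme environments are calibrated stand-ins: they encode the
statistical structure of the analysis, not predictive physics. Their
committed default strengths were tuned once against the deterministic grid
reference so the pipeline's corrected barriers land near the published
pattern, and are configuration, not fit output.

* **Water.** The charge-separated state 2 is stabilized statically by a bulk
  dielectric term (13.934 kcal/mol) plus a per-water term (1.389 kcal/mol ×
  hydration mean: 6 waters for HIS, 4 for NMH — the "two more waters around
  HIS" statistic), and couples to the solvent coordinate (k = 1.5, s_eq
  displaced by 2.0 → solvent reorganization ≈ 3 kcal/mol). Because the
  dipole of the reacting moiety peaks at the transition state, solvation
  bites hardest there: a Gaussian well in `r` (depth 0.263 kcal/mol per
  water, width 0.08 Å, centered at the diabatic crossing) is added to *both*
  states, lowering the transition-state region without touching the gap
  coordinate or the reaction free energy.
* **Enzyme.** A preorganized electrostatic field stabilizes state 2 by
  32.556 kcal/mol, attenuated by 3 % per local water (3 waters for HIS, 2
  for NMH — less shielding for NMH); nonpolar contacts add a
  transition-state-region well of 0.152 kcal/mol per contact at its
  transition-state count (4 + 0.5 for HIS, 6 + 1.5 for NMH). Solvent
  reorganization is smaller than in water (displacement 1.2), reflecting
  preorganization.

With these defaults the pipeline reproduces the published pattern: gas
barriers ~33.0/31.9 (NMH lower by ~1.06), corrected water barriers
~24.2/24.8 (HIS lower by ~0.6), corrected enzyme barriers ~21.0/19.0
(NMH lower by ~2), enzyme rate advantage ~30×, replica SEM ≤ 0.1.

One declared asymmetry: with equal gas-phase reaction free energies for both
substrates, the differential hydration stabilization that flips the water
barriers necessarily separates the water endpoints — the HIS surrogate ends
at ΔG° ≈ 3 kcal/mol (the reported near-thermoneutral value) while NMH lands
near 6. The alternative, unequal gas references, would have moved the
asymmetry into numbers this model treats as external inputs.

## Descriptors and the synthetic ensembles

Water counting uses oxygen sites within 3.5 Å (inclusive) of any solute
heavy site; hydrophobic contacts use 4.5 Å — conventional first-shell and
van-der-Waals ranges, declared here because no counting criterion is
standard. Dipoles are |Σqᵢrᵢ|·4.80320 D/(e Å); for charged sets the origin
is the center of absolute charge (declared convention; neutral sets are
origin-independent). The HIS/NMH solute templates are rough planar-imidazole
plus ethylamine-chain geometries (NMH adds the ring methyl, its one extra
heavy site); reactant and transition-state charge patterns are scaled at
construction so the computed dipoles hit 8.9 → 12.8 D (HIS) and 9.4 → 13.4 D
(NMH) exactly — the patterns set the direction, the targets set the scale.

Descriptor ensembles draw per-snapshot water counts as Poisson around the
environment's hydration mean (placed in the 2.4–3.5 Å shell, plus a few
far-field waters beyond the cutoff so the counting operator actually
selects) and contact counts as Poisson around the contact mean, raised by
the transition-state increment in TS-labeled snapshots. They emulate the
counting statistics of trajectory snapshots and nothing else: no excluded
volume, no water–water structure, no correlation between frames. Passing
count tests therefore validates the bookkeeping and the configured means,
not hydration physics.

## What the surrogates do not capture

No all-atom protein or solvent, no periodic boundaries or Ewald
electrostatics, no docking or crystal-structure input, no active-site pKa
shifts (aqueous pKa values 9.75/9.57 are used unchanged, with the
2.303 kBT (pKa − pH) correction applied to water and enzyme barriers at
pH 7.4, 300 K), no tunneling or kinetic isotope effects (TST with
transmission coefficient 1), and no binding thermodynamics (Km is outside
scope). The printed corrections 3.20/2.95 kcal/mol correspond to the formula
within 0.03 at 300 K (the formula gives 3.23/2.98); tests carry a ±0.05
tolerance for this rounding/temperature convention rather than absorbing it
silently.

## Numerical choices and degenerate inputs

Exponential averages are evaluated by log-sum-exp (overflow-safe; exact for
constant perturbations). Divergent dynamics (energies beyond 10⁵ kcal/mol or
non-finite coordinates) abort the replica with a window diagnostic; fewer
than two surviving replicas is a hard error. Profiles with no resolvable
two-well structure (constant gap, all bins under the count threshold, or no
interior maximum) raise an explicit unconverged-profile error. Restraint
sets may stack several harmonics on one coordinate (they combine exactly).
Configuration files are schema-validated with unknown keys rejected by key
path; every output artifact carries the producing version and configuration
hash, and the YAML manifest suffices to re-run any stage bit-identically.
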