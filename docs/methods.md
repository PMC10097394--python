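# Methods

`permeapoly` estimates the quantities that govern gas separation in dense
polymer membranes under the solution-diffusion model, and reduces
pressure-decay sorption experiments to the same quantities so that
simulation and experiment can be compared on one footing.  This note
records the models implemented, the defaults and why, the numerical
choices, and what the synthetic-data validation does and does not show.

## Solution-diffusion framework

Permeability factorises into a thermodynamic and a kinetic coefficient,

    P_i = D_i · S_i,        α_ij = P_i/P_j = (D_i/D_j)(S_i/S_j) = α^D α^S.

Both identities hold *exactly* for every `TransportRecord` the package
builds — they are definitions, not fits.  S is the Henry-law solubility
coefficient (mol kg⁻¹ bar⁻¹, molar basis for selectivities), D the
penetrant self-diffusivity (cm²/s).  Barrer conversion uses
1 Barrer = 10⁻¹⁰ cm³(STP)·cm·cm⁻²·s⁻¹·cmHg⁻¹ = 3.347×10⁻¹⁶ mol·m⁻¹·s⁻¹·Pa⁻¹
(with 22 413.97 cm³/mol STP) and requires the polymer density.

## Widom insertion (solubility)

The excess chemical potential of a penetrant at infinite dilution is
estimated by ghost insertions into host configurations:

    μ_ex = −RT ln ⟨exp(−ΔU/RT)⟩,
    S    = [1/(ρRT)] exp(−μ_ex/RT)   (mol kg⁻¹ Pa⁻¹; ×10⁵ → per bar).

Conventions and their rationale:

- The sign/placement convention reduces to the ideal Henry limit
  S = 1/(ρRT) at μ_ex = 0 and makes favourable insertion (μ_ex < 0)
  *raise* solubility.
- Insertions are pooled across frames; when frame volumes differ (NPT
  snapshots) the volume-weighted estimator ⟨V e^{−βΔU}⟩/⟨V⟩ is used.
- The infinite-dilution limit is realised strictly: the host never
  contains the penetrant.
- CH₄ defaults to a single united-atom site; CO₂ to a rigid linear
  3-site model (C central, O at ±1.16 Å) with orientations drawn
  uniformly over SO(3) via random rotations.
- Uncertainty is the standard error over ≥10 contiguous insertion
  blocks, propagated to μ and S by the delta method.  A Boltzmann
  average that underflows to zero (fully blocked host) raises an
  explicit "no accessible volume" error rather than returning −∞.

Validated against: the exact μ_ex = 0 ideal-gas limit; the analytic
excluded-volume result −RT ln(1 − v_excl/V) for a hard-sphere host at
10⁶ insertions; and the virial expansion βμ_ex = 2ρB₂(T) for a dilute
Lennard-Jones fluid, with B₂ computed by quadrature of the Mayer
integral of the *same truncated* potential.  At ρ* = 0.05 the neglected
O(ρ²) term contributes ~3%, which the observed 3–5% agreement reflects.

## Einstein-relation diffusivity

MSD(τ) is averaged over molecules (mass-weighted centres of mass) and
over multiple time origins; the origin stride defaults to 1 frame
(maximal averaging — origins are then correlated, which inflates the
naive fit SE; documented, not corrected).  Wrapped coordinates without
image flags are refused outright: silent unwrapping failures corrupt
MSDs far more subtly than a hard error.

The Fickian window is the longest contiguous lag range with
d log MSD/d log τ ∈ 1 ± 0.1 (tolerance exposed), excluding the final 30%
of lags where origin statistics degrade.  D = slope/6 of a weighted
least-squares line (weights = origin counts, free intercept) over that
window, converted Å²/ps → cm²/s (×10⁻⁴).  Window selection is not
specified by any standard; the log-log-slope criterion is this package's
choice and is stress-tested on ballistic, Brownian and crossover series.

## Structure: g(r), S(q), FFV, ASA

g(r) is the shell-normalised pair histogram under minimum image
(self-pairs excluded; r_max ≤ L/2).  Partial structure factors are
Fourier transforms of g−1 with a Lorch window by default (r-space
truncation at L/2 otherwise produces ripple that can shift apparent peak
positions by ~0.05–0.1 Å⁻¹ on 30–50 Å boxes); Faber–Ziman weighting with
the four-Gaussian crystallographic form factors (f(0) = Z) builds the
X-ray total, and qS(q) is emitted for locating the amorphous halo.
q ↔ 2θ conversion defaults to Cu Kα (1.5406 Å), overridable — the
wavelength convention behind published halo angles is often unstated.

Note on validation: the Debye double sum over a *non-periodic*
configuration differs from the FT-of-g route by the periodic-image
convention; equivalence is asserted against the consistent oracle
(minimum-image distances, same truncation and window), where agreement
is <0.02 absolute.

FFV is the Monte-Carlo fraction of uniform points farther than
(atom radius + probe radius) from every atom (Bondi radii by default,
probe 0 Å by default); ASA is Shrake–Rupley-style sphere-point sampling.
Both are exact in expectation and carry binomial error bars.

## Reduced energy model

A nonbonded-only evaluator (12-6 or 9-6 LJ plus truncated Coulomb,
Lorentz–Berthelot or sixth-power combining, cutoff with optional
analytic tail correction) backs the insertion and cohesive-energy
pipelines.  There are no bonded terms: "intramolecular" means same-chain
membership, and isolated-chain energies are computed without periodic
images.  Cohesive energy is

    E_coh = Σ_chains E(chain alone) − E(box),
    CED [MPa] = E_coh [kJ/mol] / V [cm³/mol] × 10³,   δ = √CED.

Truncated minimum-image Coulomb is adequate for the near-neutral reduced
systems targeted here; it is not an Ewald substitute for strongly
charged systems, and δ values for real polymer melts additionally
require equilibrated atomistic configurations that this package does not
generate.

## Pressure-decay sorption reduction

Uptake follows from the closed-cell mass balance
n(t) = V[p(0) − p(t)]/(zRT) with z = 1 or a second-virial correction.
Henry solubility is the zero-intercept slope of the equilibrium
isotherm, with a residual-based nonlinearity flag.  Kinetics fit the
Fickian slab solutions for a film of thickness ℓ with both faces
exposed:

- infinite reservoir: M/M∞ = 1 − Σ 8/((2n+1)²π²) exp(−(2n+1)²π²Dt/ℓ²);
- finite reservoir (default): Crank's limited-volume solution with root
  equation tan(q_n) = −α q_n on half-thickness ℓ/2, where the
  gas-to-sample capacity ratio α is inferred from the equilibrium
  pressure drop (absorbed fraction f ⇒ α = (1−f)/f).  This captures the
  decaying interfacial concentration of a closed cell and reduces to the
  first form as α → ∞ (verified numerically to 10⁻⁵).

Numerical choices: series terms are added until the increment falls
below 10⁻¹⁰ (minimum 50 terms); roots come from bracketed Brent solves
on ((n−½)π, nπ); M(0) = 0 is imposed exactly (the truncated series
leaves a small residue at t = 0); D is fitted in log₁₀ by
Levenberg–Marquardt.  M∞ is estimated from the tail average of the
uptake trace and its uncertainty is propagated into the reported SE by a
refit at M∞ + SE — without this the SE conditions on a noisy
normalisation and under-covers.  The monotonicity data-quality gate uses
a family-wise (~1%) threshold over all consecutive pairs so that pure
measurement noise on long traces does not false-trigger the leak check.

Crystallinity enters through the two-phase model — crystals neither sorb
nor swell — so S_am = S_sc/(1 − X_c).  The factor is gas-independent,
hence α^S is invariant under it (asserted).  No tortuosity correction is
applied to D: the geometric effect of crystals on the diffusive path
depends on crystal shape and distribution and is not captured by an
additive rule.

## Synthetic data: what passing tests show

Every estimator is validated against a generator whose truth is known:

| generator | truth | validates |
|---|---|---|
| ideal-gas frames | g = 1, S(q) = 1, μ_ex = 0 | RDF/S(q)/Widom normalisation |
| hard-sphere host | −RT ln(1 − v/V) | Widom estimator + block errors |
| LJ-fluid MC (Metropolis NVT, σ=ε=1, ρ*=0.05, T*=1.5) | virial expansion | Widom & pressure routes |
| Brownian walkers (N=100, 10⁴ frames, D=0.5 Å²/ps) | prescribed D | MSD → Einstein D |
| sc/fcc lattices | geometry | RDF peaks, coordination, S(q) peaks |
| pressure-decay traces (ℓ=19 µm, Crank kinetics + Henry balance) | prescribed (S, D) | sorption reduction |

Generator defaults mirror the study conditions they emulate (film
thickness 19 µm, crystallinity 0.42, 35 °C, ~10⁶ insertions, 5×150-mer
chains at ~1.18 g/cm³).  What passing does **not** show: these toy
ensembles share none of the physics of semicrystalline polyester melts —
no chain connectivity effects, no glassy dynamics, no specific
CO₂–carbonyl interactions, no crystallites.  They validate the
*estimators*, not polymer predictions; producing equilibrated melts is
explicitly delegated to external MD engines, and headline melt
properties (densities, δ, amorphous-halo positions, absolute
solubilities) are out of the package's validation scope.

## Known limitations

- Builder boxes are random-coil walks with no excluded volume or
  equilibration — pipeline fixtures only.
- Electrostatics are cutoff-truncated; no Ewald/pppm.
- Single-origin-stride SE inflation for correlated MSD origins is
  documented, not corrected.
- Dual-mode (glassy) sorption and concentration-dependent diffusivity
  are out of scope; Henry behaviour is assumed above T_g.
- The finite-reservoir boundary condition is Crank's well-stirred
  limited bath; apparatus-specific variants may differ in detail.
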