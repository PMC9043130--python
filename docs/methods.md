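# Methods

## The physical model

A permeant crossing a channel is modelled as one-dimensional overdamped
diffusion along the pore axis z: a free-energy profile w(z) (kcal/mol,
zeroed in bulk), a position-dependent diffusion coefficient D(z) (Å²/ps),
and a lateral flat-bottom restraint of radius r (Å) that confines the
particle to a cylinder in the bulk.  The restraint defines the effective
bulk concentration (one particle in the restrained volume), which is what
lets equilibrium crossing statistics be converted to the concentration-
independent single-channel permeability P (cm³/s).

Internally everything is Å / ps / kcal·mol⁻¹ / elementary charge; SI, eV,
pS, pA, mol/L and cm³/s appear only at API boundaries (1 Å³/ps ≡ 1e-12
cm³/s exactly).  Constants are CODATA 2018.

## The three permeability routes

**ISD.**  `P = πr²/∫_{z1}^{z2} e^{βw}/D dz` with [z1, z2] the pore interval
beyond which w is at its bulk value.  Quadrature is trapezoidal on the PMF
grid with D interpolated linearly onto it; a 100× finer Riemann oracle in
the tests bounds the quadrature error well below 0.1%.  β-exponentials are
computed with the grid maximum shifted out, so multi-kcal/mol barriers
cannot overflow.  The integrand e^{βw}/D is exposed as a local-resistance
profile whose running integral is 1/P(z).

**MFPT.**  The Smoluchowski mean first-passage time
`⟨t⟩ = ∫_{z1}^{z2} dz e^{βw}/D ∫_{a}^{z} dz' e^{−βw}` (reflecting at a,
absorbing at z2; a = z1 unless a bulk region sits behind the start) is
implemented by nested trapezoids, and
`P = πr² ∫ e^{−βw} dz / (2⟨t⟩)`.  For a flat profile the two routes are an
exact identity (asserted to machine precision); for a dominant symmetric
barrier they agree to within ~25%, which is the validity regime of the
factor-2 reduction — this is asserted as a property, not an identity,
because the reduction's assumptions are not exact for finite barriers.

**Flux/GHK.**  Currents from voltage runs are measured two ways: a
lower→inner→upper state machine over region labels (+1/−1 per completed
sequence; a direct side-to-side jump, e.g. a periodic wrap, emits nothing),
and the charge-displacement estimator Σ q_i Δz_i/(Δt·L) on unwrapped
coordinates, clipped to the pore by a midpoint test.  The unitary
conductance is the OLS slope of I on V with a free intercept (reported as a
symmetry diagnostic), and `P = γ k_BT/(q²C)` converts it at symmetric
concentration.  Boundary samples are assigned to the inner region, making
the state machine deterministic under ties.

## The trajectory generator

The Euler–Maruyama update
`z ← z + [βD(z)F(z) + D'(z)]dt + sqrt(2D(z)dt)·ξ` uses the Itô convention
with the explicit spurious-drift term D'(z); without it the stationary law
with non-constant D would not be Boltzmann (a test with sinusoidal D
asserts Kolmogorov–Smirnov distance < 0.05 against e^{−βw}).  Forces, D and
D' are tabulated on a 0.005 Å grid (analytic forms evaluated there; cubic
splines for tabulated ones) and linearly interpolated in a compiled kernel.
Reflecting boundaries mirror the position; absorbing boundaries terminate
first-passage replicas; periodic wrap intervals track wrap counts so
displacements can be unwrapped.  All noise comes from one numpy generator
per replica, seeded as SeedSequence([seed, replica]) — ensembles are
reproducible and kernels contain no RNG state.

Default dt = 0.01 ps keeps the rms step sqrt(2·D·dt) below a tenth of the
narrowest potential feature used in the fixtures; replicas that exhaust a
step budget are returned censored, never silently truncated.

The generator emulates restrained-MD collective-variable output: a scalar
coordinate at a fixed stride under harmonic (umbrella), flat-bottom
(milestoning cell) or constant-field (voltage) biasing.  What it does not
emulate: inertial/memory effects, 3-D excursions, solvent and ion-ion
interactions, or force-field error.  Passing tests therefore validate the
*estimators* under the diffusion model's own assumptions; they cannot
certify those assumptions for any particular real channel.

## PMF and D(z) estimation

Umbrella windows are reweighted by self-consistent binned WHAM (bin width
0.2 Å by default): window free energies f_i and unbiased bin weights are
iterated until the largest f-change is below tolerance, via log-sum-exp.
For 1-D binned data this agrees with MBAR-style estimators to within bin
discretization.  Coverage is checked (an empty bin strictly inside the
sampled span raises, naming the gap), and error bars come from contiguous
block halves rather than an analytic covariance — estimator-agnostic and
honest about time correlation.  The profile is offset so the bulk-region
mean is zero; without a declared bulk region the minimum is zeroed.

D(z) per window is ⟨δz²⟩/τ, with τ the integral of the normalized
positional autocovariance: summed from lag 0 at the recording stride,
truncated at the first lag where it drops below 0.01 or crosses zero
(integrating the noisy tail diverges; the truncation rule is ours and is
stated rather than inferred).  The autocovariance uses FFT evaluation of
the exact lag sums with unbiased (n−lag) normalization.  For an
Ornstein–Uhlenbeck window this reduces to τ = variance/D exactly, which is
the closed form the tests recover.  The estimator is stride-robust while
the stride stays below τ/10 (asserted), and an optional symmetrization
averages D(z) with D(−z) for symmetric channels.

## Milestoning

M cells are defined by M+1 edges; the M−1 interior edges are milestones.
Event detection is sample-based: a hit is a pair of consecutive samples
straddling an edge, or a sample landing exactly on it; a frame jumping both
edges registers hits in spatial order.  Time before the first hit of each
cell trajectory is burn-in and discarded.  Residence fractions r_i(j),
transition rates n_i(j→k) and attempted-escape rates are all normalized by
*in-cell* time — soft-wall excursion frames beyond an edge belong to the
neighboring cell's territory, and counting them here demonstrably biases
the equilibrium solve (cells whose surroundings are downhill accumulate
phantom weight).  Attempted escapes count one per contiguous excursion.

π solves the escape-rate balance (null space of the cell-rate generator,
with irreducibility checked edge by edge); the milestone rate matrix is
`q_{ij,ik} = π_i n_i(j→k) / (π_i r_i(j) + π_j r_j(j))`, the denominator
being the total stationary residence weight on the source milestone from
both adjacent cells.  MFPT profiles solve (Q restricted)·t = −1 per
absorbing target; the inward direction reverses the milestone order.
Uncertainties come from a block bootstrap: per-cell statistics are computed
on contiguous blocks, resampled with replacement, and the full π→Q→MFPT
pipeline is rebuilt per replicate.

Two known finite-stride biases matter and are characterised by the
`stride_sensitivity` tool rather than hidden: (i) mid-cell micro-touches of
a milestone between samples are missed, inflating holding times by roughly
(rms frame step)/(cell width); (ii) with stiff confining walls the wall-
excursion time k_BT/(k·D) can drop below the recording stride, so boundary
recrossings are missed wholesale.  The validation fixtures therefore use
soft walls of k = 10 kcal/mol/Å² and a 0.2 ps stride, for which wall
excursions (~3 ps at D = 0.02 Å²/ps) are well resolved; the stride-scan
fixture deliberately uses the stiff k = 100 kcal/mol/Å² protocol whose
recording-frequency sensitivity it measures (at 5 ps recording the MFPT
inflates by well over 20% while 0.2 and 0.5 ps agree within 5%).

## Fixture conditions (the package's chosen study conditions)

The canonical channel: Gaussian barrier of 4 kcal/mol (σ = 2.5 Å) at 300 K,
D = 0.02 Å²/ps, pore [−10, 10] Å inside a [−12, 12] Å domain, bulk restraint
radius 6 Å.  Umbrella sampling: 13 windows 2 Å apart, k = 2.5 kcal/mol/Å²,
40 ns-equivalent per window at 0.5 ps stride.  Diffusion-recovery windows:
200 ns each, so the τ-estimator's relative standard error (≈ sqrt(4τ/T))
sits near 1.5%, well inside the 10% recovery band.  Milestoning: 12 cells
of 2 Å, 400 ns-equivalent per cell at 0.2 ps stride.  Voltage: flat channel
in a 30 Å periodic box, D = 0.1 Å²/ps, ±0.15 and ±0.3 V, 150 ns each.
These sizes keep the full validation suite around two minutes of compute
while leaving each asserted tolerance several standard errors wide.

## Numerical and degenerate-input choices

- WHAM: convergence on max window-offset change < 1e-7 kcal/mol; failure
  raises with the residual; single windows (k = 0 allowed) reduce to a
  Boltzmann histogram inversion.
- Zero-variance series, non-positive D, empty partitions, disconnected
  cell graphs, unreachable milestones, neutral permeants in GHK and
  non-positive MFPTs all raise typed errors rather than propagating NaN.
- Samples exactly on an edge: milestone hit (closed boundary on the
  crossing side); flux regions: boundary samples are inner.
- Never-hit milestones are dropped from the rate matrix with a warning.
- Stride uniformity tolerance in trajectory files: 1e-9 ps absolute.

## Limitations

The milestoning π estimator inherits finite-stride crossing-detection bias
(a few percent under the fixture conditions; worse for stiff walls or
coarse strides — use the stride scan).  The sample-based detector cannot
recover events between samples by construction; exact-crossing milestoning
from continuous trajectories is out of scope.  The GHK conversion assumes
symmetric concentration and a linear I–V regime; concentration-gradient
setups are not handled.  All estimators assume the 1-D Smoluchowski picture
— separable orthogonal degrees of freedom and instantaneous velocity
relaxation.
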