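# permeakit

Single-channel permeability of an ion or small solute, computed three
independent ways from 1-D trajectory data:

1. **ISD route** — from a potential of mean force w(z) and a
   position-dependent diffusion profile D(z), via the (slightly modified)
   inhomogeneous solubility-diffusion equation
   `P = πr² (∫_{z1}^{z2} e^{βw(z)}/D(z) dz)⁻¹`,
   where r is the radius of the cylindrical restraint that defines the
   effective bulk concentration;
2. **MFPT route** — from Markovian milestoning on Voronoi-tessellated,
   soft-wall-confined trajectories: cell probabilities π from the
   attempted-escape balance, free energies −k_BT ln π, a milestone rate
   matrix `q_{ij,ik} = π_i n_i(j→k)/(π_i r_i(j) + π_j r_j(j))`, mean
   first-passage times from its restricted linear systems, and
   `P = πr² ∫ e^{−βw} dz / (2⟨t⟩)`;
3. **Flux route** — from steady-state runs under a constant field: currents
   by permeation-event counting and by charge displacement, the unitary
   conductance γ from the I–V slope, and `P = γ k_BT/(q²C)` (the GHK flux
   relation at symmetric concentration C).

A fourth component, an **overdamped Langevin (Brownian dynamics) simulator**
with position-dependent D(z) and harmonic / flat-bottom / constant-field
biases, generates ground-truth trajectories with exactly the statistical
structure of restrained-MD collective-variable output — so every estimator
in the package is validated against data whose true w(z), D(z) and kinetics
are known, without any molecular-dynamics engine.

The package is for computational biophysicists who have (or want to
emulate) biased 1-D trajectory data — umbrella windows, milestoning cells,
voltage runs — and want permeabilities with cross-route consistency checks.

## Worked example

`examples/isd_permeability.py` builds a symmetric 4 kcal/mol Gaussian
barrier with D = 0.02 Å²/ps, pore [−10, 10] Å and bulk restraint radius
6 Å, and runs the two PMF-based routes:

```
P (ISD)  : 1.057e-15 cm³/s
MFPT     : 0.494 µs
P (MFPT) : 1.057e-15 cm³/s
ratio    : 1.00
resistance peaks at z = +0.0 Å (the barrier top dominates 1/P)
```

The ISD permeability is ~10⁻¹⁵ cm³/s — a microsecond-scale crossing rate at
sub-molar effective concentration, typical of a small-conductance channel —
and the MFPT route agrees because the barrier is single, symmetric and
dominant.  `examples/milestoning_mfpt.py` reaches the same MFPT from
cell-confined trajectories alone (no D(z) needed), and
`examples/voltage_flux.py` closes the loop through the conductance:

```
conductance: 699 ± 7 pS (intercept +10.76 pA)
P (GHK)    : 3.824e-13 cm³/s
P (πr²D/L) : 3.770e-13 cm³/s
```

Other examples: `effective_concentration.py` (what one restrained ion is
worth in mol/L), `simulate_and_estimate_pmf.py` (umbrella windows → WHAM →
w(z), D(z)).

## Command line

A thin CLI mirrors the library for shell pipelines:

```bash
permeakit simulate  --recipe recipe.yml --seed 7 --out traj/
permeakit pmf       --config windows.yml --out profiles/
permeakit diffusion --config windows.yml --out profiles/
permeakit isd       --pmf profiles/pmf.tsv --diffusion profiles/diffusion.tsv \
                    --radius 6 --z1 -10 --z2 10 --out isd/
permeakit milestone --config cells.yml --out milestoning/
permeakit flux      --config flux.yml --out flux/
permeakit report    isd/isd.json flux/flux.json --out report/
```

Trajectories are whitespace tables (time in ps, coordinate in Å, `#`
comments) in the style of collective-variable output; profiles are TSV;
results are JSON records carrying method tags and input digests.

## Layout

- `src/permeakit/units.py` — constants (CODATA 2018), unit conversions,
  bulk geometries and effective concentrations
- `src/permeakit/trajectory.py` — time-series I/O, subsampling, blocking
- `src/permeakit/bd.py`, `_kernels.py` — the Brownian-dynamics generator
- `src/permeakit/pmf.py` — WHAM reweighting and D(z) from window statistics
- `src/permeakit/isd.py` — ISD/resistance/Smoluchowski/MFPT permeability
- `src/permeakit/milestoning.py` — cells, events, π, rate matrix, MFPT,
  diagnostics, stride sensitivity
- `src/permeakit/flux.py` — crossing counting, displacement current, I–V,
  GHK conversion
- `src/permeakit/cli.py`, `config.py` — the CLI and YAML recipes

See `docs/methods.md` for the models, estimators, numerical choices and
their limitations.
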