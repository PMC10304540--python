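# Methods

This note documents the models implemented in `memperm`, the defaults they
use, and the numerical choices made where the underlying methodology leaves
the details open.

## Free-energy profiles from umbrella sampling

Each umbrella window restrains the solute at depth `z0` with a harmonic bias
`U(z) = k/2 (z − z0)²`. The default bias force constant is
3000 kJ mol⁻¹ nm⁻² and windows are spaced 0.1 nm (1 Å) apart, the standard
setup for amphiphile permeation studies; at 298.15 K the bias width is
`sqrt(RT/k) ≈ 0.029 nm`.

`wham_solve` iterates the WHAM self-consistency equations in log space:

```
ρ(b) = Σ_i n_i(b) / Σ_i N_i exp[(f_i − U_i(z_b))/RT]
f_i  = −RT ln Σ_b ρ(b) exp[−U_i(z_b)/RT]
```

Numerical choices:

- **Bin width** 0.02 nm (5 bins per window spacing), resolving the bias
  width. Exposed as a parameter.
- **Convergence** when the largest per-iteration change of any window free
  energy falls below 10⁻⁷ kJ/mol (strict), with `max_iter = 10⁵`. The
  tolerance is cheap at these problem sizes and removes the iteration count
  as a result-affecting knob. A quasi-Newton (L-BFGS) pass on the equivalent
  convex objective provides the starting point; the self-consistent
  iteration then runs until its own tolerance, so the documented convergence
  contract is unchanged.
- **Edge trimming.** The returned profile is restricted to the contiguous
  grid whose bins hold at least `max(2, 0.5% of the fullest bin)` samples.
  Free energies read off a handful of extreme-tail samples carry O(kJ/mol)
  shot noise and would dominate any profile-wide error measure; trimming
  them changes nothing in the well-sampled region. Interior empty bins are a
  coverage gap and raise an error instead.
- Profiles are stored on the histogram grid; no spline fitting, keeping the
  WHAM output auditable.

**Reference conventions.** A PMF is defined up to a constant; `set_reference`
implements three explicit zero conventions: `bulk_water` (zero mean over
|z| ≥ z_bulk, default z_bulk = 3.5 nm, the inner edge of the bulk-water
window band), `global_minimum`, and `bilayer_center`. Changing the reference
never alters free-energy differences or barrier heights.

**Uncertainty** is the pointwise |ΔG| between profiles built from the first
and second halves of each window's series, after aligning both halves to a
common (zero-mean) reference — the usual split-half estimate. Three
truncation schemes (`convergence_scan`) probe equilibration: growing
analysis prefixes, growing discarded equilibration prefixes, and a fixed
analysis span behind a growing equilibration prefix.

**Barriers.** The equilibrium depth is the argmin of a moving-average
smoothed profile (window 0.3 nm; raw argmins are unstable on rugged PMFs),
ties broken toward smaller |z| for determinism. Barrier values are read from
the raw profile: translocation = G(0) − G(z_eq), desorption = Ḡ_bulk −
G(z_eq). Monotone or flat profiles are flagged degenerate. For asymmetric
profiles (whole-membrane sampling) per-leaflet values are reported.

## Local diffusion from restraint-force autocorrelation

The restraint-force series at fixed depth is taken as the F(z, t) whose
fluctuation autocorrelation defines the time-dependent friction; this is an
approximation valid when the free-energy slope over the distance diffused
during the friction decay time is small compared to RT, which holds in
harmonically restrained windows. The static friction is the time integral of
the fluctuation ACF over RT, and `D(z) = RT/ξ(z)`; `D·ξ = RT` holds exactly
by construction.

- **ACF estimator**: biased (1/N) normalization, which keeps the estimated
  ACF positive semidefinite and its integral bounded; computed via FFT and
  verified against the direct O(N²) sum in tests.
- **Integration cutoff**: a finite noisy ACF integrated over all lags does
  not converge, so the trapezoidal integral runs to the ACF's first zero
  crossing (that lag included). The cutoff actually used is recorded per
  window. A `full` rule is available for diagnostics.
- Windows with zero force fluctuation have undefined D and raise an error.

## ISDM permeability

`permeability` applies the requested reference to the PMF, forms the local
resistance `ℛ(z) = exp(ΔG(z)/RT)/D(z)`, integrates by the trapezoidal rule
on the PMF grid (D interpolated linearly onto it, since D is sampled at the
sparse window centers) and inverts. Units: resistance ps/nm, permeability
converted as 1 nm/ps = 10⁵ cm/s. Shifting the reference by a constant c
rescales P by exp(−c/RT) exactly — the minimum-reference variant is a pure
shift, and the known artifact that it inflates the apparent resistance of
the water phase is reported in the result's notes rather than corrected.

The rate-limiting regime compares the two barriers with a margin of
2 kJ/mol (≈ RT, below the split-half noise floor of typical profiles):
desorption-limited, translocation-limited, or indeterminate within the
margin. `decompose_resistance` splits the total resistance into entrance /
center / exit-side regions at symmetric edges (default ±1 nm; the region
boundaries are qualitative and exposed as parameters).

## Membrane descriptors

The per-species area decomposition assigns the non-water box volume to
phospholipid and cholesterol using fixed molecular volumes
(V_W = 0.0312 nm³, V_Chol = 0.593 nm³):

```
A_Chol = 2 A_box V_Chol / (V_box − N_W V_W)
A_PL   = 2 A_box (V_box − N_W V_W − x N V_Chol) / [(V_box − N_W V_W)(1 − x) N]
```

which conserves `(1 − x) N A_PL + x N A_Chol = 2 A_box` identically.
Deuterium order parameters are `S_CD = ⟨(3cos²θ − 1)/2⟩` per carbon against
the bilayer normal (+z unless overridden); C–D vectors are inputs —
reconstructing them from united-atom chains is the fixture generator's job.
The hydrogen-bond criterion is geometric — donor–acceptor distance
≤ 0.35 nm and hydrogen–donor–acceptor angle ≤ 30°, both exposed flags —
because no single convention is universal. Orientation histograms report
angles in degrees on [0, 180], normalized to unit mass.

## The synthetic generator and what it does (not) emulate

The generator provides every input the analysis consumes, with closed-form
ground truth:

- **PMF surfaces** are monotone (PCHIP) interpolants through anchor points:
  bulk-water plateau, one interfacial minimum per leaflet (default at
  ±1.8 nm, half-width 0.4 nm), a central barrier, an optional midplane dip
  (as seen for solutes in cholesterol-rich bilayers), over z ∈ (−4, 4) nm —
  the window band extended through both leaflets. Monotone interpolation
  cannot under- or overshoot, so the stated barrier heights are exact. The
  `center_barrier` is anchored to the interfacial minimum, so across a
  homologous family the translocation barrier is constant while the
  desorption barrier grows as `intercept + slope·n_carbons` (default
  10 + 2.5n kJ/mol, placing the translocation/desorption crossover between
  4 and 8 carbons); this reflects that the polar group crossing the midplane
  is shared by the family while the hydrophobic driving force scales with
  chain length. The surfaces are a parametric stand-in: they reproduce the
  qualitative shape of amphiphile PMFs, not any particular system's curve.
- **Umbrella windows** are exact stationary draws from the biased Boltzmann
  density by inverse-CDF lookup on a 10⁻³ nm grid — no Markov chain, hence
  no burn-in or autocorrelation. Real window series are time-correlated;
  passing tests therefore validate the estimators under ideal sampling, not
  the statistical efficiency of any MD protocol. Default 2000 samples per
  window (standing in for an 80 ns analysis span of decorrelated frames).
- **Force series** are stationary Ornstein–Uhlenbeck processes via the exact
  discrete update, with σ² chosen as `RT²/(D τ)` to realize a target D
  (default τ = 0.1 ps, dt = 0.01 ps — a sub-picosecond force memory typical
  of liquid-phase friction). Real force ACFs have multi-scale decays; the
  single-exponential is the simplest process with a prescribed friction.
- **The ground-truth D(z) shape** interpolates ≈8×10⁻⁴ nm²/ps
  (≈10⁻⁵ cm²/s) in bulk water, a minimum of 10⁻⁴ nm²/ps in the dense
  interfacial region, and a partial recovery at the low-density midplane.
- All randomness flows through one seeded generator per call; seeds are
  required arguments.

## Problem sizes

The shipped analysis scripts sample one leaflet (41 windows, 0–4 nm) and
mirror the profile, the usual presentation for symmetric bilayers; the
acceptance script uses 5000 samples per window, 10⁵-sample force series per
depth (10⁶ for the single aqueous-diffusion estimate), and a single shared
D(z) across family members, since the generator's diffusion truth does not
depend on chain length.

## Known limitations

- WHAM only; no MBAR, and no autocorrelation-aware statistical-inefficiency
  weighting of window samples (unnecessary for the generator's independent
  draws, relevant for real MD data).
- Whole-profile WHAM errors grow as a random walk across window junctions;
  the quoted oracle accuracies hold at the documented sample counts.
- The ISDM itself systematically overestimates P for hydrophobic solutes
  under the bulk-water reference; the minimum-reference variant restores the
  qualitative trend but misstates the water-phase resistance. Both are
  reported side by side rather than adjudicated.
- No trajectory ingestion: inputs are plain-text window/force series and
  frame descriptions, not MD topologies.
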