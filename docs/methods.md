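# Methods

This note documents the models implemented in `photosv`, the numerical
choices behind them, and what the synthetic-data tests do and do not
demonstrate.

## Sedimentation and diffusion

The concentration χ(r, t) of a species with sedimentation coefficient s and
diffusion coefficient D in a sector-shaped cell rotating at angular velocity
ω obeys the Lamm equation

    ∂χ/∂t = −(1/r) ∂/∂r ( s ω² r² χ − D r ∂χ/∂r ),

with zero net flux through the meniscus and the cell bottom. Units are CGS
throughout: radii in cm, time in s, s-values in svedberg (10⁻¹³ s,
converted internally), signals in arbitrary linear units — valid because the
fluorescence detector responds linearly to concentration in the nanomolar
range.

**Discretization.** A flux-conservative finite-volume scheme on a uniform
radial grid with Scharfetter–Gummel (exponentially fitted) face fluxes and
Crank–Nicolson time stepping. This combination was chosen over a Galerkin
finite-element scheme because (a) the finite-volume form conserves the
closed-cell mass integral ∫χ r dr to round-off by construction, which is one
of the package's contract invariants, and (b) the exponential fitting
degenerates smoothly to monotone upwinding as D → 0, so the diffusion-free
oracle cases (plateau dilution, boundary advection) stay oscillation-free
and non-negative where central schemes ring. At the cell Péclet numbers of
typical protein runs (v·Δr/D ≈ 0.2 at 20 µm) the scheme is effectively
central-difference accurate. In the plateau region the discrete operator
reproduces the radial square-dilution law exp(−2ω²st) exactly (the face-area
telescoping is exact for uniform χ), which the tests verify to six digits.

Defaults: 20 µm radial step (matching detector acquisition), internal time
step ≤ 10 s with automatic even sub-stepping between requested output times;
each distinct sub-step size factorizes its Crank–Nicolson matrix once
(sparse LU) and reuses it. Rotor acceleration is treated as instantaneous;
time is measured from reaching full speed. Species with s = 0 are allowed in
simulation but require an explicit D, because the D(s) scaling law (below)
diverges there.

**Hydrodynamic scaling law.** Distribution analysis needs D for every trial
s. With the frictional ratio f/f₀ fixed, the joint Svedberg/Stokes–Einstein
relations give

    D(s) = (√2/18π) · k_B T · s^(−1/2) · (η f/f₀)^(−3/2) · ((1−v̄ρ)/v̄)^(1/2).

The default f/f₀ = 1.42 corresponds to a moderately extended folded protein
(the value found for the GluA2/GluA3-type heterodimer); v̄ defaults to
0.73 mL/g and solvent defaults to water at 20 °C. The self-consistency of
the formula is tested by round-tripping: for f/f₀ = 1, the molar mass from
the Svedberg equation and the compact-sphere Stokes radius reproduce f = f₀
exactly.

**Coupled two-state transport.** Under spatially localized illumination the
fluorescent (χ_f) and dark (χ_d) sub-populations sediment and diffuse
identically but interconvert with local rate k(r, t) (optionally a reverse
rate for on-switchers). The solver uses Strang splitting: half-step exact
exponential exchange, full transport step shared by both states, half-step
exchange. Because the exchange conserves χ_f + χ_d exactly and transport is
linear, the sum reproduces the single-state solution on the same
discretization to machine precision — a structural identity the tests
assert, not a convergence statement.

## Photoswitching signal model

psFPs under the scanning 488 nm beam relax single-exponentially from an
initial photophysical equilibrium toward an illuminated steady state. Since
all molecules share the angular velocity, a molecule at radius r crosses the
fixed-width beam in time ∝ 1/r, so the accumulated photon dose along the
trajectory of a particle found at radius r after exposure time Δt is

    g(s, r, Δt) = (r₀/r) · (ω²s)^(−1) · (e^{ω²sΔt} − 1),

normalized to a reference radius r₀ (default: the column midpoint; any
fitted β must be quoted together with its r₀). A series expansion is used
for ω²sΔt < 10⁻⁶, where g → (r₀/r)Δt. The specific signal increment is

    E = ε₀ · (α + (1 − α) · ρᵢ · e^{−β g(s, r, t − t₄₀₅,ᵢ)}),

with ε₀ the initial molar signal increment, α the asymptotic fraction of the
initial signal (α < 1 switches off, α > 1 on, α = 1 photostable), β the
lumped illumination × quantum-yield rate constant at r₀, t₄₀₅,ᵢ the last
405 nm reset before t and ρᵢ its fractional recovery (1 = full reset; the
dose clock restarts at each reset, since the reset restores the
photophysical equilibrium). This parameterization makes α directly the
long-time signal fraction, which is how measured switching amplitudes are
reported (e.g. rsEGFP retaining 13.4% of its initial signal, α = 0.134);
β and the per-fluorophore photon-flux and beam-width constants are not
separable in this geometry and are deliberately lumped. The (r₀/r) factor
implies slightly radially sloping plateaus — positive slope for
off-switchers, negative for on-switchers — which the simulator reproduces
and the tests check, because in mixtures these slopes carry component
information.

Stationary (non-scanning) exposure is roughly two orders of magnitude
stronger than the scan-averaged exposure; the `q_strong` parameter records
this ratio. Localized illumination is modeled as a superposition of Gaussian
beams gated by exposure windows, feeding the coupled two-state solver. For
FRAP-like runs the scan-signal dose clock starts at the end of the
pre-exposure (t_eff = t − t_pre); the generator and the fitting basis share
one code path, so this convention cancels identically in fits — consistent
with the observation that the precise initial exposure profile is
inconsequential once it is shared between model and data.

Not modeled: triplet states, irreversible bleaching, wavelength-dependent
action spectra. Binding-induced changes of switching parameters are
representable as distinct `Photoswitcher` parameter sets (and can be refined
in the fit), not predicted.

## Multi-component decomposition

Scans are modeled as a(r,t) = Σₚ ∫ cₚ(s) E⁽ᵖ⁾(s,r,t) χ(s,r,t) ds. On a
discrete s-grid (default 100 points, 0.5–12 S, covering the monomer–trimer
range of small proteins) this is a linear problem in the stacked cₚ ≥ 0.
χ(s,·,·) is solved once per grid s and shared across components, which
differ only in E. The solve is non-negative least squares (active-set NNLS;
the unconstrained baseline enters as a signed column pair) with a
second-difference Tikhonov penalty per component block. The penalty weight
is chosen by bisection as the largest weight whose data χ² stays within the
one-sided F-statistic band (default P = 0.68, the documented convention for
c(s)-type analyses; the exact level is an assumption) of the unconstrained
minimum; for effectively noise-free data this reduces to the unregularized
solution. Fits are deterministic for fixed inputs.

The default fit range excludes 0.03 cm above the meniscus and 0.05 cm above
the bottom (optical artifacts and back-diffusion pile-up). The meniscus is
fixed from the run configuration. Components with identical switching
parameters and reset schedules are rejected with a singularity error rather
than splitting signal arbitrarily. Optional outer Nelder–Mead refinement of
flagged α/β values wraps the linear solve (off by default, matching the
practice of fixing them to side-by-side single-fluorophore measurements and
refining only when justified); ε₀ is absorbed into cₚ.

A "conventional" mode fits a single photostable basis, optionally with one
free additive offset per scan, eliminated algebraically by per-scan
centering of the normal equations. This impostor model is how
time-dependent signal changes would be absorbed if photoswitching were
ignored; on switching data it misfits the boundary shapes at several times
the acquisition noise, which is itself a useful diagnostic.

Weighted-average sedimentation coefficients are sw = ∫c(s)s ds / ∫c(s) ds
over a chosen range (undefined, and an error, when the integrated signal is
zero). Confidence intervals for cₚ(s) and sw come from parametric
Monte-Carlo: Gaussian noise at the fitted rmsd (500 iterations by default)
added to the best-fit model, refit at the same penalty weight, percentile
intervals; the meniscus is not varied. Intervals are reproducible given a
seed and scale linearly with the injected noise.

## Design predictor

For two fluorophores co-sedimenting at a common reference s, discretizing
the superposition model and dropping the weak radial dependence of the
signals yields the signature cross-product matrix

    𝔼ₚq = Σₜ E⁽ᵖ⁾(t) E⁽q⁾(t) w(s,t),   w(s,t) = Σᵣ χ(s,r,t)²,

with E evaluated at r₀ and w from the unit-loading Lamm solution over the
fit range. The predicted relative concentration error is

    δc = cond(𝔼) · √2 · δa / √n

for n data points of relative noise δa. The √2 prefactor is a convention;
both quantities this module is used for — the rate minimizing δc(β) and the
rate at which blinking and constant-scanning curves cross — are invariant to
it (and to any monotone transform of cond), which the tests verify by
recomputing with the constant 2. Because cond(𝔼) enters linearly, δc is a
worst-case-style propagation estimate: measured misassignment errors from
full decomposition fits fall below it (by roughly 2–10× depending on the
rate, furthest at rates well above the optimum where the NNLS constraints
suppress variance the bound cannot see). The package therefore treats δc as
a design bound and comparator between protocols, not as an unbiased error
forecast; the tests assert the one-sided bound plus a tightness floor near
the optimum.

Under the standard conditions (12 mm column, 50,000 rpm, 2.8 S, 5-min scans
for 12 h, δa = 1%) the optimal switching rate for a fully off-switching
versus photostable pair computes to ≈2.5×10⁻⁴/s, and the blinking protocol
(full resets at 26 and 69 min) crosses the constant-scanning curve at
≈2.6×10⁻⁴/s, being detrimental below — blinking keeps slow switchers from
ever populating the dark state.

## Binding isotherms

Competitive homo-/hetero-dimerization of protomers A and B: species A, B,
A₂, B₂, AB with dissociation constants Kd,22, Kd,33, Kd,23 (any of which may
be infinite). Free concentrations satisfy

    a + 2a²/Kd,22 + ab/Kd,23 = A_tot,
    b + 2b²/Kd,33 + ab/Kd,23 = B_tot.

The solver eliminates a exactly through its quadratic mass balance (written
in the cancellation-safe form a = 2A_tot/(c₁ + √(c₁² + 8A_tot/Kd,22))) and
finds b by Brent bracketing on [0, B_tot], where the remaining balance is
monotone — this closed-form-plus-bracketed-root construction cannot fail to
converge, and every solution is verified to close both mass balances to
10⁻¹⁰ relative. Assuming association/dissociation fast on the sedimentation
time scale, the observable per component is the protomer-weighted

    sw_A = (a·s_A + 2A₂·s_A2 + AB·s_AB) / (a + 2A₂ + AB),

and analogously for B. Isotherm fits minimize the inverse-variance-weighted
residuals of both components' sw simultaneously (points without error bars
receive the median error); Kd values are fitted on a log scale to guarantee
positivity, s-values linearly, with fixed/free selection per parameter —
typically the homodimer constants are fixed at separately determined values.
Confidence intervals come from parametric Monte-Carlo resampling of sw
within the stated error bars; unidentifiable combinations surface as
interval blow-up. Whether both components should be weighted equally or by
their Monte-Carlo errors is not settled; the package weights by the supplied
per-point errors.

Out of scope: higher-order oligomers, slow-exchange (kinetically limited)
boundary modeling, and direct Lamm-level global fitting of binding models.

## Synthetic data

The generator builds scans as Σₚ E⁽ᵖ⁾·χ (or E·χ_f after a FRAP
pre-exposure) plus Gaussian noise of a stated fraction of the total loading
signal, with a mandatory seed whenever noise is nonzero; outputs are
bit-reproducible and carry a ground-truth sidecar (true s, switching
parameters, loading, seed, config hash). Defaults emulate standard
acquisition: 6.0–7.2 cm column, 50,000 rpm, 20 °C, 20 µm grid, scans every
5 min for 12 h. The test suite generally runs at 50 µm / 10-min-scan /
6-hour scale — the solver is grid-converged well below these resolutions,
and the absolute-accuracy oracles (plateau dilution, mass conservation,
12-hour drift) run on the full 20 µm grid.

What the generator does **not** emulate: meniscus and bottom optical
artifacts, signal-magnification gradients from focal-plane mismatch,
photobleaching of "stable" dyes, baseline drifts, rotor acceleration ramps,
and inner-filter or adsorption effects. Closure tests (generate → fit
recovers the truth) therefore demonstrate the correctness and
self-consistency of the numerics and of the decomposition under the stated
noise model — not robustness to the systematic imperfections of real
detectors, which is why fitted switching parameters should come from
side-by-side control samples run under identical illumination.

## Numerical conventions and edge cases

* Distributions are stored as signal amounts per s-grid node; sw and total
  signal are weighted sums over nodes.
* Empty integration ranges, zero integrated signal, non-monotone grids,
  negative rates, mixed rotor speeds in a scan set, and FRAP windows
  overlapping scan times all raise explicit errors rather than returning
  degenerate values.
* The signature matrix is declared numerically singular (infinite δc, with a
  named cause) when its smallest singular value is within 10⁻¹² of scale.
* Monte-Carlo interval percentiles: 16/84 (68%) and 2.5/97.5 (95%).
* All randomness flows through numpy Generators seeded from explicit seeds;
  identical seeds give bit-identical scans, fits, and intervals.
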