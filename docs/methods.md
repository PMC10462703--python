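# Methods

## Model

The solver advances a vector of concentrations
ρ(x, t) ∈ ℝ^S under

∂ρ/∂t = D ∂²ρ/∂x² + R(ρ),

with per-species diffusion coefficients D and a mass-action network
R(ρ) = M·v(ρ): M is the constant stoichiometric matrix (products minus
reactants), v the vector of monomial rates — k for a source, kρ_a for first
order, kρ_aρ_b for A+B, and kρ_a² for A+A with a stoichiometric loss of 2
per event.  Only orders 0–2 are supported; the vector field is therefore
quadratic, which is what makes Kahan's discretisation natural.  Spherically
symmetric problems use D ∂²(rρ)/∂r² for the diffusion term, i.e. the plain
1D operator acting on u = rρ.

Assumptions inherited from this model class: continuum concentrations (no
discrete-particle corrections at low copy numbers), no interparticle forces
(charge effects are not modelled; rate constants are taken as effective),
isothermal rate constants, and geometries reducible to an interval or a
radial shell.

## Bases, grids and transforms

Four interval families are supported — sine or cosine with each combination
of Dirichlet (ρ = 0, perfect sink) and Neumann (∂ρ/∂x = 0, no flux) ends —
with frequencies ω_n = (π/L)(n+½) when the two ends differ and (π/L)n when
they match, plus the radial family φ_n(r) = sin(ω_n(r−a))/r.  Every basis
function satisfies both boundary conditions individually, so truncation
never violates them.  For the Dirichlet–Dirichlet sine family the n = 0
function is identically zero; modes n′ = 1..N+1 are stored and exposed
through a contiguous 0-based index (the tabulated frequency πn/L therefore
appears at exposed index n−1).

Values live on the midpoint grid x_m = a + (m+½)L/(N+1).  On this grid each
family pairs with a classical fast transform — DST-IV/DCT-IV
(self-conjugate) for the half-integer families, DCT-II/DCT-III for
Neumann–Neumann, DST-II/DST-III for Dirichlet–Dirichlet — with
normalisations fixed so coefficients are expansion amplitudes exactly.  The
pairing was derived against the dense synthesis (Vandermonde) matrix and is
enforced by round-trip and naive-synthesis oracle tests at 10⁻¹² relative;
an O(N²) dense path is kept as a reference fallback.  Radial fields multiply
by r before the forward transform and divide after the inverse.

## Time stepping

One Strang step: exact diffusion e^{−Dω²Δt/2} on coefficients → inverse
transform → Kahan step of the homogeneous kinetics at each grid point
(batched S×S linear solves, dense LU; S ≤ ~15 in radiolysis networks) →
forward transform → second exact diffusion half-step.  The diffusion
sub-step has no truncation error, so with R = 0 the scheme is exact; with
chemistry the splitting is globally second order (verified against the
closed form c_n(t) = c_n(0)e^{−(Dω_n²+k)t}).

Kahan's method is A-stable, linearly implicit, preserves every linear
invariant wᵀρ with wᵀM = 0 to round-off, and reproduces the scalar Riccati
flow ρ₀/(1+kρ₀t) exactly — all tested properties.  Steps that undershoot
into significant negative concentrations (below −10⁻⁹ × max|ρ| relative to
the step's starting minimum) are treated as failures and retried with a
smaller Δt rather than clipped, since clipping would break conservation.

### Adaptive control

The local error of a macro step is estimated by step doubling: one Δt step
versus two Δt/2 steps, err = max over species and modes of the absolute
coefficient difference; the accepted state is the finer result.  If
err > tol the step is halved and recomputed (aborting below dt_min); if
err < tol/10 the next step is doubled (capped at dt_max).  Defaults:
tol = 10⁻⁶ (coefficient units), Δt₀ = 10⁻³ ns, dt_min = 10⁻¹² ns,
dt_max = 10 ns.

tol is an *absolute* coefficient tolerance.  Scenarios whose field
magnitudes are far from O(1) need a proportionate tol; `scan_film` therefore
defaults to tol = 10⁻⁴ × max_s S_s L²/(2D_s), the diffusion-limited
equilibrium scale of the sourced species.  With a disproportionately large
tol the controller is blind (it will accept steps whose error exceeds the
entire solution); with a disproportionately small one it stalls.

### Equilibrium detection

"Effective equilibrium" is declared when
max |Δρ| / (Δt_macro (|ρ| + floor)) < 10⁻⁶ ns⁻¹ (floor 10⁻¹²) holds for 3
consecutive accepted macro steps — a relative rate-of-change criterion,
since only a qualitative definition ("no longer changing significantly")
exists for this notion.

## Radiolysis scenarios

**Film.** Dirichlet–Neumann sine basis on [0, L] (absorbing solid at x = 0,
no-flux gas boundary at x = L; one monolayer ≈ 0.25 nm).  Irradiation enters
as zeroth-order sources S = (G/100)·Ḋ·m_lin/q_eV, uniform in space, with G
the yield per 100 eV, Ḋ the dose rate in Gy ns⁻¹ and m_lin the water mass
per unit column length (density 997 kg m⁻³ × an assumed 1 nm² cross-section,
both configurable; second-order rate constants are rescaled by the
cross-section into the 1D system).  Applying the uniform source in value
space leaves a Gibbs mismatch near the Dirichlet end; convergence in N
(checked by the doubling protocol below) is the user's verification knob.

**Spur.** Radial sine basis with regularity at r = 0 and a Dirichlet outer
boundary at b, default 40× the widest initial σ (the builder refuses any b
that truncates more than 10⁻⁶ of an initial profile's mass).  Initial
conditions are 3D Gaussians ρ(r) = N₀(2πσ²)^{−3/2}e^{−r²/2σ²}, optionally
hollowed (a Gaussian minus a narrower Gaussian, renormalised to N₀) to
represent a prechemical ballistic transit of the electrons.  Inventories
4π∫ρr²dr and film inventories ∫ρdx are evaluated from closed-form mode
integrals, cross-checked against quadrature.

**Observables.** Boundary concentrations by direct spectral summation at the
endpoint (exactly 0 at a Dirichlet end); the hollowing diagnostic compares
the r→0 limit Σc_nω_n with the grid maximum, declaring a central minimum
when the centre falls 1% (configurable δ) below the maximum.

## Shipped data and what passing tests show

The species/reaction/G-value tables and spur widths/yields shipped under
`data/` are representative standard-literature values (compilation-style
aqueous rate constants; classic prescribed-diffusion spur parameters:
σ(e⁻_aq) = 2.3 nm wider than σ = 0.85 nm for the radicals and ions, yields
per 100 eV spur of 4.78/5.50/4.78/0.62/0.15 for e⁻_aq/·OH/H₃O⁺/H·/H₂).
They reproduce the *structural* physics — the quadratic thickness law of
equilibrium boundary H₂ across dose rates, and the transient hollowing of
the electron profile (onset ≈ 6 ps, centre/max minimum ≈ 0.61 at the 1%
margin with these parameters) — but not any specific published table's
quantitative figures; blank templates are provided for transcription.  The
synthetic fixtures module likewise emulates network *structure* (orders,
conservation, stiffness), not real radiolysis chemistry; tests passing on it
certify the numerics, not a particular chemical dataset.

## Verification protocol and problem sizes

`convergence_report` reruns a scenario with Δt/2 and 2N at pinned step size
and reports both the maximum absolute and maximum relative difference of the
final profiles on a shared query grid (both are reported because an absolute
difference carries concentration units while a relative one is
dimensionless).  On the representative α film this yields ~3×10⁻³ relative.

Default problem sizes used by the test suite and the acceptance script are
the package's own choices balancing resolution against run time: film scans
at N = 48–64 over L ∈ [0.25, 5] nm at two dose rates (10⁻² and 10² Gy ns⁻¹);
the spur at N = 160, b = 20 nm (≈ 8.7σ_max, truncation < 10⁻¹⁶), 3 ns
window.  Doubling b or N changes reported inventories/slopes at or below the
10⁻⁴ level.

## Known limitations

No charge (Debye–Smoluchowski) effects; no Robin (partial-sink) boundaries;
no reactions above second order; no multi-dimensional domains; continuum
concentrations only, so low-N₀ spur statistics are outside scope; the
uniform-source Gibbs effect near Dirichlet ends converges only as N grows;
equilibrium detection is a heuristic on sampled rates and can fire early on
artificially slow dynamics (mitigated by the 3-step persistence
requirement).
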