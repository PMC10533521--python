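# Methods

## The model

The flagellar beat is modelled as a chemo-elastic reaction–diffusion
system. The axoneme is projected onto two filaments at fixed spacing
*a*, cross-linked by passive elastic elements (shear stiffness *K*) and
by two antagonistic teams of dynein motors. Each motor obeys a linear
force–velocity relation *F±* = *f₀*(1 ± Δₜ/*v₀*) — a force generator
with internal drag *ξᵐ* = *f₀*/*v₀* — and the bound fractions *n±*
follow two-state kinetics with attachment rate *π₀*(1−*n±*) and
load-dependent detachment *ε₀ n± exp[(f₀/f_c)(1 ± Δₜ/v₀)]*. Detachment
accelerated by sliding load makes the two teams a tug of war: the
winning team unloads and recruits, the losing team sheds motors. This
sliding-control feedback is the only nonlinearity that matters.

Shear moments generated by the motors are resisted only by bending
elasticity *B* and by the internal motor friction; external fluid
moments are neglected (the high-internal-dissipation limit). In
dimensionless form (arclength in units of L, time in units of
*τ* = 1/(*π₀*+*ε₀*), angles in radians) the fields γ(s,t) (shear angle),
n±(s,t) satisfy

    μ_a ζ (n₊+n₋) γ_t = γ_ss − μ γ + μ_a (n₋−n₊)
    n±_t = η(1−n±) − (1−η) n± exp[f*(1 ± ζ γ_t)]

with γ(0)=0 (clamped base, enforced as the penalization γ_t(0) = −γ(0))
and γ_s(1)=0 (moment-free tip). Only γ diffuses (through bending
elasticity); the motors are anchored, so the diffusion matrix is
diag(1, 0, 0). The five constants are the activity μ_a = aρf₀L²/B, the
stiffness ratio μ = a²KL²/B, the duty parameter η = π₀τ, the friction
parameter ζ = a/(v₀τ), and the force ratio f* = f₀/f_c.

## Closed-form linear theory

Linearizing about (γ, n±) = (0, n₀) with n₀ = η/(η+(1−η)e^{f*}) gives a
Hopf bifurcation at

    μ_a^crit = (π² + 4μ) / (8 n₀ ζ̄ ω₀²),   ω₀² = (1−n₀) f* − 1,
    ζ̄ = ζ (η + (1−η) e^{f*})

where the π² term is the bending contribution of the slowest spatial
mode sin(πs/2); dropping it recovers the isolated-element threshold
ν_a^crit = 1/(2 ζ̄ n₀ ω₀²) for ν_a = μ_a/μ. Activity relative to onset
is ε = (μ_a − μ_a^crit)/μ_a^crit. The unstable mode is a standing wave
A e^{(α+iω)t̄} sin(πs/2) with

    α = ε ω₀² / (2(1+ε)),   ω² = [(1+ε − ω₀²ε²/4)/(1+ε)²] ω₀².

**Unit convention.** α, ω and ω₀ in these expressions are rates per
unit of the *slow* motor timescale τ̄ = 1/(π₀+ε₀e^{f*}), not per τ. We
verified this by deriving the dispersion relation of the full
linearization and by simulation: rates measured from the PDE (which
integrates in τ units) equal the closed forms multiplied by
τ/τ̄ = η+(1−η)e^{f*} = ζ̄/ζ to better than 1%.
`flagrd.stability.rate_per_tau` performs the conversion. We derive ζ̄
from ζ through this same identity, since ζ̄ = a/(v₀τ̄) and
τ/τ̄ = (π₀+ε₀e^{f*})/(π₀+ε₀).

Above roughly ε ≈ 0.2 (at μ = 100) the next spatial mode
sin(3πs/2) is also weakly unstable. Growth-rate and frequency
measurements therefore project γ(s,t) onto sin(πs/2) (exactly
orthogonal to the contaminating modes) before fitting the log-envelope
slope and counting zero crossings (`measure_linear_mode`). The plain
spatial-L2-norm slope (`measure_growth_rate`) is also provided and
agrees, since the slowest mode always has the largest growth rate.

With the feedback frozen (constant detachment) the motors relax to n₀
and γ obeys a diffusion equation with restoring force,
γ_t = D γ_ss − E γ, D = 1/(2n₀μ_aζ), E = μD (nondimensional). Its
series solution over the eigenbasis sin((k+½)πs) is implemented as an
independent oracle for the no-feedback time stepper.

## Numerics

**Discretization.** Second-order finite differences on m equally
spaced points (default m = 101), centred in the interior, one-sided
(ghost-point) at the moment-free tip; the basal condition is a
penalization row γ_t,0 = −γ₀. With m points on [0,1] the spacing is
1/(m−1), so the Laplacian prefactor is (m−1)²; the alternative m²
prefactor is selectable (`grid_factor="legacy_m2"`) for replication
studies — at m = 101 the two differ by 2% in a discrete prefactor only.
Since γ_t is available in closed form at every node, the semi-discrete
system is a stiff ODE in the 3m nodal values.

**Singular collapse and regularization.** Far above onset (the regime
of the fitted parameters, ε ≈ 6–22) both motor teams detach almost
completely during part of each cycle. The shear friction μ_aζ(n₊+n₋)
then vanishes locally and the model degenerates into an algebraic
elastica constraint — a differential-algebraic limit that defeats
standard adaptive ODE steppers. Both integration paths regularize it:
the population sum is floored at 10⁻⁶ inside the friction denominator,
and the detachment exponent f*(1±ζγ_t) is capped at ±20. The caps only
engage during the quasi-instantaneous collapse events; computed
amplitudes and periods are identical to 4 digits for caps 15 vs 20, and
the caps never engage at all in the near-onset regime where the linear
theory is tested.

**Integrators.** Two paths behind one interface:

- `method="bdf"` (reference): scipy's adaptive BDF with the hand-derived
  analytic sparse Jacobian, rtol 1e−8 / atol 1e−10. Accurate but slow
  through the collapse events.
- `method="semi"` (fast): a fixed-step semi-implicit scheme, compiled
  with numba. Each step solves the shear equation by backward Euler
  with the motor fields frozen (a tridiagonal Thomas solve — the
  implicit treatment makes the collapse harmless), then updates each
  motor fraction by an exact pointwise backward-Euler formula (the rate
  equation is linear in n± once the exponent is evaluated at the new
  shear velocity). Step 5×10⁻⁴ τ by default. First-order accurate;
  preserves n± ∈ (0,1] exactly.

The two paths agree to mode-shape R² ≥ 0.9997 and frequency within
0.5% across the near-onset and far-from-onset regimes. Fitting-grade
sweeps use the fast path; the linear-theory validations use the
reference path. The isolated element (3 ODEs) uses BDF at rtol 1e−8 /
atol 1e−10 with transient discard of the first half of the record.

All simulations start from the small Gaussian perturbation
γ(s,0) = 0.001·exp(−((s−0.5)/0.1)²), n± = n₀. (The negative exponent
is the physically meaningful reading of the initial condition; a
growing exponential would not be a small localized perturbation.)

## Waveform analysis

The fundamental mode is extracted per arclength point from the raw
periodogram bin at the peak of the spatially averaged power spectrum —
no window, no smoothing, no peak interpolation; the record is first
truncated to an integer number of (provisionally estimated) periods to
limit leakage, and the time-mean profile γ̄(s) is removed and reported
separately. The reported bin width documents the frequency resolution.
Analysis windows require ≥ 20 periods for experimental-style records;
candidate simulations in a grid sweep are scored on the final 50 τ of a
100 τ run (≥ 5 periods), which is sufficient for a converged mode
shape because the saturated signal is strictly periodic.

The spatial wavenumber uses the time-averaged spatial autocorrelation.
We use the *unbiased* estimator (each lag divided by its overlap
count): the unnormalized sum tapers linearly with lag, which biases the
peak location by several grid spacings and would break the exact
sinusoid checks; with the unbiased estimator a pure sin(2πks) field
yields q = 2πk to within one lag bin. The wavelength is the lag of the
maximal-magnitude positive peak, or twice the lag of the
maximal-magnitude valley when less than one full oscillation fits in
the domain; boundary extrema count. A periodic field repeats its
autocorrelation extremum at integer multiples of the wavelength with
near-equal magnitude, and the large-lag copies rest on very few
overlap points; among peaks within 5% of the maximum the smallest lag
is therefore taken — it is the wavelength itself.

Phase alignment between two complex modes uses the closed form
φ = arg Σ γ̃_exp conj(γ̃_sim), which minimizes Σ|γ̃_exp − e^{iφ}γ̃_sim|²
(expand the square: the φ-dependent term is −2Re[e^{−iφ}Σγ̃_exp conj(γ̃_sim)]).
The fit score is R² = 1 − Σ|γ̃_exp − e^{iφ}γ̃_sim|²/Σ|γ̃_exp|².

## Fitting

Experimental-style records are preprocessed by (i) integrating
curvature to tangent angle where needed (cumulative trapezoid, zero at
the base), (ii) subtracting the basal angle per frame (body frame), and
(iii) cubic-spline interpolation to the m = 101 simulation grid. The
static (asymmetric) beat component superposes linearly on the dynamics
(γ → γ − Cs leaves γ_t and γ_ss unchanged), so only the oscillatory
part is fitted; mean removal in the mode extraction implements this.

The three motor parameters (μ_a, η, ζ) are fitted by exhaustive grid
search at fixed μ (10 for C. reinhardtii-scale cilia, 100 for bull
sperm — μ scales with L²) and fixed f* = 2. Default axes: μ_a ∈
[100, 3000] step 100 (μ=10) or [1000, 10000] step 1000 (μ=100), η ∈
[0.02, 0.5] step 0.04, ζ ∈ [0.1, 1.3] step 0.1; all configurable. The
published grid steps are retained; the bounds are our choice (they
bracket all published estimates with margin — the original bounds are
not stated). f* = 2 is likewise a fixed default of this package: it is
the value consistent with all three published bifurcation distances
simultaneously. Candidates that decay (subcritical) score 0 and are
logged; ties break toward the lexicographically smallest triple;
frequency is reported but never scored. No continuous optimisation is
performed, deliberately.

## Synthetic data

`generate_synthetic_experiment` emulates the two data dialects: tangent
angle on 19 arclength points every 1 ms, or curvature on 30 points
every 4 ms. The model is simulated to its limit cycle (fast path), the
simulation clock is mapped to seconds by pinning the beat frequency
(defaults 50 Hz for the angle dialect, 20 Hz for curvature — typical
reactivated-cilium and low-viscosity sperm rates), an optional static
arc C·s is superposed, curvature is obtained by central differences on
the fine grid before downsampling, and i.i.d. Gaussian noise (default
σ = 0.02 rad, a few percent of the O(1) rad beat amplitude) is added
after downsampling with a seeded generator — measurement-noise
semantics. The ground-truth sidecar suffices to regenerate a record
bitwise and is never read by the fitter.

What passing the recovery test shows: the pipeline (generator →
preprocessing → spectral analysis → grid scoring) is self-consistent
and robust to sensor-scale Gaussian noise, with parameter
identifiability at the one-grid-step level around a strongly
supercritical operating point. What it does not show: robustness to
tracking artifacts, drift, non-Gaussian outliers, cell-to-cell
variability of μ, or basal sliding — none of which the generator
emulates.

## Problem sizes of the shipped studies

The packaged tests validate at desk scale, chosen to exercise every
regime: linear-theory comparison at ε ∈ {0.1, 0.2, 0.4} (reference
integrator, 60 τ runs); standing/travelling wave structure at ε = 0.05
and 1.0; the diffusion-limit oracle over five decay times at m = 101;
Hopf location by eigenvalue bisection; and parameter recovery with 10
noise seeds on an 80-candidate grid (5×4×4 around μ_a = 1200,
η = 0.10, ζ = 0.9 with the published step sizes), sharing candidate
simulations across seeds through a mode cache.

## Known limitations

- The fixed-step fast path is first-order in time; its ~0.1–0.5%
  frequency bias is common mode between target and candidates in a fit
  and does not affect recovery, but absolute frequencies quoted from
  the fast path carry that bias.
- No DAE/IDA integration path; the regularized method of lines stands
  in for it (validated by cap-insensitivity, not against IDA itself).
- Basal sliding is fixed at zero; basal compliance, 3D beating,
  hydrodynamic coupling and curvature-control alternatives are out of
  scope.
- The linear frequency formula loses meaning far above onset (its
  bracket goes negative around ε ≈ 4 for typical ω₀²); `stability_summary`
  reports NaN there while ε and α remain valid.
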