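# flagrd

Reaction–diffusion modelling of the eukaryotic flagellar beat.

Cilia and flagella beat by sliding adjacent microtubule doublets with
dynein motors. When motor detachment is load-dependent (*sliding
control*), two antagonistic motor teams form a tug of war whose
instability drives spontaneous shear oscillations; bending elasticity
couples neighbouring sections, and the beat emerges as a
reaction–diffusion pattern of the shear angle γ(s,t) and the bound
motor fractions n±(s,t):

    μ_a ζ (n₊+n₋) γ_t = γ_ss − μ γ + μ_a (n₋−n₊)
    n±_t = η(1−n±) − (1−η) n± exp[f*(1 ± ζ γ_t)]

with γ(0)=0, γ_s(1)=0. Five dimensionless constants govern the
dynamics: activity μ_a = aρf₀L²/B, stiffness ratio μ = a²KL²/B, duty
parameter η, motor friction ζ, and force ratio f* (see
`docs/methods.md`). The system crosses a Hopf bifurcation at
μ_a^crit = (π²+4μ)/(8 n₀ ζ̄ ω₀²): just above onset it oscillates as an
in-phase standing wave; far above onset the wave travels base-to-tip —
the beating gait of real cilia and sperm.

The package is for biophysicists studying flagellar motility and
molecular-motor pattern formation. It provides:

- closed-form linear-stability theory (`flagrd.stability`),
- the isolated shearing-element oscillator (`flagrd.element`),
- a stiff method-of-lines PDE solver with a validated fast path
  (`flagrd.solver`),
- fundamental-mode spectral analysis, wavenumber and centerline
  reconstruction (`flagrd.spectral`),
- grid-search fitting of (μ_a, η, ζ) to experimental-style kymographs
  (`flagrd.fitting`), exposed as a model/results pair,
- a synthetic-data generator emulating the two experimental data
  dialects (`flagrd.synthetic`),
- a `flagrd` command-line tool wrapping all of the above.

## Worked example

Distance to the Hopf bifurcation for the mean fitted wild-type
*C. reinhardtii* parameters:

```sh
$ flagrd stability --mu 10 --eta 0.096 --zeta 0.96 --fstar 2 --mu-a 1570
mu_a_crit = 69.6126
nu_a_crit = 5.58357
epsilon   = 21.5534
alpha     = 0.46429  (1/tau_bar)
omega     = nan  (1/tau_bar)
```

The critical activity is ≈ 69.6, so μ_a = 1570 puts the cell at
ε ≈ 21.6 — more than twenty times above onset, deep in the nonlinear
travelling-wave regime (the linear frequency formula no longer applies
there, hence the NaN; the growth rate α is still defined).

Fitting a synthetic target generated by the model itself
(μ_a = 1200, η = 0.10, ζ = 0.9, no noise), searching a small grid:

```python
from flagrd import NondimParams, SlidingControlBeat, SyntheticSpec
from flagrd import generate_synthetic_experiment, parameter_grid

spec = SyntheticSpec(params=NondimParams(mu_a=1200, mu=10, eta=0.10,
                                         zeta=0.9, fstar=2.0),
                     noise_sigma=0.0, seed=3)
record, truth = generate_synthetic_experiment(spec)
model = SlidingControlBeat(record, mu=10.0)
grid = parameter_grid([1100, 1200, 1300], [0.06, 0.10, 0.14], [0.8, 0.9, 1.0])
print(model.fit(grid=grid).summary())
```

```
Sliding-control reaction-diffusion beat fit
==============================================
grid candidates        27
mu (fixed)             10
fstar (fixed)          2
best mu_a              1200
best eta               0.1
best zeta              0.9
R^2                    0.9994
alignment phase (rad)  -2.5266
omega simulated (1/tau) 1.6246
omega target            314.7888 (target time units)
supercritical runs     27/27
```

The search recovers the generating parameters exactly; R² is the
phase-aligned fundamental-mode fit score (1 would be a perfect shape
match; 0.9994 reflects the 19-point downsampling of the target). The
simulated frequency is in units of the motor timescale τ; the target
frequency is in rad/s of the emulated recording (here 2π·50 Hz).

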