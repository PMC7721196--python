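# Methods

## Model

The package implements a 14-state ODE model of the core mammalian
circadian clock.  Two interlocked transcription–translation feedback
loops are represented: the negative loop (*Per*, *Cry1*, *Cry2* mRNAs,
their proteins, and the nuclear PER:CRY1/PER:CRY2 heterodimers that
repress Ebox-driven transcription) and the positive loop (*Ror*,
*Rev-erbα*, *Bmal1* mRNAs and proteins, which regulate *Bmal1*
transcription at the RORE promoter — ROR activating, REV-ERBα
repressing).

Transcription of the Ebox-controlled genes (*Per*, *Cry1*, *Cry2*,
*Ror*, *Rev-erbα*) follows the promoter-equilibrium form

    r = v / (K + K_b·[B] + [C1N] + [C2N]),

*Bmal1* transcription follows

    r_b = (v1·[ROR] + v2) / (1 + K1·[REV] + K2·[ROR]).

Translation is mass action; every species decays by Michaelis–Menten
kinetics; PER:CRY association/dissociation is mass action; the two
nuclear heterodimers compete for a shared degradation pathway (common
Michaelis denominator).  No Hill exponents and no explicit
phosphorylation states or CLOCK species are included.  Concentrations
are in arbitrary units; one model time unit is treated as one hour, so
the canonical set oscillates with a free-running period of ≈ 27.4 h
rather than 24 h (time can be rescaled via `rescale_time`, which
multiplies all per-time parameters and leaves every ratio-valued feature
unchanged).

### Parameters and the two calibrated translation rates

The canonical set carries 45 published kinetic constants.  The protein
balance equations additionally require the Cry1/Cry2 translation rates
(`K_tln_c1`, `K_tln_c2`), for which no published values exist.  They
were calibrated once against the published model outputs — the
free-running period, the Cry1/Cry2-knockout relative periods (0.95 /
1.16), the *Per* and *Rev-erbα* peak-to-trough ratios (51.19 / 18.90)
and the PER relative abundance — with a Nelder–Mead search over the two
rates, and are shipped frozen (`K_tln_c1 = 0.84609`,
`K_tln_c2 = 0.98606`).  With this completion the model reproduces the
period to ~1 %, both knockout period ratios to ~1.5 %, both
peak-to-trough ratios to ~2 % and the Bmal1→Per phase difference, but
not every published feature simultaneously (notably the rev→PER phase
difference and the PER relative abundance); the calibration residual is
an irreducible property of this completion, not a numerical artifact.

### Knockouts

A gene knockout zeroes its transcription rate(s): *Bmal1*, whose
promoter function has no single basal rate, zeroes both RORE numerator
rates.  In this parameterisation Cry1 knockout shortens and Cry2
knockout lengthens the period, double-Cry and Per knockouts silence the
oscillator, and Ror knockout leaves it essentially unchanged.  Bmal1
knockout leaves the negative loop rhythmic (BMAL1 enters the Ebox rate
only through the small K_b term), and Rev-erbα knockout silences the
oscillator — both contrary to experimental observations; they are
reported as the model produces them.

## Limit cycle and phase

`find_limit_cycle` integrates (LSODA, rtol 1e-8, atol 1e-10) from a
fixed state (all species at 1.0) through a 1000 h burn-in, then detects
the cycle on a 300 h window.  The period is the mean interval between
rising midrange crossings of *Per* mRNA (the Poincaré section), averaged
over at least five returns.  Oscillation requires: ≥ 5 section returns,
cycle-to-cycle period spread < 1 %, and every species' max/min ratio
above 1.001 over the last cycles; otherwise the verdict is
non-oscillatory (`None`) — the value the fitting cost maps to its
maximum.  The orbit is re-integrated from the *Per*-mRNA peak (phase
zero) and stored at 1000 uniform phase points with a periodic cubic
interpolant; closure ‖x(0)−x(T)‖/‖x(0)‖ is ~1e-8.

Asymptotic (isochron) phase of an arbitrary state integrates forward in
quarter-period steps until the state lies within Euclidean distance
1e-3 of the orbit, matches the nearest orbit point (golden-section
refinement on the interpolant), and subtracts the accumulated
free-running phase ω·t.

## Sensitivities and parametric phase response curves

One variational sweep over the cycle underlies all local sensitivities.
The linearised flow is propagated with a midpoint exponential (Magnus)
integrator on an 8192-step grid: per step the block-augmented matrix
exponential of [[J·h, G·h], [0, 0]] advances both the fundamental matrix
M(t) and the parameter-inhomogeneous solutions Z(t) for all parameters
at once (J = ∂f/∂x and G = ∂f/∂p are generated symbolically with sympy
and verified against the hand-coded RHS in the tests).  The exponential
propagator is exact for the frozen-Jacobian substeps, which keeps the
stiff PER-degradation spike (K_deg_P = 3.1e-4) harmless.

* **Period sensitivities** dT/dp solve the periodicity boundary-value
  problem on the section through the anchor: (M(T) − I)·w + Z(T) +
  f(x₀)·dT/dp = 0 with w constrained to the section — one 15×15 LU
  solve for all parameters.
* **Amplitude sensitivities** evaluate the perturbed-orbit state
  sensitivity M(t*)·w + Z(t*) at the species' peak time t*, where the
  timing term vanishes to first order.
* **ipPRCs** use the adjoint (left Floquet) eigenfunction: Q(0) is the
  left eigenvector of the monodromy at multiplier 1, normalised to
  Q·f = ω, swept backwards with the stored step propagators;
  PRC_p(φ(t)) = Q(t)·∂f/∂p(x(t)).

The two routes satisfy ∫₀ᵀ PRC_p(φ(t)) dt = −(2π/T)·dT/dp, checked for
every parameter; central finite differences of re-simulated periods
(relative step 1e-3) serve as the external oracle.  Positive lobe =
region with PRC > 0 (phase advance per unit parameter increase); lobe
areas are signed integrals over phase.  The loop partition places every
Per/Cry/PER:CRY constant — including the Ebox constant K_b — in the
negative loop and the Ror/Rev-erbα/Bmal1 constants in the positive
loop.

## Fitting

The cost sums weight × squared error over numeric features and weight ×
{0,1} over inequality features of the shipped 42-row feature table, and
returns 1e6 (a value dominating any achievable weighted error) for
non-oscillatory sets or failed integrations.  The genetic algorithm is
generational with tournament selection (size 3), blend crossover
(probability 0.5, α 0.5), per-gene Gaussian mutation (probability 0.1,
σ 10 % of the current value), one-individual elitism, log-uniform
initialisation within ×/÷3 of the seed vector, and optional restarts;
it is fully reproducible from its seed.  The original search ran at
population 10,000 over 50 generations; the package exercises the GA on
reduced problems and ships the published optimum as the canonical set.

The robustness scan varies each parameter individually on a 1 % grid up
to ±50 %.  A variation is tolerated when both signed variants keep
oscillating *and* keep the fitted Cry-knockout bounds (Cry1-KO relative
period < 0.95, Cry2-KO > 1.15 — the most heavily weighted cost
features).  The failure boundary is located by bisection on the grid
(failure is monotone in the variation size here, verified against a
linear scan); scan integrations use relaxed tolerances (rtol 1e-6),
under which every verdict is unchanged.

## Phase-only control

A small molecule maps to fractional modulation u ∈ [0, u_max] of its
target parameter(s) with a fixed action sign; u_max defaults to 0.5
(half the nominal value).  The phase-only model

    dφ̂/dt = ω + Σ_j [Σ_k sign_jk·p_k·PRC_{p_k}(φ̂)]·u_j

drives a receding-horizon controller (timestep 2 h, prediction horizon
3 steps): at each step the horizon problem — squared wrapped phase error
(in (−π, π]) plus a small input penalty q = 1e-3, subject to the input
bounds — is solved by enumerating the bang-bang input corners and
polishing the best with SLSQP; the first input is applied to the full
14-state model as a piecewise-constant parameter modulation for one
timestep; the asymptotic phase of the resulting state closes the loop.
Three deliberate choices:

* q > 0 (rather than exactly 0) because a flat objective at zero-gain
  phases otherwise admits arbitrary large inputs whose unmodelled
  full-model response perturbs a settled trajectory;
* the reference offset is frozen at the current time within the horizon
  (no preview of scheduled future shifts), so settling is measured per
  segment without anticipatory action;
* a soft trust region (π/2 per step) bounds the input-induced phase
  deviation the linear prediction may claim.

Settling time of a protocol segment is the earliest time (linearly
interpolated between controller steps) after which the wrapped error
stays within 0.1 rad until the segment ends, measured from the shift
onset.  The canonical protocol applies a +5 h reference advance at 12 h
and an 11 h delay at 84 h over 240–300 h.

The linearity validation modulates each small-molecule target parameter
(and each pair) by +10 % for T/24, at a uniform grid of application
phases, measures the full-model asymptotic phase shift, predicts the
shift with the phase-only model, and reports the ordinary
least-squares slope, intercept and r².

## Numerical choices and degenerate inputs

Integration tolerance undershoots below zero (|x| ≲ atol) are clipped
when states are re-used as initial conditions.  A species whose orbit
trough reaches exactly zero reports an infinite peak-to-trough ratio.
Peaks are localised by quadratic interpolation around the discrete
orbit maximum.  Phase differences use the fixed convention "from the
first-named species' peak forward to the next peak of the second";
relative abundances are ratios of one-period means.  Zero-length
integration spans return the initial state; an empty knockout set is
the wild type.

## Known limitations

The two Cry translation rates are calibrated, not published, so
waveform features sensitive to the CRY1/CRY2 balance (PER relative
abundance, rev-phase relations, the robustness margins of the Cry2
bound) deviate from the published fit.  The Bmal1/Rev-erbα knockout
rhythmicity pattern is inverted relative to experiment under this
equation set.  The controller's linear phase prediction degrades near
the PER-trough phase where the full model's response to large
modulations saturates and can slip nearly a full cycle; the closed loop
recovers by feedback but multi-input settling then need not beat the
best single input on the advance segment.  Sensitivities are local
(no global/Sobol analysis), and there is no stochastic simulation, no
delay formulation, and no pharmacokinetics of the inputs.
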