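# circadian-dualloop

A control-oriented model of the mammalian molecular circadian clock.

The package implements a 14-state ODE model of the two interlocked
transcription–translation feedback loops that drive cellular circadian
rhythms — the negative loop (*Per*, *Cry1*, *Cry2* and the nuclear
PER:CRY heterodimers repressing Ebox-driven transcription) and the
positive loop (*Ror*, *Rev-erbα*, *Bmal1* competing at the RORE
promoter) — together with everything needed to analyse and steer its
phase:

* limit-cycle detection, period estimation and asymptotic (isochron)
  phase assignment;
* the fitted waveform feature set: peak-to-trough ratios, relative
  abundances, peak phase differences, Cry-knockout period responses;
* local sensitivity analysis: period sensitivities dT/dp, amplitude
  sensitivities dA_x/dp and infinitesimal parametric phase response
  curves PRC_p(φ) = ∂²φ/∂t∂p, computed by a variational/adjoint sweep
  of the cycle;
* a weighted-feature fitting cost with a genetic-algorithm search and a
  single-parameter robustness scan;
* model-predictive control (MPC) of circadian phase using small
  molecules (KL001, Longdaysin, KK-S6, FBXW7-α, GSK3-β inhibitors) that
  act by modulating specific kinetic parameters, via the phase-only
  reduction dφ̂/dt = ω + Σ_j PRC_{p_j}(φ̂)·u_j.

It is intended for computational chronobiologists and control engineers
studying which molecular targets shift circadian phase fastest, and for
simulating closed-loop chronotherapy dosing protocols in silico.

The shipped canonical parameter set is the published fitted optimum; the
two Cry translation rates it omits were calibrated once against the
published model outputs (see `docs/methods.md`).

## Worked example

```python
import dualloop as dl

params = dl.canonical_parameters()

lc = dl.find_limit_cycle(params)
print(f"period = {lc.period:.2f} h")

ko = dl.find_limit_cycle(dl.apply_knockout(params, ["Cry1"]))
print(f"Cry1-KO relative period = {ko.period / lc.period:.3f}")

from dualloop.features import peak_trough_ratio, phase_difference
print(f"Rev-erba mRNA peak/trough = {peak_trough_ratio(lc, 'rev'):.2f}")
print(f"Bmal1->Per phase difference = {phase_difference(lc, 'b', 'p'):.1f} %")

from dualloop.sensitivity import CycleSensitivity
sens = CycleSensitivity(params, lc=lc)
print(f"dT/dK_tln_b = {sens.period_sensitivity('K_tln_b'):+.3f} h/unit")
print(f"dT/dK_tln_p = {sens.period_sensitivity('K_tln_p'):+.3f} h/unit")

from dualloop.control import canonical_inputs, run_mpc
res = run_mpc(params, [canonical_inputs()["KL001"]], analysis=sens)
print(f"advance settling = {res.settling_times([12.0, 84.0])[12.0]:.1f} h")
```

prints

```
period = 27.43 h
Cry1-KO relative period = 0.947
Rev-erba mRNA peak/trough = 19.23
Bmal1->Per phase difference = 54.0 %
dT/dK_tln_b = +0.749 h/unit
dT/dK_tln_p = -2.182 h/unit
advance settling = 43.3 h
```

The free-running period is ~27.4 h (time units are arbitrary and can be
rescaled); knocking out *Cry1* shortens the period by ~5 % while *Cry2*
knockout lengthens it; increasing BMAL1 translation lengthens the period
and increasing PER translation shortens it; and the KL001-driven
controller realigns the clock with a 5 h reference advance in about 43 h.

## Command line

Each subcommand reads one YAML config and writes CSV/JSON outputs plus a
run manifest:

```bash
circadian-dualloop simulate cfg.yaml      # trajectory CSV
circadian-dualloop features cfg.yaml      # waveform feature report
circadian-dualloop knockout cfg.yaml      # knockout rhythmicity table
circadian-dualloop sensitivity cfg.yaml   # dT/dp (+ amplitude) CSV
circadian-dualloop prc cfg.yaml           # ipPRC curves CSV
circadian-dualloop fit cfg.yaml           # GA search (reduced scale)
circadian-dualloop robustness cfg.yaml    # single-parameter scan
circadian-dualloop mpc cfg.yaml           # closed-loop phase shifting
circadian-dualloop validate cfg.yaml      # knockout/sensitivity suite
circadian-dualloop linearity cfg.yaml     # phase-only model validation
```

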