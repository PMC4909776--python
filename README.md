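# respsnn

A software re-implementation of a bio-inspired, FPGA-hosted ventilatory
pacing controller, co-simulated with a computational model of rat
breathing.

Cervical spinal cord injury can cut the brain's respiratory network off
from the diaphragm.  Closed-loop diaphragmatic pacing proposes to replace
the missing drive with electrical stimulation that *adapts* to the animal's
metabolic state instead of imposing a fixed pattern.  This package is aimed
at researchers in neuroprosthetics and computational neuroscience who want
to study such a controller without hardware: it reproduces, in Python, a
spiking-neural-network (SNN) controller faithful to its fixed-point
hardware arithmetic, and closes the loop around a rat ventilation model
(native drive, lung mechanics, CO2 metabolism) at the controller's 2 kHz
update rate.

## The model

The controller is a central pattern generator of leaky integrate-and-fire
neurons,

  τ_m dv_m/dt = −v_m(t) + R_m I_tot(t),

discretized as v[t+1] = v[t] + (TPP[t] − v[t])·2^−3 at dt = 0.5 ms, with a
spike when v crosses θ and a one-step refractory reset.  Connections carry
a fraction of bound receptors r(t) under a two-branch kinetic synapse
model, discretized as r[t+1] = B·r[t] + A during the transmitter pulse and
r[t+1] = C·r[t] after it (A = dt·α, B = 1 − dt(α+β), C = 1 − dt·β), and
each neuron integrates the total postsynaptic potential
TPP = Σ_i P_i·r_i(t) over its incoming connections.  The fixed-point
backend stores r as an 18-bit unsigned fraction, A/B/C as 14-bit unsigned
fractions, and v in a saturating signed word, with truncation everywhere —
bit-faithful to the hardware datapath; a float64 oracle backend shares the
same code path.

The plant couples a sawtooth native drive (attenuated by a weighted injury
factor), a saturating recruitment map, damped-spring lung mechanics with
non-linear stiffness, and a CO2 mass balance whose breath-by-breath pacing
mechanism holds the CO2 amount constant.  Sensor encoders turn volume and
CO2 into tonic spike trains; the follower neuron's spike density over the
trailing 10 ms (the *stimulation ratio*, spikes/20) is the muscle drive.
Simplified spike-timing-dependent plasticity adapts the frequency- and
amplitude-setting strengths on-line in the closed loop.

See `docs/methods.md` for the full model account, parameter tables and
limitations.

## Worked example

Run the eupnea experiment (non-injured rat, baseline metabolic demand,
controller off) and print the breath summary:

```python
from respsnn import Scenario, run_scenario

result = run_scenario(Scenario(name="eupnea", wi=1.0, duration=60.0))
print(result.summary)
```

```
{'scenario': 'eupnea', 'n_breaths': 55, 'schema_version': 1,
 'rr_last10': 56.0748, 'vt_last10': 1.9999,
 'minute_ventilation_last10': 112.1436, 'cv_rr_final': 0.0418,
 'stabilization_cycle': 10}
```

The calibrated plant breathes at 56.1 breaths/min with a 2.00 mL tidal
volume (the eupneic definition), minute ventilation ≈ 112 mL/min, and a
rate CV of 0.05% — far below the 4% "constant breathing" criterion, met at
the earliest possible cycle (10, when the trailing window first fills).

Closed-loop adaptation of an injured model (90% native drive, controller
switched on at t = 5 s):

```python
from respsnn import Scenario, run_scenario
from respsnn.metrics import normalized_rr

ref = run_scenario(Scenario(name="ref", wi=1.0, duration=45.0))
off = run_scenario(Scenario(name="off", wi=0.9, duration=45.0))
on = run_scenario(Scenario(name="on", wi=0.9, controller_mode="closed_loop",
                           controller_on_t=5.0, duration=50.0))
print(normalized_rr(off.records, ref.records),
      normalized_rr(on.records, ref.records))
```

```
1.0443 1.0344
```

Injury speeds breathing up (the pacing mechanism compensates for the
shallower breaths); the stimulation pulls the normalized rate back toward
1.0.

A command-line interface wraps the same machinery:

```
respsnn calibrate                 # plant calibration report (optionally --theta)
respsnn run --wi 0.8 --mode closed_loop --duration 60
respsnn sweep-bits --bits 16,18,20 --pf 4000,5000,6000
respsnn network-stats             # connectivity-density table rows
respsnn fixtures --seed 1         # synthetic reference waveforms
```

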