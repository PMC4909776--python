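# Methods

`respsnn` simulates a closed-loop ventilatory pacing system: a small spiking
neural network (SNN) controller, executed with the quantized fixed-point
arithmetic of its hardware (FPGA) implementation, coupled at a shared 0.5 ms
step to a computational model of rat breathing.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic test conditions do and do not establish.

## Controller model

**Neurons.**  Leaky integrate-and-fire, expressed in the displacement of the
membrane voltage from rest (so rest and reset are both 0):

    v[t+1] = v[t] + (TPP[t] - v[t]) / 2^leak_shift

with `leak_shift = 3` (the membrane time constant is 8 steps = 4 ms, and the
division is a hardware right shift).  A neuron spikes when `v >= theta`; the
following step is an absolute refractory step during which `v` is pinned to
rest, so the maximum firing rate is one spike per two steps.

**Synapses.**  Each connection carries a fraction of bound receptors `r`
under a two-branch kinetic scheme (a one-multiplier reduction of the
Destexhe receptor-binding model).  During the one-step transmitter pulse
that follows a presynaptic spike, and after it:

    r[t+1] = B r[t] + A        (pulse)      A = dt*alpha
    r[t+1] = C r[t]            (otherwise)  B = 1 - dt*(alpha+beta)
                                            C = 1 - dt*beta

which is forward Euler applied to dr/dt = alpha(1-r) - beta r and
dr/dt = -beta r at dt = 0.5 ms, with alpha, beta in s^-1.  Five kinetic sets
span rise constants 1-15.9 ms and decay constants 10-200 ms; the slow sets
(decay 100-200 ms) are what lets a network clocked at 2 kHz produce
breath-scale rhythms.  A neuron's total postsynaptic potential is
`TPP = sum_i P_i r_i` over its incoming connections, where the signed
strength potential `P` folds synaptic strength and input resistance into one
controller-unit number.

**Sequencer.**  Each step runs two phases exactly as the hardware does:
phase 1 advances every `r` using the previous step's spike bits; phase 2
computes every TPP from the phase-1 `r`, then every membrane/spike update.
Nothing written in a phase is read in the same phase, so update order within
a phase cannot change the result (a property test permutes connection order
and requires bit-identical trajectories).

**Fixed-point backend.**  `r` is an unsigned pure fraction (18 bits in the
reference design; sweepable 16-32), A/B/C are 14-bit unsigned fractions,
and v/TPP live in a signed word with 18 fraction bits and 17 integer bits —
chosen so the largest reference strength (8000) times `r = 1` summed over
the 8-connection hardware fan-in limit cannot overflow; the accumulator
saturates rather than wraps.  All quantization is truncation (floor on the
raw integer), the behavior of a bare multiplier/shifter datapath; negative
shifts are arithmetic (floor), pinned by test.  A float64 oracle backend
shares the identical code path.

Bit-exact agreement between the two backends cannot persist: the network
operates near threshold by design, and a single least-significant-bit
difference eventually flips a threshold crossing, after which the two runs
dephase.  The shipped checks therefore pin (a) a one-step bound — from any
shared quantized state a fixed-point kinetic update stays within one output
LSB of exact arithmetic on the 14-bit constants — and (b) rhythm-level
agreement: both backends produce the same activity ordering and steady
rates within 2.5% (measured: ≈1.9% at the reference threshold).

## Reference networks

The open-loop roster has seven neurons wired by sixteen published
(kinetic-set, strength) pairs: three trigger/output pairs — IE/E_dec
(expiratory), I_decTON/I_dec (inspiratory), EI_TON/EI (expiration-to-
inspiration transition) — plus an ON neuron carrying the external start
trigger.  The roster file uses the table names (`Edec_TON` = IE, etc.); the
`FIGURE_ALIASES` map records the correspondence.  The rhythm is a
relaxation oscillator: an IE burst drives E_dec through the slow +5000
connection (decay 200 ms), E_dec suppresses IE through the slow -2200
connection, and the two slow decays set the expiratory and inspiratory
durations.  The follower neuron I_inc — whose wiring roles are published
but whose strengths are not — converts the core activity into the
stimulation drive; its strengths ship in the reference configuration and
are labelled not-published.

The closed-loop roster adds three sensor-driven tonic neurons (Vol_spk for
lung volume, C1_spk/C2_spk for CO2 excess/deficit), for ten neurons and 24
internal connections plus three external sensor inputs.  The eight
tonic-side strengths are likewise unpublished; the shipped values were
chosen by calibration at the reference threshold so that (i) Vol_spk
phase-locks the SNN rhythm to the plant's breathing (its +60 nudge onto IE
advances the inspiratory-expiratory transition toward the volume peak),
and (ii) C1/C2 shorten/lengthen expiration when CO2 is high/low.
Connectivity-density accounting (all-to-all = 100 C/N^2, MaxC-to-all,
8-to-all, C/N) reproduces both published reference rows from roster counts
alone; densities are computed exactly and displayed truncated to one
decimal, the convention of the published table.

## Spike threshold

The threshold is not a published value, and the printed strengths span
+40 to +8000, so a single global theta must sit where the small tonic
self-excitations (+40) are subthreshold while graded firing remains
possible on the +200/+400 pathways.  The shipped calibration sweep selects
the smallest grid value for which *both* backends sustain a stable rhythm
inside the eupneic 56-67 breaths/min band: theta = 10 controller units
(fixed backend 58.7, float 57.6 breaths/min).  At this operating point the
emergent pattern reproduces the qualitative published activity: decrementing
E_dec and I_dec envelopes, a late-inspiratory I_inc ramp cut abruptly at
the IE burst, and a double-peaked EI (a brief peak as expiration fades,
before I_dec, then a longer second peak) — the same secondary behavior the
hardware study reports.

## Plasticity

Two strengths adapt on-line: P(f), the IE→E_dec node that sets rhythm
frequency, and P(a), the I_inc self-excitation that shapes stimulation
amplitude.  The kernel is the minimal "simplified" spike-timing-dependent
rule: a two-sided step function — every causal pre-before-post pairing
within a 20-step (10 ms) window adds `a_plus`, every anti-causal pairing
subtracts `a_minus`, simultaneous spikes pair with neither, and the result
clamps to `[p_min, p_max]`.  No published magnitudes exist; the shipped
rates (1.0 for P(f), 0.2 for P(a)) and bounds (P(f) in [3500, 6500], P(a)
in [500, 1300]) come from calibration and keep the adaptation inside the
band where the rhythm is well-behaved.  The updating spike trains are the
tonic teacher (Vol_spk) paired with the relevant core neuron, applied every
computation step in the kinetic-phase slot.  Sustained volume activity
preceding E_dec firing therefore potentiates P(f), lengthening expiration
and lowering the rhythm frequency (pinned by a regression test).  P(inj)
strengths are a per-scenario configuration table, not learned; the
meta-plasticity rule that would learn them is a stub interface.

## Stimulation interface

The drive delivered to the muscle each step is the stimulation ratio:
spikes of the follower neuron over the trailing 20 steps divided by 20
(resolution 1/20; the refractory period caps it at 0.5 in practice).
Electrical pulse-train synthesis is out of scope.  Sensor encoders are
deterministic clocked dividers — a phase accumulator advancing by the
instantaneous rate, spiking on wrap — with piecewise-linear clamped
transfer curves: Vol_spk rate-codes normalized volume over a calibrated
0.2-2.0 mL range, and C1/C2 code the relative CO2 excess/deficit with a
20% span and a dead band exactly at baseline.  A seeded Bernoulli variant
exists for robustness experiments; the deterministic form is the default so
that whole runs are bit-reproducible.

## Plant model

* **Native drive**: a spaced sawtooth — a linear ramp over the inspiratory
  fraction (0.35) of each cycle, silence for the rest — scaled by the
  weighted injury factor `wi` (1.0 intact; 0.9/0.8/0.75 incomplete injury;
  0 complete injury).
* **Activation**: native + stimulated, clipped at 1 (deliberate first
  approximation).  A monotone saturating static map
  `(1 - e^(-1.5 u)) / (1 - e^(-1.5))` converts activation to normalized
  force; this is a stand-in chosen here, not a motor-unit recruitment
  model.
* **Mechanics**: `m x'' = F - c x' - k(x) x` with normalized displacement
  `x`, resting stiffness 900 (natural frequency 30 s^-1), damping 72
  (damping ratio 1.2, overdamped everywhere in the working range — pinned
  by an eigenvalue test), and piecewise-linear stiffening above x = 0.7.
  Lung volume is `vol_gain * x`.  Integration is semi-implicit Euler at
  the controller step (velocity first, then position), which is stable with
  margin at 0.5 ms.
* **Metabolism**: `co2' = co2 + mbc*MBC0*dt - k_ex * (expired volume this
  step) * co2`.  Clearance is continuous (proportional to expired flow
  times the current CO2 amount) rather than a per-breath lump; per-breath
  accounting is recovered by integration, and a bookkeeping identity
  (cumulative production minus clearance equals the CO2 change, exactly)
  holds on every run.  CO2 is in arbitrary mass units — only ratios
  matter — with the eupneic amount defining 1.0 and baseline production
  0.1 units/s.
* **Breath-by-breath pacing**: at each breath boundary the native-drive
  rate is set to `(a + b*mbc) * (co2/co2_ref)^gain` (gain 8, clamped to
  [20, 150] breaths/min).  The linear regression is the published
  mechanism; the CO2-error factor is this package's closure of it — without
  it a rate keyed to metabolic demand alone could not raise the rate of an
  injured (low tidal volume) model, which the study's own controller-OFF
  results require.  At eupnea the factor is exactly 1.

**Calibration** (`calibrate_plant`) is deterministic and seed-free:
`vol_gain` is set in one shot from the steady displacement amplitude under
eupneic drive (the displacement dynamics are independent of the volume
scale); `k_ex` by a fixed-point iteration driving the per-breath CO2 change
at eupnea below 0.1% of per-breath production; and the regression by a
balance sweep over demand multipliers {1.0, 1.06, 1.11, 1.17} with a least
squares line through the balancing rates.  The calibrated non-injured model
holds 56.1 breaths/min and 2.00 mL with per-breath CO2 drift ~3e-5 units.
Calibration is idempotent and raises with its search trace when the target
is unreachable (e.g. zero muscle force).

## Metrics

Breaths are segmented at volume minima with a hysteresis detector (band =
0.2 of the overall amplitude) so 1%-amplitude noise cannot split cycles.
Per breath: period, rate (60/period), tidal volume (in-breath max minus
min), minute ventilation, and the coefficient of variation of the rate over
the trailing 10 breaths using the population (n) convention — the sample
convention is the open alternative; the population form is pinned in
config and tests.  "Constant" breathing is CV < 4%.  The stabilization
cycle is the first breath (counting from the perturbation) whose trailing
CV is below threshold *and stays below it to the end of the run*, since a
transient CV peak above threshold can precede settling.  Normalized rate is
the mean over the last 10 breaths divided by the same quantity of a
non-injured reference run.

## Problem sizes and what the tests show

The shipped experiment sizes are chosen for a desk-scale study: open-loop
rhythm runs of 12-30 s, closed-loop adaptation runs of 45-50 s (about 45
breaths), and a bit-width sweep over {16, 18, 20, 32} fraction bits by
three P(f) values at 25 s each.  At these sizes the simulator reproduces,
from first principles: the full kinetic-constant table to printed
precision; the stimulation-ratio anchors; both connectivity-density rows;
the eupneic operating point (56.0 breaths/min, 2.0 mL within 2%); the
open-loop activity ordering; the controller-OFF ordering of injured
breathing rates (more injury → faster breathing) and its reduction toward
the non-injured rate when the closed loop activates, with rate CV settling
below 4% within 30 breaths; and the monotone shrinkage of the rate error
with the bound-receptor word width (measured max deviations ≈5.3 / 0.79 /
0.18 breaths/min at 16/18/20 bits against the 32-bit reference).

What they do not show: real phrenic drives are not sawtooths, real recruitment
is not a static map, and real breathing carries variability the deterministic
plant lacks, so the closed loop's absolute adaptation delays (in breaths) are
properties of this synthetic plant, not predictions for an animal.  The
unpublished strengths (follower wiring, tonic-side connections, STDP
magnitudes, the spike threshold) are calibrated choices; conclusions that
depend on their exact values — e.g. the precise normalized-rate trajectories
of the published closed-loop figures — are reproduced as orderings and
threshold properties, not as numbers.

## Known limitations

* One neuron per population; the study itself notes a population-per-node
  design would sharpen I_dec and EI timing.
* No O2 dynamics, blood-gas transport, electrode or pulse-train modelling,
  and no axonal delays (the hardware design has none).
* The CO2-feedback pacing gain (8) is a modelling choice; the controller-OFF
  rate elevations it produces (≈1.04/1.11/1.15 at 90/80/75% drive) are
  ordered as in the published data but smaller in magnitude, partly because
  the saturating recruitment map compresses the injury's effect on tidal
  volume.
* The fixed-point backend matches its hardware conventions (truncation,
  saturation, arithmetic shifts) but no claim is made of gate-level
  equivalence to any particular device.
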