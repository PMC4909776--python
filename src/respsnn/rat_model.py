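"""Computational model of rat breathing (the plant of the closed loop).

Four coupled pieces, all advanced at the controller step (0.5 ms):

* **Native drive** — a spaced sawtooth: the phrenic activation ramps
  linearly over the inspiratory fraction of each cycle and is silent over
  the rest.  A weighted injury factor ``wi`` in [0, 1] attenuates it
  (incomplete spinal cord injury; ``wi = 0`` is complete injury).
* **Activation** — native and stimulated activation sum linearly (a
  deliberate first approximation) and clip at 1.  A monotone saturating
  static recruitment map converts activation to muscle force; it stands in
  for a full motor-unit recruitment model, which is not part of this
  simulator.
* **Musculoskeletal** — the diaphragm/thorax is a damped spring with
  non-linear (stiffening) stiffness driven by the muscle force; lung volume
  is linearly proportional to the diaphragm displacement.
* **Metabolism** — body CO2 mass grows at a fixed production rate (scaled
  by the metabolic-demand parameter ``mbc``; MBC0/MBC11/MBC17 are
  multipliers 1.0/1.11/1.17) and is cleared in proportion to expired flow
  times the current CO2 amount.  At the calibrated eupneic operating point
  (56 breaths/min, 2 mL tidal volume) production and clearance balance
  breath by breath.

The *dynamical respiratory-rate mechanism* re-paces the native drive at
each breath boundary: a linear regression RR = a + b*mbc (fitted by the
shipped calibration sweep) gives the feed-forward rate, multiplied by a
CO2-error correction ``(co2/co2_ref)^gain`` so that reduced tidal volume
(injury) raises the rate until the CO2 amount is again held constant —
exactly 1 at eupnea.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .snn_core import DT_S

__all__ = [
    "PlantParams",
    "PlantState",
    "RrRegression",
    "RatPlant",
    "native_drive",
    "combine_activation",
    "recruitment",
    "lung_step",
    "metabolism_step",
    "dynamical_rr",
    "calibrate_rr_regression",
    "calibrate_plant",
    "CalibrationError",
    "MBC_LEVELS",
]

#: Named metabolic-demand multipliers.
MBC_LEVELS = {"MBC0": 1.0, "MBC11": 1.11, "MBC17": 1.17}

#: Injury factors of the reference scenarios (fraction of native drive left).
INJURY_LEVELS = (1.0, 0.9, 0.8, 0.75, 0.0)


@dataclass(frozen=True)
class RrRegression:
    """Fitted linear relation RR = a + b*mbc (breaths/min per unit mbc)."""

    a: float
    b: float

    def __call__(self, mbc: float) -> float:
        return self.a + self.b * mbc


@dataclass(frozen=True)
class PlantParams:
    """Plant parameters.  Units: volume mL, time s, CO2 in arbitrary mass units.

    The mechanical state ``x`` is the normalized diaphragm displacement
    (working range about [0, 1]); ``vol_gain`` (mL per unit x) scales it to
    lung volume.  ``mbc0_rate`` is the baseline CO2 production (units/s) —
    only ratios of CO2 matter, so its absolute magnitude is a free choice —
    and ``k_ex`` the exhalation clearance gain (per mL of expired volume per
    CO2 unit).  ``vol_gain``, ``k_ex`` and the RR regression are set by
    :func:`calibrate_plant`.
    """

    wi: float = 1.0
    mbc: float = 1.0
    rr0: float = 56.0
    vt0: float = 2.0
    ti_frac: float = 0.35          # inspiratory fraction of the cycle
    mass: float = 1.0
    damping: float = 72.0          # zeta = 1.2 at the resting stiffness
    k0: float = 900.0              # resting stiffness (omega0 = 30 s^-1)
    k_knee: float = 0.7            # displacement where stiffening begins
    k_stiff: float = 0.5           # relative stiffening slope above the knee
    f_max: float = 900.0           # peak muscle force (same units as k0*x)
    recruit_sat: float = 1.5       # curvature of the saturating recruitment map
    vol_gain: float = 2.2          # mL per unit displacement (calibrated)
    co2_ref: float = 1.0           # eupneic CO2 amount (definition of units)
    mbc0_rate: float = 0.1         # baseline CO2 production, units/s
    k_ex: float = 0.0536           # clearance gain (calibrated)
    rr_gain: float = 8.0           # CO2-error exponent of the dynamical RR
    rr_min: float = 20.0
    rr_max: float = 150.0
    regression: RrRegression = RrRegression(a=0.0, b=56.0)

    def stiffness(self, x: float) -> float:
        """Non-linear spring stiffness: constant, then stiffening past the knee."""
        if x <= self.k_knee:
            return self.k0
        return self.k0 * (1.0 + self.k_stiff * (x - self.k_knee))


@dataclass
class PlantState:
    x: float = 0.0            # normalized diaphragm displacement
    x_dot: float = 0.0
    volume: float = 0.0       # mL
    co2: float = 1.0          # body CO2 amount (arbitrary units)
    phase: float = 0.0        # native-drive phase in [0, 1)
    rr_current: float = 56.0  # breaths/min
    t: float = 0.0            # s


def native_drive(phase: float, wi: float, ti_frac: float = 0.35) -> float:
    """Spaced-sawtooth native activation: ramp over the inspiratory fraction.

    Returns ``wi * ramp(phase)``: a linear 0-to-1 ramp for
    ``phase < ti_frac``, zero afterwards; the peak value is ``wi``.
    """
    if not 0.0 <= phase < 1.0:
        phase = phase % 1.0
    if phase < ti_frac:
        return wi * (phase / ti_frac)
    return 0.0


def combine_activation(native: float, stim: float) -> float:
    """Linear summation of native and stimulated activation, clipped at 1."""
    return min(native + stim, 1.0)


def recruitment(activation: float, sat: float = 1.5) -> float:
    """Monotone saturating static map from activation to normalized force.

    ``(1 - exp(-sat*u)) / (1 - exp(-sat))``: 0 at 0, 1 at 1, concave.
    """
    u = min(max(activation, 0.0), 1.0)
    return (1.0 - math.exp(-sat * u)) / (1.0 - math.exp(-sat))


def lung_step(state: PlantState, activation: float, params: PlantParams,
              dt: float = DT_S) -> PlantState:
    """One semi-implicit Euler step of the damped-spring lung mechanics.

    m x'' = F(activation) - c x' - k(x) x, with F through the recruitment
    map and volume = vol_gain * x.  The velocity is advanced first and then
    the position with the new velocity, which keeps the explicit scheme
    well-behaved at the 0.5 ms step.
    """
    if not (math.isfinite(state.x) and math.isfinite(state.x_dot)):
        raise ValueError("non-finite mechanical state")
    force = params.f_max * recruitment(activation, params.recruit_sat)
    acc = (force - params.damping * state.x_dot
           - params.stiffness(state.x) * state.x) / params.mass
    x_dot = state.x_dot + dt * acc
    x = state.x + dt * x_dot
    out = replace_state(state)
    out.x, out.x_dot = x, x_dot
    out.volume = params.vol_gain * x
    out.t = state.t + dt
    return out


def replace_state(s: PlantState) -> PlantState:
    return PlantState(x=s.x, x_dot=s.x_dot, volume=s.volume, co2=s.co2,
                      phase=s.phase, rr_current=s.rr_current, t=s.t)


def metabolism_step(co2: float, exhaled_volume: float, mbc: float,
                    params: PlantParams, dt: float = DT_S) -> float:
    """One step of the CO2 mass balance.

    co2' = co2 + mbc*MBC0*dt - k_ex * exhaled_volume * co2, floored at 0.
    ``exhaled_volume`` is the expired volume of this step (mL, >= 0).
    """
    if co2 < 0:
        raise ValueError("co2 must be non-negative")
    out = co2 + mbc * params.mbc0_rate * dt - params.k_ex * exhaled_volume * co2
    return max(out, 0.0)


def dynamical_rr(mbc: float, regression: RrRegression | None,
                 co2_ratio: float = 1.0, gain: float = 8.0,
                 rr_min: float = 20.0, rr_max: float = 150.0) -> float:
    """Breath-by-breath respiratory rate from the fitted RR-MBC regression.

    The feed-forward term ``a + b*mbc`` is corrected by the CO2 error,
    ``(co2/co2_ref)^gain``, so the pace rises until the CO2 amount is held
    constant; at eupnea the correction is exactly 1.
    """
    if regression is None:
        raise ValueError("RR regression has not been fitted; run calibrate_plant")
    correction = min(max(co2_ratio, 0.5), 2.0) ** gain
    return min(max(regression(mbc) * correction, rr_min), rr_max)


class RatPlant:
    """Stateful plant integrating drive, mechanics, metabolism and pacing.

    ``step(stim_ratio)`` advances one controller step and returns the new
    state.  ``dynamic_rr=False`` freezes the pace at ``rr0`` (used during
    calibration).  Cumulative CO2 production/clearance and inspired volume
    are book-kept for the mass-balance and minute-ventilation identities.
    """

    def __init__(self, params: PlantParams, dynamic_rr: bool = True,
                 rr_init: float | None = None):
        self.params = params
        self.dynamic_rr = dynamic_rr
        self.state = PlantState(co2=params.co2_ref,
                                rr_current=rr_init if rr_init is not None else params.rr0)
        self.breath_starts: list[float] = [0.0]
        self.co2_produced = 0.0
        self.co2_cleared = 0.0
        self.inspired_volume = 0.0
        self.co2_at_breath: list[float] = [params.co2_ref]

    def step(self, stim_ratio: float = 0.0, dt: float = DT_S) -> PlantState:
        p, s = self.params, self.state
        nat = native_drive(s.phase, p.wi, p.ti_frac)
        act = combine_activation(nat, stim_ratio)
        new = lung_step(s, act, p, dt)
        exhaled = max(s.volume - new.volume, 0.0)
        self.inspired_volume += max(new.volume - s.volume, 0.0)
        produced = p.mbc * p.mbc0_rate * dt
        cleared = p.k_ex * exhaled * s.co2
        new.co2 = max(s.co2 + produced - cleared, 0.0)
        self.co2_produced += produced
        self.co2_cleared += cleared
        new.rr_current = s.rr_current
        new.phase = s.phase + dt * s.rr_current / 60.0
        if new.phase >= 1.0:
            new.phase -= 1.0
            self.breath_starts.append(new.t)
            self.co2_at_breath.append(new.co2)
            if self.dynamic_rr:
                new.rr_current = dynamical_rr(
                    p.mbc, p.regression, co2_ratio=new.co2 / p.co2_ref,
                    gain=p.rr_gain, rr_min=p.rr_min, rr_max=p.rr_max,
                )
        self.state = new
        return new

    def run(self, duration_s: float, stim_fn=None, dt: float = DT_S) -> dict[str, np.ndarray]:
        """Run for ``duration_s`` seconds; returns full-rate traces."""
        n = round(duration_s / dt)
        vol = np.empty(n)
        co2 = np.empty(n)
        nat = np.empty(n)
        stim = np.empty(n)
        for k in range(n):
            u = stim_fn(self.state) if stim_fn else 0.0
            nat[k] = native_drive(self.state.phase, self.params.wi, self.params.ti_frac)
            stim[k] = u
            st = self.step(u, dt)
            vol[k] = st.volume
            co2[k] = st.co2
        return {
            "time_s": np.arange(1, n + 1) * dt + (self.state.t - n * dt),
            "volume_mL": vol,
            "co2": co2,
            "native": nat,
            "stim": stim,
        }


class CalibrationError(RuntimeError):
    """Calibration search failed to converge; the message carries the trace."""


def _breath_amplitudes(trace: dict[str, np.ndarray], boundaries_s: list[float],
                       settle: int) -> np.ndarray:
    t = trace["time_s"]
    v = trace["volume_mL"]
    amps = []
    for a, b in zip(boundaries_s[:-1], boundaries_s[1:]):
        sel = (t >= a) & (t < b)
        if sel.any():
            amps.append(v[sel].max() - v[sel].min())
    return np.asarray(amps[settle:])


def calibrate_rr_regression(params: PlantParams,
                            mbc_grid: tuple[float, ...] = (1.0, 1.06, 1.11, 1.17),
                            ) -> RrRegression:
    """Fit RR = a + b*mbc by a balance sweep.

    For each demand level the rate that zeroes the per-breath CO2 change at
    the reference CO2 amount is found from the simulated tidal volume
    (clearance = k_ex * co2_ref * Vt per breath, production =
    mbc * MBC0 * period), iterating because Vt depends weakly on the rate;
    a least-squares line through the balance points gives (a, b).
    """
    rrs = []
    for mbc in mbc_grid:
        rr = params.rr0 * mbc  # starting guess
        for _ in range(3):
            vt = _vt_at_rate(params, rr)
            rr = mbc * params.mbc0_rate * 60.0 / (params.k_ex * params.co2_ref * vt)
        rrs.append(rr)
    b, a = np.polyfit(np.asarray(mbc_grid), np.asarray(rrs), 1)
    return RrRegression(a=float(a), b=float(b))


def _vt_at_rate(params: PlantParams, rr: float, n_breaths: int = 10,
                settle: int = 5) -> float:
    p = replace(params, wi=1.0, mbc=1.0, rr0=rr)
    plant = RatPlant(p, dynamic_rr=False)
    trace = plant.run(n_breaths * 60.0 / rr)
    amps = _breath_amplitudes(trace, plant.breath_starts, settle)
    return float(np.mean(amps))


def calibrate_plant(base: PlantParams | None = None,
                    vt_tol: float = 0.02, co2_tol: float = 0.005,
                    ) -> tuple[PlantParams, dict]:
    """Deterministic calibration to the eupneic definition (56/min, 2 mL).

    1. ``vol_gain`` — one-shot: the displacement dynamics are independent of
       the volume scale, so vol_gain = vt0 / (steady displacement amplitude).
    2. ``k_ex`` — fixed-point iteration driving the per-breath CO2 change at
       eupnea to zero (clearance scaled to match production).
    3. RR-MBC regression — balance sweep (see calibrate_rr_regression).

    Returns the calibrated parameters and a report; raises
    :class:`CalibrationError` with the search trace on failure.
    """
    params = base if base is not None else PlantParams()
    report: dict = {"trace": []}

    # -- volume scale ------------------------------------------------------
    p1 = replace(params, wi=1.0, mbc=1.0, vol_gain=1.0)
    plant = RatPlant(p1, dynamic_rr=False)
    trace = plant.run(12 * 60.0 / params.rr0)
    amp_x = float(np.mean(_breath_amplitudes(trace, plant.breath_starts, settle=6)))
    if not amp_x > 0:
        raise CalibrationError("no displacement oscillation under eupneic drive")
    vol_gain = params.vt0 / amp_x
    params = replace(params, vol_gain=vol_gain)
    report["vol_gain"] = vol_gain

    # -- clearance gain ----------------------------------------------------
    period = 60.0 / params.rr0
    k_ex = params.mbc0_rate * period / (params.co2_ref * params.vt0)
    for it in range(12):
        p2 = replace(params, wi=1.0, mbc=1.0, k_ex=k_ex)
        plant = RatPlant(p2, dynamic_rr=False)
        plant.run(14 * period)
        co2b = np.array(plant.co2_at_breath)
        dper = np.diff(co2b)[7:]
        mean_d = float(np.mean(dper))
        report["trace"].append({"iter": it, "k_ex": k_ex, "dco2_per_breath": mean_d})
        production = params.mbc0_rate * period
        clearance = production - mean_d
        if clearance <= 0:
            raise CalibrationError(f"no CO2 clearance at k_ex={k_ex}: {report['trace']}")
        if abs(mean_d) <= 1e-3 * production:
            break
        k_ex *= production / clearance
    else:
        raise CalibrationError(f"k_ex iteration did not converge: {report['trace']}")
    params = replace(params, k_ex=k_ex)
    report["k_ex"] = k_ex

    # -- RR-MBC regression -------------------------------------------------
    reg = calibrate_rr_regression(params)
    params = replace(params, regression=reg)
    report["regression"] = {"a": reg.a, "b": reg.b}

    # -- verification against the eupneic contract -------------------------
    check = RatPlant(replace(params, wi=1.0, mbc=1.0), dynamic_rr=True)
    trace = check.run(20 * period)
    amps = _breath_amplitudes(trace, check.breath_starts, settle=10)
    vt = float(np.mean(amps))
    periods = np.diff(np.array(check.breath_starts))[10:]
    rr = float(60.0 / np.mean(periods))
    co2b = np.array(check.co2_at_breath)
    dco2 = float(np.mean(np.abs(np.diff(co2b)[10:])))
    report.update({"rr": rr, "vt": vt, "dco2_per_breath": dco2})
    if abs(vt - params.vt0) > vt_tol * params.vt0:
        raise CalibrationError(f"tidal volume {vt:.3f} mL misses {params.vt0} +-2%: {report}")
    if abs(rr - params.rr0) > vt_tol * params.rr0:
        raise CalibrationError(f"rate {rr:.2f} misses {params.rr0} +-2%: {report}")
    if dco2 > co2_tol * params.co2_ref:
        raise CalibrationError(f"per-breath CO2 drift {dco2:.4f} exceeds 0.5%: {report}")
    return params, report
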