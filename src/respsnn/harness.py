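"""Experiment runner: controller + plant co-simulation at a shared 0.5 ms step.

Every scenario runs the same loop: plant sensors -> spike encoders ->
network step (plus on-line plasticity in closed loop) -> stimulation ratio
-> activation summation -> lung mechanics -> metabolism, with the
breath-by-breath rate mechanism applied at breath boundaries.  All
randomness (there is none in the core; only the optional stochastic encoder
variant and fixture noise) flows from the scenario seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics
from .network_library import (
    FIGURE_ALIASES,
    NetworkRoster,
    build_closed_loop,
    build_open_loop,
)
from .plasticity import OnlineStdp, PlasticityRule
from .rat_model import (
    PlantParams,
    RatPlant,
    RrRegression,
    calibrate_plant,
)
from .snn_core import DT_S, FixedPointParams, LifParams, Network
from .stimulation import Co2Encoder, VolumeEncoder

__all__ = [
    "Scenario",
    "ControllerConfig",
    "RunResult",
    "REFERENCE_THETA",
    "REFERENCE_PLANT",
    "reference_controller",
    "reference_plant",
    "run_scenario",
    "bit_accuracy_sweep",
    "generate_fixtures",
    "calibrate_theta",
    "measure_network_rr",
    "PAPER_SCENARIO_PAIRS",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
]

# ---------------------------------------------------------------------------
# Reference parameter values.
#
# REFERENCE_THETA is the spike threshold selected by the shipped calibration
# sweep (calibrate_theta): the smallest threshold on its grid for which the
# published open-loop network, ON-triggered, settles into a stable rhythm in
# the eupneic 56-67 breaths/min band.  The threshold is NOT a published
# value.  REFERENCE_PLANT holds the frozen output of calibrate_plant (which
# regenerates it deterministically; a test pins the agreement).
# ---------------------------------------------------------------------------

REFERENCE_THETA = 10.0  # calibrated; see calibrate_theta

REFERENCE_PLANT = PlantParams(
    vol_gain=2.3428183634775213,
    k_ex=0.05390800541219115,
    regression=RrRegression(a=-9.078842512122767, b=64.63949368959683),
)

#: Drive current injected into ON while the open-loop trigger is active.
ON_DRIVE = 4000.0

#: The six published injury/metabolic-demand pairs.
PAPER_SCENARIO_PAIRS = [
    (0.90, "MBC11"), (0.90, "MBC17"),
    (0.80, "MBC11"), (0.80, "MBC17"),
    (0.75, "MBC11"), (0.75, "MBC17"),
]


@dataclass(frozen=True)
class Scenario:
    """One experiment: injury level, demand schedule, controller mode."""

    name: str
    wi: float
    mbc_schedule: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    controller_mode: str = "off"  # off | open_loop | closed_loop
    controller_on_t: float = 0.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        times = [t for t, _ in self.mbc_schedule]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("mbc schedule times must be nondecreasing")
        if self.controller_mode not in ("off", "open_loop", "closed_loop"):
            raise ValueError(f"unknown controller mode {self.controller_mode!r}")

    def mbc_at(self, t: float) -> float:
        out = self.mbc_schedule[0][1]
        for ts, m in self.mbc_schedule:
            if t >= ts:
                out = m
        return out


@dataclass
class ControllerConfig:
    """Network + backend + plasticity + encoder configuration."""

    roster: NetworkRoster
    lif: LifParams
    fixed: FixedPointParams = field(default_factory=FixedPointParams)
    backend: str = "fixed"
    pulse_steps: int = 1
    stim_source: str = "I_inc"
    #: plastic tag -> STDP rule for connections carrying that tag.
    plasticity: dict[str, PlasticityRule] | None = None
    #: plastic tag -> (teacher pre neuron, post neuron) whose spike trains
    #: drive the STDP update of connections carrying that tag.
    teachers: dict[str, tuple[str, str]] = field(default_factory=dict)
    volume_encoder: VolumeEncoder = field(default_factory=VolumeEncoder)
    co2_encoder: Co2Encoder = field(default_factory=Co2Encoder)
    #: per-scenario P(inj) strength overrides: (pre, post) -> P
    p_inj: dict[tuple[str, str], float] = field(default_factory=dict)

    def build_network(self) -> Network:
        net = Network(
            neurons=self.roster.neurons,
            connections=self.roster.connections,
            lif=self.lif,
            backend=self.backend,
            fixed=self.fixed,
            pulse_steps=self.pulse_steps,
        )
        for (pre, post), p in self.p_inj.items():
            net.set_strength(net.connection_index(pre, post), p)
        return net


def reference_controller(
    mode: str = "open_loop",
    backend: str = "fixed",
    theta: float = REFERENCE_THETA,
    r_fraction_bits: int = 18,
    include_follower: bool = True,
) -> ControllerConfig:
    """The shipped reference controller configuration."""
    if mode == "open_loop":
        roster = build_open_loop(include_follower=include_follower)
    elif mode == "closed_loop":
        roster = build_closed_loop(include_follower=include_follower)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    plast = None
    teachers: dict[str, tuple[str, str]] = {}
    if mode == "closed_loop":
        plast = {
            "P_f": PlasticityRule(a_plus=1.0, a_minus=1.0, window_steps=20,
                                  p_min=3500.0, p_max=6500.0,
                                  targets=frozenset({"P_f"})),
            "P_a": PlasticityRule(a_plus=0.2, a_minus=0.2, window_steps=20,
                                  p_min=500.0, p_max=1300.0,
                                  targets=frozenset({"P_a"})),
        }
        teachers = {
            "P_f": ("Vol_spk", "Edec_OUT"),
            "P_a": ("Vol_spk", "I_inc"),
        }
    return ControllerConfig(
        roster=roster,
        lif=LifParams(theta=theta),
        fixed=FixedPointParams(r_fraction_bits=r_fraction_bits),
        backend=backend,
        plasticity=plast,
        teachers=teachers,
        volume_encoder=VolumeEncoder(v_min=0.2, v_max=2.0),
        co2_encoder=Co2Encoder(baseline=1.0, span=0.2),
    )


def reference_plant(wi: float = 1.0, mbc: float = 1.0,
                    recalibrate: bool = False) -> PlantParams:
    """The calibrated plant at a given injury level and metabolic demand."""
    base = calibrate_plant()[0] if recalibrate else REFERENCE_PLANT
    return replace(base, wi=wi, mbc=mbc)


@dataclass
class RunResult:
    scenario: Scenario
    trace: pd.DataFrame           # per-ms tidy trace
    records: list                 # BreathRecord list
    summary: dict
    plasticity_log: pd.DataFrame | None = None


def run_scenario(
    scenario: Scenario,
    controller: ControllerConfig | None = None,
    plant_params: PlantParams | None = None,
    outdir: str | Path | None = None,
    full_rate: bool = False,
    stim_scale: float = 1.0,
) -> RunResult:
    """Run one scenario end to end and return traces, breaths and summary.

    ``stim_scale`` multiplies the delivered stimulation ratio (0 runs the
    whole controller but delivers nothing to the plant, which must then
    behave step-identically to controller_mode="off").
    """
    plant_params = plant_params if plant_params is not None else reference_plant()
    plant_params = replace(plant_params, wi=scenario.wi,
                           mbc=scenario.mbc_at(0.0))
    if controller is None and scenario.controller_mode != "off":
        controller = reference_controller(
            mode=scenario.controller_mode
            if scenario.controller_mode != "off" else "open_loop"
        )
    if controller is not None:
        if controller.lif.dt != DT_S:
            raise ValueError("controller dt must match the 0.5 ms plant step")
        net = controller.build_network()
        vol_enc = replace(controller.volume_encoder,
                          seed=scenario.seed, stochastic=controller.volume_encoder.stochastic)
        co2_enc = replace(controller.co2_encoder,
                          seed=scenario.seed + 1, stochastic=controller.co2_encoder.stochastic)
        has_tonic = "Vol_spk" in net.index
        has_follower = controller.stim_source in net.index
        stdp: dict[int, OnlineStdp] = {}
        teachers_idx: dict[int, tuple[int, int]] = {}
        if controller.plasticity:
            for i, c in enumerate(net.connections):
                rule = controller.plasticity.get(c.plastic_tag)
                if rule is not None and c.plastic_tag in rule.targets and \
                        c.plastic_tag in controller.teachers:
                    pre_t, post_t = controller.teachers[c.plastic_tag]
                    stdp[i] = OnlineStdp(rule)
                    teachers_idx[i] = (net.index[pre_t], net.index[post_t])
    else:
        net = None

    plant = RatPlant(plant_params, dynamic_rr=True)
    n_steps = round(scenario.duration / DT_S)
    rec_stride = 1 if full_rate else 2
    n_rec = n_steps // rec_stride
    cols = {k: np.empty(n_rec) for k in
            ("time_s", "volume_mL", "flow", "co2", "native", "stim", "activation")}
    plog: list[tuple[float, str, float]] = []
    prev_volume = plant.state.volume

    mbc_current = scenario.mbc_at(0.0)
    stim = 0.0
    for k in range(n_steps):
        t = k * DT_S
        mbc_t = scenario.mbc_at(t)
        if mbc_t != mbc_current:
            mbc_current = mbc_t
            plant.params = replace(plant.params, mbc=mbc_t)
        controller_on = (
            scenario.controller_mode != "off" and t >= scenario.controller_on_t
        )
        if net is not None and controller_on:
            forced = None
            external = None
            if scenario.controller_mode == "closed_loop" and has_tonic:
                vs = vol_enc.step(plant.state.volume)
                c1, c2 = co2_enc.step(plant.state.co2)
                forced = {"Vol_spk": bool(vs), "C1_spk": bool(c1), "C2_spk": bool(c2)}
            else:
                external = {"ON": ON_DRIVE}
            net.step(external=external, forced_spikes=forced)
            if stdp:
                spikes = net.spikes
                for i, machine in stdp.items():
                    pre_i, post_i = teachers_idx[i]
                    new_p = machine.step(net.get_strength(i),
                                         int(spikes[pre_i]), int(spikes[post_i]))
                    if new_p != net.get_strength(i):
                        net.set_strength(i, new_p)
                    if k % 200 == 0:
                        c = net.connections[i]
                        plog.append((t, f"{c.pre}->{c.post}", new_p))
            stim = (
                int(net.spike_history_counts()[net.index[controller.stim_source]]) / 20.0
                if has_follower else 0.0
            ) * stim_scale
        else:
            stim = 0.0

        nat = plant_native(plant)
        st = plant.step(stim)
        if k % rec_stride == 0:
            i = k // rec_stride
            cols["time_s"][i] = st.t
            cols["volume_mL"][i] = st.volume
            cols["flow"][i] = (st.volume - prev_volume) / DT_S
            cols["co2"][i] = st.co2
            cols["native"][i] = nat
            cols["stim"][i] = stim
            cols["activation"][i] = min(nat + stim, 1.0)
        prev_volume = st.volume

    trace = pd.DataFrame(cols)
    records = metrics.segment_breaths(
        trace["volume_mL"].to_numpy(), dt=DT_S * rec_stride
    )
    summary = summarize(scenario, records)
    result = RunResult(
        scenario=scenario, trace=trace, records=records, summary=summary,
        plasticity_log=pd.DataFrame(plog, columns=["time_s", "connection", "P"])
        if plog else None,
    )
    if outdir is not None:
        write_artifacts(result, Path(outdir))
    return result


def plant_native(plant: RatPlant) -> float:
    from .rat_model import native_drive
    return native_drive(plant.state.phase, plant.params.wi, plant.params.ti_frac)


def summarize(scenario: Scenario, records: list) -> dict:
    out = {
        "scenario": scenario.name,
        "n_breaths": len(records),
        "schema_version": 1,
    }
    if len(records) >= metrics.CV_WINDOW:
        out["rr_last10"] = float(np.mean([r.rr for r in records[-10:]]))
        out["vt_last10"] = float(np.mean([r.vt for r in records[-10:]]))
        out["minute_ventilation_last10"] = float(
            np.mean([r.minute_ventilation for r in records[-10:]])
        )
        out["cv_rr_final"] = metrics.cv_rr(records)
        out["stabilization_cycle"] = metrics.stabilization_cycle(records)
    return out


def write_artifacts(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.trace.to_csv(outdir / f"{result.scenario.name}_trace.csv", index=False)
    metrics.records_to_frame(result.records).to_csv(
        outdir / f"{result.scenario.name}_breaths.csv", index=False
    )
    with open(outdir / f"{result.scenario.name}_summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
    if result.plasticity_log is not None:
        result.plasticity_log.to_csv(
            outdir / f"{result.scenario.name}_plasticity.csv", index=False
        )


# ---------------------------------------------------------------------------
# Open-loop rhythm measurement, threshold calibration, bit-accuracy sweep.
# ---------------------------------------------------------------------------


def measure_network_rr(
    theta: float = REFERENCE_THETA,
    backend: str = "fixed",
    r_fraction_bits: int = 18,
    pf: float | None = None,
    duration_s: float = 30.0,
    plant_params: PlantParams | None = None,
) -> float:
    """Steady respiratory rate of the complete-injury open-loop experiment.

    Runs the published network (plus follower) against the calibrated plant
    with the native drive at zero, so breathing is stimulation-only, and
    reports the mean RR over the last 10 segmented breaths.  Returns NaN
    when no rhythm is detected.
    """
    controller = reference_controller(
        "open_loop", backend=backend, theta=theta,
        r_fraction_bits=r_fraction_bits,
    )
    if pf is not None:
        conns = [
            replace(c, P=pf) if (c.pre == "Edec_TON" and c.post == "Edec_OUT") else c
            for c in controller.roster.connections
        ]
        controller.roster = replace(controller.roster, connections=conns)
    scenario = Scenario(name="complete_injury_open_loop", wi=0.0,
                        controller_mode="open_loop", duration=duration_s)
    result = run_scenario(scenario, controller,
                          plant_params=plant_params or reference_plant(wi=0.0))
    recs = result.records
    # drop the start-up transient
    recs = [r for r in recs if r.t_start > duration_s * 0.3]
    if len(recs) < 5:
        return float("nan")
    return float(np.mean([r.rr for r in recs[-10:]]))


def calibrate_theta(
    grid: np.ndarray | None = None,
    band: tuple[float, float] = (56.0, 67.0),
    duration_s: float = 20.0,
) -> tuple[float, pd.DataFrame]:
    """Sweep the spike threshold; return the smallest value for which BOTH
    backends (fixed-point and float oracle) settle into a stable rhythm in
    the eupneic band, plus the sweep table."""
    grid = np.arange(6.0, 31.0, 2.0) if grid is None else np.asarray(grid)
    rows = []
    chosen = None
    for theta in grid:
        rr_fx = measure_network_rr(theta=theta, backend="fixed", duration_s=duration_s)
        rr_fl = measure_network_rr(theta=theta, backend="float", duration_s=duration_s)
        rows.append({"theta": float(theta), "rr_fixed": rr_fx, "rr_float": rr_fl})
        if chosen is None and band[0] <= rr_fx <= band[1] and band[0] <= rr_fl <= band[1]:
            chosen = float(theta)
    table = pd.DataFrame(rows)
    if chosen is None:
        raise RuntimeError(f"no threshold on the grid yields a rhythm in {band}:\n{table}")
    return chosen, table


#: Functional (figure-style) names of the five rhythm neurons, in the
#: order their activity peaks within one respiratory cycle.
RHYTHM_ORDER = ["I_dec", "I_inc", "IE", "E_dec", "EI"]


def rhythm_activity_onsets(
    theta: float = REFERENCE_THETA,
    backend: str = "fixed",
    duration_s: float = 12.0,
    settle_s: float = 4.0,
    activity_floor: float = 0.03,
) -> pd.DataFrame:
    """Per-cycle activity-onset times of the five rhythm neurons.

    Runs the open-loop network standalone with the ON trigger held, splits
    the run into respiratory cycles at E_dec burst onsets, and records for
    every other neuron the first step of the cycle at which its windowed
    activity ratio rises above ``activity_floor`` (searching after a 100-step
    blanking window so leftovers of the previous transition are ignored).
    One row per cycle; columns are offsets in steps from the E_dec onset.
    """
    controller = reference_controller("open_loop", backend=backend, theta=theta)
    net = controller.build_network()
    steps = round(duration_s / DT_S)
    names = net.neurons
    funcs = {f: names.index(FIGURE_ALIASES[f]) for f in RHYTHM_ORDER}
    ratios = np.zeros((steps, len(names)))
    for t in range(steps):
        net.step(external={"ON": ON_DRIVE})
        ratios[t] = net.spike_history_counts() / 20.0
    e_dec = ratios[:, funcs["E_dec"]]
    on = e_dec > 0.1
    onsets = np.nonzero(on[1:] & ~on[:-1])[0] + 1
    onsets = onsets[onsets > round(settle_s / DT_S)]
    rows = []
    blank = 100
    for a, b in zip(onsets[:-1], onsets[1:]):
        row = {"E_dec": 0}
        ok = True
        for f in ("EI", "I_dec", "I_inc", "IE"):
            seg = ratios[a + blank:b + blank, funcs[f]]
            hit = np.nonzero(seg >= activity_floor)[0]
            if len(hit) == 0:
                ok = False
                break
            row[f] = int(hit[0]) + blank
        if ok:
            rows.append(row)
    return pd.DataFrame(rows)


def rhythm_ordering_ok(onsets: pd.DataFrame) -> bool:
    """True when the median onsets follow the respiratory sequence
    E_dec -> EI -> I_dec -> I_inc -> IE within the cycle (equivalently the
    cyclic order I_dec -> I_inc -> IE -> E_dec -> EI)."""
    if len(onsets) < 3:
        return False
    med = onsets.median()
    return bool(
        med["E_dec"] < med["EI"] < med["I_dec"] < med["I_inc"] < med["IE"]
    )


def bit_accuracy_sweep(
    fraction_bits: list[int],
    pf_values: list[float],
    duration_s: float = 30.0,
    theta: float = REFERENCE_THETA,
) -> pd.DataFrame:
    """RR per (r-width, P(f)) plus each width's max deviation from 32-bit.

    Reproduces the design study: sweep the bound-receptor word width and the
    frequency-setting strength P(f) (the IE -> E_dec node), measure the
    stimulated respiratory rate, and compare each width against the widest
    reference.
    """
    widths = sorted(set(fraction_bits) | {32})
    rows = []
    for bits in widths:
        for pf in pf_values:
            rr = measure_network_rr(theta=theta, r_fraction_bits=bits, pf=pf,
                                    duration_s=duration_s)
            rows.append({"bits": bits, "pf": pf, "rr": rr})
    table = pd.DataFrame(rows)
    ref = table[table.bits == 32].set_index("pf")["rr"]
    table["rr_dev_from_32"] = [
        abs(row.rr - ref.loc[row.pf]) for row in table.itertuples()
    ]
    return table


def save_probes(probe_output: dict, prefix: str | Path) -> None:
    """Write run_network probe output as two tidy CSVs.

    ``<prefix>_neurons.csv`` has columns time_s, neuron, v, spike;
    ``<prefix>_r.csv`` has time_s, connection, r.
    """
    prefix = Path(prefix)
    t = probe_output["time_s"]
    rows = []
    for j, name in enumerate(probe_output["probes"]):
        for i, ts in enumerate(t):
            rows.append((ts, name, probe_output["v"][i, j],
                         int(probe_output["spike"][i, j])))
    pd.DataFrame(rows, columns=["time_s", "neuron", "v", "spike"]).to_csv(
        f"{prefix}_neurons.csv", index=False
    )
    rows = []
    for j, (pre, post) in enumerate(probe_output["r_probes"]):
        for i, ts in enumerate(t):
            rows.append((ts, f"{pre}->{post}", probe_output["r"][i, j]))
    pd.DataFrame(rows, columns=["time_s", "connection", "r"]).to_csv(
        f"{prefix}_r.csv", index=False
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def generate_fixtures(seed: int, outdir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Synthetic reference waveforms: the eupneic volume trace (56 breaths/min,
    2 mL, sawtooth drive through the plant), a 1%-noise variant, and a small
    hand-checkable spike raster.  Byte-identical for a fixed seed."""
    rng = np.random.default_rng(seed)
    plant = RatPlant(reference_plant(), dynamic_rr=False)
    trace = plant.run(20 * 60.0 / 56.0)
    eupnea = pd.DataFrame({"time_s": trace["time_s"],
                           "volume_mL": trace["volume_mL"]})
    noisy = eupnea.copy()
    noisy["volume_mL"] = noisy["volume_mL"] + rng.normal(
        0.0, 0.01 * 2.0, size=len(noisy)
    )
    raster = pd.DataFrame({
        "step": np.arange(20),
        "spike": ([1, 0] * 10),
    })
    out = {"eupnea": eupnea, "eupnea_noisy": noisy, "raster": raster}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# Config file round-trip (YAML)
# ---------------------------------------------------------------------------


def config_to_dict(controller: ControllerConfig, plant: PlantParams) -> dict:
    from .snn_core import Connection  # noqa: F401  (schema reference)

    return {
        "network": {
            "name": controller.roster.name,
            "neurons": list(controller.roster.neurons),
            "connections": [
                {"pre": c.pre, "post": c.post, "K": c.kinetic, "P": c.P,
                 "plastic_tag": c.plastic_tag}
                for c in controller.roster.connections
            ],
            "external_inputs": controller.roster.external_inputs,
            "count_external_as_connections":
                controller.roster.count_external_as_connections,
        },
        "lif": {
            "theta": controller.lif.theta,
            "leak_shift": controller.lif.leak_shift,
            "refractory_steps": controller.lif.refractory_steps,
            "dt": controller.lif.dt,
        },
        "fixedpoint": {
            "r_format": str(controller.fixed.r_format),
            "const_format": str(controller.fixed.const_format),
            "v_format": str(controller.fixed.v_format),
        },
        "backend": controller.backend,
        "pulse_steps": controller.pulse_steps,
        "stim_source": controller.stim_source,
        "plasticity": None if not controller.plasticity else {
            "rules": {
                tag: {
                    "a_plus": r.a_plus, "a_minus": r.a_minus,
                    "window_steps": r.window_steps,
                    "p_min": r.p_min, "p_max": r.p_max,
                }
                for tag, r in controller.plasticity.items()
            },
            "teachers": {k: list(v) for k, v in controller.teachers.items()},
        },
        "encoders": {
            "volume": {"v_min": controller.volume_encoder.v_min,
                       "v_max": controller.volume_encoder.v_max},
            "co2": {"baseline": controller.co2_encoder.baseline,
                    "span": controller.co2_encoder.span},
        },
        "plant": {
            "wi": plant.wi, "mbc": plant.mbc, "rr0": plant.rr0, "vt0": plant.vt0,
            "ti_frac": plant.ti_frac, "mass": plant.mass, "damping": plant.damping,
            "k0": plant.k0, "k_knee": plant.k_knee, "k_stiff": plant.k_stiff,
            "f_max": plant.f_max, "recruit_sat": plant.recruit_sat,
            "vol_gain": plant.vol_gain, "co2_ref": plant.co2_ref,
            "mbc0_rate": plant.mbc0_rate, "k_ex": plant.k_ex,
            "rr_gain": plant.rr_gain,
            "regression": {"a": plant.regression.a, "b": plant.regression.b},
        },
    }


def config_from_dict(d: dict) -> tuple[ControllerConfig, PlantParams]:
    from .snn_core import Connection

    net = d["network"]
    roster = NetworkRoster(
        name=net["name"],
        neurons=list(net["neurons"]),
        connections=[
            Connection(c["pre"], c["post"], int(c["K"]), float(c["P"]),
                       c.get("plastic_tag", "none"))
            for c in net["connections"]
        ],
        external_inputs=int(net.get("external_inputs", 0)),
        count_external_as_connections=bool(
            net.get("count_external_as_connections", False)
        ),
    )
    from .fixed_point import FixedFormat
    fxd = d.get("fixedpoint", {})
    r_fmt = FixedFormat.parse(fxd.get("r_format", "U0.18"))
    c_fmt = FixedFormat.parse(fxd.get("const_format", "U0.14"))
    v_fmt = FixedFormat.parse(fxd.get("v_format", "S17.18"))
    fixed = FixedPointParams(
        r_fraction_bits=r_fmt.fraction_bits,
        const_fraction_bits=c_fmt.fraction_bits,
        v_int_bits=v_fmt.integer_bits,
        v_fraction_bits=v_fmt.fraction_bits,
    )
    lif = LifParams(
        theta=float(d["lif"]["theta"]),
        leak_shift=int(d["lif"].get("leak_shift", 3)),
        refractory_steps=int(d["lif"].get("refractory_steps", 1)),
        dt=float(d["lif"].get("dt", DT_S)),
    )
    plast = None
    teachers: dict[str, tuple[str, str]] = {}
    if d.get("plasticity"):
        p = d["plasticity"]
        plast = {
            tag: PlasticityRule(
                a_plus=float(r["a_plus"]), a_minus=float(r["a_minus"]),
                window_steps=int(r["window_steps"]),
                p_min=float(r["p_min"]), p_max=float(r["p_max"]),
                targets=frozenset({tag}),
            )
            for tag, r in p.get("rules", {}).items()
        }
        teachers = {k: tuple(v) for k, v in p.get("teachers", {}).items()}
    enc = d.get("encoders", {})
    controller = ControllerConfig(
        roster=roster,
        lif=lif,
        fixed=fixed,
        backend=d.get("backend", "fixed"),
        pulse_steps=int(d.get("pulse_steps", 1)),
        stim_source=d.get("stim_source", "I_inc"),
        plasticity=plast,
        teachers=teachers,
        volume_encoder=VolumeEncoder(**enc.get("volume", {})),
        co2_encoder=Co2Encoder(**enc.get("co2", {})),
    )
    pl = d["plant"]
    reg = pl.get("regression", {"a": 0.0, "b": 56.0})
    plant = PlantParams(
        wi=float(pl.get("wi", 1.0)), mbc=float(pl.get("mbc", 1.0)),
        rr0=float(pl.get("rr0", 56.0)), vt0=float(pl.get("vt0", 2.0)),
        ti_frac=float(pl.get("ti_frac", 0.35)), mass=float(pl.get("mass", 1.0)),
        damping=float(pl.get("damping", 72.0)), k0=float(pl.get("k0", 900.0)),
        k_knee=float(pl.get("k_knee", 0.7)), k_stiff=float(pl.get("k_stiff", 0.5)),
        f_max=float(pl.get("f_max", 900.0)),
        recruit_sat=float(pl.get("recruit_sat", 1.5)),
        vol_gain=float(pl["vol_gain"]), co2_ref=float(pl.get("co2_ref", 1.0)),
        mbc0_rate=float(pl.get("mbc0_rate", 0.1)), k_ex=float(pl["k_ex"]),
        rr_gain=float(pl.get("rr_gain", 8.0)),
        regression=RrRegression(a=float(reg["a"]), b=float(reg["b"])),
    )
    return controller, plant


def save_config(path: str | Path, controller: ControllerConfig,
                plant: PlantParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(controller, plant), fh, sort_keys=False)


def load_config(path: str | Path) -> tuple[ControllerConfig, PlantParams]:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
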