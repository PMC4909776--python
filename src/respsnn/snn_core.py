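"""Discrete-time spiking neural network core.

The controller is a small network of leaky integrate-and-fire (LIF) neurons
coupled by a two-branch kinetic synapse model (a reduction of the Destexhe
receptor-binding scheme).  Everything advances on a fixed 0.5 ms step
(2 kHz), the update rate of the hardware design the simulator mirrors.

Per step the network runs two phases, exactly as the hardware sequencer does:

* **Kinetic phase** — every connection's fraction of bound receptors ``r``
  is advanced using the *previous* step's spike bits:
  ``r' = B r + A`` while the presynaptic pulse is active, ``r' = C r``
  otherwise, with ``A = dt·alpha``, ``B = 1 - dt(alpha+beta)``,
  ``C = 1 - dt·beta`` (forward Euler of dr/dt = alpha(1-r) - beta r during
  a transmitter pulse and dr/dt = -beta r after it).
* **Spike phase** — every neuron's total postsynaptic potential
  ``TPP = sum_i P_i r_i`` is computed from the phase-1 ``r``, then the
  membrane displacement from rest is advanced,
  ``v' = v + (TPP - v) / 2^leak_shift``, thresholded, and the refractory
  and spike-history state updated.

No value written in a phase is read in the same phase, so the result is
independent of the update order within a phase.

Two backends share this code path: a float64 oracle and a bit-faithful
fixed-point backend in which ``r`` is an unsigned pure fraction (18 bits in
the reference design), the kinetic constants are 14-bit unsigned fractions,
and the membrane/TPP accumulator is a saturating signed word.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fixed_point import FixedFormat

__all__ = [
    "DT_S",
    "KineticSet",
    "Connection",
    "LifParams",
    "FixedPointParams",
    "NeuronState",
    "NetworkState",
    "derive_kinetic_constants",
    "DEFAULT_KINETICS",
    "kinetic_step",
    "total_postsynaptic_potential",
    "membrane_spike_step",
    "Network",
    "network_step",
    "run_network",
]

#: Controller time step in seconds (2 kHz update rate).
DT_S = 0.5e-3

#: Length of the per-neuron spike-history window (20 steps = 10 ms).
HISTORY_STEPS = 20

#: Hardware fan-in limit ("8-to-all" architecture).
MAX_FAN_IN = 8


@dataclass(frozen=True)
class KineticSet:
    """One synapse kinetics parameterization and its discrete-time constants.

    ``alpha``/``beta`` are the forward/backward transmitter-binding rates in
    s^-1; ``r_inf = alpha/(alpha+beta)`` is the saturation level of the
    bound-receptor fraction and ``tau_r_ms = 1000/(alpha+beta)`` its rise
    time constant.  A, B, C are the Euler constants at the controller dt.
    """

    r_inf: float
    tau_r_ms: float
    alpha: float
    beta: float
    A: float
    B: float
    C: float


def derive_kinetic_constants(alpha: float, beta: float, dt: float = DT_S) -> KineticSet:
    """Derive (r_inf, tau_r, A, B, C) from binding rates at time step ``dt``.

    Raises ``ValueError`` when the forward-Euler step would be unstable,
    i.e. when ``dt*(alpha+beta) >= 1``.
    """
    if alpha < 0 or beta <= 0 or dt <= 0:
        raise ValueError("require alpha >= 0, beta > 0, dt > 0")
    if dt * (alpha + beta) >= 1.0:
        raise ValueError(
            f"kinetic set (alpha={alpha}, beta={beta}) is unstable at dt={dt}: "
            f"dt*(alpha+beta) = {dt * (alpha + beta):.3f} >= 1"
        )
    return KineticSet(
        r_inf=alpha / (alpha + beta),
        tau_r_ms=1000.0 * dt_to_tau(alpha, beta),
        alpha=alpha,
        beta=beta,
        A=dt * alpha,
        B=1.0 - dt * (alpha + beta),
        C=1.0 - dt * beta,
    )


def dt_to_tau(alpha: float, beta: float) -> float:
    return 1.0 / (alpha + beta)


#: The five kinetic sets of the reference design, from slow (1) to fast (5).
#: Binding rates are in s^-1; at dt = 0.5 ms they yield e.g. set 5:
#: A = 0.4500, B = 0.5000, C = 0.9500, r_inf = 0.90, tau_r = 1.0 ms.
DEFAULT_KINETIC_RATES: dict[int, tuple[float, float]] = {
    1: (58.0, 5.0),
    2: (115.0, 10.0),
    3: (230.0, 20.0),
    4: (450.0, 50.0),
    5: (900.0, 100.0),
}

DEFAULT_KINETICS: dict[int, KineticSet] = {
    k: derive_kinetic_constants(a, b) for k, (a, b) in DEFAULT_KINETIC_RATES.items()
}


@dataclass(frozen=True)
class Connection:
    """A directed synapse: kinetic-set index plus signed strength potential P.

    ``P`` is the absolute synaptic strength potential in controller units
    (synaptic strength times input resistance folded into one signed
    number); positive values excite, negative inhibit.  ``plastic_tag``
    marks connections whose P is adapted on-line (``P_f``/``P_a``) or set
    per scenario (``P_inj``).
    """

    pre: str
    post: str
    kinetic: int
    P: float
    plastic_tag: str = "none"


@dataclass(frozen=True)
class LifParams:
    """LIF neuron parameters shared by all neurons of a network.

    ``theta`` is the spike threshold on the membrane displacement from rest
    (controller units).  ``leak_shift`` encodes dt/tau_m = 2^-leak_shift as
    a right shift (3 in the reference design, i.e. tau_m = 8 dt = 4 ms).
    """

    theta: float
    leak_shift: int = 3
    refractory_steps: int = 1
    dt: float = DT_S


@dataclass(frozen=True)
class FixedPointParams:
    """Word layouts of the fixed-point backend.

    ``r_fraction_bits`` is sweepable (the hardware study ranged 16-32 bits;
    the reference design uses 18).  Constants A, B, C are 14-bit unsigned
    fractions.  The membrane/TPP word is signed with 18 fraction bits and
    17 integer bits: the largest reference |P| (8000) times r = 1 summed
    over the 8-connection fan-in limit (64000) fits without wrapping, and
    the accumulator saturates instead of overflowing.
    """

    r_fraction_bits: int = 18
    const_fraction_bits: int = 14
    v_int_bits: int = 17
    v_fraction_bits: int = 18

    @property
    def r_format(self) -> FixedFormat:
        return FixedFormat(0, self.r_fraction_bits, signed=False)

    @property
    def const_format(self) -> FixedFormat:
        return FixedFormat(0, self.const_fraction_bits, signed=False)

    @property
    def v_format(self) -> FixedFormat:
        return FixedFormat(self.v_int_bits, self.v_fraction_bits, signed=True)


@dataclass
class NeuronState:
    """Scalar view of one neuron used by the functional single-step API."""

    v: float = 0.0
    refractory: bool = False
    spike: bool = False
    spike_history: list[int] = field(default_factory=lambda: [0] * HISTORY_STEPS)


@dataclass
class NetworkState:
    """Snapshot of a network: per-neuron states, per-connection r, step count."""

    neurons: list[NeuronState]
    r: np.ndarray
    t: int


# ---------------------------------------------------------------------------
# Functional single-element operations (float semantics; these double as the
# reference definitions the vectorized engine is tested against).
# ---------------------------------------------------------------------------


def kinetic_step(r: float, pre_spiking: bool, k: KineticSet) -> float:
    """Advance one bound-receptor fraction by one time step."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r = {r} outside [0, 1]")
    return k.B * r + k.A if pre_spiking else k.C * r


def total_postsynaptic_potential(
    neuron: str, connections: list[Connection], r: np.ndarray
) -> float:
    """Sum P_i * r_i over the incoming connections of ``neuron``."""
    return float(
        sum(c.P * r[i] for i, c in enumerate(connections) if c.post == neuron)
    )


def membrane_spike_step(
    n: NeuronState, tpp: float, theta: float, leak_shift: int = 3
) -> NeuronState:
    """Advance one LIF neuron: leak/integrate, threshold, refractory, history.

    During the refractory step the membrane sits at its resting displacement
    (0) regardless of input, and the flag is cleared for the next step.
    """
    if leak_shift < 0:
        raise ValueError("leak_shift must be non-negative")
    history = n.spike_history[1:]
    if n.refractory:
        out = NeuronState(v=0.0, refractory=False, spike=False,
                          spike_history=history + [0])
        return out
    v = n.v + (tpp - n.v) * 2.0 ** (-leak_shift)
    spike = v >= theta
    return NeuronState(v=v, refractory=spike, spike=spike,
                       spike_history=history + [int(spike)])


# ---------------------------------------------------------------------------
# Vectorized network engine (float oracle and fixed-point backends).
# ---------------------------------------------------------------------------

_HISTORY_MASK = (1 << HISTORY_STEPS) - 1


class Network:
    """A complete network with state, runnable step by step.

    Connections are canonicalized (sorted by post then pre neuron) at
    construction so that the result of a step never depends on the order in
    which a roster lists them.
    """

    def __init__(
        self,
        neurons: list[str],
        connections: list[Connection],
        lif: LifParams,
        kinetics: dict[int, KineticSet] | None = None,
        backend: str = "fixed",
        fixed: FixedPointParams | None = None,
        max_fan_in: int = MAX_FAN_IN,
        pulse_steps: int = 1,
    ) -> None:
        if backend not in ("fixed", "float"):
            raise ValueError(f"unknown backend {backend!r}")
        kinetics = dict(DEFAULT_KINETICS if kinetics is None else kinetics)
        self.neurons = list(neurons)
        self.index = {name: i for i, name in enumerate(self.neurons)}
        if len(self.index) != len(self.neurons):
            raise ValueError("duplicate neuron names")
        for c in connections:
            if c.pre not in self.index or c.post not in self.index:
                raise ValueError(f"connection {c.pre}->{c.post} names unknown neuron")
            if c.kinetic not in kinetics:
                raise ValueError(f"connection {c.pre}->{c.post}: no kinetic set {c.kinetic}")
        fan_in: dict[str, int] = {}
        for c in connections:
            fan_in[c.post] = fan_in.get(c.post, 0) + 1
        for name, n_in in fan_in.items():
            if n_in > max_fan_in:
                raise ValueError(
                    f"neuron {name} has fan-in {n_in} > max_fan_in {max_fan_in}"
                )
        self.connections = sorted(
            connections, key=lambda c: (self.index[c.post], self.index[c.pre], c.kinetic)
        )
        self.lif = lif
        self.kinetics = kinetics
        self.backend = backend
        self.fixed = fixed or FixedPointParams()
        self.pulse_steps = int(pulse_steps)
        if self.pulse_steps < 1:
            raise ValueError("pulse_steps must be >= 1")

        n, m = len(self.neurons), len(self.connections)
        self._pre = np.array([self.index[c.pre] for c in self.connections], dtype=np.int64)
        self._post = np.array([self.index[c.post] for c in self.connections], dtype=np.int64)
        A = np.array([kinetics[c.kinetic].A for c in self.connections])
        B = np.array([kinetics[c.kinetic].B for c in self.connections])
        C = np.array([kinetics[c.kinetic].C for c in self.connections])
        self._P = np.array([float(c.P) for c in self.connections])

        if backend == "fixed":
            fp = self.fixed
            cf = fp.const_fraction_bits
            rf = fp.r_fraction_bits
            self._A = np.floor(A * (1 << cf)).astype(np.int64)
            self._B = np.floor(B * (1 << cf)).astype(np.int64)
            self._C = np.floor(C * (1 << cf)).astype(np.int64)
            # A aligned to the r format for the add after the B*r multiply.
            if rf >= cf:
                self._A_r = self._A << (rf - cf)
            else:
                self._A_r = self._A >> (cf - rf)
            self._P_int = np.rint(self._P).astype(np.int64)
            self._r = np.zeros(m, dtype=np.int64)
            self._v = np.zeros(n, dtype=np.int64)
            self._theta_raw = int(round(lif.theta * (1 << fp.v_fraction_bits)))
            self._v_max = fp.v_format.max_raw
            self._v_min = fp.v_format.min_raw
            self._r_max = (1 << rf) - 1
        else:
            self._A_f, self._B_f, self._C_f = A, B, C
            self._r = np.zeros(m, dtype=np.float64)
            self._v = np.zeros(n, dtype=np.float64)

        self._spike = np.zeros(n, dtype=bool)
        self._refr = np.zeros(n, dtype=np.int64)
        self._pulse = np.zeros(n, dtype=np.int64)
        self._history = np.zeros(n, dtype=np.int64)  # 20-bit ring as a bitmask
        self.t = 0

    # -- state access -------------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def v(self) -> np.ndarray:
        """Membrane displacement from rest, in controller units (float view)."""
        if self.backend == "fixed":
            return self._v / (1 << self.fixed.v_fraction_bits)
        return self._v.copy()

    @property
    def r(self) -> np.ndarray:
        """Per-connection bound-receptor fraction (float view)."""
        if self.backend == "fixed":
            return self._r / (1 << self.fixed.r_fraction_bits)
        return self._r.copy()

    @property
    def spikes(self) -> np.ndarray:
        return self._spike.copy()

    def spike_history_counts(self) -> np.ndarray:
        """Spike count of each neuron over the trailing 20-step window."""
        return np.bitwise_count(self._history.astype(np.uint64)).astype(np.int64)

    def history_bits(self, neuron: str) -> list[int]:
        """The 20-bit spike history of one neuron, oldest first."""
        h = int(self._history[self.index[neuron]])
        return [(h >> (HISTORY_STEPS - 1 - i)) & 1 for i in range(HISTORY_STEPS)]

    def state(self) -> NetworkState:
        """Dataclass snapshot of the full network state."""
        neurons = [
            NeuronState(
                v=float(self.v[i]),
                refractory=bool(self._refr[i] > 0),
                spike=bool(self._spike[i]),
                spike_history=self.history_bits(self.neurons[i]),
            )
            for i in range(self.n_neurons)
        ]
        return NetworkState(neurons=neurons, r=self.r, t=self.t)

    def connection_index(self, pre: str, post: str) -> int:
        for i, c in enumerate(self.connections):
            if c.pre == pre and c.post == post:
                return i
        raise KeyError(f"no connection {pre}->{post}")

    def get_strength(self, i: int) -> float:
        return float(self._P[i])

    def set_strength(self, i: int, P: float) -> None:
        """Update one connection strength (used by the plasticity rules)."""
        self._P[i] = float(P)
        if self.backend == "fixed":
            self._P_int[i] = int(np.rint(P))

    # -- stepping -----------------------------------------------------------

    def step(
        self,
        external: dict[str, float] | None = None,
        forced_spikes: dict[str, bool] | None = None,
    ) -> None:
        """Advance the network by one 0.5 ms step (two phases).

        ``external`` adds a constant current (controller units) to the named
        neurons' TPP this step.  ``forced_spikes`` overrides the spike bit of
        the named neurons (used for the sensor-driven tonic neurons, whose
        firing is set by the encoders rather than by their membrane).
        """
        gate = self._pulse[self._pre] > 0  # pre pulse active (from previous steps)

        if self.backend == "fixed":
            self._step_fixed(gate, external)
        else:
            self._step_float(gate, external)

        if forced_spikes:
            for name, bit in forced_spikes.items():
                i = self.index[name]
                self._spike[i] = bool(bit)
                self._refr[i] = 0
        # bookkeeping shared by both backends
        self._pulse = np.where(self._spike, self.pulse_steps,
                               np.maximum(self._pulse - 1, 0))
        self._history = ((self._history << 1) | self._spike.astype(np.int64)) & _HISTORY_MASK
        self.t += 1

    def _step_fixed(self, gate: np.ndarray, external: dict[str, float] | None) -> None:
        fp = self.fixed
        cf = fp.const_fraction_bits
        rising = ((self._B * self._r) >> cf) + self._A_r
        decaying = (self._C * self._r) >> cf
        self._r = np.clip(np.where(gate, rising, decaying), 0, self._r_max)

        shift = fp.r_fraction_bits - fp.v_fraction_bits
        prod = self._P_int * self._r
        prod = prod >> shift if shift >= 0 else prod << (-shift)
        tpp = np.zeros(self.n_neurons, dtype=np.int64)
        np.add.at(tpp, self._post, prod)
        if external:
            for name, cur in external.items():
                tpp[self.index[name]] += int(np.floor(cur * (1 << fp.v_fraction_bits)))
        tpp = np.clip(tpp, self._v_min, self._v_max)

        refractory = self._refr > 0
        dv = (tpp - self._v) >> self.lif.leak_shift  # arithmetic shift = floor
        v_new = np.clip(self._v + dv, self._v_min, self._v_max)
        v_new[refractory] = 0
        spike = (v_new >= self._theta_raw) & ~refractory
        self._v = v_new
        self._spike = spike
        self._refr = np.where(
            spike, self.lif.refractory_steps, np.maximum(self._refr - 1, 0)
        )

    def _step_float(self, gate: np.ndarray, external: dict[str, float] | None) -> None:
        rising = self._B_f * self._r + self._A_f
        decaying = self._C_f * self._r
        self._r = np.clip(np.where(gate, rising, decaying), 0.0, 1.0)

        tpp = np.zeros(self.n_neurons)
        np.add.at(tpp, self._post, self._P * self._r)
        if external:
            for name, cur in external.items():
                tpp[self.index[name]] += cur

        refractory = self._refr > 0
        v_new = self._v + (tpp - self._v) * 2.0 ** (-self.lif.leak_shift)
        v_new[refractory] = 0.0
        spike = (v_new >= self.lif.theta) & ~refractory
        self._v = v_new
        self._spike = spike
        self._refr = np.where(
            spike, self.lif.refractory_steps, np.maximum(self._refr - 1, 0)
        )


def network_step(
    net: Network,
    external: dict[str, float] | None = None,
    forced_spikes: dict[str, bool] | None = None,
) -> Network:
    """Advance ``net`` by one step (thin functional wrapper over Network.step)."""
    net.step(external=external, forced_spikes=forced_spikes)
    return net


def run_network(
    net: Network,
    n_steps: int,
    probes: list[str] | None = None,
    r_probes: list[tuple[str, str]] | None = None,
    external_fn=None,
    forced_fn=None,
) -> dict[str, np.ndarray]:
    """Run ``n_steps`` steps, recording traces for the probed elements.

    ``probes`` names neurons (records v and spike); ``r_probes`` lists
    (pre, post) connection pairs (records r).  ``external_fn(t)`` /
    ``forced_fn(t)`` may supply per-step inputs.  Returns arrays sampled at
    the 2 kHz controller rate, plus ``time_s``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    probes = probes or []
    r_probes = r_probes or []
    for p in probes:
        if p not in net.index:
            raise KeyError(f"unknown probe neuron {p!r}")
    conn_idx = [net.connection_index(pre, post) for pre, post in r_probes]
    neuron_idx = [net.index[p] for p in probes]

    v_trace = np.empty((n_steps, len(probes)))
    s_trace = np.empty((n_steps, len(probes)), dtype=np.int8)
    r_trace = np.empty((n_steps, len(conn_idx)))
    for k in range(n_steps):
        ext = external_fn(net.t) if external_fn else None
        forced = forced_fn(net.t) if forced_fn else None
        net.step(external=ext, forced_spikes=forced)
        if neuron_idx:
            v_trace[k] = net.v[neuron_idx]
            s_trace[k] = net.spikes[neuron_idx]
        if conn_idx:
            r_trace[k] = net.r[conn_idx]
    return {
        "time_s": (np.arange(1, n_steps + 1) + (net.t - n_steps)) * net.lif.dt,
        "v": v_trace,
        "spike": s_trace,
        "r": r_trace,
        "probes": probes,
        "r_probes": r_probes,
    }
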