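"""Reference network rosters and connectivity-density accounting.

The open-loop controller is a seven-neuron central pattern generator built
from three reciprocally coupled pairs (a triggering "TON" neuron plus a core
output neuron for each of the expiratory-decrementing, inspiratory-
decrementing and expiration-inspiration-transition populations) and an ON
neuron that receives the external start trigger.  The sixteen published
(kinetic-set, strength) pairs are reproduced verbatim below.

Functional aliases follow the respiratory-physiology names: the E_dec
trigger neuron is the IE (inspiration-expiration transition) neuron — it
bursts at the end of inspiration and drives E_dec — and the core outputs
are E_dec, I_dec and EI.  A follower neuron I_inc (the stimulation output,
whose wiring strengths were never published) ships as a documented
extension with calibrated values.

The closed-loop roster adds three sensor-driven tonic neurons (Vol_spk,
C1_spk, C2_spk); their connection strengths into the core are likewise
unpublished and ship as calibrated reference values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .snn_core import MAX_FAN_IN, Connection

__all__ = [
    "NetworkRoster",
    "ConnectivityStats",
    "FIGURE_ALIASES",
    "OPEN_LOOP_NEURONS",
    "build_open_loop",
    "build_closed_loop",
    "connectivity_stats",
    "format_stats_row",
]

#: Mapping from functional (figure-style) names to roster (table-style) names.
FIGURE_ALIASES: dict[str, str] = {
    "IE": "Edec_TON",
    "E_dec": "Edec_OUT",
    "I_decTON": "Idec_TON",
    "I_dec": "Idec_OUT",
    "EI_TON": "EI_TON",
    "EI": "EI_OUT",
    "ON": "ON",
    "I_inc": "I_inc",
}

OPEN_LOOP_NEURONS = [
    "Edec_TON", "Edec_OUT", "Idec_TON", "Idec_OUT", "EI_TON", "EI_OUT", "ON",
]

# The sixteen published (pre, post, kinetic-set, P) entries, row by row.
_OPEN_LOOP_TABLE: list[tuple[str, str, int, float]] = [
    ("Edec_TON", "Edec_TON", 3, +600),
    ("Edec_TON", "Edec_OUT", 1, +5000),
    ("Edec_OUT", "Edec_TON", 1, -2200),
    ("Edec_OUT", "Idec_OUT", 4, -250),
    ("Edec_OUT", "EI_TON", 4, +8000),
    ("Edec_OUT", "EI_OUT", 4, -500),
    ("Idec_TON", "Idec_TON", 3, +40),
    ("Idec_TON", "Idec_OUT", 4, +500),
    ("Idec_OUT", "Edec_OUT", 1, -1500),
    ("Idec_OUT", "Idec_TON", 3, -5000),
    ("Idec_OUT", "EI_OUT", 4, -350),
    ("EI_TON", "EI_TON", 3, +40),
    ("EI_TON", "EI_OUT", 2, +400),
    ("EI_OUT", "Idec_TON", 2, +200),
    ("EI_OUT", "EI_TON", 2, +1280),
    ("ON", "Edec_TON", 4, +1280),
]

# Follower extension: the stimulation-output neuron I_inc.  The roles are
# published (EI triggers I_inc; E_dec inhibits it; it self-excites) but the
# strengths are not; these values come from the shipped calibration and are
# NOT published values.
_FOLLOWER_TABLE: list[tuple[str, str, int, float, str]] = [
    ("EI_OUT", "I_inc", 4, +1500, "none"),
    ("Edec_OUT", "I_inc", 4, -4000, "none"),
    ("I_inc", "I_inc", 2, +900, "P_a"),
]

# Closed-loop tonic-side connections.  Roles published (Vol_spk triggers the
# loop and modulates the IE node; C1_spk/C2_spk respond to CO2 excess and
# deficit), strengths not published; calibrated reference values.
_CLOSED_LOOP_TABLE: list[tuple[str, str, int, float, str]] = [
    ("Vol_spk", "ON", 2, +800, "none"),
    ("Vol_spk", "Edec_TON", 4, +60, "P_inj"),
    ("C1_spk", "ON", 2, +300, "P_inj"),
    ("C1_spk", "Edec_OUT", 4, -40, "P_inj"),
    ("C1_spk", "EI_TON", 4, +30, "none"),
    ("C2_spk", "Edec_OUT", 4, +40, "P_inj"),
    ("C2_spk", "ON", 2, -300, "none"),
    ("C2_spk", "Idec_OUT", 4, -20, "none"),
]


@dataclass(frozen=True)
class NetworkRoster:
    """A named set of neurons and connections plus external-input accounting.

    ``external_inputs`` counts the off-network spike/current sources
    (the ON trigger in open loop; the three sensor feeds in closed loop).
    ``count_external_as_connections`` controls whether those inputs are
    included in the connection count C of the density statistics — the
    published open-loop accounting includes its single trigger (C = 17 for
    16 internal pairs) while the closed-loop accounting reports them
    separately (C = 24, *27 with inputs).
    """

    name: str
    neurons: list[str]
    connections: list[Connection]
    external_inputs: int = 0
    count_external_as_connections: bool = False

    def connection(self, pre: str, post: str) -> Connection:
        for c in self.connections:
            if c.pre == pre and c.post == post:
                return c
        raise KeyError(f"no connection {pre}->{post} in roster {self.name}")

    def alias(self, functional_name: str) -> str:
        """Resolve a figure-style functional name to the roster name."""
        return FIGURE_ALIASES.get(functional_name, functional_name)


def build_open_loop(
    include_follower: bool = False,
    trigger_as_connection: bool = True,
) -> NetworkRoster:
    """The published open-loop roster: 7 neurons, 16 printed pairs + trigger.

    ``include_follower`` adds the I_inc stimulation-output neuron and its
    (calibrated, unpublished) wiring.  ``trigger_as_connection`` keeps the
    external ON trigger in the connection count, reproducing the published
    C = 17 accounting.
    """
    neurons = list(OPEN_LOOP_NEURONS)
    conns = [Connection(pre, post, k, p) for pre, post, k, p in _OPEN_LOOP_TABLE]
    # P(f): the frequency-setting node between pre-neuron IE and post-neuron
    # E_dec (the rhythm's expiratory drive).
    conns = [
        replace(c, plastic_tag="P_f")
        if (c.pre == "Edec_TON" and c.post == "Edec_OUT") else c
        for c in conns
    ]
    if include_follower:
        neurons.append("I_inc")
        conns += [Connection(p, q, k, s, tag) for p, q, k, s, tag in _FOLLOWER_TABLE]
    return NetworkRoster(
        name="open_loop" + ("+follower" if include_follower else ""),
        neurons=neurons,
        connections=conns,
        external_inputs=1,
        count_external_as_connections=trigger_as_connection,
    )


def build_closed_loop(
    open_loop: NetworkRoster | None = None,
    include_follower: bool = False,
) -> NetworkRoster:
    """The closed-loop roster: open loop + Vol_spk, C1_spk, C2_spk (10 neurons).

    The three tonic neurons are driven by the plant sensors (3 external
    inputs); their eight connections into the core carry calibrated,
    unpublished strengths.  ``include_follower`` additionally wires in the
    I_inc stimulation output (the configuration scenarios actually run).
    """
    base = open_loop if open_loop is not None else build_open_loop(
        include_follower=include_follower, trigger_as_connection=False
    )
    neurons = list(base.neurons) + ["Vol_spk", "C1_spk", "C2_spk"]
    conns = list(base.connections)
    conns += [Connection(p, q, k, s, tag) for p, q, k, s, tag in _CLOSED_LOOP_TABLE]
    return NetworkRoster(
        name="closed_loop" + ("+follower" if include_follower else ""),
        neurons=neurons,
        connections=conns,
        external_inputs=3,
        count_external_as_connections=False,
    )


@dataclass(frozen=True)
class ConnectivityStats:
    """Connection-density statistics in the conventions of the hardware study."""

    n_connections: int
    n_connections_with_inputs: int
    n_neurons: int
    max_fan_in: int
    all_to_all_density: float
    maxc_to_all_density: float
    eight_to_all_density: float
    c_per_n: float


def connectivity_stats(roster: NetworkRoster, max_fan_in: int = MAX_FAN_IN) -> ConnectivityStats:
    """Compute C, N, MaxC and the three density measures for a roster.

    all-to-all density = 100 C / N^2; MaxC-to-all = 100 C / (N MaxC) with
    MaxC the maximum observed fan-in; 8-to-all = 100 C / (8 N).
    """
    n = len(roster.neurons)
    if n == 0:
        raise ValueError("empty roster")
    c_internal = len(roster.connections)
    c = c_internal + (roster.external_inputs if roster.count_external_as_connections else 0)
    fan_in: dict[str, int] = {}
    for conn in roster.connections:
        fan_in[conn.post] = fan_in.get(conn.post, 0) + 1
    maxc = max(fan_in.values(), default=0)
    for name, k in fan_in.items():
        if k > max_fan_in:
            raise ValueError(f"neuron {name} fan-in {k} exceeds limit {max_fan_in}")
    return ConnectivityStats(
        n_connections=c,
        n_connections_with_inputs=c_internal + roster.external_inputs,
        n_neurons=n,
        max_fan_in=maxc,
        all_to_all_density=100.0 * c / n**2 if c else 0.0,
        maxc_to_all_density=(100.0 * c / (n * maxc)) if (c and maxc) else 0.0,
        eight_to_all_density=100.0 * c / (8 * n) if c else 0.0,
        c_per_n=c / n,
    )


def _trunc1(x: float) -> float:
    """Truncate to one decimal place (the convention of the published table)."""
    return math.floor(x * 10.0 + 1e-9) / 10.0


def format_stats_row(name: str, stats: ConnectivityStats) -> str:
    """One table-style row: C N MaxC and the densities truncated to 1 d.p."""
    c = stats.n_connections
    star = (
        f" (*{stats.n_connections_with_inputs})"
        if stats.n_connections_with_inputs != c
        else ""
    )
    return (
        f"{name}\t{c}{star}\t{stats.n_neurons}\t{stats.max_fan_in}\t"
        f"{_trunc1(stats.all_to_all_density)}\t{_trunc1(stats.maxc_to_all_density)}\t"
        f"{_trunc1(stats.eight_to_all_density)}\t{_trunc1(stats.c_per_n)}"
    )
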