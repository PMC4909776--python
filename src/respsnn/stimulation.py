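"""Stimulation drive and sensor-to-spike encoders.

The controller's output is the *stimulation ratio*: the number of spikes the
follower neuron fired over the trailing 20 computation steps (10 ms),
divided by 20 — 0 spikes = 0, 10 spikes = 0.5, 20 spikes = 1.  It is the
proportion of maximum activation delivered to the respiratory muscle; the
electrical pulse-train parameters behind it are outside this simulator.

Going the other way, the plant's sensors are encoded into tonic-neuron
spike trains: Vol_spk rate-codes the normalized lung volume, C1_spk the CO2
excess over baseline and C2_spk the CO2 deficit.  The default encoders are
deterministic clocked dividers (a phase accumulator emits a spike each time
it wraps), which makes runs bit-reproducible; a seeded Bernoulli variant is
available.  Transfer curves are piecewise-linear and clamped; rates respect
the one-step refractory limit (at most one spike every other step).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "stimulation_ratio",
    "RateEncoder",
    "VolumeEncoder",
    "Co2Encoder",
    "STIM_WINDOW",
]

#: Width of the stimulation-ratio window in computation steps (10 ms).
STIM_WINDOW = 20

#: Maximum attainable firing rate (spikes per step) under the one-step
#: refractory period: one spike per two-step slot.
MAX_RATE = 0.5


def stimulation_ratio(spike_history: Sequence[int]) -> float:
    """Fraction of maximum activation from a 20-step spike window.

    ``popcount(window) / 20``; resolution is therefore 1/20.
    """
    window = list(spike_history)
    if len(window) != STIM_WINDOW:
        raise ValueError(f"window must have exactly {STIM_WINDOW} bits, got {len(window)}")
    return sum(1 for b in window if b) / STIM_WINDOW


@dataclass
class RateEncoder:
    """Deterministic rate coder: spike rate = ``max_rate`` x drive in [0, 1].

    A phase accumulator advances by the instantaneous rate each step and
    emits a spike on wrap; at drive 0 it never spikes, at drive 1 it spikes
    once per refractory-limited slot.  ``stochastic=True`` replaces the
    divider with a seeded Bernoulli draw of the same mean rate.
    """

    max_rate: float = MAX_RATE
    stochastic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.max_rate <= MAX_RATE:
            raise ValueError(f"max_rate must be in (0, {MAX_RATE}]")
        self._phase = 0.0
        self._rng = np.random.default_rng(self.seed)

    def reset(self) -> None:
        self._phase = 0.0
        self._rng = np.random.default_rng(self.seed)

    def step(self, drive: float) -> int:
        """Advance one step with normalized drive in [0, 1]; return spike bit."""
        drive = min(max(drive, 0.0), 1.0)
        rate = self.max_rate * drive
        if self.stochastic:
            return int(self._rng.random() < rate)
        self._phase += rate
        if self._phase >= 1.0:
            self._phase -= 1.0
            return 1
        return 0


@dataclass
class VolumeEncoder:
    """Encode lung volume into the Vol_spk tonic spike train.

    The calibrated range [v_min, v_max] (mL) maps piecewise-linearly onto
    [0, 1] drive; baseline volume yields silence, full range the maximum
    refractory-limited rate.
    """

    v_min: float = 0.0
    v_max: float = 2.0
    max_rate: float = MAX_RATE
    stochastic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_max <= self.v_min:
            raise ValueError("v_max must exceed v_min")
        self._enc = RateEncoder(self.max_rate, self.stochastic, self.seed)

    def reset(self) -> None:
        self._enc.reset()

    def drive(self, volume_ml: float) -> float:
        return min(max((volume_ml - self.v_min) / (self.v_max - self.v_min), 0.0), 1.0)

    def step(self, volume_ml: float) -> int:
        return self._enc.step(self.drive(volume_ml))


@dataclass
class Co2Encoder:
    """Encode body CO2 into the C1_spk (excess) / C2_spk (deficit) trains.

    Both channels are silent at baseline; C1's rate grows with the relative
    CO2 excess and C2's with the relative deficit, each saturating at
    ``span`` (relative error at which the channel reaches full rate).
    """

    baseline: float = 1.0
    span: float = 0.2
    max_rate: float = MAX_RATE
    stochastic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.span <= 0:
            raise ValueError("span must be positive")
        self._c1 = RateEncoder(self.max_rate, self.stochastic, self.seed)
        self._c2 = RateEncoder(self.max_rate, self.stochastic, self.seed + 1)

    def reset(self) -> None:
        self._c1.reset()
        self._c2.reset()

    def drives(self, co2: float) -> tuple[float, float]:
        rel = (co2 - self.baseline) / self.baseline
        up = min(max(rel / self.span, 0.0), 1.0)
        down = min(max(-rel / self.span, 0.0), 1.0)
        return up, down

    def step(self, co2: float) -> tuple[int, int]:
        up, down = self.drives(co2)
        return self._c1.step(up), self._c2.step(down)
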