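"""Simplified spike-timing-dependent plasticity (STDP).

Connection strengths tagged ``P_f`` (rhythm frequency node) and ``P_a``
(stimulation amplitude node) are adapted on-line in the closed loop.  The
kernel is the minimal two-sided step function: every causal pairing (a pre
spike followed by a post spike within the window) potentiates by a fixed
amount ``a_plus``, every anti-causal pairing depresses by ``a_minus``;
there is no exponential decay with lag, and simultaneous spikes pair with
neither branch.  Strengths are clamped to ``[p_min, p_max]``.

The ``P_inj`` strengths (injury/metabolic operating point) are *not*
learned — they are a per-scenario configuration table — and the
meta-plasticity rule that would learn them is a stub interface only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["PlasticityRule", "stdp_update", "OnlineStdp", "MetaPlasticityRule"]


@dataclass(frozen=True)
class PlasticityRule:
    """Step-kernel STDP parameters.

    ``a_plus``/``a_minus`` are the strength increments per causal /
    anti-causal spike pairing (controller units); ``window_steps`` the
    pairing window in 0.5 ms steps; ``p_min``/``p_max`` the hard strength
    bounds; ``targets`` the set of plastic tags the rule applies to.
    """

    a_plus: float
    a_minus: float
    window_steps: int = 20
    p_min: float = -8000.0
    p_max: float = 8000.0
    targets: frozenset[str] = frozenset({"P_f", "P_a"})

    def __post_init__(self) -> None:
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("pairing amplitudes must be non-negative")
        if self.p_min > self.p_max:
            raise ValueError("p_min must not exceed p_max")
        if self.window_steps < 1:
            raise ValueError("window_steps must be >= 1")


def stdp_update(
    P: float,
    pre_history: Sequence[int],
    post_history: Sequence[int],
    rule: PlasticityRule,
) -> float:
    """Apply the step-kernel STDP to one strength given full spike histories.

    Histories are aligned, oldest first, and must cover at least
    ``window_steps + 1`` steps.  Every ordered pair (pre at i, post at j)
    with ``0 < j - i <= window_steps`` adds ``a_plus``; every (post at i,
    pre at j) with the same lag subtracts ``a_minus``.  The result is
    clamped to the rule's bounds.
    """
    pre = np.asarray(pre_history, dtype=np.int64)
    post = np.asarray(post_history, dtype=np.int64)
    if pre.shape != post.shape:
        raise ValueError("pre and post histories must have equal length")
    if len(pre) < rule.window_steps + 1:
        raise ValueError(
            f"histories of length {len(pre)} do not cover window_steps="
            f"{rule.window_steps} plus the paired step"
        )
    dP = 0.0
    for lag in range(1, rule.window_steps + 1):
        # pre at t-lag paired with post at t  -> LTP
        dP += rule.a_plus * float(np.sum(pre[:-lag] * post[lag:]))
        # post at t-lag paired with pre at t  -> LTD
        dP -= rule.a_minus * float(np.sum(post[:-lag] * pre[lag:]))
    return float(np.clip(P + dP, rule.p_min, rule.p_max))


@dataclass
class OnlineStdp:
    """Incremental step-kernel STDP applied once per computation step.

    Feeding the per-step spike bits (pre, post) reproduces ``stdp_update``
    over the whole run: on a post spike the strength gains ``a_plus`` per
    pre spike in the trailing window; on a pre spike it loses ``a_minus``
    per post spike in the trailing window.  Updates land during the kinetic
    phase slot of the sequencer, so a step's own spikes pair only on later
    steps.
    """

    rule: PlasticityRule
    _pre_hist: list[int] = field(default_factory=list)
    _post_hist: list[int] = field(default_factory=list)

    def step(self, P: float, pre_spike: int, post_spike: int) -> float:
        w = self.rule.window_steps
        pre_count = sum(self._pre_hist[-w:])
        post_count = sum(self._post_hist[-w:])
        dP = self.rule.a_plus * post_spike * pre_count
        dP -= self.rule.a_minus * pre_spike * post_count
        self._pre_hist.append(int(pre_spike))
        self._post_hist.append(int(post_spike))
        if len(self._pre_hist) > w:
            del self._pre_hist[:-w]
            del self._post_hist[:-w]
        return float(np.clip(P + dP, self.rule.p_min, self.rule.p_max))


class MetaPlasticityRule:
    """Stub for the slow rule that would learn the P_inj operating points.

    Selecting the injury/metabolic strengths on-line is future work; the
    shipped scenarios use a per-scenario P_inj configuration table instead.
    """

    def step(self, *args, **kwargs):  # pragma: no cover - interface stub
        raise NotImplementedError(
            "P_inj meta-plasticity is a stub; set P_inj per scenario instead"
        )
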