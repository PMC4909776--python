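"""Quantized fixed-point arithmetic mirroring an FPGA datapath.

The controller core runs on integer words: the fraction of bound receptors
r(t) is stored as an unsigned pure-fraction vector (U0.18 in the reference
design), the kinetic constants A, B, C as 14-bit unsigned fractions, and the
membrane displacement in a signed word with fraction bits matching r.  This
module supplies the format descriptions and the three primitive operations
the datapath needs: quantization of a real number, a truncating multiply,
and an arithmetic-shift leak.  All rounding is floor on the raw integer
(truncation toward minus infinity), which is what a bare FPGA multiplier and
shifter produce; a nearest-rounding mode is available but not the default.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "FixedFormat",
    "QuantizedValue",
    "quantize",
    "fx_mul",
    "fx_add",
    "shift_leak",
]

_FMT_RE = re.compile(r"^([US])(\d+)\.(\d+)$")


@dataclass(frozen=True)
class FixedFormat:
    """A fixed-point word layout: ``integer_bits.fraction_bits`` plus a sign bit.

    ``U0.18`` is an 18-bit unsigned pure fraction in [0, 1 - 2^-18];
    ``S17.18`` is a signed word with 17 integer bits, 18 fraction bits and a
    sign bit, covering about +-131072 with resolution 2^-18.
    """

    integer_bits: int
    fraction_bits: int
    signed: bool = False

    def __post_init__(self) -> None:
        if self.integer_bits < 0 or self.fraction_bits < 0:
            raise ValueError("bit counts must be non-negative")
        if self.width <= 0:
            raise ValueError("format must have at least one bit")

    @property
    def width(self) -> int:
        return self.integer_bits + self.fraction_bits + (1 if self.signed else 0)

    @property
    def resolution(self) -> float:
        return 2.0 ** (-self.fraction_bits)

    @property
    def max_raw(self) -> int:
        return (1 << (self.integer_bits + self.fraction_bits)) - 1

    @property
    def min_raw(self) -> int:
        if not self.signed:
            return 0
        return -(1 << (self.integer_bits + self.fraction_bits))

    @property
    def max_value(self) -> float:
        return self.max_raw * self.resolution

    @property
    def min_value(self) -> float:
        return self.min_raw * self.resolution

    @classmethod
    def parse(cls, spec: str) -> "FixedFormat":
        """Parse a format string such as ``"U0.18"`` or ``"S17.18"``."""
        m = _FMT_RE.match(spec.strip())
        if m is None:
            raise ValueError(f"unrecognized fixed-point format: {spec!r}")
        sign, ibits, fbits = m.groups()
        return cls(int(ibits), int(fbits), signed=(sign == "S"))

    def __str__(self) -> str:
        return f"{'S' if self.signed else 'U'}{self.integer_bits}.{self.fraction_bits}"


# Formats of the reference hardware design.
U0_18 = FixedFormat(0, 18, signed=False)  # fraction of bound receptors r(t)
U0_14 = FixedFormat(0, 14, signed=False)  # kinetic constants A, B, C
S17_18 = FixedFormat(17, 18, signed=True)  # membrane displacement / TPP accumulator


@dataclass(frozen=True)
class QuantizedValue:
    """An integer raw word together with its format."""

    raw: int
    fmt: FixedFormat

    def __post_init__(self) -> None:
        if not (self.fmt.min_raw <= self.raw <= self.fmt.max_raw):
            raise ValueError(
                f"raw {self.raw} outside range of {self.fmt} "
                f"[{self.fmt.min_raw}, {self.fmt.max_raw}]"
            )

    @property
    def value(self) -> float:
        return self.raw * self.fmt.resolution

    def __float__(self) -> float:
        return self.value


def _saturate(raw: int, fmt: FixedFormat) -> int:
    return max(fmt.min_raw, min(fmt.max_raw, raw))


def quantize(x: float, fmt: FixedFormat, mode: str = "truncate") -> QuantizedValue:
    """Quantize a real number onto ``fmt``.

    ``truncate`` floors the scaled value (the FPGA default here), ``round``
    rounds to nearest (ties away from zero).  ``saturate`` is accepted as an
    alias of ``truncate``; out-of-range inputs saturate to the nearest bound
    in every mode.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot quantize non-finite value {x!r}")
    scaled = x * (1 << fmt.fraction_bits)
    if mode in ("truncate", "saturate"):
        raw = math.floor(scaled)
    elif mode == "round":
        raw = math.floor(abs(scaled) + 0.5)
        raw = raw if scaled >= 0 else -raw
    else:
        raise ValueError(f"unknown quantization mode {mode!r}")
    return QuantizedValue(_saturate(raw, fmt), fmt)


def fx_mul(a: QuantizedValue, b: QuantizedValue, out_fmt: FixedFormat) -> QuantizedValue:
    """Truncating fixed-point multiply.

    The exact integer product carries ``fa + fb`` fraction bits; it is
    arithmetic-shifted down (floor) to the output format and saturated.
    """
    prod = a.raw * b.raw
    shift = a.fmt.fraction_bits + b.fmt.fraction_bits - out_fmt.fraction_bits
    if shift >= 0:
        raw = prod >> shift
    else:
        raw = prod << (-shift)
    return QuantizedValue(_saturate(raw, out_fmt), out_fmt)


def fx_add(a: QuantizedValue, b: QuantizedValue, out_fmt: FixedFormat) -> QuantizedValue:
    """Saturating fixed-point add (operands aligned to the output format)."""

    def align(q: QuantizedValue) -> int:
        shift = q.fmt.fraction_bits - out_fmt.fraction_bits
        return q.raw >> shift if shift >= 0 else q.raw << (-shift)

    return QuantizedValue(_saturate(align(a) + align(b), out_fmt), out_fmt)


def shift_leak(v: QuantizedValue, shift: int) -> QuantizedValue:
    """Multiply by 2^-shift via an arithmetic right shift on the raw word.

    Python's ``>>`` on negative integers is an arithmetic shift (floor), the
    convention of signed shifters in hardware: ``-9 >> 3 == -2``.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    return QuantizedValue(v.raw >> shift, v.fmt)
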