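"""Emulation of 16-bit fixed-point trace arithmetic with LUT transcendentals.

Digital neuromorphic cores without a floating-point unit store the BCPNN
star traces in a signed fixed-point word — here 6 integer and 9 fractional
bits (S6.9) — and evaluate ``exp`` and ``log`` through precomputed lookup
tables.  This module reproduces that arithmetic bit-faithfully enough to
study its consequences: saturation of the P* trace under sustained firing
(which bounds the representable ``tau_p``) and underflow of small traces
(which corrupts weights of nearly silent units).

The emulation keeps values as Python floats restricted to the format's
grid; ``encode``/``decode`` expose the underlying raw integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FixedFormat", "S6_9", "DecayLUT", "LogLUT", "FixedArithmetic",
    "encode", "decode", "fixed_mul", "lut_decay", "lut_log",
    "p_star_max", "max_tau_p",
]


@dataclass(frozen=True)
class FixedFormat:
    """A signed fixed-point format: 1 sign + ``int_bits`` + ``frac_bits``."""

    int_bits: int = 6
    frac_bits: int = 9
    signed: bool = True

    def __post_init__(self) -> None:
        if self.int_bits < 0 or self.frac_bits < 0:
            raise ValueError("bit counts must be non-negative")
        if not self.signed:
            raise ValueError("only signed formats are supported")

    @property
    def total_bits(self) -> int:
        return 1 + self.int_bits + self.frac_bits

    @property
    def scale(self) -> int:
        return 1 << self.frac_bits

    @property
    def raw_max(self) -> int:
        return (1 << (self.int_bits + self.frac_bits)) - 1

    @property
    def raw_min(self) -> int:
        return -(1 << (self.int_bits + self.frac_bits))

    @property
    def max(self) -> float:
        """Largest representable value, ``2^int_bits - 2^-frac_bits``."""
        return self.raw_max / self.scale

    @property
    def min(self) -> float:
        return self.raw_min / self.scale

    @property
    def resolution(self) -> float:
        return 1.0 / self.scale

    def quantize(self, x: float) -> float:
        return decode(encode(x, self), self)


#: The trace format used throughout: 16-bit signed, 6 integer / 9 fractional.
S6_9 = FixedFormat(6, 9)


def _round_half_even(x: float) -> int:
    # numpy.round / Python round are round-half-even already
    return int(round(x))


def encode(x: float, fmt: FixedFormat = S6_9, rounding: str = "nearest") -> int:
    """Encode a real value as a raw integer (round-to-nearest-even,
    saturating at the format limits)."""
    if rounding == "nearest":
        raw = _round_half_even(x * fmt.scale)
    elif rounding == "truncate":
        raw = math.floor(x * fmt.scale)
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return min(max(raw, fmt.raw_min), fmt.raw_max)


def decode(raw: int, fmt: FixedFormat = S6_9) -> float:
    return raw / fmt.scale


def fixed_mul(a: int, b: int, fmt: FixedFormat = S6_9,
              rounding: str = "nearest") -> int:
    """Multiply two raw fixed-point values: widened product, shifted back by
    ``frac_bits`` with rounding, then saturated."""
    wide = a * b
    if rounding == "nearest":
        raw = _round_half_even(wide / fmt.scale)
    elif rounding == "truncate":
        raw = wide >> fmt.frac_bits
    else:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return min(max(raw, fmt.raw_min), fmt.raw_max)


# ---------------------------------------------------------------------------
# Representability analysis
# ---------------------------------------------------------------------------

def p_star_max(f_max: float, tau_p: float) -> float:
    """Steady-state maximum of the P* trace under sustained firing at
    ``f_max`` (Hz), with ``tau_p`` in ms.

    Periodic unit increments at interval ``1/f_max`` with decay ``tau_p``
    form a geometric series summing to ``1/(1 - exp(-1/(f_max tau_p)))``
    (``f_max tau_p`` in consistent units, i.e. Hz times seconds).
    """
    if f_max < 0 or tau_p <= 0:
        raise ValueError("f_max must be >= 0 and tau_p > 0")
    if f_max == 0:
        return 1.0
    return 1.0 / (1.0 - math.exp(-1.0 / (f_max * tau_p * 1e-3)))


def max_tau_p(f_max: float, fmt: FixedFormat = S6_9) -> float:
    """Largest P-trace time constant (in seconds) whose steady-state
    maximum still fits the format: solves ``p_star_max = fmt.max`` giving
    ``tau_p = 1 / (f_max ln(M / (M - 1)))``."""
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    m = fmt.max
    return 1.0 / (f_max * math.log(m / (m - 1.0)))


# ---------------------------------------------------------------------------
# Lookup tables
# ---------------------------------------------------------------------------

@dataclass
class DecayLUT:
    """Precomputed ``exp(-k step / tau)`` factors in fixed point.

    The table is truncated at the first entry that rounds to zero in the
    format; indices past the horizon decay a value to exactly 0.
    """

    tau: float
    step: float = 1.0
    fmt: FixedFormat = S6_9
    entries: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.step <= 0:
            raise ValueError("tau and step must be positive")
        raws = []
        k = 0
        while True:
            raw = encode(math.exp(-k * self.step / self.tau), self.fmt)
            if raw == 0:
                break
            raws.append(raw)
            k += 1
        self.entries = np.array(raws, dtype=np.int64)

    @property
    def horizon(self) -> int:
        return len(self.entries)

    def to_text(self) -> str:
        lines = [f"# decay LUT tau={self.tau} ms step={self.step} ms "
                 f"format=S{self.fmt.int_bits}.{self.fmt.frac_bits}",
                 "# k\traw\tvalue"]
        for k, raw in enumerate(self.entries):
            lines.append(f"{k}\t{raw}\t{decode(int(raw), self.fmt):.9f}")
        return "\n".join(lines) + "\n"


def lut_decay(value: int, k: int, lut: DecayLUT,
              fmt: Optional[FixedFormat] = None,
              rounding: str = "nearest") -> int:
    """Decay a raw value over ``k`` elapsed steps using the table."""
    if k < 0:
        raise ValueError("elapsed steps must be non-negative")
    if k >= lut.horizon:
        return 0
    return fixed_mul(value, int(lut.entries[k]), fmt or lut.fmt, rounding)


@dataclass
class LogLUT:
    """Tabulated ``ln(y)`` for ``y in [1, 2)``.

    ``ln(x)`` for arbitrary positive ``x`` is recovered by normalizing
    ``x = y 2^n`` and returning ``ln(y) + n ln 2``; with 256 entries and
    linear interpolation the absolute error stays below the 2^-9
    resolution of the 9 fractional trace bits.
    """

    n_entries: int = 256
    entries: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_entries < 2:
            raise ValueError("need at least two entries")
        y = 1.0 + np.arange(self.n_entries) / self.n_entries
        self.entries = np.log(y)

    def to_text(self) -> str:
        lines = [f"# log LUT over [1,2) with {self.n_entries} entries",
                 "# y\tln(y)"]
        for k, v in enumerate(self.entries):
            lines.append(f"{1.0 + k / self.n_entries:.6f}\t{v:.9f}")
        return "\n".join(lines) + "\n"


def lut_log(x: int, lut: LogLUT, fmt: FixedFormat = S6_9) -> float:
    """Logarithm of a raw fixed-point value via the normalized table."""
    if x <= 0:
        raise ValueError("lut_log requires a positive argument")
    val = decode(x, fmt)
    n = math.floor(math.log2(val))
    y = val / (2.0 ** n)  # exact: division by a power of two
    # linear interpolation in the table
    pos = (y - 1.0) * lut.n_entries
    k = min(int(pos), lut.n_entries - 1)
    frac = pos - k
    if k + 1 < lut.n_entries:
        ln_y = lut.entries[k] * (1.0 - frac) + lut.entries[k + 1] * frac
    else:
        ln_y = lut.entries[k] + frac * (math.log(2.0) - lut.entries[k])
    return float(ln_y + n * math.log(2.0))


# ---------------------------------------------------------------------------
# Kernel arithmetic backend
# ---------------------------------------------------------------------------

class FixedArithmetic:
    """Drop-in replacement for :class:`ebcpnn.kernel.FloatArithmetic` that
    quantizes every trace operation to a fixed-point format and evaluates
    ``exp`` decays and ``log`` through LUTs.

    Elapsed times are discretized to ``step`` (the simulation timestep);
    one decay table is built per time constant on demand.
    """

    def __init__(self, fmt: FixedFormat = S6_9, step: float = 1.0,
                 rounding: str = "nearest", log_entries: int = 256) -> None:
        self.fmt = fmt
        self.step = step
        self.rounding = rounding
        self._decay_luts: dict[float, DecayLUT] = {}
        self.log_lut = LogLUT(log_entries)

    def _lut_for(self, tau: float) -> DecayLUT:
        lut = self._decay_luts.get(tau)
        if lut is None:
            lut = DecayLUT(tau=tau, step=self.step, fmt=self.fmt)
            self._decay_luts[tau] = lut
        return lut

    def decay(self, value: float, dt: float, tau: float) -> float:
        k = int(round(dt / self.step))
        raw = lut_decay(encode(value, self.fmt, self.rounding), k,
                        self._lut_for(tau), self.fmt, self.rounding)
        return decode(raw, self.fmt)

    def mul(self, a: float, b: float) -> float:
        raw = fixed_mul(encode(a, self.fmt, self.rounding),
                        encode(b, self.fmt, self.rounding),
                        self.fmt, self.rounding)
        return decode(raw, self.fmt)

    def quantize(self, x: float) -> float:
        return self.fmt.quantize(x)

    def log(self, x: float) -> float:
        # Probability estimates passed here live on a finer scale than the
        # trace format; normalize through the LUT directly from the float.
        if x <= 0:
            raise ValueError("log requires a positive argument")
        n = math.floor(math.log2(x))
        y = x / (2.0 ** n)
        lut = self.log_lut
        pos = (y - 1.0) * lut.n_entries
        k = min(int(pos), lut.n_entries - 1)
        frac = pos - k
        if k + 1 < lut.n_entries:
            ln_y = lut.entries[k] * (1.0 - frac) + lut.entries[k + 1] * frac
        else:
            ln_y = lut.entries[k] + frac * (math.log(2.0) - lut.entries[k])
        return float(ln_y + n * math.log(2.0))
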