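"""Fixed-point number formats and order-independent force accumulation.

The force engine modelled here keeps particle coordinates and accumulated
forces in 32-bit fixed-point words while evaluating each pairwise
interaction at single-precision-grade accuracy.  Integer accumulation is
commutative and associative bit-for-bit, so the total force on a particle
is identical no matter how the pair list is partitioned across compute
units — the property that makes domain-decomposed runs reproducible to
the last bit.

Words are held as Python/NumPy signed 64-bit integers internally and
wrapped to the configured word width on every addition (two's-complement
wraparound, with a sticky overflow flag rather than saturation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixedFormat",
    "FixedAccumulator",
    "coordinate_format",
    "encode_coordinate",
    "decode_coordinate",
    "quantize",
    "accumulate_write",
    "ForceBank",
]


@dataclass(frozen=True)
class FixedFormat:
    """A signed two's-complement fixed-point format.

    Parameters
    ----------
    word_bits:
        Width of the word in bits (32 for the modelled hardware).
    lsb:
        Physical value of one least-significant bit (length units for
        coordinate formats, force units for force formats).  Must be
        positive.
    """

    word_bits: int = 32
    lsb: float = 1.0

    def __post_init__(self) -> None:
        if self.word_bits < 2:
            raise ValueError("word_bits must be at least 2")
        if not self.lsb > 0:
            raise ValueError("lsb must be positive")

    @property
    def min_word(self) -> int:
        return -(1 << (self.word_bits - 1))

    @property
    def max_word(self) -> int:
        return (1 << (self.word_bits - 1)) - 1

    @property
    def modulus(self) -> int:
        return 1 << self.word_bits

    def wrap(self, word: int) -> int:
        """Reduce an arbitrary integer to the signed word range."""
        m = self.modulus
        w = word & (m - 1)
        if w > self.max_word:
            w -= m
        return w


def coordinate_format(box_length: float, word_bits: int = 32) -> FixedFormat:
    """Box-relative coordinate format: one lsb spans ``box_length / 2**bits``."""
    if not box_length > 0:
        raise ValueError("box_length must be positive")
    return FixedFormat(word_bits=word_bits, lsb=box_length / (1 << word_bits))


def _round_half_even(x):
    """Round to nearest integer, ties to even (unbiased accumulation)."""
    return np.rint(np.asarray(x)).astype(np.int64)


def encode_coordinate(x, box_length: float, fmt: FixedFormat | None = None):
    """Encode positions in ``[0, box_length)`` as unsigned-fraction words.

    The word is the position measured in units of ``lsb = L / 2**bits``,
    rounded to nearest; a position rounding up to ``L`` wraps to word 0
    (periodic image).  Callers must wrap coordinates into the box first.
    """
    if fmt is None:
        fmt = coordinate_format(box_length)
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0) or np.any(x >= box_length):
        raise ValueError("coordinate outside [0, box_length); wrap first")
    words = _round_half_even(x / fmt.lsb) % fmt.modulus
    return words if words.ndim else int(words)


def decode_coordinate(word, box_length: float, fmt: FixedFormat | None = None):
    """Decode an unsigned-fraction coordinate word back to a position."""
    if fmt is None:
        fmt = coordinate_format(box_length)
    w = np.asarray(word, dtype=np.int64) % fmt.modulus
    x = w.astype(np.float64) * fmt.lsb
    return x if x.ndim else float(x)


def quantize(value, fmt: FixedFormat):
    """Quantize a physical value to integer lsb units (round half to even)."""
    return _round_half_even(np.asarray(value, dtype=np.float64) / fmt.lsb)


@dataclass
class FixedAccumulator:
    """A single fixed-point accumulator word with a sticky overflow flag."""

    fmt: FixedFormat
    value: int = 0
    overflow_flag: bool = False

    def add_word(self, word: int) -> "FixedAccumulator":
        exact = self.value + int(word)
        wrapped = self.fmt.wrap(exact)
        if wrapped != exact:
            self.overflow_flag = True
        self.value = wrapped
        return self

    def add(self, term: float) -> "FixedAccumulator":
        """Quantize a physical term to the format's lsb and accumulate it."""
        return self.add_word(int(quantize(term, self.fmt)))

    @property
    def physical(self) -> float:
        return self.value * self.fmt.lsb


def accumulate_write(bank: np.ndarray, index, values, mode: str = "sum") -> np.ndarray:
    """Memory-bank write with optional accumulate-on-write.

    ``mode="sum"`` adds 32-bit integer payloads element-wise into the bank
    with two's-complement wraparound (the write port performs the addition,
    so concurrent writers need no read-modify-write lock and any arrival
    order yields the same final state).  ``mode="overwrite"`` replaces.
    Only integer payloads may be summed — the accumulate port has no
    floating-point adder.
    """
    bank = np.asarray(bank)
    if bank.dtype != np.int32:
        raise TypeError("memory bank must hold 32-bit integer words")
    values_arr = np.asarray(values)
    if mode == "sum":
        if not np.issubdtype(values_arr.dtype, np.integer):
            raise TypeError("accumulate-on-write accepts integer payloads only")
        # int32 + int32 wraps modulo 2^32 exactly in C semantics
        total = bank[index].astype(np.int64) + values_arr.astype(np.int64)
        wrapped = np.atleast_1d((total & 0xFFFFFFFF).astype(np.uint32)).view(np.int32)
        bank[index] = wrapped if np.ndim(total) else wrapped[0]
    elif mode == "overwrite":
        bank[index] = values_arr.astype(np.int32)
    else:
        raise ValueError(f"unknown write mode: {mode!r}")
    return bank


class ForceBank:
    """Per-particle 3-vector force accumulators in a fixed-point format.

    Backed by an ``(n, 3)`` int64 array wrapped to the word width on each
    deposit, so permuting or re-partitioning the deposit stream cannot
    change the final words.
    """

    def __init__(self, n_particles: int, fmt: FixedFormat):
        self.fmt = fmt
        self.words = np.zeros((n_particles, 3), dtype=np.int64)
        self.overflow_flag = False

    def deposit_words(self, indices, words) -> None:
        """Add integer force words (already in lsb units) to particles."""
        words = np.asarray(words, dtype=np.int64)
        np.add.at(self.words, np.asarray(indices), words)
        self._wrap()

    def deposit(self, indices, forces) -> None:
        """Quantize physical force vectors and add them."""
        self.deposit_words(indices, quantize(forces, self.fmt))

    def _wrap(self) -> None:
        m = self.fmt.modulus
        wrapped = self.words & (m - 1)
        wrapped[wrapped > self.fmt.max_word] -= m
        if not np.array_equal(wrapped, self.words):
            self.overflow_flag = True
            self.words = wrapped

    @property
    def physical(self) -> np.ndarray:
        return self.words.astype(np.float64) * self.fmt.lsb

    def total_word(self) -> np.ndarray:
        """Fixed-point sum of all per-particle words (wrapped)."""
        m = self.fmt.modulus
        tot = self.words.sum(axis=0) & (m - 1)
        tot[tot > self.fmt.max_word] -= m
        return tot
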