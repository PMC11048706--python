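"""Thermometer (cumulative) coding of the six ordered LN-RADS levels.

LN-RADS grades a lymph node's ultrasound appearance on an ordered scale
1 < 2 < 3 < 4a < 4b < 5 (normal → definitely malignant).  Level at ordinal
position p (0-based) is coded as p ones followed by zeros, so bit i answers
"is the level above threshold i".  The 5-bit form drops the constant leading
one of the original 6-bit table; the 6-bit form is exposed for completeness.
"""

from __future__ import annotations

import numpy as np

#: The six LN-RADS levels in increasing order of suspicion.
LEVELS: tuple[str, ...] = ("1", "2", "3", "4a", "4b", "5")

#: Number of bits in the reduced cumulative code.
N_BITS = 5

_LEVEL_INDEX = {lvl: i for i, lvl in enumerate(LEVELS)}


class InvalidLevelError(ValueError):
    """Raised for a string that is not one of the six LN-RADS levels."""


class InvalidCodeError(ValueError):
    """Raised for a bit vector that is not a valid thermometer code."""


def level_index(level: str) -> int:
    """Ordinal position (0..5) of an LN-RADS level string."""
    try:
        return _LEVEL_INDEX[str(level)]
    except KeyError:
        raise InvalidLevelError(
            f"unknown LN-RADS level {level!r}; expected one of {LEVELS}"
        ) from None


def encode_level(level: str) -> np.ndarray:
    """Encode an LN-RADS level as its 5-bit cumulative (thermometer) code.

    Level at ordinal position p maps to p ones followed by ``5 - p`` zeros,
    e.g. ``"4a" -> [1, 1, 1, 0, 0]`` and ``"1" -> [0, 0, 0, 0, 0]``.
    """
    p = level_index(level)
    code = np.zeros(N_BITS, dtype=np.int64)
    code[:p] = 1
    return code


def decode_code(code) -> str:
    """Inverse of :func:`encode_level`.

    Raises :class:`InvalidCodeError` for non-binary or non-monotone bit
    vectors (a 0 followed by a 1 does not correspond to any level).
    """
    bits = np.asarray(code)
    if bits.shape != (N_BITS,):
        raise InvalidCodeError(f"expected {N_BITS} bits, got shape {bits.shape}")
    if not np.isin(bits, (0, 1)).all():
        raise InvalidCodeError(f"bits must be 0/1, got {bits.tolist()}")
    if np.any(np.diff(bits.astype(int)) > 0):
        raise InvalidCodeError(
            f"non-monotone thermometer code {bits.tolist()}: 0 followed by 1"
        )
    return LEVELS[int(bits.sum())]


def code_with_leading_one(level: str) -> np.ndarray:
    """The original 6-bit coding: a constant 1 prepended to the 5-bit code.

    Kept for parity with the original code table; the experiments use the
    reduced 5-bit form.
    """
    return np.concatenate(([1], encode_level(level)))


def encode_levels(levels) -> np.ndarray:
    """Vectorised :func:`encode_level`: (n,) level strings -> (n, 5) int array."""
    return np.stack([encode_level(lvl) for lvl in levels])
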