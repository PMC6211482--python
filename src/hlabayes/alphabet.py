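"""Shared six-symbol alphabet: four bases, N, and the gap character.

All sequences handled by the model live over ``ACGTN-``; integer codes are
used internally so that likelihood tables can be indexed with numpy.
"""

from __future__ import annotations

import numpy as np

SYMBOLS = "ACGTN-"
BASES = "ACGT"
GAP_CHAR = "-"

A, C, G, T, N, GAP = range(6)
N_SYMBOLS = 6

_LOOKUP = {ch: i for i, ch in enumerate(SYMBOLS)}


def encode(seq: str) -> np.ndarray:
    """Encode a string over ``ACGTN-`` into int8 codes."""
    try:
        return np.fromiter((_LOOKUP[ch] for ch in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ValueError(f"symbol outside alphabet {SYMBOLS!r}: {exc}") from exc


def decode(codes) -> str:
    return "".join(SYMBOLS[int(i)] for i in codes)


def symbol_code(ch: str) -> int:
    if ch not in _LOOKUP:
        raise ValueError(f"symbol outside alphabet {SYMBOLS!r}: {ch!r}")
    return _LOOKUP[ch]


def is_base(code: int) -> bool:
    return 0 <= code <= 3
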