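"""Fixed-length sequence windows and one-hot encoding for the CNN.

Two windows are taken from each intron: the first k bp (containing the 5'
splice donor) and the last k bp (containing the branch site and the 3'
acceptor), k = 1000 by default.  Introns shorter than k are padded with
uniform rows, following the DeepBind convention of representing unknown
positions as (0.25, 0.25, 0.25, 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import IUPAC_DNA

__all__ = ["first_window", "last_window", "one_hot", "decode", "encode_windows",
           "OneHotSequence", "DEFAULT_WINDOW_BP"]

DEFAULT_WINDOW_BP = 1000

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_UNIFORM = np.full(4, 0.25, dtype=np.float32)


def first_window(sequence: str, k: int = DEFAULT_WINDOW_BP) -> str:
    """First min(L, k) bases, right-padded with 'N' to length k."""
    if not sequence:
        raise ValueError("empty sequence")
    return sequence[:k].ljust(k, "N")


def last_window(sequence: str, k: int = DEFAULT_WINDOW_BP) -> str:
    """Last min(L, k) bases, left-padded with 'N' to length k."""
    if not sequence:
        raise ValueError("empty sequence")
    return sequence[-k:].rjust(k, "N")


@dataclass
class OneHotSequence:
    """L x 4 one-hot matrix, columns ordered A, C, G, T."""

    matrix: np.ndarray
    origin: str  # {first_window, last_window, raw}
    pad_len: int


# byte -> column lookup: 0..3 for ACGT, 4 for IUPAC ambiguity, -1 invalid
_LOOKUP = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _LOOKUP[ord(_b)] = _i
for _b in IUPAC_DNA - set("ACGT"):
    _LOOKUP[ord(_b)] = 4


def one_hot(sequence: str, origin: str = "raw") -> OneHotSequence:
    """Encode a window as an L x 4 row-stochastic matrix.

    A/C/G/T become unit indicator rows; N, IUPAC ambiguity codes and 'N'
    padding become uniform (0.25, 0.25, 0.25, 0.25) rows.  A character
    outside the IUPAC alphabet raises ``ValueError`` naming its position.
    """
    a = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    idx = _LOOKUP[a]
    if (idx == -1).any():
        pos = int(np.flatnonzero(idx == -1)[0])
        raise ValueError(f"unexpected character {sequence[pos]!r} at position {pos}")
    # 5 templates: the 4 unit rows plus the uniform ambiguity row
    templates = np.vstack([np.eye(4, dtype=np.float32), _UNIFORM])
    m = templates[idx]
    return OneHotSequence(matrix=m, origin=origin, pad_len=int((idx == 4).sum()))


def decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot` for unambiguous rows ('N' for uniform rows)."""
    bases = np.array(list("ACGT"))
    out = []
    for row in matrix:
        if np.isclose(row.max(), 1.0):
            out.append(bases[int(row.argmax())])
        else:
            out.append("N")
    return "".join(out)


def encode_windows(
    sequences: list[str], which: str, k: int = DEFAULT_WINDOW_BP
) -> np.ndarray:
    """Encode many introns into an (N, k, 4) float32 array.

    ``which`` selects the window: "first" or "last".
    """
    if which not in ("first", "last"):
        raise ValueError("which must be 'first' or 'last'")
    win = first_window if which == "first" else last_window
    out = np.empty((len(sequences), k, 4), dtype=np.float32)
    for n, seq in enumerate(sequences):
        out[n] = one_hot(win(seq, k)).matrix
    return out
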