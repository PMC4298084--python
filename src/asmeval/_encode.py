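"""Low-level sequence encodings shared by the aligner, simulators and k-mer code.

Bases are encoded A=0, C=1, G=2, T=3.  Any other character (including N)
maps to 255 and never matches a read base.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_COMP = np.full(256, 255, dtype=np.uint8)
_COMP[:4] = [3, 2, 1, 0]

_REVCOMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into a uint8 array (non-ACGT -> 255)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    out = np.empty(arr.shape[0], dtype=np.uint8)
    for i, b in enumerate(BASES):
        out[arr == i] = ord(b)
    out[arr > 3] = ord("N")
    return out.tobytes().decode("ascii")


def revcomp_encoded(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr[::-1]]


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP_TABLE)[::-1]


def pack_kmers(arr: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of an encoded sequence into uint64 (2 bits/base).

    Requires k <= 31.  K-mers containing a non-ACGT base are reported as
    invalid via the companion boolean mask.

    Returns (kmers, valid) where kmers has length len(arr) - k + 1.
    """
    if k > 31:
        raise ValueError("packed k-mers support k <= 31")
    n = arr.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    bad = windows > 3
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    kmers = (windows.astype(np.uint64) * powers).sum(axis=1)
    return kmers, ~bad.any(axis=1)
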