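"""Internal 2-bit nucleotide encoding and k-mer packing helpers.

Bases are encoded A=0, C=1, G=2, T=3, N=4; the numeric order matches the
lexicographic order on {A,C,G,T}, so packed k-mer codes sort lexicographically.
k-mers are packed big-endian into uint64 (2 bits per base), which limits k to 31.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
N_CODE = 4
MAX_K = 31

_ENC = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)
# complement: A<->T, C<->G, N stays N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase ACGTN string to uint8 codes."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp_enc(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_enc(encode(seq)))


def _powers(k: int) -> np.ndarray:
    if k > MAX_K:
        raise ValueError(f"k={k} exceeds the packed-code limit of {MAX_K}")
    return (np.uint64(1) << (2 * np.arange(k - 1, -1, -1, dtype=np.uint64))).astype(np.uint64)


def pack(windows: np.ndarray) -> np.ndarray:
    """Pack (m, k) base-code rows into m uint64 codes (big-endian, lexicographic)."""
    m, k = windows.shape
    if m == 0:
        return np.empty(0, dtype=np.uint64)
    return windows.astype(np.uint64) @ _powers(k)


def unpack(codes: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`pack`: (m,) uint64 -> (m, k) uint8."""
    shifts = (2 * np.arange(k - 1, -1, -1, dtype=np.uint64))
    return ((codes[:, None] >> shifts[None, :]) & np.uint64(3)).astype(np.uint8)


def windows_enc(enc: np.ndarray, k: int) -> np.ndarray:
    """All length-k sliding windows of an encoded sequence as an (m, k) view."""
    if enc.size < k:
        return np.empty((0, k), dtype=np.uint8)
    return np.lib.stride_tricks.sliding_window_view(enc, k)
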