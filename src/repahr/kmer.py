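"""Low-level k-mer primitives: 2-bit encoding, canonicalisation, window scans.

k-mers over {A,C,G,T} are packed into Python ints / int64 arrays, two bits per
base (A=0, C=1, G=2, T=3), most significant bits first.  All vectorised scans
tolerate arbitrary other symbols: a window containing any non-ACGT byte is
flagged invalid rather than counted.  Supports k <= 31 (62 bits).
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_LUT = np.full(256, -1, dtype=np.int64)
for _b, _c in zip(b"ACGT", range(4)):
    _LUT[_b] = _c
for _b, _c in zip(b"acgt", range(4)):
    _LUT[_b] = _c

_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def encode_kmer(kmer: str) -> int:
    """Pack an ACGT string into an int. Raises ValueError on other symbols."""
    code = 0
    for ch in kmer:
        c = _LUT[ord(ch)]
        if c < 0:
            raise ValueError(f"non-ACGT symbol {ch!r} in k-mer {kmer!r}")
        code = (code << 2) | int(c)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement of a packed k-mer."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 ^ (code & 3))
        code >>= 2
    return out


def base_codes(seq: str) -> np.ndarray:
    """Per-base 2-bit codes (int64), -1 for non-ACGT symbols."""
    return _LUT[np.frombuffer(seq.encode("latin-1"), dtype=np.uint8)]


def _window_poly(codes: np.ndarray, k: int) -> np.ndarray:
    # Doubling scheme: window value of length m+m' from the two halves.
    # Exact in int64 for k <= 31.
    tables = [codes]
    i = 0
    while (2 << i) <= k:
        t = tables[i]
        m = 1 << i
        tables.append(t[: t.size - m] * (1 << (2 * m)) + t[m:])
        i += 1
    vals = None
    mlen = 0
    n = codes.size
    for i in range(len(tables) - 1, -1, -1):
        if k & (1 << i):
            t = tables[i]
            m = 1 << i
            if vals is None:
                vals, mlen = t, m
            else:
                n_out = n - (mlen + m) + 1
                vals = vals[:n_out] * (1 << (2 * m)) + t[mlen : mlen + n_out]
                mlen += m
    return vals


def window_codes(seq: str, k: int, canonical: bool = True):
    """Packed codes of every length-k window of ``seq``.

    Returns ``(vals, valid)``: int64 array of window codes (garbage where
    invalid) and a boolean mask of windows free of non-ACGT symbols.  Both
    have length ``len(seq) - k + 1`` (empty arrays if the sequence is shorter
    than k).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    codes = base_codes(seq)
    n = codes.size
    if n < k:
        empty = np.empty(0, dtype=np.int64)
        return empty, np.empty(0, dtype=bool)
    invalid = codes < 0
    c0 = np.where(invalid, 0, codes)
    fwd = _window_poly(c0, k)
    if canonical:
        r0 = (3 - c0)[::-1]
        rc = _window_poly(r0, k)[::-1]
        vals = np.minimum(fwd, rc)
    else:
        vals = fwd
    bad = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(invalid, out=bad[1:])
    valid = (bad[k:] - bad[:-k]) == 0
    return vals, valid
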