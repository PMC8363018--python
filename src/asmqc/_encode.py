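"""Low-level sequence encoding and k-mer window scanning.

Sequences are handled as ASCII ``uint8`` arrays.  A k-mer is packed into an
``int64`` using two bits per base (A=0, C=1, G=2, T=3), which supports
k <= 31.  Larger k (up to 64) is handled by string-based fallbacks in the
modules that need it (notably dot plots at k = 50).

The canonical form of a k-mer is the lexicographic minimum of the k-mer and
its reverse complement; with the A<C<G<T code this coincides with the
numeric minimum of the packed forward and reverse-complement codes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_PACKED_K = 31

# ASCII -> 2-bit code; 255 marks invalid (any non-ACGT symbol, incl. N).
ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    ENCODE[_b] = _i

_DECODE = "ACGT"

COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCATGCA"):
    COMPLEMENT[_a] = _b


def seq_to_bytes(seq) -> np.ndarray:
    """Return an ASCII uint8 view/copy of a sequence (str, bytes or array)."""
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return np.frombuffer(bytes(seq), dtype=np.uint8)


def revcomp(seq: str) -> str:
    arr = COMPLEMENT[seq_to_bytes(seq)][::-1]
    return arr.tobytes().decode("ascii")


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(_DECODE[(int(code) >> shift) & 3])
    return "".join(out)


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        b = int(ENCODE[ord(ch)])
        if b > 3:
            raise ValueError(f"non-ACGT base in k-mer: {kmer!r}")
        code = (code << 2) | b
    return code


@njit(cache=False)
def _scan_kernel(enc, k):  # pragma: no cover - exercised via window_codes
    n = enc.size - k + 1
    canon = np.zeros(n, dtype=np.int64)
    valid = np.zeros(n, dtype=np.bool_)
    mask = (np.int64(1) << (2 * k)) - 1
    hi_shift = 2 * (k - 1)
    fwd = np.int64(0)
    rev = np.int64(0)
    run = 0
    for i in range(enc.size):
        b = enc[i]
        if b > 3:
            run = 0
            fwd = 0
            rev = 0
        else:
            bb = np.int64(b)
            fwd = ((fwd << 2) | bb) & mask
            rev = (rev >> 2) | ((np.int64(3) - bb) << hi_shift)
            run += 1
        j = i - k + 1
        if j >= 0 and run >= k:
            canon[j] = fwd if fwd < rev else rev
            valid[j] = True
    return canon, valid


def window_codes(seq, k: int, invalid_mask: np.ndarray | None = None):
    """Canonical packed codes for every window of ``seq``.

    Returns ``(codes, valid)`` arrays of length ``len(seq) - k + 1``
    (empty if the sequence is shorter than k).  ``valid`` is False for
    windows containing a non-ACGT base or a base flagged in
    ``invalid_mask`` (a boolean array aligned with the sequence).
    """
    if not 2 <= k <= MAX_PACKED_K:
        raise ValueError(f"packed window scan requires 2 <= k <= {MAX_PACKED_K}, got {k}")
    arr = seq_to_bytes(seq)
    enc = ENCODE[arr]
    if invalid_mask is not None:
        enc = enc.copy()
        enc[invalid_mask] = 255
    if arr.size < k:
        return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool))
    return _scan_kernel(enc, k)


def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Random DNA with the requested GC content, as a string."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return arr.tobytes().decode("ascii")
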