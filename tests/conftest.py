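"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain Python string handling (no shared code
with the package's packed-integer kernels) so that agreement is a real
cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

_COMP = str.maketrans("ACGTacgt", "TGCATGCA")


def py_revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def py_canonical(kmer: str) -> str:
    rc = py_revcomp(kmer)
    return kmer if kmer <= rc else rc


def oracle_count(reads, k: int, min_quality: int = 0):
    """Naive sliding-window canonical k-mer counts.

    ``reads`` is an iterable of (id, seq, qual|None); qual is a Phred+33
    string or a list of ints.  Returns (counts dict, n_total, n_rejected).
    """
    counts: dict[str, int] = {}
    total = rejected = 0
    for _rid, seq, qual in reads:
        seq = seq.upper()
        if isinstance(qual, str):
            qual = [ord(c) - 33 for c in qual]
        for i in range(max(0, len(seq) - k + 1)):
            total += 1
            w = seq[i:i + k]
            bad = any(c not in "ACGT" for c in w)
            if qual is not None and min_quality > 0:
                bad = bad or any(q < min_quality for q in qual[i:i + k])
            if bad:
                rejected += 1
                continue
            key = py_canonical(w)
            counts[key] = counts.get(key, 0) + 1
    return counts, total, rejected


def oracle_copy_numbers(scaffolds: dict[str, str], k: int):
    """Naive per-window assembly copy numbers (None for invalid windows)."""
    occ: dict[str, int] = {}
    windows: dict[str, list] = {}
    for name, seq in scaffolds.items():
        seq = seq.upper()
        ws = []
        for i in range(max(0, len(seq) - k + 1)):
            w = seq[i:i + k]
            if any(c not in "ACGT" for c in w):
                ws.append(None)
            else:
                key = py_canonical(w)
                ws.append(key)
                occ[key] = occ.get(key, 0) + 1
        windows[name] = ws
    return {name: [None if w is None else occ[w] for w in ws]
            for name, ws in windows.items()}


def oracle_union_coverage(intervals, lo: int, hi: int) -> int:
    """Per-base marking union length of intervals clipped to [lo, hi)."""
    marked = np.zeros(hi - lo, dtype=bool)
    for s, e in intervals:
        s, e = max(s, lo), min(e, hi)
        if e > s:
            marked[s - lo:e - lo] = True
    return int(marked.sum())


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_seq(rng):
    def make(length: int, seed: int | None = None) -> str:
        r = np.random.default_rng(seed) if seed is not None else rng
        return "".join(r.choice(list("ACGT"), size=length))
    return make
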