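"""Haplotig detection: purge contigs duplicating a longer contig's sequence.

In a consensus assembly of a diploid sample, the assembler sometimes emits
both haplotypes of a region as separate contigs; the shorter duplicate
("haplotig") should be removed.  Detection is k-mer based: for every contig
the set of distinct canonical 22-mers is listed, and a shorter contig
sharing more than 80% of its set with a longer contig is classified as a
haplotig and removed.

"Unique 22-mers" is read as the set of distinct 22-mers of the contig; an
alternative occurs-exactly-once reading is available via
``kmer_semantics="occurs_once"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._encode import window_codes, decode_kmer


@dataclass
class HaplotigReport:
    """Pairwise sharing fractions and the removal decision per contig."""

    pairs: list[tuple[str, str, float]]  # (shorter, longer, shared fraction)
    removed: list[str]
    k: int
    threshold: float
    retained: list[str] = field(default_factory=list)


def _contig_codes(seq, k: int, semantics: str) -> np.ndarray:
    codes, valid = window_codes(seq, k)
    codes = codes[valid]
    uniq, counts = np.unique(codes, return_counts=True)
    if semantics == "occurs_once":
        return uniq[counts == 1]
    return uniq


def contig_kmer_set(contig, k: int = 22, kmer_semantics: str = "distinct") -> frozenset:
    """The set of distinct canonical k-mers of one contig (as strings).

    ``contig`` is a sequence or a (name, sequence) pair.  A contig shorter
    than k yields an empty set with a warning.
    """
    name, seq = contig if isinstance(contig, tuple) else ("contig", contig)
    if len(seq) < k:
        warnings.warn(f"{name}: shorter than k={k}; empty k-mer set", stacklevel=2)
        return frozenset()
    codes = _contig_codes(seq, k, kmer_semantics)
    return frozenset(decode_kmer(int(c), k) for c in codes)


def detect_haplotigs(
    contigs,
    k: int = 22,
    threshold: float = 0.80,
    kmer_semantics: str = "distinct",
) -> HaplotigReport:
    """Classify and remove haplotigs from a contig set.

    ``contigs`` is a dict name -> sequence or an iterable of (name,
    sequence) pairs.  Contigs are processed shortest-first; a contig is
    removed iff its shared fraction against ANY longer, not-yet-removed
    contig exceeds ``threshold``, so a haplotig cannot shelter another
    haplotig.  For equal-length pairs the lexicographically later name is
    treated as the shorter one (deterministic, arbitrary tie-break).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    items = list(contigs.items()) if isinstance(contigs, dict) else [
        (r.id, str(r.seq)) if hasattr(r, "seq") and hasattr(r, "id") else (r[0], r[1])
        for r in contigs]
    names = [n for n, _ in items]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate contig names: {', '.join(dupes)}")
    if len(items) < 2:
        raise ValueError("need at least 2 contigs")

    codes = {n: _contig_codes(s, k, kmer_semantics) for n, s in items}
    lengths = {n: len(s) for n, s in items}
    # shortest first; ties: lexicographically later name counts as shorter
    order = sorted(sorted(names, reverse=True), key=lambda n: lengths[n])

    pairs: list[tuple[str, str, float]] = []
    removed: list[str] = []
    removed_set: set[str] = set()
    for i, short in enumerate(order):
        if codes[short].size == 0:
            continue
        for longer in order[i + 1:]:
            if longer in removed_set:
                continue
            shared = np.intersect1d(codes[short], codes[longer],
                                    assume_unique=True).size
            frac = shared / codes[short].size
            pairs.append((short, longer, frac))
            if frac > threshold and short not in removed_set:
                removed.append(short)
                removed_set.add(short)
    retained = [n for n in names if n not in removed_set]
    return HaplotigReport(pairs=pairs, removed=removed, k=k,
                          threshold=threshold, retained=retained)
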