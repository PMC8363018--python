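"""Quality-aware canonical k-mer counting and assembly k-mer indexing.

This module provides the three k-mer containers the rest of the package is
built on:

``KmerSpectrum``
    multiplicities of canonical k-mers in a read set (M), counted from
    quality-filtered sliding windows;
``MultiplicityHistogram``
    the k-mer multiplicity histogram with detected peaks, from which the
    unique-homozygous mode D is taken;
``AssemblyKmerIndex``
    per-window assembly copy numbers (C) and a global occurrence map.

Counting is exact.  Windows containing a non-ACGT base, or any base below
the Phred quality threshold, are rejected and accounted for; remaining
windows are counted under their canonical form (lexicographic minimum of
the k-mer and its reverse complement), so counts are strand-independent.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._encode import (
    MAX_PACKED_K,
    canonical,
    decode_kmer,
    encode_kmer,
    seq_to_bytes,
    window_codes,
)

_SEP = ord("N")  # read separator; invalidates any window crossing it
_CHUNK_WINDOWS = 1 << 25


class MalformedRecordError(ValueError):
    """A read record whose quality string does not match its sequence."""


def _merge_code_counts(parts):
    """Merge a list of (codes, counts) pairs into one sorted pair."""
    if not parts:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    codes = np.concatenate([p[0] for p in parts])
    counts = np.concatenate([p[1] for p in parts])
    uniq, inv = np.unique(codes, return_inverse=True)
    summed = np.zeros(uniq.size, dtype=np.int64)
    np.add.at(summed, inv, counts)
    return uniq, summed


class _KmerMapping(Mapping):
    """Read-only dict-like view of a spectrum (decodes k-mers lazily)."""

    def __init__(self, spectrum: "KmerSpectrum"):
        self._s = spectrum

    def __getitem__(self, kmer: str) -> int:
        m = self._s.get(kmer)
        if m == 0:
            raise KeyError(kmer)
        return m

    def __iter__(self):
        k = self._s.k
        for code in self._s.codes:
            yield decode_kmer(int(code), k)

    def __len__(self):
        return self._s.codes.size


@dataclass
class KmerSpectrum:
    """Multiplicity of every canonical k-mer observed in a read set."""

    k: int
    codes: np.ndarray  # sorted packed canonical codes (int64)
    multiplicities: np.ndarray  # int64, aligned with codes
    min_quality: int = 0
    n_windows_total: int = 0
    n_windows_rejected: int = 0

    @property
    def counts(self) -> Mapping:
        """Mapping canonical k-mer string -> multiplicity."""
        return _KmerMapping(self)

    def get(self, kmer: str, default: int = 0) -> int:
        return int(self.multiplicity_of_code(encode_kmer(canonical(kmer)))) or default

    def __contains__(self, kmer: str) -> bool:
        return self.get(kmer) > 0

    def __len__(self) -> int:
        return int(self.codes.size)

    @property
    def total_multiplicity(self) -> int:
        return int(self.multiplicities.sum())

    def multiplicity_of_code(self, code: int) -> int:
        i = np.searchsorted(self.codes, code)
        if i < self.codes.size and self.codes[i] == code:
            return int(self.multiplicities[i])
        return 0

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized multiplicity lookup; absent k-mers get 0."""
        idx = np.searchsorted(self.codes, codes)
        idx = np.clip(idx, 0, max(self.codes.size - 1, 0))
        out = np.zeros(codes.size, dtype=np.int64)
        if self.codes.size:
            hit = self.codes[idx] == codes
            out[hit] = self.multiplicities[idx[hit]]
        return out

    @classmethod
    def from_counts(cls, mapping: Mapping, k: int, **kw) -> "KmerSpectrum":
        """Build a spectrum from an explicit {k-mer: multiplicity} mapping.

        K-mers are canonicalized; counts for a k-mer and its reverse
        complement are summed.
        """
        agg: dict[int, int] = {}
        for kmer, m in mapping.items():
            if len(kmer) != k:
                raise ValueError(f"k-mer {kmer!r} does not have length {k}")
            code = encode_kmer(canonical(kmer))
            agg[code] = agg.get(code, 0) + int(m)
        dtype = np.int64 if k <= MAX_PACKED_K else object
        ordered = sorted(agg)
        codes = np.array(ordered, dtype=dtype)
        mult = np.array([agg[c] for c in ordered], dtype=np.int64)
        kw.setdefault("n_windows_total", int(mult.sum()))
        return cls(k=k, codes=codes, multiplicities=mult, **kw)

    def items(self):
        for code, m in zip(self.codes, self.multiplicities):
            yield decode_kmer(int(code), self.k), int(m)


def _iter_records(reads):
    """Normalize heterogeneous read inputs to (id, seq, qual|None) tuples."""
    for i, rec in enumerate(reads):
        if isinstance(rec, str):
            yield f"read{i}", rec, None
        elif isinstance(rec, (tuple, list)):
            if len(rec) == 2:
                yield f"read{i}", rec[0], rec[1]
            else:
                yield rec[0], rec[1], rec[2]
        elif hasattr(rec, "letter_annotations"):  # Bio.SeqRecord
            qual = rec.letter_annotations.get("phred_quality")
            yield rec.id, str(rec.seq), qual
        else:
            raise TypeError(f"unsupported read record type: {type(rec)!r}")


def count_kmers(reads, k: int, min_quality: int = 20, canonical: bool = True) -> KmerSpectrum:
    """Count canonical k-mers in a read set with per-base quality filtering.

    Any window containing a base with Phred quality below ``min_quality``
    or a non-ACGT symbol is rejected.  ``reads`` may be an iterable of
    strings, ``(seq, qual)`` / ``(id, seq, qual)`` tuples, Biopython
    SeqRecords (FASTQ qualities honoured), or a ``simdata.ReadBatch``.

    Quality values may be given as Phred integers or as a Phred+33 string.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not canonical:
        raise NotImplementedError("only canonical counting is supported")
    if k > MAX_PACKED_K:
        return _count_kmers_strings(reads, k, min_quality)

    if hasattr(reads, "seqs") and getattr(reads, "seqs", None) is not None \
            and getattr(reads.seqs, "ndim", 0) == 2:
        big, n_total = _concat_batch(reads, k, min_quality)
    else:
        big, n_total = _concat_records(reads, k, min_quality)

    if n_total == 0:
        warnings.warn(f"k={k} exceeds every read length; empty spectrum", stacklevel=2)
        return KmerSpectrum(k=k, codes=np.zeros(0, np.int64),
                            multiplicities=np.zeros(0, np.int64),
                            min_quality=min_quality)

    parts = []
    n_valid = 0
    step = _CHUNK_WINDOWS
    for start in range(0, max(big.size - k + 1, 1), step):
        chunk = big[start:start + step + k - 1]
        codes, valid = window_codes(chunk, k)
        ok = codes[valid]
        n_valid += int(valid.sum())
        if ok.size:
            parts.append(np.unique(ok, return_counts=True))
    codes, mult = _merge_code_counts(parts)
    spec = KmerSpectrum(
        k=k, codes=codes, multiplicities=mult, min_quality=min_quality,
        n_windows_total=int(n_total), n_windows_rejected=int(n_total - n_valid),
    )
    assert spec.total_multiplicity == spec.n_windows_total - spec.n_windows_rejected
    return spec


def _qual_to_phred(qual, n, rid):
    if qual is None:
        return None
    if isinstance(qual, str):
        arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    else:
        arr = np.asarray(qual, dtype=np.int16)
    if arr.size != n:
        raise MalformedRecordError(
            f"record {rid!r}: quality length {arr.size} != sequence length {n}")
    return arr


def _concat_records(reads, k, min_quality):
    pieces = []
    n_total = 0
    for rid, seq, qual in _iter_records(reads):
        arr = seq_to_bytes(seq).copy()
        phred = _qual_to_phred(qual, arr.size, rid)
        if phred is not None and min_quality > 0:
            arr[phred < min_quality] = _SEP
        n_total += max(0, arr.size - k + 1)
        pieces.append(arr)
        pieces.append(np.array([_SEP], dtype=np.uint8))
    if not pieces:
        raise ValueError("reads is empty")
    return np.concatenate(pieces), n_total


def _concat_batch(batch, k, min_quality):
    n, length = batch.seqs.shape
    mat = batch.seqs
    if batch.quals is not None and min_quality > 0:
        mat = mat.copy()
        mat[batch.quals.astype(np.int16) - 33 < min_quality] = _SEP
    sep = np.full((n, 1), _SEP, dtype=np.uint8)
    big = np.hstack([mat, sep]).ravel()
    return big, n * max(0, length - k + 1)


def _count_kmers_strings(reads, k, min_quality):
    # Fallback for k > 31: canonical string keys in a plain dict.
    from ._encode import revcomp

    agg: dict[str, int] = {}
    n_total = 0
    n_valid = 0
    for rid, seq, qual in _iter_records(reads):
        seq = seq.upper()
        phred = _qual_to_phred(qual, len(seq), rid)
        bad = np.zeros(len(seq), dtype=bool)
        arr = seq_to_bytes(seq)
        bad |= ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        if phred is not None and min_quality > 0:
            bad |= phred < min_quality
        nw = max(0, len(seq) - k + 1)
        n_total += nw
        run = np.cumsum(np.concatenate([[0], bad.astype(int)]))
        for i in range(nw):
            if run[i + k] - run[i] == 0:
                w = seq[i:i + k]
                rc = revcomp(w)
                key = w if w <= rc else rc
                agg[key] = agg.get(key, 0) + 1
                n_valid += 1
    spec = KmerSpectrum.from_counts(agg, k, min_quality=min_quality)
    spec.n_windows_total = n_total
    spec.n_windows_rejected = n_total - n_valid
    return spec


@dataclass
class MultiplicityHistogram:
    """Histogram of k-mer multiplicities with detected distribution peaks.

    ``D`` is the multiplicity at the unique-homozygous peak — the mode of
    k-mers present once per haploid copy on both haplotypes — used to
    normalize read-depth-derived multiplicities.  ``status`` is ``"ok"``
    when D was determined, ``"undetermined"`` otherwise.
    """

    bins: dict[int, int]
    peaks: list[tuple[int, int]] = field(default_factory=list)
    D: int | None = None
    status: str = "ok"

    def require_D(self) -> int:
        if self.D is None:
            raise ValueError(
                "homozygous-peak multiplicity D is undetermined; "
                "inspect the histogram or set D explicitly")
        return self.D


def build_histogram(
    spectrum: KmerSpectrum,
    min_multiplicity_reported: int = 1,
    smooth_window: int = 3,
    min_peak_height_frac: float = 0.01,
    min_peak_multiplicity: int = 5,
    max_multiplicity: int = 1000,
    right_peak_min_frac: float = 0.10,
) -> MultiplicityHistogram:
    """Histogram the spectrum and locate the unique-homozygous peak D.

    Peaks are detected on a moving-average smoothed copy of the histogram
    (window ``smooth_window``); candidate peaks must reach
    ``min_peak_height_frac`` of the global maximum and lie at multiplicity
    >= ``min_peak_multiplicity`` (suppressing the sequencing-error spike
    near multiplicity 1).  Among the two highest surviving peaks, D is the
    one at greater multiplicity (the homozygous peak lies right of the
    heterozygous peak) — unless that right-hand peak is tiny (height below
    ``right_peak_min_frac`` of the highest peak), in which case it is
    treated as a repeat harmonic (k-mers at assembly copy number 2 peak
    near 2D) and the highest peak itself is taken as homozygous.
    """
    if len(spectrum) == 0:
        raise ValueError("spectrum is empty")
    mults, nk = np.unique(spectrum.multiplicities, return_counts=True)
    bins = {int(m): int(c) for m, c in zip(mults, nk)
            if m >= min_multiplicity_reported}

    cap = int(min(mults.max(), max_multiplicity))
    # trailing zero-padding so a peak at the maximum multiplicity is not
    # suppressed as a boundary plateau
    dense = np.zeros(cap + smooth_window + 2, dtype=float)
    inside = mults <= cap
    dense[mults[inside].astype(int)] = nk[inside]
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(dense, kernel, mode="same")

    idx, _ = find_peaks(smoothed)
    floor = min_peak_height_frac * smoothed.max()
    idx = [i for i in idx if smoothed[i] >= floor and i >= min_peak_multiplicity]
    # smoothing locates peaks; refine each to the raw-histogram maximum in
    # its neighbourhood (the smoothed argmax can drift on sparse bins)
    refined: dict[int, int] = {}
    for i in idx:
        lo_i = max(i - smooth_window, 0)
        j = lo_i + int(np.argmax(dense[lo_i:i + smooth_window + 1]))
        if j >= min_peak_multiplicity:
            refined[j] = int(dense[j])
    peaks = sorted(refined.items())

    if not peaks:
        return MultiplicityHistogram(bins=bins, peaks=[], D=None, status="undetermined")
    top2 = sorted(peaks, key=lambda p: (p[1], p[0]), reverse=True)[:2]
    (m1, h1) = top2[0]
    D = m1
    if len(top2) == 2:
        m2, h2 = top2[1]
        if m2 > m1 and h2 >= right_peak_min_frac * h1:
            D = m2  # heterozygous peak is the global max; hom lies right
    return MultiplicityHistogram(bins=bins, peaks=peaks, D=D, status="ok")


class AssemblyKmerIndex:
    """Per-window assembly copy numbers and a global k-mer occurrence map.

    For every valid window (no non-ACGT base) of every scaffold, the copy
    number C is the total number of occurrences of that window's canonical
    k-mer anywhere in the indexed assembly set.  Invalid windows are marked
    in ``valid`` rather than given C = 0.
    """

    def __init__(self, k: int, names, codes_by_scaffold, valid_by_scaffold, lengths):
        self.k = k
        self.names = list(names)
        self._codes = codes_by_scaffold
        self._valid = valid_by_scaffold
        self.lengths = lengths

        all_codes, all_sid, all_pos = [], [], []
        for sid, name in enumerate(self.names):
            v = self._valid[name]
            c = self._codes[name][v]
            all_codes.append(c)
            all_sid.append(np.full(c.size, sid, dtype=np.int32))
            all_pos.append(np.flatnonzero(v).astype(np.int64))
        codes = np.concatenate(all_codes) if all_codes else np.zeros(0, np.int64)
        order = np.argsort(codes, kind="stable")
        self._occ_codes = codes[order]
        self._occ_sid = np.concatenate(all_sid)[order] if all_codes else np.zeros(0, np.int32)
        self._occ_pos = np.concatenate(all_pos)[order] if all_codes else np.zeros(0, np.int64)
        self._uniq, self._group_start, group_counts = np.unique(
            self._occ_codes, return_index=True, return_counts=True)
        self._group_counts = group_counts

        self._cn = {}
        for name in self.names:
            v = self._valid[name]
            cn = np.zeros(self._codes[name].size, dtype=np.int32)
            if v.any():
                gi = np.searchsorted(self._uniq, self._codes[name][v])
                cn[v] = self._group_counts[gi]
            self._cn[name] = cn

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def window_codes_of(self, name: str) -> np.ndarray:
        return self._codes[name]

    def valid_windows(self, name: str) -> np.ndarray:
        return self._valid[name]

    def copy_number(self, name: str) -> np.ndarray:
        """Per-window C for one scaffold (0 at invalid windows)."""
        return self._cn[name]

    def occurrences(self, kmer: str) -> list[tuple[str, int]]:
        """All (scaffold, position) occurrences of a k-mer's canonical form."""
        return self.occurrences_by_code(encode_kmer(canonical(kmer)))

    def occurrences_by_code(self, code: int) -> list[tuple[str, int]]:
        i = np.searchsorted(self._uniq, code)
        if i >= self._uniq.size or self._uniq[i] != code:
            return []
        s = self._group_start[i]
        e = s + self._group_counts[i]
        return [(self.names[sid], int(pos))
                for sid, pos in zip(self._occ_sid[s:e], self._occ_pos[s:e])]

    def group_reduce_all(self, occ_flags: np.ndarray) -> np.ndarray:
        """AND-reduce a per-occurrence boolean over k-mer groups.

        Returns one boolean per distinct k-mer (aligned with the internal
        unique-code order): True iff the flag holds at every occurrence.
        """
        return np.logical_and.reduceat(occ_flags, self._group_start)

    def per_window_group_index(self, name: str) -> np.ndarray:
        """Index into the distinct-code arrays for each valid window."""
        v = self._valid[name]
        return np.searchsorted(self._uniq, self._codes[name][v])


def _normalize_scaffolds(scaffolds):
    if isinstance(scaffolds, dict):
        items = list(scaffolds.items())
    else:
        items = []
        for rec in scaffolds:
            if hasattr(rec, "seq") and hasattr(rec, "id"):
                items.append((rec.id, str(rec.seq)))
            else:
                items.append((rec[0], rec[1]))
    names = [n for n, _ in items]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate scaffold names: {', '.join(dupes)}")
    return items


def index_assembly(scaffolds, k: int) -> AssemblyKmerIndex:
    """Index an assembly's k-mer content (copy numbers and occurrences).

    ``scaffolds`` may be a dict name -> sequence, an iterable of
    ``(name, sequence)`` pairs, or SeqRecords.  Scaffold names must be
    unique.
    """
    items = _normalize_scaffolds(scaffolds)
    codes_by, valid_by, lengths = {}, {}, {}
    for name, seq in items:
        codes, valid = window_codes(seq, k)
        codes_by[name] = codes
        valid_by[name] = valid
        lengths[name] = len(seq)
    return AssemblyKmerIndex(k, [n for n, _ in items], codes_by, valid_by, lengths)
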