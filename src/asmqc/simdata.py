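"""Seed-controlled synthetic diploid genomes, reads, and truth sets.

The generator emulates the structures that make immune loci hard to
assemble and that k-mer validation is designed to expose:

* heterozygous deletions (present on one haplotype only; expected
  normalized multiplicity 0.5 over the interval when the assembly carries
  the non-deleted haplotype),
* duplications with per-haplotype copy numbers, covering both collapsed
  duplications (2 copies per haplotype assembled once; expected N = 2) and
  compound CNVs (1 copy vs 3 copies; expected N = 2 on the single
  assembled copy),
* tandem satellite arrays (an optionally signature-bearing unit repeated
  with per-copy divergence),
* planted label motifs for in-silico optical-map digestion.

All randomness flows from a single integer seed; the same spec renders
byte-identical haplotypes, and a truth set records feature coordinates in
each rendering together with the expected N level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._encode import COMPLEMENT, random_sequence, seq_to_bytes


@dataclass
class HetDeletion:
    """Backbone interval present on haplotype A, absent from haplotype B."""
    start: int
    length: int
    name: str = "het_deletion"


@dataclass
class Duplication:
    """Backbone segment in tandem copy numbers (copies_a, copies_b).

    ``copies_a = copies_b = 2`` with a single-copy assembly models a
    collapsed duplication; ``(1, 3)`` models a compound CNV.
    """
    start: int
    length: int
    copies_a: int = 2
    copies_b: int = 2
    name: str = "duplication"


@dataclass
class TandemArray:
    """Tandem repeat array inserted at a backbone point (homozygous)."""
    start: int
    copies: int
    unit_length: int | None = None
    unit: str | None = None
    divergence: float = 0.0
    signature: str | None = None
    name: str = "tandem_array"

    @property
    def footprint(self) -> int:
        return 0  # insertion at a point


@dataclass
class MotifLattice:
    """Plant a motif every ``spacing`` bp (with jitter) across an interval."""
    start: int
    length: int
    motif: str = "CTTAAG"
    spacing: int = 8000
    jitter: int = 0
    name: str = "motif_lattice"


Feature = HetDeletion | Duplication | TandemArray | MotifLattice


@dataclass
class GenomeSpec:
    """Blueprint of a synthetic diploid genome."""
    length: int
    gc: float = 0.5
    seed: int = 0
    features: list = field(default_factory=list)


@dataclass
class TruthSet:
    """Feature coordinates per rendering and expected validation levels.

    ``intervals[role][feature_name]`` is the (start, end) of the feature in
    the ``role`` rendering ('A', 'B' or 'consensus'; None when absent).
    ``expected_N[feature_name]`` is the normalized multiplicity expected
    over the feature when the consensus (single-copy) rendering is used as
    the assembly and reads are drawn evenly from both haplotypes.
    """
    intervals: dict[str, dict[str, tuple[int, int] | None]]
    expected_N: dict[str, float]
    motif_positions: dict[str, list[int]] = field(default_factory=dict)
    error_positions: list[int] = field(default_factory=list)


def _footprint(f: Feature) -> tuple[int, int]:
    if isinstance(f, TandemArray):
        return f.start, f.start
    return f.start, f.start + f.length


def _check_features(spec: GenomeSpec):
    feats = sorted(spec.features, key=lambda f: f.start)
    names = [f.name for f in feats]
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    for f in feats:
        if _footprint(f)[1] > spec.length or f.start < 0:
            raise ValueError(f"feature {f.name!r} extends past the backbone")
    # MotifLattice only edits backbone bases in place, so it may span
    # other features; structural features must not overlap each other.
    structural = [f for f in feats if not isinstance(f, MotifLattice)]
    for a, b in zip(structural[:-1], structural[1:]):
        if _footprint(a)[1] > _footprint(b)[0]:
            raise ValueError(f"overlapping features: {a.name!r} and {b.name!r}")
    return feats


def make_tandem_array(copies: int, unit: str | None = None,
                      unit_length: int | None = None,
                      divergence: float = 0.0, seed: int = 0,
                      signature: str | None = None,
                      rng: np.random.Generator | None = None) -> str:
    """Concatenate ``copies`` copies of a repeat unit with per-copy divergence.

    Each copy is independently mutated (substitutions at the stated rate).
    When a ``signature`` motif is given it is embedded once per unit and
    protected from divergence mutations, so every emitted copy carries one
    exact signature occurrence.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if unit is None:
        if unit_length is None:
            raise ValueError("give either unit or unit_length")
        unit = random_sequence(unit_length, rng)
    protected = np.zeros(len(unit), dtype=bool)
    if signature:
        if len(signature) > len(unit):
            raise ValueError("signature longer than unit")
        at = max(0, (len(unit) - len(signature)) // 2)
        unit = unit[:at] + signature + unit[at + len(signature):]
        protected[at:at + len(signature)] = True
    base = seq_to_bytes(unit).copy()
    enc = "ACGT"
    out = []
    for _ in range(copies):
        copy = base.copy()
        if divergence > 0:
            hit = (rng.random(copy.size) < divergence) & ~protected
            idx = np.flatnonzero(hit)
            for i in idx:
                cur = chr(copy[i])
                choices = [c for c in enc if c != cur]
                copy[i] = ord(choices[rng.integers(0, 3)])
        out.append(copy.tobytes().decode("ascii"))
    return "".join(out)


def _materialize(spec: GenomeSpec):
    """Backbone and concrete feature sequences, deterministic in the seed."""
    feats = _check_features(spec)
    rng = np.random.default_rng(spec.seed)
    backbone = bytearray(random_sequence(spec.length, rng, spec.gc), "ascii")
    motif_positions: dict[str, list[int]] = {}
    arrays: dict[str, str] = {}
    for f in feats:
        if isinstance(f, MotifLattice):
            pos_list = []
            p = f.start
            while p + len(f.motif) <= f.start + f.length:
                jit = int(rng.integers(-f.jitter, f.jitter + 1)) if f.jitter else 0
                q = min(max(p + jit, f.start), f.start + f.length - len(f.motif))
                backbone[q:q + len(f.motif)] = f.motif.encode("ascii")
                pos_list.append(q)
                p += f.spacing
            motif_positions[f.name] = pos_list
        elif isinstance(f, TandemArray):
            arrays[f.name] = make_tandem_array(
                f.copies, unit=f.unit, unit_length=f.unit_length,
                divergence=f.divergence, signature=f.signature, rng=rng)
    return backbone.decode("ascii"), feats, arrays, motif_positions


def _copies(f: Feature, role: str) -> int:
    if isinstance(f, HetDeletion):
        return {"A": 1, "B": 0, "consensus": 1}[role]
    if isinstance(f, Duplication):
        return {"A": f.copies_a, "B": f.copies_b, "consensus": 1}[role]
    return 1


def render(spec: GenomeSpec, role: str):
    """Render one haplotype ('A', 'B') or the single-copy 'consensus'.

    Returns ``(sequence, intervals)`` where ``intervals`` maps feature
    names to their (start, end) span in the rendered sequence (None when
    the feature is absent from this rendering).
    """
    if role not in ("A", "B", "consensus"):
        raise ValueError("role must be 'A', 'B' or 'consensus'")
    backbone, feats, arrays, _ = _materialize(spec)
    parts: list[str] = []
    intervals: dict[str, tuple[int, int] | None] = {}
    cursor = 0
    out_len = 0
    for f in feats:
        if isinstance(f, MotifLattice):
            continue  # lattice edits live in the backbone already
        s, e = _footprint(f)
        parts.append(backbone[cursor:s])
        out_len += s - cursor
        seg = arrays[f.name] if isinstance(f, TandemArray) else backbone[s:e]
        piece = seg * _copies(f, role)
        intervals[f.name] = (out_len, out_len + len(piece)) if piece else None
        parts.append(piece)
        out_len += len(piece)
        cursor = e
    parts.append(backbone[cursor:])
    out_len += spec.length - cursor
    return "".join(parts), intervals


def build_diploid(spec: GenomeSpec):
    """Build haplotypes A and B plus the truth set.

    The truth set also records feature intervals in the 'consensus'
    rendering (each duplication at one copy), which is the natural
    stand-in for a collapsed/consensus assembly, and the normalized
    multiplicity expected over each feature when validating that
    rendering against diploid reads.
    """
    hapA, ivA = render(spec, "A")
    hapB, ivB = render(spec, "B")
    _, ivC = render(spec, "consensus")
    _, feats, _, motif_positions = _materialize(spec)
    expected = {}
    for f in feats:
        ca, cb = _copies(f, "A"), _copies(f, "B")
        expected[f.name] = (ca + cb) / 2.0  # over consensus copy number 1
    truth = TruthSet(
        intervals={"A": ivA, "B": ivB, "consensus": ivC},
        expected_N=expected, motif_positions=motif_positions)
    return hapA, hapB, truth


class ReadBatch:
    """Fixed-length reads held as ASCII matrices (fast path for counting)."""

    def __init__(self, seqs: np.ndarray, quals: np.ndarray | None,
                 prefix: str = "r"):
        self.seqs = seqs
        self.quals = quals
        self.prefix = prefix

    @property
    def n(self) -> int:
        return self.seqs.shape[0]

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1]

    @property
    def total_bases(self) -> int:
        return int(self.seqs.size)

    def __len__(self):
        return self.n

    def __iter__(self):
        for i in range(self.n):
            seq = self.seqs[i].tobytes().decode("ascii")
            qual = (self.quals[i].tobytes().decode("ascii")
                    if self.quals is not None else "I" * len(seq))
            yield f"{self.prefix}{i}", seq, qual

    def to_fastq(self, path_or_handle):
        handle = (open(path_or_handle, "w")
                  if isinstance(path_or_handle, str) else path_or_handle)
        try:
            for rid, seq, qual in self:
                handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        finally:
            if isinstance(path_or_handle, str):
                handle.close()

    @classmethod
    def concatenate(cls, batches: list["ReadBatch"]) -> "ReadBatch":
        seqs = np.vstack([b.seqs for b in batches])
        quals = (np.vstack([b.quals for b in batches])
                 if batches[0].quals is not None else None)
        return cls(seqs, quals, batches[0].prefix)


def simulate_reads(
    genome,
    depth: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    quality: int = 40,
    seed: int = 0,
    low_quality_sites=None,
    low_quality_value: int = 2,
    circular: bool = False,
) -> ReadBatch:
    """Uniform shotgun reads with i.i.d. substitution errors.

    ``genome`` is one sequence or a list of sequences (e.g. both
    haplotypes); each is sampled at ``depth`` fold coverage with random
    strand.  Qualities are constant Phred ``quality`` except at bases
    covering ``low_quality_sites`` (positions on the forward genome),
    which get ``low_quality_value`` — a two-tier model for exercising the
    quality filter.

    With ``circular=True`` read start positions wrap around the sequence
    end, giving uniform coverage everywhere; linear sampling (the
    default) under-covers the terminal read-length of each sequence, as
    real shotgun data does at contig ends.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    seqs = [genome] if isinstance(genome, str) else list(genome)
    rng = np.random.default_rng(seed)
    batches = []
    for si, seq in enumerate(seqs):
        L = len(seq)
        if read_length > L:
            raise ValueError(f"read length {read_length} exceeds genome length {L}")
        n = int(round(depth * L / read_length))
        arr = seq_to_bytes(seq)
        if circular:
            starts = rng.integers(0, L, size=n)
            mat = arr[(starts[:, None] + np.arange(read_length)) % L]
        else:
            starts = rng.integers(0, L - read_length + 1, size=n)
            mat = arr[starts[:, None] + np.arange(read_length)]
        flip = rng.random(n) < 0.5
        mat[flip] = COMPLEMENT[mat[flip]][:, ::-1]
        if error_rate > 0:
            _apply_substitutions(mat, error_rate, rng)
        if low_quality_sites:
            quals = np.full(mat.shape, quality + 33, dtype=np.uint8)
            site_set = set(low_quality_sites)
            for i in range(n):
                for off in range(read_length):
                    gpos = (starts[i] + read_length - 1 - off) if flip[i] \
                        else starts[i] + off
                    if gpos in site_set:
                        quals[i, off] = low_quality_value + 33
        else:
            quals = np.full(mat.shape, quality + 33, dtype=np.uint8)
        batches.append(ReadBatch(mat, quals, prefix=f"s{si}_"))
    return batches[0] if len(batches) == 1 else ReadBatch.concatenate(batches)


def _apply_substitutions(mat: np.ndarray, rate: float, rng: np.random.Generator,
                         chunk: int = 100_000):
    from ._encode import ENCODE
    decode = np.frombuffer(b"ACGT", dtype=np.uint8)
    for lo in range(0, mat.shape[0], chunk):
        block = mat[lo:lo + chunk]
        hit = rng.random(block.shape) < rate
        if not hit.any():
            continue
        enc = ENCODE[block[hit]]
        ok = enc <= 3
        shift = rng.integers(1, 4, size=enc.size).astype(np.uint8)
        newb = block[hit]
        newb[ok] = decode[(enc[ok] + shift[ok]) % 4]
        block[hit] = newb


def plant_errors(sequence: str, n: int, min_separation: int, seed: int = 0):
    """Plant ``n`` substitutions at positions >= ``min_separation`` apart.

    Returns ``(mutated sequence, sorted positions)``.  Used to exercise
    the cluster-based error-rate estimator against known truth.
    """
    L = len(sequence)
    if n == 0:
        return sequence, []
    if n * min_separation >= L:
        raise ValueError("cannot fit errors with the requested separation")
    rng = np.random.default_rng(seed)
    slack = L - (n - 1) * min_separation - 1
    xs = np.sort(rng.choice(slack, size=n, replace=False))
    positions = (xs + np.arange(n) * min_separation).astype(int)
    arr = bytearray(sequence, "ascii")
    for p in positions:
        cur = chr(arr[p]).upper()
        options = [c for c in "ACGT" if c != cur]
        arr[p] = ord(options[rng.integers(0, len(options))])
    return arr.decode("ascii"), [int(p) for p in positions]


def demo_spec(length: int = 2_000_000, seed: int = 17) -> GenomeSpec:
    """A compact genome exercising every planted-structure class at once:
    one heterozygous deletion, one collapsed duplication, one 1-vs-3
    compound CNV, one signature-bearing 59-mer satellite cluster, and a
    label-motif lattice for optical-map digestion."""
    hsat_sig = "TTCGATTCCATTTGATGATTCCAT"
    return GenomeSpec(length=length, seed=seed, features=[
        MotifLattice(start=0, length=length, spacing=8000, name="dle1"),
        HetDeletion(start=int(length * 0.15), length=60_000),
        Duplication(start=int(length * 0.40), length=30_000,
                    copies_a=2, copies_b=2, name="collapse"),
        Duplication(start=int(length * 0.65), length=25_000,
                    copies_a=1, copies_b=3, name="compound_cnv"),
        TandemArray(start=int(length * 0.85), copies=45, unit_length=59,
                    divergence=0.0, name="satellite_59mer"),
        TandemArray(start=int(length * 0.92), copies=20, unit_length=6000,
                    divergence=0.02, signature=hsat_sig, name="hsat_like"),
    ])
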