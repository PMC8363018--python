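"""File input/output: FASTA/FASTQ (gzip transparent), PAF/SAM candidates,
and the package's tabular outputs (spectrum, histogram, tracks, BED,
label maps, placements, plans)."""

from __future__ import annotations

import gzip
import json

import numpy as np
import pandas as pd
from Bio import SeqIO

from .anchoring import CandidateAlignment
from .scaffolding import LabelMap, MapPlacement


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """FASTA (optionally gzipped) as an ordered dict name -> sequence."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, sequences: dict[str, str], width: int = 80):
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path):
    """Iterate (id, sequence, phred string) records from a FASTQ file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in
                           rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq), qual


def write_spectrum_tsv(spectrum, path, sidecar: str | None = None):
    """Spectrum as sorted two-column TSV plus a JSON accounting sidecar."""
    with _open_text(path, "wt") as fh:
        for kmer, mult in spectrum.items():
            fh.write(f"{kmer}\t{mult}\n")
    meta = {
        "k": spectrum.k,
        "min_quality": spectrum.min_quality,
        "n_windows_total": spectrum.n_windows_total,
        "n_windows_rejected": spectrum.n_windows_rejected,
        "n_distinct_kmers": len(spectrum),
    }
    with open(sidecar or str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_spectrum_tsv(path, k: int | None = None, **kw):
    from .kmerlib import KmerSpectrum
    counts = {}
    with _open_text(path) as fh:
        for line in fh:
            kmer, mult = line.split()
            counts[kmer] = int(mult)
    if k is None:
        k = len(next(iter(counts)))
    return KmerSpectrum.from_counts(counts, k, **kw)


def write_histogram_tsv(hist, path):
    pd.DataFrame(sorted(hist.bins.items()),
                 columns=["multiplicity", "n_kmers"]).to_csv(
        path, sep="\t", index=False)


def write_track_bedgraph(track, path, noninformative_bed: str | None = None):
    """NormalizedTrack as bedGraph (scaffold, start, end, N); optionally a
    BED of noninformative windows alongside."""
    with _open_text(path, "wt") as fh:
        for p, n in zip(track.positions, track.N):
            fh.write(f"{track.scaffold}\t{p}\t{p + track.k}\t{n:.4f}\n")
    if noninformative_bed:
        with _open_text(noninformative_bed, "wt") as fh:
            for p, info in zip(track.positions, track.informative):
                if not info:
                    fh.write(f"{track.scaffold}\t{p}\t{p + track.k}\n")


def write_regions_bed(regions, path):
    with _open_text(path, "wt") as fh:
        for r in regions:
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{r.interpretation}"
                     f"\t{r.median_N:.3f}\n")


def write_clusters_bed(clusters, path):
    with _open_text(path, "wt") as fh:
        for scaffold, s, e, n in clusters.clusters:
            fh.write(f"{scaffold}\t{s}\t{e}\terror_cluster\t{n}\n")


def read_paf(path) -> list[CandidateAlignment]:
    """Candidate alignments from a PAF file (one per line)."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(CandidateAlignment(
                read_id=f[0], read_start=int(f[2]), read_end=int(f[3]),
                strand=f[4], target=f[5],
                target_start=int(f[7]), target_end=int(f[8])))
    return out


def write_paf(alignments, path, read_lengths=None, target_lengths=None):
    with _open_text(path, "wt") as fh:
        for a in alignments:
            rl = (read_lengths or {}).get(a.read_id, a.read_end)
            tl = (target_lengths or {}).get(a.target, a.target_end)
            span = a.target_end - a.target_start
            fh.write("\t".join(map(str, [
                a.read_id, rl, a.read_start, a.read_end, a.strand,
                a.target, tl, a.target_start, a.target_end,
                span, span, 255])) + "\n")


def read_sam_candidates(path) -> list[CandidateAlignment]:
    """Candidate alignments (primary, secondary, supplementary) from SAM/BAM."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            out.append(CandidateAlignment(
                read_id=rec.query_name,
                target=rec.reference_name,
                target_start=rec.reference_start,
                target_end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                read_start=rec.query_alignment_start or 0,
                read_end=rec.query_alignment_end or 0))
    return out


def write_label_map_tsv(lmap: LabelMap, path):
    with _open_text(path, "wt") as fh:
        fh.write(f"#name={lmap.name}\tlength={lmap.length}\tmotif={lmap.motif}\n")
        for i, p in enumerate(lmap.labels, start=1):
            fh.write(f"{lmap.name}\t{i}\t{p}\n")


def read_label_map_tsv(path) -> LabelMap:
    labels = []
    name = length = motif = None
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                fields = dict(kv.split("=") for kv in
                              line[1:].strip().split("\t"))
                name, length, motif = fields["name"], int(fields["length"]), \
                    fields.get("motif", "CTTAAG")
                continue
            _, _, p = line.split()
            labels.append(int(p))
    return LabelMap(name=name, length=length,
                    labels=np.array(labels, dtype=np.int64), motif=motif)


def write_placements_tsv(placements, path):
    with _open_text(path, "wt") as fh:
        fh.write("contig\tmap\torientation\tconfidence\tpairs\n")
        for p in placements:
            pairs = ";".join(f"{ci},{mi}" for ci, mi in p.pairs)
            fh.write(f"{p.contig}\t{p.map_name}\t{p.orientation}"
                     f"\t{p.confidence}\t{pairs}\n")


def read_placements_tsv(path) -> list[MapPlacement]:
    out = []
    with _open_text(path) as fh:
        header = fh.readline()
        assert header.startswith("contig")
        for line in fh:
            contig, map_name, orient, conf, pairs = line.rstrip("\n").split("\t")
            parsed = [tuple(map(int, kv.split(","))) for kv in pairs.split(";")]
            out.append(MapPlacement(contig=contig, map_name=map_name,
                                    orientation=orient, pairs=parsed,
                                    confidence=float(conf)))
    return out


def write_plan_tsv(plan, path):
    """Scaffold plan as an AGP-like TSV."""
    with _open_text(path, "wt") as fh:
        fh.write("contig\torientation\taction\tgap_before\n")
        for e in plan.entries:
            fh.write(f"{e.contig}\t{e.orientation}\t{e.action}\t{e.gap_before}\n")
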