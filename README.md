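# asmqc

k-mer based validation, curation and interpretation of *de novo* assemblies
of complex, repeat-rich genomic loci — the kind of toolkit needed when
assembling regions such as the human immunoglobulin, T-cell-receptor, HLA
and KIR loci, where high-identity segmental duplications, satellite arrays
and heterozygous structural variants defeat both aligners and standard QC.

It is aimed at people building or evaluating locus-scale consensus
assemblies from long reads plus optical maps, who need *reference-free*
answers to questions like: is this repeat assembled in the right copy
number? is this contig the alternate haplotype in disguise? which of an
aligner's fifty candidate placements of a read is the right one?

## The core statistic

For every k-mer (default k = 31) appearing in an assembly, define its
**normalized multiplicity**

```
N = M / (C × D)
```

where `M` is the multiplicity of the (canonical) k-mer in a validation read
set, `C` its copy number in the assembly, and `D` the modal multiplicity of
unique homozygous k-mers, read off the k-mer multiplicity histogram.  If
reads sample the genome uniformly, correctly assembled homozygous sequence
sits at N ≈ 1; a heterozygous deletion shows N ≈ 0.5 (reads carry only one
haplotype's copies); a collapsed duplication shows N ≈ 2 (two genomic
copies of the sequence map onto one assembly copy).

Around this sit:

- **kmerlib** — exact, quality-filtered canonical k-mer counting
  (Phred < 20 windows rejected), multiplicity histograms with peak
  detection, per-window assembly copy-number indexing;
- **validation** — N tracks with informative/noninformative flags,
  discrepant-region calling with interpretation bands, and a cluster-based
  error-rate estimator: assembly 22-mers with validation multiplicity < 5
  are erroneous and are clustered allowing at most k−1 correct k-mers
  between neighbours; clusters per Mb is the error rate;
- **haplotigs** — purge a shorter contig when > 80% of its distinct
  canonical 22-mers occur in a longer contig;
- **anchoring** — anchoring k-mers (read multiplicity in [31, 231], copy
  number exactly 1 inside the target locus, none outside) and selection of
  the candidate alignment per read that covers the most anchored reference
  bases, after dropping alignments shorter than 5 kb;
- **dotplot** — shared-k-mer dot plots (k = 50), diagonal chaining, exact
  SV sizing from breakpoint displacements, and two-strand motif scanning
  (e.g. the HSat2B signature `TTCGATTCCATTTGATGATTCCAT`);
- **scaffolding** — in-silico DLE-1 (`CTTAAG`) digestion, ordering and
  orienting contigs along an optical genome map, merging overlapping
  neighbours at shared labels, sizing gaps from inter-label distances, and
  incorporating contained contigs;
- **regions** — flank expansion with clamping, printed-table Mb lengths,
  31-mer repeat fractions, segmental-duplication overlap, within-region
  NG50;
- **simdata** — a seed-deterministic diploid simulator with planted
  heterozygous deletions, collapsed duplications, compound CNVs
  (1-vs-3-copy haplotypes), signature-bearing satellite arrays, label-motif
  lattices, shotgun reads and truth sets, so everything above is testable
  without downloading anything.

## A worked example

`examples/validate_assembly.py` simulates a 600 kb diploid genome with a
40 kb heterozygous deletion and a 25 kb collapsed duplication, then
validates the consensus assembly against 60× reads:

```
validation reads: 480000 x 150 bp; homozygous-peak multiplicity D = 96
track: 594970 windows on 'asm'
  asm:149970-190391  median N = 0.50  -> het_deletion_like
  asm:350000-375000  median N = 1.99  -> collapsed_duplication_like
planted: {'het_deletion': (150000, 190000), 'collapse': (350000, 375000)}
```

The two flagged intervals recover the planted features: the deletion is
reported at median N = 0.50 (haplotype B lacks it, so reads supply only
half the expected coverage) and the collapse at N = 1.99 (both genomic
copies pile onto the single assembled copy).  The other examples each
exercise one capability the same way: `estimate_error_rate.py` (3 planted
substitutions → 3.0 errors/Mb), `purge_haplotigs.py`,
`dotplot_sv_sizing.py` (500 bp and 1,200 bp variants sized exactly),
`scaffold_with_optical_map.py`, `region_metrics.py` and
`anchored_alignment.py`.

A thin CLI mirrors the library (`asmqc count`, `validate`, `errors`,
`purge`, `anchor`, `dotplot`, `scaffold`, `regions`, `simulate`); run
`asmqc --help` for details.

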