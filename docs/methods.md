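# Methods

## The model

A gene's pre-mRNA may be cleaved and polyadenylated inside its 5′-UTR,
releasing a short, capped, polyadenylated transcript upstream of the main ORF
(mORF). Evidence for such a site comes from 3′-end sequencing tags (PAT-seq),
but two artifacts dominate: oligo-dT priming on genomic adenine tracts
(internal priming), and short transcripts that actually terminate an upstream
gene on the same strand. The pipeline encodes the corresponding controls as
explicit, parameterized filters, and adds an evolutionary test: whether a
5′-UTR that hosts such a site arose by duplication of the mORF's own 5′ end
(exon shuffling), which predicts (a) detectable nucleotide identity between
the 5′-UTR and the mORF 5′ end, (b) uORF stop codons created by point
mutation of mORF codons, and (c) an intron at the 3′ margin of the duplicated
tract.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_pat_reads` | 3 | tags required to call a poly(A) site |
| `a_run_threshold` | 8 nt | genomic A-run that flags internal priming |
| `cluster_gap_nt` | 24 nt | max gap between co-clustered sites (microheterogeneity) |
| `three_prime_extension_nt` | 120 nt | downstream extension rescuing unannotated 3′-UTR sites |
| `a_scan_window_nt` | 10 nt | half-width of the sense-strand A-run scan window |
| upstream `max_distance` | 2000 nt | how far a same-strand upstream neighbour disqualifies a candidate |
| tail `min_tail` | 10 nt | minimum detected poly(A) tail |
| alignment thresholds | 90% cov / 95% id | for a RACE body to count as aligned |
| duplication scan | ≥ 50 columns, ≥ 40% id | to report a 5′-UTR/mORF self-alignment |
| intron margin tolerance | 30 nt | distance qualifying as "intron at the tract margin" |

The A-run scan window (±10 nt around the cleavage point, gene-sense strand) is
a design choice: internal-priming mimics arise from oligo-dT annealing at or
just downstream of the apparent cleavage point, and ±10 covers both
microheterogeneity and the annealing tract. The cleavage classifier
(3′-RACE side) scans only the 10 nt immediately downstream; both decisions
flow through one shared A-run primitive (`has_a_run`).

Coordinates are 0-based half-open internally; every report is 1-based
inclusive to match conventional genome-browser coordinates.

## Numerical and procedural choices

* **Representative PAC position**: the member site with the highest tag
  count; ties go to the most 3′-distal site in the transcription direction.
* **Multi-gene overlap**: sense-strand genes win over antisense; among sense
  genes, the one whose 5′-UTR contains the site, then the smallest distance
  to the transcription start.
* **Longest-transcript tie**: lexicographically smallest transcript id.
* **Tail trimming**: the maximal 3′ suffix starting with an A in which non-A
  positions are at least 10 nt apart ("≤ 1 non-A per 10 tail bases"). A
  global-rate reading would absorb body nucleotides adjacent to the tail;
  the windowed rule keeps the body/tail boundary sharp while tolerating
  isolated Sanger miscalls inside the homopolymer. Consequently a genomic A
  immediately 5′ of the true cleavage site is still absorbed into the tail,
  so called cleavage positions can drift a few nt 5′-ward on A-ending bodies;
  PAC confirmation uses a 24-nt tolerance and is insensitive to this.
* **Local alignment** (RACE bodies and the duplication scan): Biopython's
  `PairwiseAligner`, match +2, mismatch −3, gap open −5, gap extend −2.
  Percent identity is matched columns over *all* alignment columns, gap
  columns included; this definition is fixed and recorded with the output,
  because identity figures shift by a few points under other conventions.
* **Ranking**: descending expression, then farther upstream neighbour, then
  longer 5′-UTR, then gene id — a deterministic total order. The original
  experimental shortlist also involved manual genome-browser inspection, so a
  specific published gene list is not a reproduction target; only the hard
  exclusion rule (same-strand upstream neighbour) is reproduced.

## The synthetic world

`make_genome` builds a single chromosome of uniformly random sequence in
which ATG, stop-codon 3-mers and A/T homopolymers ≥ 5 are suppressed
everywhere except where planted. That makes the generator's promises sharp:

* the internal-priming filter has essentially zero background false-positive
  rate, so contaminant removal can be asserted at 100%;
* planted cleavage sites sit ≥ 15 nt inside their 5′-UTR exon or intron, and
  tag jitter is truncated at ±12 nt, so each planted site yields exactly one
  24-nt cluster whose representative classifies into the planted region;
* contaminant sites are 12-nt A-tracts in coding sequence: long enough to
  trigger the ≥ 8 filter and to pass the ≥ 10 tail detector when a RACE read
  runs into them, which is precisely the mimic scenario;
* per-PAC expression is drawn log-uniformly over 26–646 tags, the range
  spanned by experimentally confirmed 5′-UTR PACs.

`plant_duplication` rebuilds a host gene so its 5′-UTR carries a copy of the
mORF's first L nt with an exact substitution mask and no indels. The mask is
spread evenly (Bresenham-style) because an evenly spread mask keeps every
terminal window of the tract below 40% mismatch density, which makes the full
ungapped tract the provably optimal local alignment under the default scoring
— the scan then reports exactly 100·(1 − |mask|/L) percent identity. The
stop-creating codon edits (TAC→TAA, TGA→TAA, single-nucleotide changes) are
counted inside the mask so the identity bookkeeping stays exact. The 12
spliced-UTR bases after the tract are C's while the 12 mORF bases after the
tract are G's, so the alignment cannot creep past the boundary even via gaps.
On the rare random tract where a gapped detour still outscores the planted
register, the generator re-draws the tract (construct-and-verify,
deterministic per seed).

What the generator does **not** emulate: real *Arabidopsis* base composition,
codon usage, splice-site strength, transcript-level splicing of RACE reads
(bodies are genomic-sense, matching the genomic locus they are aligned to),
sequencing quality values, or indel errors. A green recovery test therefore
establishes the correctness of the pipeline's logic and thresholds, not its
performance on real, messier libraries.

Substitution-rate recovery is exercised at 10–31% divergence. At 50%
divergence the planted register has negative score density under the declared
scoring (2·0.5 − 3·0.5 < 0), so no local aligner can return the full tract
there; that regime is outside the scan's detectability limit by construction
and is documented rather than tested.

## Known limitations

* GFF3 support covers the common gene/mRNA/exon/CDS dialect (UTRs are derived
  from exons minus CDS); exotic dialects may need pre-normalisation.
* Reads are validated against a per-read target locus; genome-wide multi-locus
  placement (e.g. a pseudogene sharing the duplicated tract) is reported as
  unaligned/ambiguous rather than guessed.
* The duplication scan reports its own best local interval; figure-embedded
  interval endpoints from any particular study are not reproduced exactly, and
  identity values are tied to the declared scoring scheme.
* Organellar chromosomes are excluded by name (`ChrM`, `ChrC`, configurable),
  not by content.
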