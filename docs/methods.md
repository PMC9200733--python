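# Methods

## Scope and model of the problem

`mitoqc` treats a mitogenome assembly as a circular sequence whose identity
is invariant under rotation and strand choice. All quality-control questions
are posed as comparisons between two assemblies of the same molecule (a
draft versus a polished/short-read reference, or a simulated truth versus a
corrupted copy): which bases differ, how the differences distribute over
error types and homopolymer context, what sequence exists in only one
assembly, and whether the annotated gene order is rearranged.

## Circular normalization

`canonical_rotation` brings a circular sequence to a reproducible form.
With an anchor (by convention the start of cox1 when an annotation is
available), the sequence is rotated so the anchor begins at position 0 on
the plus strand; the anchor is searched on both strands with a configurable
mismatch allowance (default 0). Without an anchor the canonical form is the
minimum over all 2L rotations of both strands, computed with Booth's
algorithm per strand and a final comparison between the two strand minima.
(Choosing the strand first by comparing the unrotated strings, then rotating,
can miss the global minimum — e.g. `CAAT` versus its reverse complement
`ATTG`: the smaller unrotated string is `ATTG`, but the overall minimal
rotation `AATC` lives on the forward strand.) The applied rotation and flip
are recorded on the sequence so normalization is exactly invertible.

## Difference calling

`align_assemblies` compares two assemblies natively:

1. **Anchors.** k-mers (default k = 15) unique in both sequences, paired by
   identity.
2. **Circular pre-rotation.** If both inputs are circular, candidate query
   rotations are derived from the (ref − query) position offsets of shared
   anchors; the rotation retained is the one maximizing the colinear anchor
   chain, with no rotation preferred on ties. This is equivalent to matching
   against a logically doubled reference and reducing positions modulo the
   length, but is robust to the two situations that fool a plain modal-offset
   vote: small cumulative indel drift, and a large insertion that splits the
   offset votes without breaking colinearity.
3. **Chaining.** Longest increasing subsequence over anchor pairs; ties are
   broken toward the leftmost reference coordinate for determinism.
   Overlapping consecutive anchors on the same diagonal extend the running
   match; off-diagonal overlaps are dropped and resolved by gap closure.
4. **Gap closure.** Inter-anchor gaps are aligned globally with edlib.
   A gap whose length difference exceeds 2,500 bp is not force-aligned; both
   sides are reported as unaligned segments. Within an alignment, indel runs
   of at least `segment_min` bp (default 200, below typical tRNA size and
   above alignment-gap noise) are likewise emitted as unaligned segments
   rather than difference records, so multi-kilobase technology-specific
   sequence surfaces as structure, not as base error.
5. **Classification.** Substitutions are recorded per base (matching the
   granularity of cs `*rq` tokens); insertions and deletions are merged per
   run. All indels are left-normalized — shifted to the lowest equivalent
   reference coordinate — which makes counts comparable between the native
   aligner and external aligners. Left-normalization is idempotent.

`differences_from_paf` derives the same record stream from a minimap2
(`-x asm5 --cs`) PAF: the cs token walk is validated base-by-base against the
reference and against the alignment's stated coordinates, and the resulting
records pass through the same segment-threshold and left-normalization
logic, so the two routes agree record-for-record on well-separated events
(verified in tests on randomized pairs). Minus-strand alignments are
rejected with a hint to normalize both assemblies first; this keeps the
record semantics unambiguous.

Replaying a difference stream onto the reference reproduces the query
byte-exactly, and `invert_records` re-expresses a stream in query
coordinates so the corrupted copy can be walked back to the original — both
used as oracles in the test suite.

## Error profiling

A difference record's homopolymer context is the maximal identical-base run
containing a substituted base, or adjacent to an indel whose base equals the
run base (an indel lengthens or shortens that run); records with no matching
run get run length 1. A record is *in* a homopolymer when its run length is
at least `min_run` = 3: runs of 2 cover roughly a third of random sequence
and would make the statistic uninformative. The threshold is exposed because
published analyses rarely state their definition.

The profile reports: counts by type label (`+A`, `-T`, `*CT`, ...); the
fraction of errors that are single-base indels (size exactly 1); the
fraction of all errors that are single T or A indels; the fraction in
homopolymers; a single-base-indel count by run length and base; and the
consensus quality `QV = -10*log10(n/L)` with spacing `L/n = 10^(QV/10)`.
Fractions always use all records as denominator; a separate plotting view
drops labels with fewer than 3 occurrences. With zero differences the QV is
capped at `-10*log10(1/L)` and flagged as a lower bound, mirroring standard
consensus-QV practice and avoiding infinities. `compare_before_after`
counts modified sites between a draft and its polished version (one per
record regardless of size) and refuses circular inputs that have not been
normalized to a shared rotation/strand, since positional comparison is
meaningless otherwise.

## Composition, segments, annotation, gene order

* **Windows.** AT fraction is (A+T)/(A+C+G+T) per window — ambiguity codes
  excluded from numerator and denominator so unknown bases do not bias
  extreme-composition estimates. The final partial window is kept and
  flagged.
* **Unique segments.** Unaligned segments at or above `min_length`
  (default 200 bp) are reported with owner, AT fraction (read across the
  circular origin when needed) and nearest flanking annotated genes.
* **N50.** Largest length such that reads at least that long contain half
  the bases (descending cumulative sum), verified against an exhaustive
  oracle.
* **Completeness.** Compared against the canonical metazoan complement of
  13 PCGs, 2 rRNAs and 22 tRNAs; leucine and serine expect two isoacceptor
  copies each, and `trnL`/`trnL1`/`trnL2` labels are interchangeable within
  the pool. Missing, duplicated (with copy counts) and unrecognized names
  are listed.
* **Premature stops.** CDS translated in frame 0 under a configurable NCBI
  code table (default 5, invertebrate mitochondrial, where TGA is Trp);
  internal stops are those strictly before the final codon, and a terminal
  stop codon does not count against the longest-ORF fraction. The default is
  configurable because gastropod datasets span lineages.
* **Control region length.** The plus-strand circular gap from the annotated
  end of tRNA-Phe to the start of cox3 — the usual location of the major
  non-coding region in gastropod mitogenomes; intergenic spacers within that
  gap are counted as part of it.
* **Gene order.** Orders are signed circular permutations (sign = strand)
  reduced to shared gene names. Adjacencies are unordered pairs of facing
  gene extremities (head/tail), making breakpoint counts invariant under
  rotation and full reflection of either order; breakpoints are adjacencies
  of one order absent from the other. Inverted blocks are maximal runs of
  consecutive genes appearing consecutively in the other order reversed and
  strand-flipped.

## Synthetic data generator

The generator emulates the study system so that every stage can be tested
against exact truth, with defaults fixed at realistic values:

* **Genome.** 16 kb (configurable), background AT 0.66 — inside the 61.8 to
  69.5% range of real gastropod assemblies — with a 37-gene template in a
  caenogastropod-like order and a control region (default 1 kb, AT 0.987)
  between tRNA-Phe and cox3, annotated as class `other`. Protein-coding
  genes are emitted as stop-free in-frame CDS under code table 5
  (reverse-complemented onto the genome for minus-strand genes); tRNA/rRNA
  and intergenic sequence are i.i.d. composition draws. Non-coding sequence
  is run-length enriched by a copy-previous-base process with probability
  `h/(1+h)` (default h = 0.3), which lengthens homopolymer runs while
  leaving the stationary composition unchanged; coding sequence is not
  enriched so the stop-free guarantee holds.
* **Errors.** Per-position Bernoulli events: substitution at a flat rate
  (default 8e-4) or a single-base indel at `base_indel_rate *
  multiplier^(min(run,len_sat)-1)` (defaults 2e-3, multiplier 1.3,
  saturation at run length 8). The multiplicative growth reproduces the
  positive indel-versus-run-length trend of nanopore consensus errors; the
  saturation reflects that per-base miscount probability cannot grow
  unboundedly — without it, the ~20 bp AT runs that a 98.7%-AT control
  region occasionally produces would push the scaled probability past 1.
  Rates that still exceed 1 after saturation are a configuration error
  naming the offending run length. Indels duplicate or drop the resident
  base, as basecalling errors do, which on a 66%-AT genome makes single T/A
  indels about half of all errors. At most one event lands per homopolymer
  run, keeping the truth list exactly replayable after left-normalization
  (at realistic rates such collisions are rare, so event counts remain
  binomial to good approximation). The defaults yield QV ~ 24 drafts with
  roughly three-quarters single-base indels.
* **Coverage.** Per-window expected depth is flat for the long-read model;
  the short-read model multiplies expected depth by `at_suppression`
  (default 0.05) in windows whose AT fraction exceeds `at_threshold`
  (default 0.85). Noise is gamma-distributed with variance
  `dispersion * mean^2` (default dispersion 0.05); zero dispersion returns
  expectations exactly.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: read-level artifacts (chimeras, adapter
sequence, coverage waves from read-length structure), basecaller-specific
error confusion matrices, systematic strand asymmetries, and true
replication-origin structure inside the control region (which is modeled as
composition only). Under the defaults roughly 40–50% of injected errors sit
in homopolymer runs of 3 or more; pushing this to the ~70% seen in real
nanopore data would require enrichment so strong that the T/A and
single-indel fractions leave their observed ranges, so the model matches
those two statistics exactly and the homopolymer concentration only
qualitatively. Conclusions from simulation are therefore about the
*pipeline's* correctness (recovery of known truth), not about absolute
real-world error rates.

## Numerical and design choices

* Internal coordinates are uniformly 0-based half-open; files keep native
  conventions (PAF/BED 0-based half-open, the package's annotation table
  1-based inclusive). Circularity travels in the FASTA header
  (`circular=true`) to keep fixtures single-file.
* All stochastic operations take explicit integer seeds; there is no global
  RNG state, and fixed seeds give bit-identical outputs.
* Chaining and block-merge tie-breaks are deterministic (leftmost reference
  coordinate).
* Degenerate alignments fail loudly and distinguishably: empty input or a
  length ratio beyond 3 is reported as degenerate; zero shared unique
  k-mers as insufficient homology.
* Analysis drivers under `analysis/` use a six-sample panel spanning
  14–18 kb and 62–70% AT; test and acceptance runs use 16 kb genomes and
  20-replicate batches, sizes at which every statistic of interest is
  already stable.

## Known limitations

* The native aligner is designed for near-identical assemblies of the same
  molecule (the QC setting); it is not a general-purpose genome aligner and
  refuses length ratios beyond 3.
* Record-for-record equality between the native and external-aligner routes
  holds for events separated by at least ~10 bp; clustered events can be
  re-expressed differently by different optimal alignments (both
  reconstruct the same query).
* Events cut by the circular origin under automatic rotation detection may
  be re-expressed at the opposite end; comparisons requiring strict record
  equality should normalize both assemblies with a shared anchor first.
* Gene-order comparison requires unique shared gene names; duplicated genes
  make a circular order ambiguous and are rejected.
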