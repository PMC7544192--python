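# Methods

## Scope and model

`plasmidqc` verifies small circular plasmids (the design regime is
2.5–3.3 kb, the scale of common expression and cloning vectors) from
Illumina paired-end reads, without requiring a reference. The pipeline is
filter → coverage cap → de Bruijn assembly → read back-mapping. Its two
scientific claims are (a) that strict quality filtering plus a coverage
cap makes single-contig circular assembly of clean plasmid libraries
essentially deterministic, and (b) that the fraction of distinct
high-quality reads failing exact back-mapping to the assembly separates
contaminated from clean libraries even when the contaminant differs by a
single SNP.

## Circular-sequence primitives

Assemblies of circular molecules have arbitrary start and strand, so all
sequence comparison is performed on a canonical form: the
lexicographically least string over all rotations of the sequence and of
its reverse complement, computed with Booth's least-rotation algorithm
(O(n)). Two circular sequences are equal iff their canonical forms are
equal. When a tie occurs between a rotation of the forward and of the
reverse strand the shared string is returned; no strand flag is kept,
because only equality semantics are needed. Sequences containing N are
rejected from canonicalization (no ambiguity logic anywhere in the
pipeline); reads containing N simply never match. Exact read matching
against a circular contig searches the contig extended by its first
(read length − 1) bases, so origin-spanning reads count.

## Read filtering and coverage capping

Filtering is whole-read, pair-gated: a pair survives iff both mates have
arithmetic mean Phred ≥ `min_mean_q` (default 36, the floor of the
quality range observed for strictly filtered libraries in this regime)
and length ≥ `min_len` (default 125 nt). No trimming is performed — the
contract is a high-quality read *subset*, and gating whole pairs keeps R1
and R2 synchronized. An alternative top-fraction mode keeps the best
⌈fraction·n⌉ pairs ranked by the weaker mate's mean quality. After
filtering, nominal coverage (n·2·mean read length / plasmid length
estimate) above `target_coverage` (default 500×, the point beyond which
deep-coverage pathologies appear in de novo assembly) is reduced by
uniform pair subsampling; the empirically favorable band of roughly
113–1030× is exposed as `OPTIMAL_COVERAGE_BAND` for diagnostics rather
than enforced.

## Assembler

A single fixed k (default 31, odd so no k-mer is its own reverse
complement) is used instead of a multi-k scheme: at capped coverage and
plasmid scale, one k suffices and keeps behavior fully analyzable. k-mers
are packed two bits per base into int64 (hence k ≤ 31) and counted on the
canonical strand; the extraction loop is numba-compiled. Counts below
`min_kmer_count` (default 3) are discarded — at ~300–400× k-mer depth
this removes the overwhelming majority of error k-mers while never
touching real sequence.

Graph cleaning iterates to a fixed point (bounded at 10 rounds):

* **Tips**: dead-end unitigs of ≤ `tip_len_max` k-mers (default 2k)
  attached at exactly one end are removed. Isolated short paths are kept;
  they are either the entire signal or fall to the component filter.
* **Bubbles**: two parallel unitigs sharing both flanking anchor k-mers
  are resolved by deleting the lower-mean-depth arm (ties: keep the
  lexicographically smaller arm). Arms of very different lengths are
  allowed — an indel between the primary plasmid and a minority
  contaminant is exactly such a bubble (a 608 bp arm vs a short junction
  arm), and a SNP is the equal-length special case. This is what makes
  the assembler reproduce the majority haplotype under SNP/indel
  contamination.
* **Shallow components**: after cleaning, any connected component whose
  median k-mer depth is below `rel_depth_floor` (default 0.25) times the
  median depth of the deepest component is dropped. A minority unrelated
  contaminant forms its own component at depth ratio f/(1−f)
  (≈0.11 at 10% spiking), well under the floor; at 33%+ spiking the ratio
  crosses 0.25 and the library correctly presents as fragmented. The
  0.25 default is chosen to sit between those regimes.

A component in which every k-mer has exactly one predecessor and one
successor is a simple cycle: it is emitted as a circular contig of one
base per k-mer (the redundant k−1 overlap removed) in canonical rotation.
Everything else is emitted as linear unitigs. Contigs are sorted by
length then sequence; all traversal and tie-breaking is ordered, so
assembly output is byte-identical across runs. Paired-end information is
not used for scaffolding — a deliberate simplification that fails only on
repeats longer than k, which is also where short-read plasmid assembly
fails generally (documented limitation).

## Contamination statistic and calibration

The detector deduplicates the filtered reads to distinct literal strings
(each mate separately; a read and its reverse complement are distinct
strings, since matching itself checks both strands) and counts how many
occur exactly in any contig. Even clean libraries have a nonzero baseline
— a read with any sequencing error fails exact matching, so the baseline
is ≈ the per-read error probability, inflated somewhat by deduplication
(error-free reads collapse onto at most one string per start position,
erroneous reads rarely collapse). Contaminant reads that overlap a
variant position fail additionally, so the statistic grows with
contamination fraction and variant density.

The mapping from mismatch percentage to a contamination probability is a
maximum-likelihood logistic fit on that single feature, with the slope
bounded below by zero (more mismatches can never mean less
contamination) and a 1e-4 ridge term so perfect separation stays finite;
the fit is a bounded L-BFGS-B optimization and fully deterministic. The
packaged default model (`src/plasmidqc/data/default_calibration.json`)
is trained by `scripts/train_default_calibration.py` on 40 clean and 40
contaminated simulated libraries (1–4-SNP contaminants at 20% spiking,
fixed seed); it is only valid for error regimes resembling the
simulation defaults, and `plasmidqc calibrate` retrains it for others.
ROC AUC is computed as the Mann–Whitney rank statistic (ties = ½).

## Synthetic data: what it does and does not emulate

The generator reproduces the validation regime: uniform-random circular
plasmids of 2521–3294 bp, FR paired 150 nt reads with uniform circular
fragment starts and Gaussian insert length (300 ± 30), per-pair
good/bad quality classes (means Q38/Q20, 30% bad by default, sd 3 per
base) emulating the broad observed per-read quality distribution, and
substitution errors at max(base_error_rate, 10^(−q/10)) per base with
`base_error_rate = 0` acting as a strict error-free switch. Contaminant
libraries use the same error model and are spiked at an exact pair
fraction (round-half-even, capped at 50%), with provenance labels
preserved for scoring.

Not emulated: read-length heterogeneity within a library (real runs had
35–251 nt reads; we simulate fixed-length), indel sequencing errors,
adapter read-through, PCR/optical duplicates, position-dependent quality
decay, and GC-coverage bias. Consequently, passing simulations
demonstrate the pipeline's algorithmic behavior under the stated
abstractions, not performance on every real library; in particular the
clean mismatch baseline here (~19–21%) differs from baselines on real
data, which is why the calibration is retrainable and the statistic is
always reported alongside the probability.

## Problem sizes used in validation

The replicate experiments run 100 replicates per contamination condition
(clean; 1-, 2-, 4-SNP at 20–35%; 608 bp deletion at 10%; unrelated at
10%) at ~500× raw coverage capped to ≤500× post-filter, and 100
libraries per class for the detector AUC — a deliberate desk-scale twin
of the original 500-replicate design, sized so the whole validation runs
in minutes on one CPU while keeping binomial noise on any percentage
below ~5 points.

## Known limitations

* Repeats ≥ k collapse in the graph; such plasmids assemble fragmented.
  A paired-end or multi-k extension is the natural fix and is out of
  scope.
* Near-50% contamination by a SNP variant is fundamentally ambiguous at
  the graph level: bubble arms have equal depth and the assembler picks
  one haplotype per bubble, possibly producing a chimera (reported as a
  mismatching assembly, never silently as correct).
* The component depth filter assumes a dominant primary; at spiking
  fractions near `rel_depth_floor`/(1+`rel_depth_floor`) its behavior
  switches from suppression to fragmentation within a few percent.
* Contamination probabilities are only as good as the calibration
  regime; the default model is simulation-trained and should be
  retrained for real instrument/chemistry combinations.
* The detector reports *that* a library looks contaminated, not which
  contaminant is present.
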