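# Methods

This note documents the models and procedures implemented in `soilvirome`,
their assumptions, the tunable parameters that matter, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The analysis problem

Soil harbors a large, mostly uncharacterized virosphere. Metagenomes yield
assembled viral sequences but say nothing about activity; mapping
metatranscriptome reads (and metaproteome peptides) onto a curated viral
sequence catalog reveals which viruses are transcribed and translated and how
activity shifts between environmental conditions — here, a wet/dry soil
moisture contrast with a few replicate samples per condition and site. The
package implements the computational chain around that idea. External tools
(assemblers, read mappers, VirSorter/VirFinder, hmmsearch, BLAST, spectral
search engines) are deliberately out of scope: their outputs are consumed as
tables, and the package owns the integration, filtering, quantification and
inference logic.

## Ensemble viral identification (`viral_screen`)

A contig is viral iff `length > 2500` (strict) and at least `min_criteria =
3` of four criteria hold. Criterion 1 counts gene origins: each gene's
origin is the channel class (viral: viral-HMM, viral-Pfam, NCVOG; cellular:
bacterial, archaeal) holding its maximum bit score, and the criterion
requires strictly more viral than cellular genes (unassigned genes are
ignored; zero genes fail the strict inequality). Criteria 2–4 threshold
external channel values: VirSorter category ∈ {1, 2, 3}; IMG/VR E ≤ 1.0e−5
(boundary inclusive); VirFinder p < 0.05 together with score > 0.90 (both
strict).

Open choices and their resolutions:

* A bit-score tie between a viral and a cellular channel resolves to
  cellular — conservative viral calling; the source procedure does not
  specify tie handling.
* A missing external channel makes that criterion false rather than
  excluding the contig, because the integration rule is defined over four
  fixed criteria.

Auxiliary metabolic genes (AMGs) are flagged on viral contigs when a gene
carries a metabolic annotation at E ≤ 1e−5 and viral-origin genes exist both
strictly before and strictly after it in genome order.

## Catalog: dereplication and clustering (`catalog`)

`dereplicate` removes exact duplicates and substrings on the forward strand
(case-insensitive), retaining the longest representative (ties: smallest
id); it is idempotent. `pairwise_aai` aligns every cross-pair of proteins
locally under BLOSUM62 (gap open −11 / extend −1), keeps reciprocal best
hits with ≥ 20 aligned columns and ≥ 20% identity (enveomics-style defaults;
the source names the script but not its parameters), and averages percent
identity — computed over all aligned columns including internal gaps — across
RBH pairs. `single_linkage` clusters at AAI ≥ 70 via connected components,
with cluster ids named by the smallest member id for determinism.

Tetranucleotide z-scores use the maximal-order Markov expectation
`E(w) = O(abc)·O(bcd)/O(bc)` with variance
`E·(1 − O(abc)/O(bc))·(1 − O(bcd)/O(bc))`; counts pool both strands and skip
windows containing N; undefined components (zero variance or zero context
count) are set to z = 0. On i.i.d. sequence this standardization is
approximate — palindromic 4-mers are counted twice with perfectly correlated
strand contributions, inflating the overall z SD a few percent — which the
acceptance band (SD 1 ± 0.1) accommodates.

`rescue_assign` is threshold-free (argmax correlation, ties to the smallest
cluster id) as a primitive. At the pipeline level, rescue of singletons into
multi-member clusters is additionally gated at a minimum correlation
(default 0.9): without a gate, every singleton would merge somewhere and the
catalog could never retain genuinely unrelated singletons.

## Transcriptional activity (`activity`)

Identity is defined over aligned read bases (CIGAR M/=/X) as
`(aligned − NM)/aligned`; the aligned fraction is `aligned/read_length`
(soft clips count toward read length only). Both filter cutoffs
(identity > 0.95, fraction > 0.80) are strict. Records lacking an NM tag are
flagged at parse time and rejected with an explicit reason, never silently
scored. Deletions consume reference depth; insertions do not.

Average base coverage is `sum(depth)/contig_length`, an exact integer
identity against the total aligned reference bases of retained records.
Normalized activity divides average coverage by total sample reads in
millions. The phrase "normalized by total counts of reads per sample and the
length of the contigs" is ambiguous about whether length is applied once or
twice, since average coverage is already length-normalized; the default
applies length once (per-million scaling of average coverage), and
`length_norm_twice=True` exposes the alternative reading.

A contig counts as "transcribed" in a sample with ≥ 1 retained alignment (no
minimum read threshold is imposed). Coding/noncoding partition assigns each
read by majority of its aligned reference bases over gene intervals, ties to
coding. Marker (integrase/excisionase) counts are per million total reads
after the same filter; note that because the normalization uses each
sample's own total, a planted k-fold marker contrast is recovered exactly
only when marker reads are a small fraction of the library.

## Host linkage (`host_link`)

CRISPR arrays are found by exact-word seeding (23-mers, the minimum repeat
length) chained at array-compatible periods, requiring ≥ 3 identical repeat
copies, then extending the repeat rightward while all copies agree and
spacers stay ≥ 26 nt. Because maximal extension is ambiguous when the bases
after every repeat copy coincide, a detected spacer can be a trimmed
substring of the planted one; exact substring matching against viral contigs
(both strands) is unaffected. Spacer matching is exact — the source reports
exact spacer matches — and strand-agnostic.

Similarity channels qualify at E ≤ 1e−3 and bit score ≥ 50; the
reference-virus channel adopts the host of the single best hit (highest bit
score, then lowest E, then smallest id). Both apply only to contigs the
spacer method left unassigned (nested workflow).

Markov models are homogeneous order-k chains (default k = 2 at desk scale;
4^k contexts must be trainable from a single genome — the published
alignment-free host predictors use higher orders on full genome corpora),
trained on both strands with add-one pseudocounts. Contigs are scored by
mean per-nucleotide log-likelihood computed circularly (the context wraps at
the end), which makes the score exactly invariant under self-concatenation;
the linear/circular difference is O(k/L). Consensus requires agreement
between a nested-workflow pairing and the Markov prediction at the phylum
rank — the reporting rank of the source analysis; the agreement rank is not
stated there and is exposed as a choice. A contig may retain several
consensus hosts.

## RNA virus screening (`rna_screen`)

Profile HMMs are approximated by ungapped position-specific score matrices:
the synthetic generator plants exact consensus motifs, and the contract is a
motif-profile detection route, not full profile-HMM semantics. Two numerical
points matter:

* **Composition correction.** A window's raw score is reduced by the score
  expected under the window's own residue composition (mean of matrix column
  sums over the window's residues). Without this, low-complexity translated
  regions — which Markov-generated host fragments produce readily — reach
  spuriously high scores that no uniform-residue null can calibrate away.
* **Scan-scale null.** Thresholds are the 99.9th percentile of best-window
  scores of 2000-residue random peptides, not single-window scores, because
  classification takes a maximum over every window of every ORF of a contig;
  calibrating at the scan scale keeps the per-contig false-call rate at the
  nominal tail.

The reference route accepts the best hit at E ≤ 1e−5 and adopts its taxon.
Per-taxon abundance is the mean average-base-coverage over member contigs
(absent, not zero, for memberless taxa), reported alongside log10(x + 1);
the log base and offset are conventions chosen here.

## Peptide filtering (`proteo_filter`)

FDR is #decoy/#target among records passing both cutoffs (scores are
MSGF-style spectral probabilities, lower better; ppm errors absolute). An
undefined FDR (no passing target) is an explicit sentinel, never 0. The
optimizer grid-searches observed (score, ppm) values for the pair maximizing
passing targets subject to FDR < 5%, ties toward stricter cutoffs. The raw
FDR is not monotone along a score sweep (admitting a target lowers the
ratio), so `fdr_sweep` also reports standard monotonized q-values (running
minimum over equal-or-looser cuts). Peptide identity for viral-specificity
exclusion strips modification annotations and collapses I/L; FDR is
optimized per dataset. The simplest estimator (#decoy/#target rather than
2·decoy/(target+decoy)) is used; the source does not specify one.

## Statistics (`stats`)

`t_test` is Welch's two-sample test (two-sided, Welch–Satterthwaite df);
unequal variances across moisture treatments are plausible and the source
does not specify the variant. Two calibration facts, both computed by the
acceptance suite: under the heteroscedastic null the correction targets
(n = 3 vs 3, variance ratio 9) the empirical size is within 0.05 ± 0.01;
under an equal-variance null at n = 3 the Welch test is conservative
(size ≈ 0.035) — a known small-sample property, not an implementation
artifact.

`differential` is a documented simplification of count-model differential
expression: ε-offset log2 fold change (ε = smallest positive matrix value /
10) with Welch p-values on the normalized values, and both raw (p < α) and
Benjamini–Hochberg-adjusted significance flags; the negative-binomial
shrinkage model of DESeq2-style tools is deliberately not re-implemented,
and the output metadata says so. All-zero entities are excluded as absent.

## The synthetic community (`synthetic_data`)

The generator emits a stated world, not a tuning knob: per-host order-2
Markov chains with Dirichlet(1)-distributed transition rows (compositionally
distinct, hence learnable by the Markov host predictor); viral contigs drawn
from their true host's chain (emulating compositional amelioration);
prophages planted verbatim into host genomes for a lysogenic subset; CRISPR
arrays with ≥ 3 repeat copies (repeats 23–47 nt) whose spacers copy 26–50 nt
of a target virus of the same host, reverse-complemented with probability
0.5; condition-dependent expression (default depth 2×, two-fold activation
of a wet-active and a dry-active subset); RdRP-bearing RNA contigs with
planted consensus ORFs; and two-component target/decoy PSM score tables
(log-normal spectral probabilities, 10^−12 vs 10^−5 centers).

Reads are emitted with truth-based alignments — no aligner is implemented,
since the in-scope computation is alignment filtering, not mapping — with
uniform start positions, Poisson per-contig counts proportional to planted
depth, and binomial per-base substitution errors recorded exactly in the NM
tag. Not emulated: realistic error profiles, quality strings, insert-size
models, chimeras, strand-specific library artifacts. A green test therefore
establishes the correctness of the filtering/quantification logic on
well-formed alignments with exact truth labels, not robustness to mapper
idiosyncrasies or real soil community structure.

Two acceptance-level constants were fixed once: the "low noise" level of the
differential-recovery simulation is 3% CV multiplicative noise (at
n = 3/condition the planted four-fold effect then clears the BH threshold
reliably; at 5% CV recovery is marginal), and the lysogeny-marker contrast
uses library totals of 10⁶ with marker depths 4 vs 80 so the planted 20-fold
ratio is estimated from hundreds of reads against a fixed denominator.

## Known limitations

* AAI is computed by exhaustive pairwise local alignment; fine for catalog
  sizes in the hundreds, not for hundreds of thousands of contigs.
* The PSSM route cannot detect divergent motifs that a profile HMM with
  indel states would; the reference route is the only fallback.
* The Markov host predictor assigns every contig a top host; only the
  consensus requirement keeps precision high.
* `differential` on per-million activity values is not a count model; very
  low-count entities inherit the usual instability of ratio statistics.
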