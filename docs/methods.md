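# Methods

`lincscout` reimplements a genome-wide long intergenic non-coding RNA
(lincRNA) discovery workflow of the kind used for the diamondback moth
(*Plutella xylostella*): candidate transcript models assembled from
RNA-seq are filtered down to a lincRNA catalog, quantified as RPKM,
tested for differential expression between insecticide-susceptible and
insecticide-resistant libraries with a weighted count-proportion test,
and characterized (GC content, scaffold distribution, neighboring genes,
embedded pre-miRNAs, term enrichment). Because the original raw
sequencing libraries and the commercial assembler are outside the scope
of a reusable package, every stage is exercised against a synthetic
genome and count simulator with planted ground truth.

## The identification cascade

A transcript is a lincRNA candidate when it is longer than 200 nt,
intergenic, and has no open reading frame above 100 amino acids. The
cascade applies, in order:

1. **Known-gene overlap.** A candidate is removed iff any of its exons
   overlaps (>= 1 bp) the *span* of a protein-coding gene — exons and
   introns both count, on either strand. Strand-agnostic overlap is the
   conservative reading for the intergenic class: it also excludes
   antisense-overlapping transcripts.
2. **Distance.** Survivors must lie strictly more than 1 kb (gap between
   half-open spans) from every protein-coding gene span on their
   scaffold. Gene spans, not exons, are used, matching the "away from
   any known transcript" notion.
3. **ORF length.** The longest ORF over all six frames must not exceed
   100 aa. An ORF starts at ATG and ends at the first in-frame stop
   (TAA/TAG/TGA); an ORF still open at the sequence end counts with its
   current length — conservative toward discarding coding fragments.
   `aa_length` counts codons from the ATG (Met included, stop excluded).
   Ties between equally long ORFs are broken by frame order
   (+1,+2,+3,-1,-2,-3), then by smaller start offset, for determinism.
4. **Coding potential.** A logistic regression on four sequence features
   — ORF size (nt), ORF coverage (ORF size / transcript length), the
   Fickett TESTCODE statistic, and hexamer usage bias — assigns each
   candidate a coding probability; candidates at or above 0.3 are
   discarded as putative coding. The boundary is inclusive on the coding
   side ("threshold of 0.3" read as at-or-above).
5. **Expression.** A candidate must have strictly more than 10 mapped
   reads in at least 3 of the (by default 8) libraries. The rule applies
   to raw counts, not RPKM, because it is a read-presence criterion.
6. **Collapse.** Candidates with identical spliced sequences collapse to
   one (lexicographically smallest id); candidates whose genomic spans
   overlap on the same scaffold collapse component-wise to the longest
   (ties to the smallest id). The operation is idempotent.

External-evidence stages of the published workflow — Pfam domain search,
BLASTx against protein databases, and the CPC SVM (score above −1 called
coding) — require external databases and are deliberately not executed;
they are recorded as skipped stages in the `StageReport` schema so the
cascade's provenance stays explicit.

### Fickett TESTCODE

For each base B the statistic combines a position parameter
`max(c0,c1,c2)/(min(c0,c1,c2)+1)` (codon-phase asymmetry) and a content
parameter (base fraction) through the published Fickett (1982) lookup
tables and weights. It is computed on the full transcript sequence;
ambiguous bases are excluded. Typical values run from ~0.2 (noncoding)
to ~1.1 (strongly coding).

### Hexamer usage bias

Two hexamer frequency tables are trained: in-frame (step 3, phase 0)
counts over coding ORF-containing sequences, and sliding (step 1) counts
over noncoding sequences, each with additive pseudocount 1 and
normalized over the 4096 hexamers. A transcript's score is the mean of
`log(f_coding(h)/f_noncoding(h))` over the in-frame hexamers of its
longest ORF (full sequence if there is no usable ORF). Positive means
coding-like.

### The classifier

Features are standardized internally and fit by maximum-likelihood
logistic regression (a ridge penalty of 1e-6 scale keeps perfectly
separated training sets finite; the fit is deterministic). Training
needs at least 20 examples per class; the model serializes to JSON.

## Expression and differential expression

**RPKM** is `1e9 * C / (N * L)` with C the transcript's read count in a
library, N the library's total mapped reads, and L the transcript length
in bp. The formula is exact per cell and invariant to jointly scaling a
library's counts and total.

**The count test** follows the weighted beta-binomial construction of
Baggerly et al. (2003) for two groups of libraries. Per library the
proportion `p_i = x_i/n_i` has variance `p(1-p)(1/n_i + phi)` under
binomial sampling around a beta-distributed group proportion with
between-library overdispersion `phi`. A single `phi` is estimated by the
method of moments pooled over both groups' size-weighted residuals and
floored at 0 (at the floor the weights reduce to `w_i ~ n_i`, i.e. the
pooled proportion). Each group proportion is the weight-optimal estimate
`p_hat = sum(w_i p_i)/sum(w_i)` with `w_i = n_i/(1 + phi n_i)` and
variance `p_hat(1-p_hat)/sum(w_i)`; the statistic
`t = (p_A - p_B)/sqrt(V_A + V_B)` is referred to a t distribution with
Welch–Satterthwaite degrees of freedom (component df `K_g - 1`, floored
at 1 overall). Single-library groups use pure binomial variance.

Pooling the overdispersion across groups (rather than estimating it
independently per group) is the package's choice: with four libraries a
group, independent estimates make the Satterthwaite df so noisy that the
test becomes conservative; the pooled estimate keeps the null
type-I error near nominal (empirically 0.04–0.05 at alpha 0.05 under the
simulator's default conditions) while leaving the construction otherwise
unchanged. In the vanishing-dispersion limit the statistic reduces
exactly to the classical unpooled two-proportion z on pooled counts.

**The DE call** for a contrast (reference group A, e.g. susceptible, vs
group B, e.g. resistant) requires all of: fold change strictly above 4,
where `fc = (mean RPKM_B + 0.1)/(mean RPKM_A + 0.1)` and the threshold
applies to `max(fc, 1/fc)`; raw p-value below 0.05; and at least 10
reads in at least one library of either group. "Up" means higher in
group B. No multiple-testing correction enters the call — the published
criteria filter on the raw p — but a Benjamini–Hochberg q-value over the
tested set is attached for information. The pseudocount 0.1 bounds fold
changes at low expression; the fold-change denominator is a design
choice exposed as a parameter since the source workflow does not define
it.

## Characterization

- **GC content**: `(G+C)/(A+C+G+T)` per sequence, ambiguity codes
  excluded; all-ambiguous sequences are reported missing.
- **Scaffold summaries**: per-scaffold gene and lincRNA counts with
  length statistics; the gene-vs-lincRNA count relation is summarized by
  OLS with `r_squared` the squared Pearson correlation and the slope
  t-test p-value. A packaged survey table
  (`data/px_lincrna_scaffold_survey.tsv`) carries the published
  per-scaffold tallies of the 18 lincRNA-richest *P. xylostella*
  scaffolds as a worked example; the richness threshold is inclusive
  (>= 20 lincRNAs), which is the reading consistent with the printed
  18-row table.
- **Nearest neighbors**: per catalog entry the protein-coding gene with
  the smallest span gap on the same scaffold (0 if abutting); ties go to
  the smaller gene start and are flagged. Expression of lincRNAs vs
  their neighbors is compared with a two-sided Wilcoxon rank-sum test.
- **Pre-miRNA search**: each precursor (50–200 nt) and its reverse
  complement are aligned locally (match +1, mismatch −2, gap −2) against
  each lincRNA; a hit needs identity >= 90% over >= 80% of the precursor
  length. This replaces a BLAST search with an explicit scorer so the
  package is self-contained at desk scale.
- **Term enrichment**: hypergeometric upper-tail p per term over a
  user-supplied gene-to-term map, with BH q-values; the raw counts (k,
  n, K, N) are emitted alongside so frequency rankings remain available.

## The simulator

The generator emulates the statistical structure the analysis assumes,
not sequencing reads. Defaults are the study conditions under test:

| parameter | default | meaning |
| --- | --- | --- |
| `n_scaffolds` x `scaffold_length` | 30 x 400 kb | assembly fragmentation |
| `n_coding_genes` | 300 | annotated protein-coding genes |
| `n_noncoding_loci` | 200 | planted intergenic lincRNAs |
| `n_decoy_coding_transcripts` | 100 | intergenic coding-like decoys (ORF > 100 aa) |
| `n_gene_overlap_candidates` | 50 | candidates straddling known genes |
| `gc_coding` / `gc_noncoding` | 0.42 / 0.369 | published GC averages of the two classes |
| `libraries` | 4 susceptible + 4 resistant, ~2M reads each | two-group design |
| `de_fraction`, `planted_log2_fc` | 0.30, 3.0 | 30% of lincRNAs planted at 8-fold |
| `dispersion` | 0.05 | negative-binomial overdispersion (typical biological replicates) |
| `baseline_mean_count`, `baseline_log_sigma` | 80, 0.6 | lognormal per-locus abundance |
| `n_mirna_embeds` | 10 | lincRNAs carrying a verbatim 70–90 nt pre-miRNA copy |
| `min_intergenic_gap` | 1200 bp | placement clearance (strictly beyond the 1 kb rule) |

Coding CDS sequences come from a first-order codon chain over a fixed
built-in codon-usage vector with a junction-dinucleotide coupling, which
produces the positional periodicity and hexamer bias the classifier
needs; genes carry 1–3 exons, UTRs, and random strand. Noncoding loci
are i.i.d. sequences at the noncoding GC with the longest ORF kept below
100 aa by rejection sampling (re-checked after pre-miRNA embedding;
embeds are exact substrings, forward or reverse-complement by coin
flip). Features are assigned to scaffolds via shared Dirichlet
propensities so per-scaffold gene and lincRNA counts correlate, as in
real assemblies, and placed with intergenic gaps of 1.2–2 kb; an
infeasible packing raises a configuration error rather than silently
overlapping loci. Counts are gamma-Poisson (negative binomial,
`Var = mu + phi mu^2`) around group means that scale with recorded
library depth; planting multiplies the non-reference group's mean by
`2^true_log2_fc`. The classifier's training material is drawn from an
independent random stream so candidate loci never leak into training.
Everything is deterministic given the seed.

What the simulator does **not** model: read-level artifacts (mapping
bias, positional coverage), splice-site sequence realism, repeat
families, GC-dependent coverage, and between-library batch structure.
Passing recovery tests therefore demonstrates the correctness and
calibration of the pipeline's logic under its stated assumptions, not
robustness to real-data artifacts upstream of the count matrix.

## Numerical and interface conventions

- All in-memory intervals are 0-based half-open; GFF3 (1-based closed)
  and BED (0-based half-open) conversions happen only at I/O
  boundaries, so `internal (s,e) <-> GFF3 (s+1,e)` is a bijection.
- FASTA input is uppercased; IUPAC codes other than N become N with a
  warning (real scaffolds contain them; rejecting would be unhelpful).
- Candidate strand may be unknown; ORF scanning always covers both
  strands, so the catalog does not depend on assembler strand calls.
- All tie-breaks (ORF selection, duplicate collapse, nearest-gene ties)
  are positional/lexicographic and documented, making byte-identical
  reruns a testable contract: `run-all` writes SHA-256 digests of every
  output into `manifest.json`, and equal seeds reproduce equal digests.
- p-values are clamped into `(0, 1]`; degenerate test inputs (both
  groups all zero) return statistic 0, p 1.

## Problem sizes used in validation

The shipped test-suite and acceptance checks run the default scenario
(30 scaffolds, 350 candidates, 8 libraries), a 10,000-locus null
calibration of the count test, a 1,000-sequence ORF oracle comparison,
and exhaustive hypergeometric enumeration up to population size 30 —
sizes chosen so that every check re-derives its expected values from
first principles while the whole suite stays interactive on a laptop.

## Known limitations

- The four-feature classifier is trained on simulator-matched material;
  applying the pipeline to real genomes requires supplying real coding
  and noncoding training sequences (the interface accepts any FASTA
  pair).
- The Pfam/BLASTx/CPC evidence arm is out of scope, so real-data
  catalogs from this package alone will be more permissive than the
  original multi-database workflow.
- The count test assumes library totals much larger than per-locus
  counts; it is not intended for features absorbing a sizable fraction
  of a library.
- Fold changes use mean RPKM with a fixed pseudocount; alternatives
  (proportion-based fold changes) are exposed but not defaulted.
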