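# Methods

## Scope and model

`lncscreen` implements the desk half of a stress-responsive lncRNA screen:
everything downstream of read alignment and transcript assembly.  Its inputs
are a transcript catalogue (FASTA + per-transcript genomic loci in GFF3), a
gene annotation (GFF3 gene spans), per-transcript read counts for a control
and a treatment condition, a miRNA hairpin precursor library, shRNA and
siRNA read libraries, a CDS set, and optionally a multi-tissue expression
matrix.  Upstream read mapping/assembly and the external coding-potential
classifier are out of scope by design; the latter is replaced by a pluggable
stage (see below).

## Differential expression

Expression is RPKM: `10^9 · count / (total_mapped · length_nt)`.
Replicates are summed to pooled counts before testing; the per-replicate
table is exposed for user-supplied alternative tests.  The default count
test is a two-sided exact binomial test: under no differential expression,
each of a transcript's `c + t` pooled reads falls in the treatment library
with probability `N_t / (N_c + N_t)`.  This is the classic test for pooled
digital counts; it is exact, dependency-light and appropriate when no
replicate-level dispersion model is wanted.  P-values are Benjamini–Hochberg
adjusted across all transcripts (via statsmodels, cross-checked in the test
suite against a brute-force step-up enumeration).

Fold change is computed on RPKM after adding one pseudo-read to each
condition, so condition-specific transcripts (zero counts on one side, a
real phenomenon for tissue- or condition-specific lncRNAs) get a finite
fold change.  A transcript is called `up` when fold ≥ 2 **and** FDR < 0.001,
`down` when fold ≤ 0.5 and FDR < 0.001, else `unchanged`.  Both gates are
required on purpose: the binomial test measures a transcript's *relative*
share of the library, which shifts for genuinely unchanged transcripts when
the conditions differ in composition, while the fold gate anchors the call
to the magnitude of the change.  Whether fold change should be computed on
raw counts instead, and which count test to use, are left configurable
because reasonable screens differ here.

## Non-coding screen

ORF finding scans the three forward frames only — transcripts arrive
orientation-resolved from assembly, so reverse-frame ORFs are not
meaningful.  An ORF is ATG…in-frame stop (TAA/TAG/TGA); codons containing N
never match ATG or a stop.  `aa_length` counts the initiating Met and
excludes the stop, matching the convention of a "<80 AA" peptide threshold.
An ATG running off the 3′ end is not an ORF by default (conservative,
deterministic; a flag admits stop-less ORFs).  Ties on length resolve to the
smallest start offset, then the smallest frame.

The coding-potential stage is pluggable.  The built-in heuristic labels a
transcript coding when the longest-ORF span exceeds half the transcript or
the ORF reaches 100 AA; it deliberately implements only the screen's
reproducible core, not the feature set of SVM-based classifiers.  Users with
access to such a classifier supply its labels as a TSV and they are honoured
verbatim.  The retention rule is: noncoding label, length > 200 nt, and
(no ORF or longest ORF < 80 AA); all thresholds strict and configurable.
(Some descriptions of such screens quote "no ORF > 70 AA"; the default here
is the 80 AA variant, and the threshold is a single config value.)

## Positional classification

Classification is against gene *spans*, not exon models: a transcript inside
an intron still counts as intragenic, because the screen's classes describe
loci, not splicing relationships.  The cascade is: no overlap → intergenic;
overlaps only opposite-strand genes → antisense; same-strand overlap with
full containment in one gene span → intragenic; same-strand overlap crossing
a boundary → overlapping.  When both same- and opposite-strand overlaps
exist, the same-strand relation wins by default (the antisense class is
defined against sense genes); a switch reverses the precedence.  The
supporting gene is the one with maximal overlap, ties broken by smaller gene
start.  Intervals are half-open with ≥1 shared nucleotide required, which
eliminates off-by-one ambiguity: GFF3's 1-based inclusive coordinates are
converted at the I/O boundary and nowhere else.

## Precursor taxonomy

Local alignment is affine-gap Smith–Waterman with match +2, mismatch −3,
gap open −5 (first gap position), gap extend −2, executed by Biopython's
`PairwiseAligner`; the test suite checks its optima against an independent
full-matrix Gotoh implementation.  `hit_len` counts every alignment column
including gap columns — which is why a coverage can exceed 100 % — and
percentages are reported to 2 decimals while classification always uses
unrounded values.  When several alignments are co-optimal the first
alignment in the library's deterministic traceback order is reported, so
outputs are bit-reproducible.

A lncRNA is a **miRNA precursor** when some hairpin aligns with identity
> 99 % and *precursor* coverage > 90 % (the coverage side is configurable;
the precursor side is the reading under which a short hairpin embedded in a
long host passes, consistent with hosts printing 100/100).  Both
orientations are searched.  All qualifying hairpins are reported: one host
may carry several, and one hairpin may occur in several hosts.

Zero-mismatch short-read mapping is semantically identical to exact
substring occurrence, and is implemented as such — every occurrence offset
of each read, on the sense strand and (by default) of its reverse complement,
is recorded; siRNA duplexes yield reads of both polarities.  The hierarchy
is then: miRNA precursor ≻ shRNA/siRNA precursor (≥ `min_reads` distinct
reads in **both** libraries) ≻ siRNA precursor (siRNA library only) ≻ other.
`min_reads` defaults to 1 since no principled larger value exists without an
abundance model.  The taxonomy has no shRNA-only class; a transcript with
shRNA support but no siRNA support falls to `other` and is flagged in the
evidence column so it can be audited.

## CDS pairing

Non-antisense `other` lncRNAs (positionally antisense transcripts already
sit opposite a gene and are excluded) are aligned plus/minus against every
CDS.  A pair passes at identity > 90 % with coverage > 90 %, where coverage
is the *larger* of the two per-side coverages by default: a short CDS fully
covered by a long lncRNA is a near-perfect match even though it covers
little of the lncRNA — published examples of such tables include rows with
query coverage near 14 % — so a query-side reading of the gate cannot be
right.  `both` and `query` modes exist for stricter analyses.  The report
carries the standard eight columns (names, lengths, hit length, identity,
both coverages); `q_cov·q_len = s_cov·s_len = 100·hit_len` holds up to
rounding for every row.

## Tissue specificity and qPCR

The specificity metric is tau (Yanai's index), `Σ(1 − xᵢ/x_max)/(n−1)`:
0 for a flat profile, 1 for single-tissue expression, scale-invariant.  A
transcript is called specific to its argmax tissue at tau ≥ 0.8 — a
conventional cutoff for "tissue-specific" in tau-based surveys; the screen
this package automates asserted specificity without defining a score, so the
metric is an explicit design choice here.  All-zero rows are undefined
(NaN in the matrix helper, an error for a single profile).

The Pfaffl ratio is `E_t^ΔCp_t / E_ref^ΔCp_ref` with `ΔCp = Cp(control) −
Cp(treatment)` for both genes and efficiencies E ≥ 1.  The sign convention
follows the formula as usually printed; the CLI logs the convention in use
and offers a `--flip-sign` switch, because the two orientations are easy to
confuse and invert the ratio.

## Synthetic data: what it emulates and what it does not

The generator builds a toy genome of 2 chromosomes × 14 genes (spans
1.5–3 kb, both strands) separated by ≥1.5 kb gaps, and plants a 60-lncRNA
cohort whose composition follows the shape such screens report: precursor
classes 4 miRNA / 10 shRNA+siRNA / 20 siRNA / 26 other (miRNA rarest, other
largest), positional mix leaning intergenic (35/15/4/6).  Hosts embed
verbatim hairpins of 100–140 nt (one hairpin shared by two hosts, as
happens for real miRNA families); read-supported hosts shed 21–24 nt slices
at random offsets and polarities into the appropriate libraries; CDS
partners are reverse complements of lncRNA subsequences (so the planted
pair has identity 100 and subject coverage 100); tissue-specific profiles
put 50–200 expression units in one of nine tissues against a 0–3 background.
Planted expression changes are 4-fold — generous relative to the 2-fold
gate — with Poisson replicate noise at control means of 80–250 (up) or
150–400 (down) reads.  Decoys exercise every filter: too-short transcripts,
transcripts with 82–98 AA ORFs (pass the coding-potential heuristic, fail
the ORF gate), transcripts with ≥105 AA ORFs (fail the coding-potential
stage), unchanged background transcripts, and never-matching precursor /
read / CDS decoys.

Background (stable) transcripts carry the bulk of sequencing depth, with
means log-uniform between 100 and 3000 reads.  This mirrors real libraries,
where differentially expressed transcripts are a small fraction of depth;
it keeps the control/treatment library-size ratio near 1, as in a real
experiment where the unmodelled majority of the transcriptome is stable.

Background sequence is i.i.d. uniform over {A,C,G,T}.  At ≥90 % identity
over ≥90 % coverage, spurious alignments between independent random
sequences are vanishingly rare, as are spurious exact 21-mers, so the
planted truth is clean by construction.  Consequently, passing the
truth-recovery tests shows the cascade's *logic* is correct under generous
margins; it does not show robustness to the things real data add —
paralogous sequence similarity, partial hairpin matches, sequencing error
in reads, overdispersed counts, GC or length bias, or ambiguous positional
cases.  The threshold-sensitivity tests (e.g. hairpin identity degraded
below 99 % flips hosts out of the miRNA class) probe the gates, not those
confounders.  All randomness flows from one `numpy` generator seeded once;
the same seed yields byte-identical files.

## Problem sizes and numerics

Default synthetic runs use ~320 transcripts (60-cohort + decoys + 250
background), 28 genes, ~600 small-RNA reads, 10 hairpins and ~25 CDS — sizes
chosen so a full cascade completes in seconds while every class and filter
is exercised multiple times.  The miRNA stage skips alignment tracebacks
whose optimal score is provably below what the identity/coverage gates
require (a conservative lower bound with a 0.8 safety factor); this is a
pure optimisation and cannot change any call.  Reported percentages round
half-to-even at 2 decimals; gates compare unrounded values, and all gate
inequalities are strict (`> 200 nt`, `< 80 AA`, `> 99 %`, `> 90 %`,
`FDR < 0.001`, fold `≥ 2`).

## Known limitations

- The binomial count test ignores replicate-level biological variance;
  with few replicates and strong dispersion it is anti-conservative.  The
  test is pluggable for exactly this reason.
- Positional classification uses gene spans, so exon-aware sense/antisense
  distinctions (e.g. an intronic antisense transcript of a nested gene) are
  out of reach.
- The coding-potential heuristic is an ORF-geometry rule, not a trained
  classifier; for real catalogues, injecting external classifier labels is
  recommended.
- Hairpin calls are homology-only; no secondary-structure validation is
  attempted.
- The tissue matrix is taken as given; no cross-platform normalisation is
  applied before tau.
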