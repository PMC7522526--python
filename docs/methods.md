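# Methods

## Scope and data model

`methylink` operates on one circular bacterial chromosome in a single
0-based, half-open, forward-frame coordinate system. Genes are flat spans
with a strand; wrap-spanning features are represented with `end > length`
and interpreted modulo the genome length. Exported BED keeps the internal
convention; exported GFF3 converts to 1-based inclusive.

## Modification calling from kinetics

The kinetic signal for a DNA modification is the interpulse-duration (IPD)
ratio: the mean IPD measured in the sample of interest divided by the mean
IPD of an unmethylated control at the same position and strand. The package
uses a two-sample design (control IPD supplied per record); a single-sample
mode with a user-supplied expected-IPD table can be emulated by writing that
table into the control column.

A record is called modified when three conditions hold:

1. the template base is callable — adenine (→ m6A) or cytosine (→ m4C);
   modified-G/T signals are ignored;
2. per-strand coverage is **strictly greater than** 25 (a literal reading of
   a ">25× per strand" sequencing design; configurable);
3. IPD ratio ≥ `min_ipd_ratio`, default 2.0. No portable published cutoff
   exists for platform-internal modification callers, so the package uses
   this common kinetic-detection heuristic, keeps it configurable, and
   echoes it into every output header.

Census percentages use duplex denominators: each A·T base pair contributes
exactly one adenine site (on one strand or the other) and each C·G pair one
cytosine site, so both-strand A+C equals genome length minus N count. Site
totals are reported both strand-specifically and collapsed to unique
positions, since published per-condition totals do not always state which
convention they use.

## Feature assignment

Categories are `gene_body` (position inside any annotated span),
`upstream500` (inside the fixed-length window 5′ of a gene's start,
strand-aware: for minus-strand genes the window is `[end, end+500)` in
forward coordinates), else `intergenic`. Design choices:

- gene_body beats upstream500; a call in gene X's body and gene Y's
  upstream window is categorized gene_body but keeps both associations;
- the strand of the call is ignored (methylation on either strand of a
  gene's span counts for that gene);
- upstream windows are a flat fixed length, never truncated at neighbors —
  with bacterial coding density upstream windows frequently overlap
  adjacent genes, and truncation rules would silently change gene-level
  counts;
- gene-level "percent methylated" is computed both with and without
  upstream association, because published gene-level figures are often
  ambiguous between the two.

## Differential expression

Transcript matrices are assumed normalized upstream (array-vendor
pipelines); the package tests log2 intensities per gene with Welch's
unequal-variance *t* statistic and Satterthwaite degrees of freedom, and
calls significance at raw p < α (default 0.05), the standard rule for array
pipelines. Benjamini–Hochberg q-values are computed and reported alongside.

Proteome intensity tables are log2-transformed and missing cells imputed
with the lowest observed log2 intensity. The global matrix-wide minimum is
the default ("the lowest intensity" is one number; label-free dropout is
missing-not-at-random at the detection floor, so the floor is the natural
fill value); a per-sample-minimum option exists. Proteome significance uses
BH q < 0.05. The default statistic is Welch, on the view that replicate
variances are rarely equal in label-free data; a strict equal-variance
Student option (`student=True`) is provided.

Degenerate inputs: identical zero-variance groups give p = 1; zero-variance
groups with unequal means give p = 0 with a degeneracy note; genes with
fewer than two replicates per group after dropping missing values are
flagged untested rather than silently zero.

**Known property of the Welch test at triplicate scale:** with 3-vs-3
replicates the Welch approximation is conservative — its true size under a
Gaussian null is ≈0.035 at nominal α = 0.05 (the equal-variance Student
test is essentially exact there). The null-simulation tests in this package
measure exactly this; users comparing rejection counts across pipelines at
n = 3 should expect mildly conservative transcript calls.

## Three-tier integration

A `TriLevelRecord` joins, per gene: per-condition methylation profiles
(body/upstream counts by modification type), the transcript DE result, and
the protein DE result; genes absent from an assay are marked absent, not
zero. Co-occurrence summaries report, for one treatment-vs-control
contrast:

- % of genes methylated in the treatment (body ∪ upstream) and transcript
  down- or up-regulated — over **both** denominators (all genes, and
  methylated genes only), labeled, since published percentages of this kind
  rarely state the denominator;
- % of genes traceable at all three levels (methylated + transcript
  significant + protein significant in the same contrast);
- up/down fractions among methylation-associated DE genes, split by assay
  and modification type (the two fractions in each cell sum to 1 when any
  DE genes exist; empty cells are flagged undefined, never 0/0);
- per-modification-type relative count changes vs the control condition,
  computed positionally (same coordinate + strand + type), not gene-level.

## Melting-energy profile

Duplex stability uses the unified Watson–Crick nearest-neighbor parameter
set for 1 M NaCl, shipped as a versioned JSON data file
(`data/nn_unified_1M_NaCl.json`) so an alternative table can be swapped in;
the loader verifies all 16 stacks and complement symmetry of the table.

`duplex_dG37` is the stack sum plus the two terminal-pair initiation terms.
The self-complementarity symmetry correction is deliberately **excluded**
here — it would break the reverse-complement invariance a genome-strand
profile relies on — and enters only `melting_temperature`, which applies
the symmetry entropy term and uses x = 1 (self-complementary) or x = 4 in
Tm = ΔH / (ΔS + R ln(C_T/x)) − 273.15.

Genome profiles are non-overlapping tiles by default (window 100 kb, the
resolution at which whole-genome melting maps are usually drawn); a sliding
step is a flag. The final window of a circular genome wraps through the
origin so the tiling covers the full length. Windows whose N fraction
exceeds 10% are flagged masked (NaN); N-containing stacks are always
excluded from window means. Internally the signed ΔG°37 is stored; the
bedGraph/Circos exporters can negate it for "melting energy" plots.

## Ka/Ks estimation

The estimator is counting-based (Nei–Gojobori family) rather than a
maximum-likelihood or rate-heterogeneity method: it is fully specifiable,
fast, and adequate for discriminating purifying (ω « 1) from neutral
(ω ≈ 1) regimes, which is the decision this screen supports.

- **Sites.** For each codon position, the fraction of the three single-base
  mutations that are synonymous, with mutations creating stop codons
  excluded from the denominator and the fraction renormalized — each codon
  contributes exactly 3 sites (S + N = 3). Site counts are averaged over
  the two sequences.
- **Differences.** For codons differing at k positions, all k! minimal
  mutational orders are enumerated; orders passing through a stop codon are
  discarded (if every order does, all are kept with stop-crossing steps
  counted nonsynonymous). Synonymous/nonsynonymous step counts are averaged
  with equal weights.
- **Correction.** Jukes–Cantor on both proportions: K = −(3/4)·ln(1 − 4p/3);
  p ≥ 3/4 flags saturation.
- **Significance.** Two-tailed Fisher exact test on the rounded 2×2 table
  [[Sd, Nd], [S − Sd, N − Nd]].
- **Filters.** Pairs with fewer than 3 total substitutions **or** p > 0.05
  are removed (either criterion suffices; a strict both-criteria mode is a
  flag), each with a reason tag. Note the significance filter removes
  genuinely neutral pairs by design — a neutrality control must therefore be
  evaluated on unfiltered estimates, as the test suite does.
- **Genetic code.** Standard code by default, NCBI table id configurable
  (e.g. 11 for bacterial annotations; the two differ only in start-codon
  policy, which this estimator does not use).

Alignments may contain gaps; codon columns containing a gap or ambiguity in
either sequence are excluded pairwise, and in-frame stops are rejected.

## Synthetic data generator

The generator emulates the structure of a three-condition
(optimal-temperature control, cold shift, UV exposure) multi-omics study of
a small heterotrophic freshwater bacterium, at desk scale. All randomness
flows from one integer seed through NumPy's PCG64; identical seeds give
byte-identical outputs, and every generator returns machine-readable
planted truth. Defaults (a single choice, not tuned per test):

| parameter | default | rationale |
|---|---|---|
| genome length / GC | 200 kb / 0.45 | desk-scale stand-in for a ~2.1 Mb, ~45% GC chromosome |
| genes | 200, N(900, 200²) bp, head-to-tail with exponential gaps | bacterial coding density; full study has ~2,100 genes |
| motif | CTAYNNNNNNNNTRTC, methylated offset 2, 20 planted copies | bipartite type-I R-M recognition site |
| motif methylation | 0.97 / 0.97 / 0.92 (control, cold, UV) | near-complete motif methylation, reduced under UV |
| genes methylated | 25% / 21% / 16% (exact counts) | per-condition gene-level methylation prevalence |
| in-gene∪upstream fraction of background calls | 0.52 | roughly half of genomic methylation is gene-associated |
| P(down∣methylated), P(up∣methylated) | 0.78, 0.22 | methylation predominantly co-occurs with down-regulation |
| expression | triplicates, baseline log2 ~ N(10, 1.5), effect ∣Δ∣ ~ N(2, 0.5), replicate noise sd 0.25 | array-like dynamic range and effect sizes |
| proteome | attenuation 1.0, noise sd 0.25, MNAR dropout ≤10% with logistic intensity dependence | label-free missingness concentrates at low intensity |
| kinetics | control IPD lognormal(0, 0.25), methylated multiplier 4, multiplicative noise sd 0.2, coverage Poisson(60) | coverage in the 54–70× range; multiplier well above the 2.0 call threshold |
| codon evolution | branch length 0.3 = expected mutation proposals per codon | a few percent nucleotide divergence |

Codon-pair evolution is an acceptance–rejection scheme: single-base
proposals arrive per codon at the branch-length rate; synonymous proposals
are always accepted, nonsynonymous ones with probability ω, stop-creating
ones rejected. This is a deliberate simulator approximation — it is
specifiable in a paragraph and reproduces the ω regimes the estimator must
discriminate, but it is not a GY94-style continuous-time codon model: rates
are not transition/transversion-aware and proposals are serial, so realized
ω can drift slightly from nominal at high divergence. Measured counting-
estimator bias against planted ω is under 10% at 10,000 codons for
ω ∈ {0.2, 0.5}.

What the generator does **not** emulate — and hence what passing recovery
tests do not demonstrate about real data: read-level sequencing noise and
mapping artifacts, context-dependent IPD baselines (real kinetic
backgrounds vary with sequence context; here the control IPD is i.i.d.),
microarray probe effects and normalization residues, peptide-level
quantification and shared-peptide ambiguity, operon structure (genes are
independent), and selection heterogeneity along sequences.

## Numerical and degenerate-input conventions

- N bases never match any motif character during scanning (no phantom hits
  in gap regions); overlapping motif matches are all reported.
- Strand-balance ratios with a zero minus-strand count are flagged infinite
  rather than raised; zero calls give an undefined flag.
- Methylation-count deltas against a zero control count are flagged
  undefined.
- BH q-values follow the step-up procedure exactly (permutation-invariant,
  monotone over the sorted order).
- Kinetics records with zero control IPD raise an error naming the
  position; they are never silently dropped.
- File outputs round floats (kinetics to 6 decimals) so that fixed seeds
  give byte-identical files across platforms.

## Acceptance surface

`scripts/acceptance.py` recomputes two statistics end to end from the
package alone: (1) the median counting-method Ka/Ks across 50 simulated
1,000-codon ortholog pairs at ω = 0.2 after pair filtering — the purifying-
selection screen, expected well below 1; (2) the empirical type-I error of
the transcript DE test on a 2,000-gene 3-vs-3 null — expected near, and in
practice slightly below, the nominal 0.05 (see the Welch note above). The
test suite additionally checks the genome-scale census arithmetic on a
synthetic reference-scale chromosome (2.18 Mb, 2,088 genes, 196 planted
motif instances): the scanner must recover the full planted census, and
1,504 / 873 calls over the duplex A+C denominator reproduce 0.069% / 0.040%.

## Known limitations

- No methylation-fraction (partial methylation) estimation; calls are
  binary per position/strand.
- Single-contig genomes only; multi-contig input must be concatenated.
- The melting model has no salt correction beyond the fixed 1 M table, no
  mismatch/dangling-end terms, and no secondary-structure prediction.
- The Ka/Ks module does not detect orthologs or align sequences; it
  consumes frame-preserved alignments.
- PCA export is descriptive QC only and intentionally unvalidated.
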