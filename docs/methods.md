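# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical details a user would need to reproduce or audit a run.

## Copy-number divergence

Orthologous-group membership is an input (the package does no homology
inference). For species with ploidies *p_A*, *p_B* and family counts *c_A*,
*c_B*, the comparison statistic is the relative copy number rcn = c/p,
which removes the expected doubling a tetraploid carries for every family.
A family is flagged divergent when the rcn ratio (larger over smaller) is at
least `fold` (default 2), or whenever one count is zero and the other is
not: the ratio is then undefined and species-specific presence/absence is
the strongest form of divergence. The fold threshold is exposed because no
canonical value exists; 2 is the default as the smallest value that treats
whole-family doubling/halving — the natural unit of change after polyploidy
— as divergence while ignoring sub-fold drift. Classification into
specific_A/specific_B/1:1/1:many/many:1/many:many depends only on the two
counts and swaps consistently under species exchange.

## Stage-series profile clustering

Expression is RPKM-like and non-negative; series are transformed to
(0, log2(v1/v0), ..., log2(vn/v0)). The transform is undefined at v0 = 0, so
such genes are excluded rather than pseudocounted — reproducible and
conservative, at the cost of discarding genes silent at the first stage.
Genes whose transformed series never reaches |change| >= 2 (i.e. 4-fold on
the raw scale) are treated as flat.

Model profiles are all shapes starting at 0 with per-step integer changes in
{-c..c}; at 4 stages and c = 1 there are 27. The catalogue keeps m = 20 of
them (matching the cluster count conventional for 4-stage seed courses),
chosen greedily by max-min Euclidean distance starting from the all-flat
shape, ties broken lexicographically — fully deterministic. Genes join the
profile with the highest Pearson correlation; constant transformed series
are unassignable, and a flat profile can never win (its correlation is
undefined), which is intended: it represents "no temporal signal".

Significance per profile: the null permutes the stage order of every gene
and re-assigns. Because the transform of a reordered raw series equals the
reordered transformed vector re-anchored at its new first element, and
Pearson correlation is shift-invariant, permutations act directly on the
transformed matrix. With n <= 5 stages all n! permutations are enumerated
(24 at 4 stages); the expected cluster size is the mean over permutations
and the observed size is tested with an upper-tail Binomial(total,
expected/total). Raw p < 0.05 is reported without multiplicity correction,
matching how such cluster p-values are conventionally quoted; on label-free
data the significant-profile rate sits at the nominal level (measured 1/20
at seed 1). Trends are called over the window (t2, t3) — the rapid
oil-accumulation phase — as up/down/other by comparing shape endpoints.

Candidate genes are the union (flag: intersection) of genes in divergent
query families and genes assigned to significant up/down profiles,
restricted to the query (pathway-anchored) families. Union is the default
because the two evidence streams are complementary, not confirmatory.

## Enrichment

One-sided hypergeometric upper tail P(X >= k | N, K, n) via
`scipy.stats.hypergeom.sf`, verified in tests against explicit
combinatorial enumeration for every universe size N <= 25. The background
defaults to all annotated genes (server-style convention), terms with fewer
than 5 background genes are dropped, Benjamini-Hochberg adjustment uses
`statsmodels.multipletests`, and top-k ranking is by corrected p with ties
on term id.

## Co-expression networks

Pearson r with the t-transform p-value, t = r sqrt((n-2)/(1-r^2)) on n-2
df (the standard test for a product-moment correlation; the thresholds are
|r| >= 0.9 AND p <= 0.05, enforced conjunctively). An important caveat is
documented and tested: with only 4 stage samples, df = 2 and
p(r = 0.9) ≈ 0.10, so the p criterion dominates and the effective |r|
cutoff is ~0.95; short stage courses admit only near-perfect correlations.
The sample count is taken from the matrix, not assumed. Network comparison
splits the two species' neighbor sets into ortholog-shared pairs (same OG)
and species-specific remainders, which are the natural input for
enrichment of species-specific biology.

## miRNA duplex scoring

Scoring is positional along the miRNA from its 5' end, pairing antiparallel
against the target window: Watson-Crick 0, G:U wobble 0.5, mismatch 1, gap
2, with non-gap penalties doubled in the seed region (miRNA positions 2-7).
Gap penalties are not seed-doubled, and at most one gap per duplex is
considered — both choices fixed by the published worked alignments this
scheme reconstructs exactly (expectations 4, 3.5 and 3, including a
seed-doubled wobble and a position-7 gap). The expectation cutoff defaults
to 3 but is configurable: published hit tables include sites at 3.5 and 4
despite a stated cutoff of 3, a discrepancy the package exposes rather than
resolves. Inhibition is called Translation when any of miRNA positions 9-11
is a mismatch or gap (slicing requires central pairing), else Cleavage.
Target accessibility (UPE) requires a partition-function RNA energy model
and is carried as an optional pass-through field, not computed. U/T are
equivalent throughout, so DNA transcripts score identically to their RNA
transcriptions.

## Molecular evolution

Protein distances: p-distance with pairwise deletion (columns with a gap in
either row are skipped per pair), Poisson-corrected as d = -ln(1 - p).
Neighbor joining follows the standard Q-criterion with the three-lineage
closing step, so additive matrices are reproduced exactly (tested to 8
taxa, and cross-checked against scikit-bio's implementation). Negative
branch-length estimates are clamped to zero with the deficit moved to the
sister branch (display convention); the raw value stays on the node as
`raw_length`. Bootstrap: columns resampled with replacement, support = the
percentage of replicate trees containing each internal bipartition,
deterministic for a seed.

Ka/Ks uses Nei-Gojobori (1986) counting: per-codon synonymous site
fractions (changes to stops count as nonsynonymous), pathway-averaged
differences for codons differing at 2-3 positions (paths through stop
codons excluded; all paths used if every path is blocked), Jukes-Cantor
correction of both proportions, ω = Ka/Ks undefined (flagged None) when
Ks = 0 or a proportion saturates. The estimator agrees with Biopython's
independent NG86 implementation to ~1e-5 on simulated pairs. It is a
desk-scale stand-in for codon-model maximum likelihood: branch and
branch-site ML fitting are out of scope, but their reported log-likelihoods
can be tested with `branch_lrt`, which computes 2|dlnL| against chi-square.
The absolute value matters: published fits sometimes print the freer model
with the lower likelihood, and the package reports that anomaly in a
`label_swap` flag instead of silently relabeling the models.

## Synthetic data generator

The generator emulates the study design — a diploid and a tetraploid, four
matched stages, RPKM-like values — with planted, recorded ground truth.

* **Families:** per-haploid family size is zero-truncated geometric with
  mean 2 (realistic 1:many classes without external data); raw counts are
  size x ploidy, so non-divergent families have exactly equal rcn. A
  planted fraction (default 20%) is made divergent: 25% of those by
  presence/absence, the rest by multiplying one species' per-haploid size
  by an integer factor >= 2. The 2-fold rule therefore recovers the planted
  set with precision = recall = 1 (counts carry no noise).
* **Expression:** gene series = baseline x 2^(shape + eps), eps Gaussian on
  the log2 scale (sd 0.2 by default — matching the scale the transform
  works on), baseline log-normal around ~8 RPKM. Labels are planted on the
  10 most spread-out non-flat profiles at 200 genes each by default: flat
  shapes carry no recoverable signal, and the recovery guarantee (>= 90%
  label recovery at noise 0.2; measured ~94% at seed 1) is stated for >=
  200 genes per planted profile. Planting on all 19 non-flat shapes
  including near-collinear ones lowers recovery to ~88%, which is a
  property of profile geometry, not of the assignment code.
* **miRNA targets:** random RNA miRNAs and DNA transcripts; each planted
  site is the reverse complement of its miRNA with a configured number of
  mismatches and wobbles placed outside the seed region (default 1 + 1,
  expectation 1.5), at recorded 1-based coordinates.
* **Codon alignments:** sequences evolve along a supplied tree by proposed
  point mutations at the neutral rate; synonymous proposals are accepted
  with probability min(1, 1/omega) and nonsynonymous with min(1, omega), so
  the acceptance ratio equals omega on every branch; stop codons are
  rejected. There are no indels, so tip sequences are trivially aligned.

What the generator does **not** emulate: read-level sampling noise,
replicate structure, library-size effects, correlated noise across genes,
real genome copy-number distributions, or the sequence composition of real
transcripts. Passing recovery tests therefore demonstrates that each
estimator inverts its own generative assumptions at realistic noise — not
that those assumptions hold for any particular real dataset.

## Pipeline

The orchestrator validates the config up front (fail-fast with the
offending field), executes stages in dependency order, logs wall time per
stage, hashes all inputs into `metadata.json`, skips stages whose inputs
are not configured, and marks downstream stages of a failed stage as
skipped. Every candidate row in the report is traceable to at least one
trigger (copy-number divergence or a significant trend profile). With a
fixed seed the run is byte-deterministic.

## Problem sizes used in validation

The test-suite and acceptance checks run at desk scale, chosen so the whole
suite completes in seconds while keeping each statistical check
well-powered: 2,000 genes for profile recovery and null calibration, 200
families for divergence recovery, 3,000 codons for the neutral-omega check,
trees to 8 taxa, 1 kb transcripts for scanner/brute-force equivalence, and
enrichment enumeration over all universes N <= 25.
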