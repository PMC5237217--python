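# Methods

## Scope and model

`hybridpanel` treats identification of hybrid and backcrossed individuals
between two long-diverged populations (A and B) as a sequence of
well-separated statistical problems: screening candidate diagnostic SNPs
from pooled sequencing, validating a genotyped panel, simulating the
pedigree categories a baseline must contain, and classifying or assigning
individuals.  Throughout, loci are biallelic, unphased, unlinked, and
autosomal; genotypes are counts of one named allele (0/1/2, with an
explicit MISSING state that is never imputed).

### Pedigree categories and the binomial heterozygote model

Categories are pure A, pure B, F1, and backcrosses FgA/FgB, where
FgA = F(g−1)A × pure A (so g−1 backcross rounds).  Along such a chain each
marker lineage is, independently of the others, "still carrying foreign
material" with probability f_g = 2^(1−g); on a fully diagnostic panel that
is exactly the probability of being heterozygous.  The heterozygote count
over n markers is therefore Binomial(n, p_g) with:

| scenario | per-marker heterozygosity p_g | native p |
|---|---|---|
| diagnostic | 2^(1−g) | 0 |
| introgressing MAF m (one-directional) | 2^(1−g)·(1−m) | 0 |
| symmetric MAF m | f_g(1−h) + (1−f_g)h, h = 2m(1−m) | h |

The introgressing factor (1−m) reflects that the foreign-derived
chromosome may itself carry the local-type allele at frequency m; the
symmetric form mixes the backcross-chain heterozygosity with baseline
Hardy–Weinberg heterozygosity h on the fraction of the genome that is
locally derived.

Classification compares categories by binomial likelihood at the observed
k, which partitions 0..n into disjoint intervals covering every k exactly
once; the probability of correct classification of a true Fg is the
binomial mass of its own interval.

### Numerical conventions in the classifier

* **F1 boundary.**  p_1 = 1 collapses the F1 likelihood onto k = n, so a
  pure likelihood argmax would classify k = n−1 as F2.  We instead fix the
  F1 interval at [⌈n/√2⌉, n] (36–50 for n = 50), the geometric mean of the
  adjacent expected counts n and n/2, in every scenario.  This is a
  convention, not a derivation; it reproduces the published interval
  tables cell-for-cell, including the probability columns.
* **Ties.**  Exact likelihood ties at a boundary k go to the lower (more
  recent) generation, favouring follow-up of possible introgressants;
  Native loses ties to any generation.
* **Native.**  Under diagnostic/introgressing scenarios Native has p = 0:
  likelihood 1 at k = 0 and 0 elsewhere.  Under symmetric MAF it competes
  with p = h like any other category.
* **Missing markers.**  An individual called at n_obs < n markers is
  classified against a table rebuilt at n = n_obs; k is never rescaled.
* **max_generation** defaults to 8.  Under m = 0 and m = 0.05
  (one-directional) generations 8+ own no interval.  One documented edge:
  under symmetric m = 0.05 the model assigns k = 5 to F8 (the F7/F8/Native
  likelihoods are within a whisker of each other there — the boundary sits
  at ≈5.06); published tables leave that cell to Native's neighbourhood and
  declare F7+ never most likely.  We report what the model computes and do
  not assert that single cell.

### Dual-ancestry detection

Hybrid × hybrid offspring are the one category the backcross-chain model
cannot represent: they carry homozygotes specific to *both* ancestral
populations.  Expected marker-class fractions for FgxFg crosses are
computed by exact enumeration of parental states (each parent heterozygous
with probability h = 2^(1−g), transmitting the foreign allele with
probability h/2): F1×F1 gives (¼, ½, ¼); F2×F2 gives
(0.5625, 0.375, 0.0625) for (local-hom, het, foreign-hom), so a 50-marker
F2×F2 offspring shows no foreign homozygote with probability
0.9375⁵⁰ ≈ 4% and would then be misread as a backcross.  The probability
that both ancestral homozygote classes reach a threshold t is computed by
exact trinomial summation.  For n = 50, t = 3, F1×F1 this gives 0.99983;
the figure sometimes quoted as "99.8%" appears to be a rounding of a
slightly different computation — we report the exact trinomial value.

### Panel diagnosticity

A locus is oriented by the majority allele of each population (ties broken
toward `allele_a`, deterministically); its observed MAF in population A is
the sample frequency of B's diagnostic allele there, with an Agresti–Coull
interval computed on allele copies (2 × called individuals) — the
standard genetic convention.  "Fully diagnostic" is an observed-data
property: zero copies of the opposite allele seen in either population.
For a fully diagnostic marker called in ~95 individuals the 95% upper
bound on the true MAF is ≈2.4% (190 copies); published summaries quoting a
3–4% upper-bound range for comparable call counts are not recoverable
under either the allele-copy or the individual-count convention, so the
formula, not the printed range, is this package's contract, and the
discrepancy is documented here rather than tuned away.

### Assignment

Both assignment methods score an individual against every baseline
category and report the best category's likelihood as a percentage of the
summed likelihoods (computed in log space):

* **Conditional ML**: product over called loci of Hardy–Weinberg genotype
  probabilities at the category's empirical allele frequencies, with
  frequencies floored/capped at 1/(2N+1) so unseen alleles never zero out
  a likelihood (a standard assignment-software convention).
* **Rannala–Mountain**: the individual's two allele copies are drawn
  sequentially from the Dirichlet-multinomial posterior with prior 1/K per
  allele (K = 2), i.e. P(first = b) = (n_b + ½)/(n + 1), updated before
  the second draw.  This is the default: it handles the all-but-fixed loci
  of a diagnostic panel gracefully.

Leave-one-out removes the tested individual's own allele copies from its
category before frequency estimation; it is a no-op for individuals not in
the baseline.  The deterministic hybrid index q (ancestry proportion from
population A) maximises the HWE likelihood at per-locus mixture
frequencies q·p_A + (1−q)·p_B over a 2001-point grid on [0,1], with the
95% CI taken as the profile-likelihood region within 1.92 log units of the
maximum.  It is a clearly labelled deterministic alternative to MCMC
admixture clustering, which this package deliberately does not
reimplement, and is never compared against MCMC outputs.

### Pooled-sequencing screening

Selection follows the published strategy: (1) drop sites whose total
depth is outside mean ± 2 SD (both moments computed over the dataset
itself, two-pass); (2) score each surviving site; (3) keep the two
top-scoring sites on each of the 50 longest scaffolds (ties in length
broken lexicographically); (4) within a multiplex, remove the
lower-scoring of two same-scaffold loci, transitively.  The per-site score
is a declared **surrogate** for the expected SNP information value (ESIV)
of the original screening tool, whose formula is unpublished: the lower
95% Agresti–Coull bound of |freq_B(group A) − freq_B(group B)| on read
counts, truncated at zero.  It is monotone in both the frequency contrast
and the depth — the two stated criteria of the original score — and is a
plug-in point (`score_fn`) for a faithful ESIV.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical* structure of a real validation
study: ~50 markers fixed or nearly fixed between populations (minor
alleles up to ~5%, matching estimated MAFs of 0.6–4.7% in validated
panels), 95 individuals per pure population, and pooled sequencing with 2
pools per population of 18 diploids at ~12× per-pool coverage.  Pool reads
are drawn in two stages (pool allele copies, then reads with Poisson
depth), so finite pool size inflates read-frequency variance as in real
pooled-seq; a one-stage binomial is available via `two_stage=False`.

Not modelled: linkage disequilibrium (markers are independent by
construction, as the one-to-two-per-long-scaffold selection is designed to
approximate), sequencing and genotyping error, allele dropout, unequal
DNA contribution within pools, sex-linked or organellar inheritance, and
real allele-frequency spectra.  Passing tests therefore demonstrate the
correctness of the statistical machinery under its own assumptions, not
the field accuracy of any specific panel; in particular the simulated
assignment accuracies depend on the synthetic frequency profile, and real
baselines with different MAF structure will differ in detail.

## Study defaults and problem sizes

The canonical simulated study (used by the test suite and
`scripts/acceptance.py`) uses: 50 markers; pure populations of 95; the
one-directional scenario with per-locus MAF ~ Uniform(0, 0.05] on the B
side (the empirically relevant case of B-alleles leaking into an otherwise
fixed panel); an 11-category baseline (pures as sampled, plus 100
simulated individuals per hybrid category — 1090 total); fresh test
cohorts of 200 F1 and 250 per direction for F2 and F3; Rannala–Mountain
leave-one-out assignment.  Distributional checks (Hardy–Weinberg and
binomial goodness-of-fit) use 10⁴ simulants.  These sizes make every
Monte-Carlo tolerance (3 standard errors) small while keeping the whole
suite in seconds.

## File formats

* Genotype CSV: `individual_id,label,<locus ids…>`, calls as two allele
  letters (`AG`), `NA` missing.  On read, allele identity per locus is
  inferred from the observed letters (alphabetical orientation); matrix
  equality is defined on unordered allele pairs, so round-trips are exact.
  Scaffold metadata is not carried by the CSV.
* Genepop 4-digit diploid dialect (`0101`/`0102`/`0202`, missing `0000`).
  Genepop has no slot for population names or allele letters, so the
  writer records both in the free-text title line and the reader recovers
  them; foreign files get POP1..POPn labels and placeholder alleles.
  POP blocks force grouping of individuals by label on write.
* Pooled counts TSV:
  `scaffold_id  scaffold_length  position  pool_id  depth  count_allele_a  count_allele_b`;
  scaffold catalogue TSV: `scaffold_id  length`.

## Known limitations

* The generation classifier assumes a *pure* backcross chain into one
  population; pedigrees mixing directions are outside its model (the
  dual-ancestry test covers the hybrid × hybrid case only).
* Likelihood percentages ("scores") are relative to the candidate set and
  are not posterior probabilities; no generation priors are applied.
* The baseline composition (100 per simulated category) is a parameter,
  not an estimate; real studies may weight categories differently.
* The hybrid-index CI is asymptotic and grid-quantised (resolution 5e-4).
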