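# Methods

## The question and the test

`tamscan` asks whether spontaneous mutations fall preferentially in highly
transcribed parts of a genome. The unit of analysis is a sliding genomic
window (defaults: 10 kb sliding by 1 kb, and 1 kb sliding by 100 bp, as in
`bedtools makewindows`). For each expression profile (an RNA-seq coverage
track labelled by genotype/stage/condition) every window receives two
metrics:

* **depth** — a TPM-like rate: the window's mean per-base coverage over its
  unmasked bases, rescaled so that the rates of the *canonical tiling* (the
  non-overlapping windows whose starts are multiples of the window size)
  sum to 10⁶. The tiling is the normalisation universe so that overlapping
  sliding windows do not double-count the library; the Σ = 10⁶ contract is
  enforced to a relative tolerance of 10⁻⁹ in the tests.
* **breadth** — the percentage of unmasked bases covered by ≥ 1 read.

Mutations (base substitutions, insertions, deletions from VCF or TSV) are
anchored at their leftmost-aligned VCF position; a window is *flagged* when
it contains at least one anchor base. The test statistic is the **median**
of the metric over the k flagged windows. The null distribution is built
by drawing k windows uniformly without replacement from all included
windows (flagged windows are not removed from the pool) 10,000 times and
recording each draw's median. The p-value is one-sided for elevated
expression: the fraction of permuted medians greater than the observed
median (`strict_greater`, the default tie rule). Because a strict rule
degenerates to p = 0 under heavy ties (e.g. breadth saturated at 100%),
`greater_or_equal` and the add-one-corrected p = (b+1)/(n+1) are available;
the calibration analyses below use `greater_or_equal`, which is the
conservative choice under ties and identical to `strict_greater` for
continuous metrics.

An exhaustive oracle (`exhaustive_pvalue`) enumerates every k-subset when
C(n, k) ≤ 10⁶ and is used to verify the Monte-Carlo p-values.

## Controls

* **GC matching** — GC content correlates with both expression and
  mutation rate, so the permutation test can be repeated with both the
  flagged set and the sampling universe restricted to windows with GC in
  a band (default 0.30–0.50, bounds inclusive). GC per window is computed
  over unmasked bases, with N excluded from numerator and denominator; a
  window with no unmasked unambiguous base has undefined GC and is dropped
  from GC-filtered analyses only.
* **Quartile enrichment** — included tiling windows are ranked by depth
  with seeded random tie-breaking (many windows tie at zero TPM), split
  into four equal-size rank groups, and the fraction of flagged windows in
  each quartile is reported. Random tie-breaking makes the uniform 0.25
  null exact.
* **Genic restriction** — the same machinery applied to gene spans from a
  GFF3 annotation. Gene depth uses the full genomic span, not the spliced
  exonic length: the windowed analysis quantifies coverage genomically,
  and span-based gene quantification keeps the two analyses on the same
  footing. Per-mutation-type strata reuse the pipeline with the mutation
  set filtered by type.

## Masking

Regions masked before mutation calling (repeats, low-confidence regions)
are also masked before expression quantification, so mutation and
expression are measured over the same effective genome. A window's
*effective length* is its unmasked bp; fully masked windows are excluded
from all statistics. Effective-length normalisation also neutralises the
truncated final window each chromosome produces.

## Synthetic data

The generator emulates the statistical structure of a mutation-accumulation
study crossed with public RNA-seq: defaults are 3 chromosomes × 1 Mb, 10%
masked, per-window GC ~ truncated normal(0.40, 0.05), window expression
rates zero-inflated (30%) log-normal(μ = 0, σ = 1.5), four profiles (three
developmental stages plus a chemical-exposure condition) sharing one
underlying landscape with multiplicative log-normal profile noise
(σ = 0.3), read depth scaled so mean coverage is a few reads per base, and
nine genotypes × 73 mutations (657 total, matching the order of magnitude
of a real MA panel with 39–136 mutations per genotype). Mutation types mix
0.8/0.1/0.1 substitution/insertion/deletion.

Mutation placement uses the simplest monotone link: window w is chosen
with probability ∝ exp(β·z_w), where z_w is the z-score of log1p(rate_w)
across included tiling windows, and the base is uniform over the window's
unmasked positions. β = 0 is the null; the model is a verification device,
not a mechanistic claim. What the generator does **not** emulate: spatial
autocorrelation of expression along chromosomes, mutation-rate covariates
other than expression (replication timing, chromatin), read mapping
artefacts, and strand asymmetries — so passing tests demonstrate
correctness and calibration of the statistical machinery, not robustness
to every property of real data.

All randomness flows from one `numpy` generator seeded by the config;
identical configs produce byte-identical files.

## Calibration and power

Statistical behaviour is checked on a single-chromosome calibration
geometry (1 Mb, 10 kb tiling → 100 windows, 100 mutations, one genotype
and profile, no mask — masking is exercised separately and would only
enter these checks through effective lengths, which the TPM rate already
normalises away). With 10,000 permutations and `greater_or_equal`:

* at β = 0 the rejection rate at α = 0.05 is ~0.04 (tested over 500
  datasets against the [0.03, 0.07] band);
* power rises steeply with β: ≈ 0.8 at β = 0.5 and ≈ 1 from β = 1. The
  expected power at β = 1.5 was computed beforehand with an independent
  plain-numpy simulation of the same generative model
  (`scripts/power_oracle.py`, 400 replicates: 1.00, exact binomial 95%
  lower bound 0.991) and the pipeline's observed power is pinned to that
  expectation's binomial interval.

## Numerical choices

* Coordinates are 0-based half-open internally (BED convention); VCF and
  GFF3 positions are converted at the parser boundary.
* Quantification runs on piecewise-constant step functions with one
  cumulative array per chromosome (two binary searches per window), and is
  tested for *exact* equality against a per-base array reference — sums of
  integer coverage are exact in double precision.
* Permutation draws are vectorised (argpartition of a uniform random
  matrix) when the index matrix fits comfortably in memory, with a
  sequential fallback; the path chosen depends only on problem size, so
  results are reproducible either way.
* Battery rows derive per-row random streams from the master seed and the
  row key (genotype, profile, metric, stratum, control), so adding or
  removing rows does not perturb other rows, and reruns are byte-identical.
* Benjamini–Hochberg adjusted p-values are reported alongside raw p-values
  and never substituted for them; the battery's headline counts use raw p
  with strict thresholds (p < 0.05/0.01/0.001).
* Quartile boundaries are reported as the 25/50/75% value quantiles, but
  group membership comes from the randomised ranks, keeping groups equal
  sized (±1) under ties.

## Known limitations

* Indels are assigned to windows by their anchor base only; a deletion
  spanning a window boundary counts for the anchor window alone.
* Gene expression is span-based; intron-dense genes are averaged over
  introns too.
* Coverage input is per-base bedGraph (e.g. `bedtools genomecov -bga`);
  BAM conversion is an external one-liner and out of scope.
* The permutation null treats windows as exchangeable; long-range
  autocorrelation of expression would make the test anti-conservative on
  real data to the extent that flagged windows cluster.
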