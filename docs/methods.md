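# Methods

This note records the models, conventions and numerical choices behind
`svpanel`, in the spirit of the methods documentation of mature
population-genetics packages: what is computed, under which assumptions,
and what the synthetic studies do and do not demonstrate.

## Genotype coding and the depth mask

All SV analyses run on presence/absence per genotype: any call with an
alternate allele (0/1 or 1/1) is a carrier, 0/0 is a non-carrier, and an
uncalled genotype — or one whose read depth is below `min_depth`
(default 10) — is missing.  Dosage is deliberately not retained: every
downstream statistic (spectrum bins, MAF, r², carrier counts) is defined
on carriers, and heterozygous/homozygous deletion calls from short-read SV
genotypers are not reliable enough to separate.  Depth comes from FORMAT
`DP` when present, else the summed allele-depth field; when neither
exists the mask passes (depth unknown is not evidence of a bad call).
Coordinates are 1-based inclusive throughout, matching VCF and GFF3.

## Filter cascade

Stages run in a fixed order (paired-end support ≥ 4, PRECISE flag,
break-end removal, 50 bp ≤ size ≤ 100 kb, missingness ≤ 20%, minor
frequency ≥ 5%), each applied to the survivors of the previous stage, so
the per-stage tally is monotone and the cascade is idempotent.  Reading of
the thresholds:

* "more than 20% missing" is strict — a site is removed iff its missing
  fraction exceeds 0.20 exactly;
* the size filter is inclusive at both bounds (a 50 bp or 100,000 bp
  variant survives);
* the MAF stage keeps a site iff its minor-carrier count divided by the
  *panel size* is ≥ 0.05 (for 347 genotypes: at least 18 carriers).  The
  panel-size denominator makes the threshold a fixed carrier count;
  a nonmissing-count denominator is available via
  `FilterConfig(maf_denominator="nonmissing")` for panels where
  missingness varies strongly between sites.

The MAF stage is optional (`apply_maf=False`) because the site frequency
spectrum and diversity estimates must include rare variants; the tally
reports the would-be MAF survivors either way.

## Site frequency spectrum and neutrality

n counts *genotypes*, not chromosomes: with presence/absence coding a
deletion can be carried by at most n genotypes and the minor side of a
site by at most ⌊n/2⌋, so for a 347-genotype panel the spectrum has bins
1–173.  θ_w = S / H(n−1) with H the harmonic number, S the number of
sites entering the spectrum (monomorphic-on-nonmissing sites are
excluded).  The expected bin count is the plain unfolded θ_w/i, used
literally; the textbook folded expectation
θ_w (1/i + 1/(n−i)) / (1 + [i = n−i]) is available as
`expected_mode="textbook_folded"` for comparison.  A per-genotype
"chromosome" reading (2n) is likewise a switch (`n_mode="chromosomes"`).

The goodness-of-fit statistic treats the spectrum as a multinomial
sample: 1/i weights renormalized over the bins give cell probabilities,
consecutive cells are pooled until every pooled expectation is ≥ 5, and
the χ² upper tail with (cells − 1) degrees of freedom is reported.  One
subtlety matters: a site with m nonmissing genotypes folds at m/2, not
n/2, so when data are missing the bins from min(m) − ⌊n/2⌋ upward can
gain or lose sites purely through censoring.  Those bins are pooled into
a single tail cell before testing.  On complete data the bound lies
beyond the last bin and the statistic is unchanged; on pure multinomial
draws the test is exactly calibrated (verified at 200 replicates), and
without the censoring pool it would reject genuinely neutral panels with
a few percent missingness.

## Diversity

Per-site π is the average pairwise difference among nonmissing calls:
2·c₁·c₀ / (m(m−1)) for c₁ carriers and c₀ non-carriers among m nonmissing
genotypes.  SNP sites use the same estimator at the allele level
(m = 2 × nonmissing genotypes, a = summed dosage).  Window π sums site
values over sites whose *start* falls in the window and divides by the
window length in bp (500 kb default); windows tile each chromosome from
position 1 with step = window unless a sliding step is requested.
Dividing by window length (rather than callable sites) makes windows
comparable when site density varies, at the cost of underestimating π
where coverage is poor — the same trade-off the windowed convention in
standard diversity pipelines makes.

## Linkage disequilibrium

r² is the squared Pearson correlation of two 0/1 carrier vectors over the
samples nonmissing at *both* sites; pairs monomorphic on that shared set
are undefined and skipped.  The decay profile averages r² over all
intra-chromosome pairs within 500 kb (configurable) in fixed-width
distance bins (100 bp default, matching moving-average presentations; a
rolling mean over bins is provided for plotting).  LD½ is the smallest
bin midpoint whose mean r² is at or below half of the *largest bin mean*
— a literal reading of "half of its maximum value" that is robust to a
noisy first bin.  Two practical notes: binned means underestimate the
d→0 limit by roughly half a bin of decay, and cross-block sample noise
adds a ~1/m floor, so recovered LD½ carries a positive bias of about one
bin width; recovery studies therefore use bins wide enough (a quarter of
the expected half-distance) that the bias stays within one bin.

## Population structure

SNP genotypes are coded 0/1/2 alternate-allele dosage; monomorphic sites
are dropped and missing calls mean-imputed (imputation to the site mean
is neutral for the Euclidean geometry k-means uses).  k-means runs with
25 random restarts at a fixed seed; the average silhouette width over the
candidate k range (default 2–15) selects k, ties toward the smaller k.
Final labels are renumbered by decreasing cluster size, which makes label
identity stable under sample reordering and reruns.  No PCA reduction
precedes clustering by default (silhouette is computed on the same
dosage geometry the clustering used); reducing first is a caller-side
option for very large panels.

## Cluster-specific deletions

The screen is a conjunction of three stages, evaluated per site:

1. **GOF:** expected carriers per cluster are proportional to the exact
   nonmissing counts — e.g. 26 × 53/286 — not to rounded percentages; with
   the exact counts the canonical example (carriers 1,2,1,0,2,19,0,1 over
   nonmissing 32,31,31,30,35,53,44,30) gives χ² = 52.67 and
   p = 4.314 × 10⁻⁹ with 7 degrees of freedom.  Significance is tested at
   uncorrected α = 0.05 by default (a Bonferroni switch exists); the
   multiple-testing correction in this pipeline is reserved for the
   window scan.
2. **Dominance:** the argmax cluster (ties to the lowest index) must hold
   ≥ 70% of carriers.
3. **Permutation:** T carriers are re-placed uniformly without replacement
   among the M nonmissing genotype slots — a multivariate hypergeometric
   draw over clusters; missing genotypes are never assigned carriers.  The
   default criterion monitors the *focal* (observed dominant) cluster;
   `permutation_scope="any"` monitors all clusters.  Fewer than 5% of 100
   permutations reaching the dominance threshold confirms specificity.

Sites are processed on independent RNG streams spawned from one seed, so
results are order-independent and reproducible.  The screen is invariant
to cluster relabeling.  The windowed companion scan sums carriers per
500-kb window, tests homogeneity against nonmissing-proportional
expectations, and applies Bonferroni across windows that contain
carriers; weighted abundance divides each cluster's carriers by its
nonmissing total before converting to percentages, so cluster size and
missingness do not masquerade as abundance differences.

## Synthetic panels

The generator targets the summary structure the statistics assume, not
population history — there is no coalescent, recombination map or
mutation model.  Defaults mirror the emulated study design: 347 genotypes
in 8 clusters of 43, 44, 37, 31, 40, 58, 55 and 39; 1,000 deletion sites
(950 exchangeable background + 50 cluster-specific), 2,000 SNP sites,
Poisson(30) read depths, 5% per-entry missingness, ten 5-Mb chromosomes
with uniform site placement and log-normal deletion sizes (median
~900 bp, clipped to the filter range).

Background sites draw a minor-carrier count i with P(i) ∝ 1/i over
1..⌊n/2⌋.  The missing mask (call failure plus depth < 10) is drawn
*first* and carriers are placed uniformly among the observable genotypes
— the same convention the permutation null uses — so the planted count is
exactly the count the spectrum sees.  Placing carriers before masking
would thin them binomially and measurably distort the planted spectrum.
Background placement ignores cluster labels (an exchangeable null), which
makes the specificity false-positive rate interpretable.

Specific sites draw a carrier total uniformly from [18, 35] — above the
18-carrier MAF floor that any site in the frequency-filtered analysis set
satisfies, and bracketing the canonical example's 26 — and place
round(0.9 × total) carriers in a randomly chosen focal cluster, the rest
uniformly elsewhere.  Requests that cannot be honored (dominance ×
carriers exceeding the focal cluster's observable size) raise an error
naming the site.  Because specificity screening operates on the
frequency-filtered set (as the full pipeline does), recovery studies
apply the MAF threshold before classifying.

SNP sites are each diagnostic for one cluster (round-robin): alternate
allele frequency 0.5 + s/2 in the focal cluster and 0.5 − s/2 elsewhere,
s = 0.8 by default — a strong-contrast regime in which silhouette
selection should recover the planted k essentially always.

The LD generator is a hard-block model: latent per-block haplotypes,
sites copying their block's latent state with a probability calibrated so
same-block pairs have expected r² equal to the configured value, and
independence across blocks.  For uniform site placement the expected
binned r² decays linearly to zero at the block length B, so the analytic
half-distance emitted with the truth is B/2.

**What passing on synthetic panels does not show:** real SV call sets
have correlated missingness (batch and depth structure), linked sites,
admixed individuals, genotyping error correlated with size and type, and
selection — none of which the generator produces.  The simulation studies
validate the statistical machinery under its own assumptions; they are
not evidence about error rates on real data.

## Problem sizes in the bundled studies

The calibration and recovery studies run at sizes chosen to make their
binomial success criteria sharp while remaining quick on a laptop:
20 panels of 5,000 background sites for spectrum calibration, three
default panels (1,000 sites) for specificity recovery, 10 seeds per
planted k for silhouette recovery (400 SNPs), and 10 block-model panels
(400 sites, 20-kb blocks) for LD½ recovery.

## Known limitations

* Break-end records are parsed but never analyzed; insertions do not
  occur in the emulated call sets at all.
* Functional impact classes are parsed from precomputed ANN strings;
  the package performs no effect prediction, GO enrichment or gene
  function lookup.
* The window scan's χ² uses summed counts within a window and therefore
  treats sites as independent; linked sites in a window share carriers
  and can inflate the statistic.
* `gof_test` follows the classical χ² even when expected counts are
  small (as the screened procedure does); the permutation stage, not the
  asymptotic p-value, is what controls false calls at low carrier counts.
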