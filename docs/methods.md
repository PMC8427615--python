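# Methods

This note documents the statistical models behind `msapop`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that affect results.

## Data model

The unit of analysis is a `BandMatrix`: individuals × loci scores in
{0, 1, missing}, with each individual labelled by a site nested in a
habitat, and optional per-locus fragment sizes (bp). Dominant markers do
not distinguish heterozygotes from dominant homozygotes, so all
allele-frequency work estimates the recessive (band-absent) frequency q
from the band-absent phenotype fraction x₀.

Band filters follow field practice for capillary AFLP scoring: loci
carried by fewer than 4 individuals, loci outside the 150–500 bp sizing
window (skipped with a warning when sizes are unknown), and loci where
exactly one individual deviates from the consensus state are removed,
each with a logged reason.

## MSAP scoring and MSL/NML classification

Each (HpaII, MspI) pair maps cellwise to a state: (1,1) unmethylated,
(1,0) hemimethylated, (0,1) internal-cytosine methylation, (0,0)
uninformative (fragment absence and hypermethylation are confounded, so
the binary view treats it as missing; a missing input score is also
uninformative, but is tracked separately because an *observed* (0,0) is
informative for the discordance denominator).

A locus is methylation-susceptible (MSL) when its discordance — the
fraction of type-2/3 individuals among individuals with both enzyme
scores observed — *strictly exceeds* ε, the expected per-individual
mismatch probability due to scoring error. ε is estimated globally by
pooling discordant cells across duplicate assays of the same
individuals; when no duplicates are supplied, a default of 0.05 is used
and logged loudly. Strict inequality means a locus exactly at the error
rate stays NML.

A consequence worth knowing: for a truly nonmethylated locus the
expected HpaII/MspI discordance *equals* ε (both are 2e(1−e) for
per-assay cell error e), so NML loci scatter around the threshold and a
substantial minority of them exceed it by binomial fluctuation. MSL
recovery (sensitivity) is essentially perfect whenever planted
methylation rates exceed the error rate, but the *fraction* of loci
labelled MSL is biased upward at any nonzero error rate — a property of
the thresholding method itself, not of this implementation. The
fraction-recovery check therefore uses the error-free limit, where it is
exact.

Downstream, MSL loci are analysed on the methylated/unmethylated binary
view and NML loci as ordinary dominant bands from the MspI profile (raw
HpaII banding is available by flag).

## Diversity

Allele-frequency estimators: `sqrt` (q̂ = √x₀, Hardy–Weinberg
assumption; the default, matching the classical dominant-marker
convention), `lynch_milligan` (Taylor-corrected, applied only when
x₀ > 3/n), and `bayes_uniform` (q̂² is the posterior mean of the
band-absent phenotype frequency under a uniform prior, (a₀+1)/(n+2);
never fixed for polymorphic samples). He = 2p̂q̂, Ne = 1/(p̂²+q̂²),
P = % loci with both band states observed, P5 = % loci with estimated
minor allele frequency ≥ 0.05. Shannon's I is computed on band-state
(phenotype) frequencies with natural logs, so MSL and NML can be
compared on one scale; the MSL-vs-NML comparison uses a Wilcoxon
rank-sum test (exact enumeration for small tie-free samples, otherwise
tie-corrected normal approximation with continuity correction).

Gst = (Ht − Hs)/Ht with Hs and Ht summed over loci and Ht from pooled
mean frequencies; Nm = 0.5(1 − Gst)/Gst. With few demes the plain Nei
Gst carries a (K−1)/K deflation which, at survey-scale sample sizes, is
partly offset by estimator sampling variance; at two demes of 30
individuals and 2,000 loci the net estimate of a planted θ = 0.10 is
≈ 0.08. The dominant `sqrt` estimator is also not exactly symmetric
under 0/1 relabelling of a locus (band orientation matters to it);
per-locus differentiation ranks are stable under relabelling, and the
phenotype-scale locus AMOVA Φ is exactly invariant.

## AMOVA

Sums of squares are computed from pairwise *squared* Euclidean distances
(missing-data rescaled by L/L_ij); on balanced designs the variance
components agree with a direct nested ANOVA on the 0/1 coordinates to
1e−10 (tested). Unbalanced designs use the standard three-coefficient
nested-design correction. Negative variance components are retained in
Phi computation; % variation is reported both raw and with negatives
truncated to zero and renormalized. Permutation schemes: individuals
among all units for ΦPT/ΦST, individuals among populations within groups
for ΦSC, whole populations among groups for ΦCT; p = (#{≥ observed}+1)/(n_perm+1).
All-zero distance matrices return Φ = 0 with a degenerate flag.

The locus-by-locus variant shares one set of individual permutations
across loci (so 2,000 loci × 999 permutations run in seconds) and
excludes monomorphic loci with a flag.

## Mantel suite

Mantel r is the Pearson correlation of the n(n−1)/2 off-diagonals; the
null jointly permutes rows and columns of the second matrix; for n ≤ 7
the p-value is an exhaustive enumeration over all n! permutations. The
partial variant residualizes both target matrices' off-diagonals on the
control matrix by simple linear regression and permutes the
*residualized* first matrix (Smouse–Long–Sokal), chosen for its type-I
control under confounding. A constant control degrades to the simple
test with a warning. Soil-difference matrices assign each individual its
site mean, so within-site entries are zero. The default tail is upper
(one-sided positive association); signed r is always reported, and no
sign convention is imposed on distance-vs-similarity inputs.

The off-diagonal correlation utility (for pairwise-Φ matrices and trait
tables) is a plain Pearson correlation with a t-test p, no permutation.

The 2×2 chi-square defaults to the Pearson statistic without continuity
correction — the form that reproduces published outlier-vs-epilocus
statistics from their printed counts — with the likelihood-ratio G
statistic selectable.

## Outlier scan

Per-locus Fst = (Ht − Hs)/Ht on estimated allele frequencies, with Ht
(the pooled expected heterozygosity) as the conditioning variable. The
neutral envelope simulates loci under a Balding–Nichols beta island
model: ancestral frequency uniform on (0.01, 0.99), group frequencies
Beta-distributed at the target Fst, dominant phenotypes binomial under
Hardy–Weinberg proportions — then pushes every simulated locus through
the *same* estimator as the data, so estimator bias cancels between
observation and null. Quantiles (default 0.005/0.995) are taken per
equal-count heterozygosity bin; bins are widened when underfilled.

The neutral target Fst cannot be the observed multilocus Fst directly:
with small groups the dominant estimator's sampling variance inflates
the observed value (at 12 sites × 7 individuals it roughly doubles), and
using it as the Beta parameter would double-count that noise and
mis-center the envelope. `calibrate_target_fst` instead tunes θ by a
multiplicative fixed-point iteration until simulated loci reproduce the
observed mean — the standard FDIST practice — and the scan re-estimates
the target once after trimming provisional outliers. Null calibration
under this scheme is accurate (≈0.5–1% directional flags at the 0.995
envelope). Power at five-fold θ enrichment depends strongly on sampling
design: ≈0.85–0.94 at 20 demes × 60 individuals (the benchmark used in
the acceptance suite), but only ≈0.5 at a 12-site × 7-individual field
design, where per-group information is the limiting factor.

## Environmental association

Per locus × soil variable, band presence is regressed on the variable
(individuals carry site means) by maximum-likelihood logistic
regression; the model is significant only when both the likelihood-ratio
G test and the Wald test pass the corrected threshold, default
Bonferroni α/(n_loci × n_variables) and fully configurable (published
thresholds do not always correspond to an obvious test count, so the
threshold is never hard-coded). Perfect separation suppresses the Wald
statistic and flags the record.

## Ordination

PCoA is the classical Gower double-centering with eigendecomposition;
coordinates are eigenvectors scaled by √λ for positive eigenvalues,
proportions are over positive eigenvalues only, negative eigenvalues are
reported (Lingoes correction by flag). DistLM works on the centered
inner-product matrix G using the trace identities tr(HGH) = tr(GH),
tr((I−H)G(I−H)) = tr(G) − tr(GH); marginal tests permute the units of
the distance matrix, and forward selection (added proportion of total SS
as criterion) tests each step by permuting the reduced-model residual
matrix. Candidates adding < 1e−12 proportion are skipped as collinear.
Storey q-values estimate π₀ on the λ grid 0.05…0.95 with a cubic
polynomial read off at λ = 0.95 and clamped to (0, 1]; below 20
p-values the grid is unreliable and π₀ is fixed at 1 (Benjamini–Hochberg
fallback). RDA exploits the equivalence of centered-matrix Euclidean
DistLM and RDA; missing band scores are mean-imputed per locus before
centering; forward selection uses the double stopping rule (per-step α
and the global adjusted-R² ceiling), with the ceiling applied from the
second variable onward so that a significant global model never yields
an empty selection. UPGMA is implemented directly so that merge ties
break deterministically on the lexicographically smaller id pair;
bootstrap resamples loci (columns), and support is the percentage of
replicates containing each internal bipartition.

## Synthetic data generator

The generator emulates a four-habitat, three-sites-per-habitat survey of
80 individuals (site sizes 6–8, configurable), ~2,478 AFLP and ~2,884
MSAP loci with the MSL fraction ≈ 2/3, nested neutral structure
(θ_habitat = 0.10, θ_site = 0.05 by default), 24 planted outlier loci at
θ = 0.50, habitat-linked soil gradients over the 14 canonical variables
(means chosen to reflect a wet meadow / saline-alkaline patch / meadow
steppe / sandy-soil contrast, within-habitat between-site sd 8% of the
mean), and per-cell MSAP scoring errors at rate 0.02.

MSL methylation indicators come from a mixture of epilocus classes:
*obligate* (deterministic in an underlying genotype with the same nested
structure), *facilitated* (methylated with probability 0.8 given the
genotype carrier state, 0.2 otherwise — an operational stand-in, since
no quantitative model of facilitated variation is established), and
*pure* (logistic in a standardized soil variable, default slope 2 per sd
so presence probability spans ≈0.05–0.95 across the gradient).
Methylated cells render as (1,0) or (0,1) equiprobably, unmethylated as
(1,1), fragment-absent as (0,0); errors flip cells independently in both
matrices.

By default the Balding–Nichols island model is placed directly on
band-presence frequencies, so the planted θ is the quantity the
distance-based Φ statistics estimate (recovery 0.100 ± 0.003 at 2,000
loci); with `band_model="hwe_dominant"` the Beta draw is a
presence-allele frequency and dominant diploid phenotypes are sampled,
which reproduces the classical upward bias of band-based Φ relative to
allelic Fst (≈0.134 for θ = 0.10). Recovery tests use the former;
estimator-facing simulations (Gst, the outlier scan) use the latter,
matching the envelope's own sampling model.

One master seed drives independent per-component sub-streams
(`numpy.random.SeedSequence.spawn`), so changing the locus count does
not reshuffle soil draws; equal parameters and seed give byte-identical
output.

What the generator does **not** emulate: spatially explicit gene flow,
clonal structure, linkage between loci, per-primer error heterogeneity,
fragment-size homoplasy, and any coupling between outlier loci and the
epilocus classes. Passing tests therefore demonstrate correctness and
calibration of the statistics under an idealized island model, not
robustness to those real-data features.

## Problem sizes and runtime

The test suite and the reproduction script run simulations at 2,000 loci
and 80–1,200 individuals with permutation counts of 99–999 and envelope
sizes of 12,000, completing in well under a minute each on one CPU; the
library defaults (9,999 AMOVA / 10,000 Mantel / 100,000 partial-Mantel
permutations, 20,000 envelope simulations) match standard practice for a
full analysis and run in minutes.

## Known limitations

* Global (not per-locus or per-primer) error threshold ε.
* The NML-inflation property of threshold classification described above.
* Plain Nei Gst at very few demes underestimates θ; use AMOVA Φ for
  designs with K < 4.
* The FDIST-style envelope is an island-model surrogate, not a
  coalescent simulator; counts of flagged outliers need not match tools
  built on other null models.
* Two hierarchy levels at most; codominant data are out of scope.
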