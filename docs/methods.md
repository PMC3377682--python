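# Methods

## The problem

Cultivated carrot (*Daucus carota* ssp. *sativus*) was bred for root color,
so genes of the carotenoid biosynthesis pathway are natural candidates for
artificial selection. Any selection scan on such a sample faces the standard
confounder: the sampled cultivars are not a panmictic population. Western
and Eastern gene pools diverged recently, and population structure alone
can mimic balancing selection (intermediate-frequency excess) or produce
extreme FST. The package therefore tests candidate genes not against the
standard neutral model but against a *fitted demographic null*: a
two-population divergence model estimated from unlinked control loci, so
that only signals exceeding what demography explains are flagged.

The full analysis chain is:

1. fit the divergence model to control loci (17 microsatellites, 3 anonymous
   sequence loci) by approximate Bayesian computation (ABC);
2. simulate per-gene null distributions from the posterior and rank each
   observed statistic — Tajima's D, normalised Fay–Wu H, Hudson's FST —
   within its null (pooled sample, geographic groups, and root-color groups);
3. run HKA and maximum-likelihood HKA tests of polymorphism/divergence
   ratios against a single outgroup (tuberous-rooted chervil);
4. compute pairwise Nei–Gojobori dN/dS across dicot orthologs;
5. correlate all outcomes with the gene's position along the pathway
   (Kendall's tau_b, Kruskal–Wallis heterogeneity, Wilcoxon contrast of
   genes upstream vs downstream of the lycopene node).

## Demographic model and simulator

Western and Eastern populations of constant diploid effective sizes `N_W`
and `N_E` merge, `T_d` generations back, into an ancestral population of
size `N_A`; no migration after the split, no growth, no recombination
within loci. Every autosomal locus carries `2N` gene copies in a population
of `N` diploid individuals, so `k` lineages coalesce at rate
`k(k-1)/(2 * 2N)` per generation — one time-scaling convention for both the
haploid-sampled sequence loci (one sequence per individual, no phasing) and
the diploid microsatellites. The coalescent is simulated in continuous time
with exponential waiting times per epoch; populations are independent
within an epoch, so each is coalesced on its own clock.

Sequence mutation has two modes. *Jukes–Cantor* (used for the ABC reference
table and for materialised synthetic alignments): mutations fall on
branches at rate `mu_seq * L`, hit uniform sites, and change the current
base to one of the other three; recurrent hits are resolved by evolving the
affected site down the tree. *Infinite sites* (used for candidate-gene null
distributions): every mutation is a fresh biallelic column with known
derived state. Ancestral-state misorientation — mistaking derived for
ancestral because the outgroup lineage itself mutated — is injected into
infinite-sites nulls post hoc by flipping each site's polarity
independently with probability `m`, matching how the observed H statistic
is biased.

Microsatellites follow a generalised stepwise model: mutation count Poisson
in `mu_ssr` per generation, step sizes geometric with parameter `p_ssr`
(support 1, 2, ...; `p_ssr = 0` gives the strict stepwise model), direction
±1 equiprobable. Allele values are folded back into the observed allele
range by boundary reflection applied to the per-lineage sums — exact for
unit steps, an approximation for rare multi-step excursions beyond the
boundary.

The misorientation rate is estimated from the Jukes–Cantor-corrected
ingroup–outgroup divergence `d` as `m = (1/4)(1 - exp(-4d/3))`: the JC
probability that the outgroup lineage changed state, times 1/3 for the
chance the change matches the ingroup's other allele. The estimator is
monotone, `m(0) = 0`, ceiling 1/4 at saturation, and is pluggable — it
stands in for an external method that is cited but not specified in the
source literature of this analysis style.

## Summary statistics

Sequence loci: segregating sites `S` (biallelic sites only; triallelic
ingroup sites are excluded entirely — the simplest defensible rule, logged),
Watterson's `theta_w = S / a_1` reported per locus and per site, nucleotide
diversity pi as the mean pairwise difference count, haplotype counts by
exact string equality, Tajima's D with the full 1989 variance constants
(identically zero at `n = 3`, where D is returned as flagged-undefined),
and the normalised Fay–Wu H of Zeng et al. (2006):
`H = (theta_pi - theta_L)/sqrt(Var)` with `theta_L = (1/(n-1)) sum i*xi_i`
and the variance using `theta = S/a_n` and
`theta^2 = S(S-1)/(a_n^2 + b_n)` plug-ins. Hudson's FST is `1 - Hw/Hb`;
with two groups `Hw` averages the two unbiased within-group mean pairwise
differences, with more groups (the color-group test) all within-group pairs
are pooled, as are all between-group pairs. Undefined statistics are NaN,
never silently zero.

Microsatellites: mean allele number per population, multi-locus
multiallelic Weir–Cockerham (1984) theta (variance components summed over
alleles and loci; loci monomorphic everywhere are excluded), and the
shared-allele distance `DAS = 1 - mean proportion of shared alleles` over
cross-population individual pairs.

The ABC summary vector has nine entries in fixed order: SSR mean allele
number (West, East), SSR Weir–Cockerham FST, SSR shared-allele distance,
mean haplotype number (West, East, pooled) and mean pooled `S` across the
control sequence loci, and a multi-locus Hudson FST with `Hw` and `Hb`
summed over loci before the ratio. The ratio-of-sums form keeps the
statistic defined when an individual locus is monomorphic, which matters
because the observed and simulated vectors must be computed by the same
code path — both call the same kernels.

## ABC fit

Priors: `T_d ~ Normal(500, 100)` truncated to [350, 750] generations (the
documented cultivation-history prior — biennial carrot, spread to Europe
around the 10th–12th centuries); effective sizes log-uniform on
[1e2, 1e5]; `mu_seq` log-uniform on [1e-9, 1e-7] and `mu_ssr` log-uniform
on [1e-5, 1e-3] (spanning plant-typical rates); `p_ssr` uniform on
[0, 0.9]. All are configurable; the non-`T_d` priors are this package's
choices where the original supplementary material is not available.

The fit is rejection ABC with Beaumont-style local linear regression:
statistics are standardized by their median absolute deviation (robust to
the heavy-tailed prior predictive; SD fallback when the MAD is zero), the
`ceil(tolerance * rows)` nearest draws in Euclidean distance are accepted
(default tolerance 1e-2), Epanechnikov weights `1 - (d/delta)^2` are
assigned (the largest-distance accepted particle gets weight zero — the
open-kernel convention), and each parameter is adjusted by a weighted
linear regression on the centred statistics. Positive parameters (sizes,
rates) are regressed on log10 scale and back-transformed; adjusted
particles are clamped to the prior support. A rank-deficient regression
design falls back to rejection-only with a warning. Reference-table rows
whose statistics are undefined (near-zero-mutation corners of the prior)
are retried and, if persistent, replaced by fresh prior draws so the table
keeps its configured size.

Model checking: PCA fitted on the prior-simulated statistics with prior,
posterior-predictive and observed clouds projected on PC1–PC2 (coordinates
written as TSV), plus a two-tailed rank p-value for each observed statistic
within its posterior-predictive distribution.

## Rank neutrality tests

For each candidate gene, parameter combinations `(N_W, N_E, N_A, T_d,
mu_seq)` are resampled from the weighted posterior; each draw yields one
infinite-sites simulation at the gene's own fragment length and the
observed West/East sample sizes, with misorientation injected at the
gene's estimated rate. The observed statistic is ranked with
`r_low = (#{sim < obs} + 0.5 #{sim = obs} + 1)/(n + 1)` and symmetrically
`r_high`; Tajima's D and FST are two-tailed (`min(1, 2 min(r_low,
r_high))`; two-tailed FST deliberately detects significantly *low*
differentiation, the signature of structure-independent balancing
selection), normalised H is one-tailed low. Both tails carry the
pseudo-count, so p-values are never zero. Because FST rank tests are
sensitive to the mutation rate, the FST null is restricted to simulations
whose per-locus `theta_w` lies within ±1.5 of the observed value (per-locus
units); the retained count is reported.

Color-group tests subsample, from every simulated dataset, as many
sequences from the simulated Western and Eastern samples as the observed
color group contains of each — the composition comes straight from the
metadata. D and H are recomputed per color group; the color FST pools
within/between pairs across all color groups. Orientation is performed
once on the full alignment and subset afterwards.

## HKA and ML-HKA

With a single outgroup sequence and `theta_i` per site, the classic test
uses `E[S_i] = theta_i L_i a_i` and `E[D_i] = theta_i L_i (T + 1)` (`T` in
2N-generation units; the `+1` absorbs ancestral polymorphism with equal
ancestral and ingroup sizes). Moment estimates solve
`S_i + D_i = w_i (a_i + T + 1)` per locus together with
`sum D = (T + 1) sum w_i` (scalar root-finding in `T`); the chi-square sums
`(obs - exp)^2 / Var` with `Var(S_i) = E[S_i] + w_i^2 b_i` and
`Var(D_i) = E[D_i] + w_i^2`, df = 1 for a pairwise test.

The ML extension gives loci in a selected set a free multiplier `k_i` on
the polymorphism rate, entering the ancestral half of divergence as well:
`S_i ~ Poisson(k_i theta_i L_i a_i)`,
`D_i ~ Poisson(theta_i L_i (T + (1 + k_i)/2))`. `theta_i` profiles out in
closed form, leaving a bounded multi-start Nelder–Mead maximisation over
`(log T, log k)` (starts at k in {0.3, 1, 3}; tolerance 1e-8 on lnL). The
neutral model fixes all `k_i = 1`; `LRT = 2 delta lnL` with
df = |selected set|. `k < 1` is a sweep-like diversity deficit, `k > 1` a
balancing-like excess.

## NG86 dN/dS

Site counts per codon are the fractions of one-step changes that are
synonymous (changes to stop codons count as nonsynonymous); differences in
multi-hit codons are averaged over all orderings of single-step paths,
excluding paths through stop codons (if every ordering hits a stop, all
changes count as nonsynonymous). Proportions use site counts averaged
between the two sequences and are Jukes–Cantor corrected,
`d = -(3/4) ln(1 - 4p/3)`; `p >= 3/4` is flagged saturated, and omega is
undefined (not 0, not inf) when dS is undefined or zero. Codons containing
ambiguity symbols are skipped. Chloroplast-leader removal is an input
preparation concern; a frame validator checks its absence.

## Pathway position

Default ordinal indexes follow the enzyme chain from IPI: IPI 1, PDS 2,
CRTISO 3, LCYB1 4, LCYE 4 (both cyclise lycopene — a genuine tie), CHXE 5,
ZEP 6. Exact published indexes can be supplied as overrides; an override
violating the canonical relative order only warns, since the machinery is
usable for other pathways. Kendall's tau_b depends only on rank order, so
results are insensitive to affine changes of the indexes, only to ties.
Group tests use midranks: Kruskal–Wallis across genes on the pooled
p-values of all tests per gene, and a two-sided Mann–Whitney rank-sum
contrast of upstream-of-lycopene (IPI, PDS, CRTISO) versus downstream
(LCYB1, LCYE, CHXE, ZEP). p-values are reported raw throughout (one test
per gene and statistic, as is conventional for candidate-gene scans); a
Benjamini–Hochberg column is available behind a flag.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design: 46 individuals, a 23/23
West/East split (the published text does not give the exact split; balance
is the neutral choice), colors white 8 / yellow 10 / orange 16 / red 6 /
purple 6 shuffled over individuals, three control sequence loci of
550–650 bp, 17 dinucleotide/trinucleotide microsatellites with plausible
allele ranges, and seven candidate genes at their surveyed fragment lengths
(PDS at 911 sites, matching its comparable-site count). Default true
parameters — `N_W = N_E = 600`, `N_A = 30 000`, `T_d = 500`,
`mu_seq = 5e-8`, `mu_ssr = 2e-4`, `p_ssr = 0.22` — were chosen once to
reproduce the observed orders of magnitude: per-locus `theta_w` in the
5–17 range, appreciable West–East differentiation after ~500 generations
of small-population drift, and high ancestral diversity. The outgroup
splits 1e6 generations back, giving percent-scale divergence like the
carrot–chervil comparison.

Selection regimes distort candidate genes structurally rather than by
forward simulation: a *sweep* shrinks within-population sizes by 1/6
(echoing the six-fold diversity deficit the ML-HKA k is meant to recover);
*balancing* forces two allelic classes whose common ancestor lies
`32 * N_A` generations back. The depth matters: under this divergence
model the neutral null itself sits at mean D near +1 (recent split, large
ancestral population), so a detectable intermediate-frequency excess
requires the class split to be far older than the neutral TMRCA — an
ancient, trans-domestication balanced polymorphism. Class membership can
be correlated with root color to exercise the color-FST test.

What the generator does not emulate: recombination and intragenic LD decay,
sequencing or cloning error, missing data and alignment gaps (gap handling
is tested separately on constructed alignments), selection at linked sites,
and any base-composition realism. Passing tests therefore demonstrate that
the machinery is correct and calibrated under the stated model, not that
the model captures every feature of real resequencing data.

## Numerical choices and problem sizes

Desk-scale defaults keep every stage on one CPU in minutes: 1e5 ABC
simulations by default in the pipeline (the full-scale analysis uses 1e6;
a flag raises it), 1e4 null simulations per gene, and the validation suite
uses reference tables of 2.5–5e3 rows, 2000-replicate calibration runs,
and 200–1000-replicate recovery experiments. Seeds are explicit
everywhere; identical configuration and seed reproduce byte-identical
outputs. Ties in rank tests use midranks; undefined statistics propagate
as NaN and are dropped from nulls with logging; the theta_w-matched FST
test reports and errors on an empty match window rather than widening it.

## Known limitations

- The divergence model has no migration, growth or recombination; these
  are model assumptions inherited from the analysis design, not
  capabilities waiting for data.
- The misorientation estimator is a documented approximation; alternative
  estimators can be plugged in.
- Weir–Cockerham FST on microsatellites ignores allele-size information
  (no R_ST analogue).
- ML-HKA assumes free recombination between loci and no intralocus
  recombination, as in the underlying Poisson formulation.
- The NG86 estimator undercorrects multiple hits at high divergence; pairs
  near saturation are flagged rather than extrapolated.
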