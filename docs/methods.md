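# Methods

`popdecline` detects and predicts population decline from SNP-array
genotypes of wild populations.  It chains five analyses — single-sample
reconstruction of effective population size (Ne) over time from linkage
disequilibrium, a confidence-interval rule for calling significant
declines, latitude-conditioned partial redundancy analysis (RDA) for
decline-associated loci, a windowed selective-sweep contrast between
declining and non-declining groups, and weighted polygenic
risk-of-decline scores — and ships a forward Wright–Fisher generator so
that every stage can be exercised and calibrated against known truth.

## The synthetic cohort generator

Each population is an independent Wright–Fisher process: `2 Ne(t)`
haplotypes, discrete non-overlapping generations, monoecious random
mating with selfing allowed.  Gametes recombine between adjacent mapped
loci with probability `c = (1 − e^(−2d))/2` (Haldane, no interference;
`d` in Morgans) and chromosomes assort freely.  There is no mutation:
loci start from standing variation (initial frequencies uniform on
[0.05, 0.5] by default) and drift, which matches the SNP-array setting
where markers are pre-ascertained polymorphisms — an important
difference from sequence data that shapes the sweep statistic below.
Calibration is verified in the test suite against closed forms:
heterozygosity decays as `(1 − 1/2Ne)^t`, one-generation frequency-change
variance is `p(1−p)/2Ne`, and the mean composite r² between unlinked
loci is `1/(3Ne) + 1/S` at sample size `S`.

Two signals can be injected.  *Decline loci* get a `+δ` offset (default
0.15, clamped to [0.01, 0.99]) to their initial frequency in the
declining populations — the polygenic association that RDA and the risk
model are meant to recover.  *Sweeps* apply multiplicative fitness
(1, 1+s, 1+2s by dosage) at one locus in one group from a set
generation, optionally resimulated until the allele exceeds a target
frequency.  Sweep experiments condition near fixation (final frequency
> 0.95): in a panel without mutation a partial sweep leaves little
trace, whereas a completed one leaves the local desert of group-fixed
SNPs that the scan is built to see.

The default decline history holds Ne at 2000 and steps to 100 ten
generations before sampling; non-declining populations sit at constant
Ne (500 in the demo cohort).  Per-population random streams are keyed on
the population *name* and the master seed, so adding a population never
perturbs the others, and identical configurations are bit-reproducible.

What the generator does **not** emulate: migration and admixture between
rivers, overlapping generations and age structure, sex-biased
recombination (the map is already sex-averaged), array ascertainment
bias, genotyping error, and missingness (the QC and imputation code
handles missing calls, but simulated panels are complete).  Passing the
simulation-based tests therefore says the estimators are correct under
drift-recombination dynamics, not that real salmonid data meet these
assumptions.

## Ne trajectories from linkage-binned LD

For a locus pair with recombination fraction `c`, drift-recombination
equilibrium gives approximately

    E[r²] ≈ γ(c)/Ne + 1/S,   γ(c) = ((1−c)² + c²) / (2c(2−c)),

with `γ(0.5) = 1/3` for unlinked pairs.  LD at recombination fraction
`c` turns over on a timescale of roughly `1/(2c)` generations, so pairs
binned by map distance probe Ne at depth `t = 1/(2c̄)` generations,
mapped to calendar years with a 5-year generation time anchored at 2010
(the unlinked bin is therefore "2005", one generation back).

Pairwise LD is the Burrows composite estimator computed from unphased
dosages `g ∈ {0,1,2}`:

    Δ̂ = (1/2S) Σᵢ g_aᵢ g_bᵢ − 2 p̂_a p̂_b,
    r̂² = Δ̂² / (p̂_a(1−p̂_a) p̂_b(1−p̂_b)),  capped at 1,

over samples typed at both loci; pairs monomorphic among the compared
samples are skipped and counted.  No `S/(S−1)` inflation is applied; the
sampling contribution is handled entirely by subtracting `1/S̄`
(harmonic mean of per-pair compared-sample counts) from the bin mean
r̂².  This simple correction is an approximation to the exact
small-sample expectations used by dedicated LD-Ne software, and it keeps
r̂² ≤ 1 on toy cases; its residual bias at S = 50 is within the ±30%
recovery band the tests enforce (measured medians: 117 at true Ne 100,
466 at true Ne 500).

Pairs are binned on map distance with 0.05-Morgan bins up to 0.25 M
(deeper bins rarely hold enough pairs); all cross-chromosome pairs form
the unlinked bin with `c = 0.5` exactly.  Distances convert to `c`
through Haldane, consistently with the simulator.  The bin estimate is
`N̂e = γ(c̄)/(r̄² − 1/S̄)`; a non-positive denominator reports `+∞`
("too large to resolve at this sample size"), which is a meaningful
outcome, not an error.

**Confidence intervals** come from a delete-one-individual jackknife on
the `1/Ne` scale with normal quantiles, back-transformed; a lower `1/Ne`
bound ≤ 0 becomes an infinite upper Ne bound.  Individuals — not loci —
are the exchangeable unit: every pair's r̂² is computed from the same
sampled individuals, so that shared sampling noise dominates the
variance of the bin mean, and a locus-deletion jackknife cannot see it
(measured: locus-deletion intervals are ~2× too narrow, 75–85% coverage;
individual-deletion intervals achieve 92–100% across the tested
scenarios).  Leave-one-individual re-estimation is cheap because the
pair-sum matrices admit rank-one downdates.  Bins drawing on fewer than
10 loci report (0, ∞).

## Calling significant declines

The rule compares the bins nearest 1975 and 2005 (nearest calendar year;
ties to the more recent bin).  A population is *declining* when

(a) the deep bin's CI is unbounded above — including any negative bound,
    which is an artifact of a negative value on the `1/Ne` scale — while
    the recent bin's CI is fully bounded (checked first, so the audit
    column names the unbounded-to-bounded transition); or
(b) the recent estimate is lower and the CIs do not overlap
    (`CI_low(1975) > CI_high(2005)`).

Everything else, including significant increases, is non-declining.

**Power under the default crash scenario.**  LD at recombination
fraction `c` integrates drift over roughly the last `1/(2c)` generations
with geometric weights.  The 1975-horizon bin (`c̄ ≈ 0.07`, `t ≈ 7`)
therefore probes mostly *post*-crash drift when the crash happened ten
generations before sampling: its estimate collapses toward the new Ne
(measured ≈ 120–280 against a pre-crash 2000), both anchor bins agree,
and the rule rarely fires (0/40 replicates at S = 50).  This is the
package's measured operating point, reported as such by the acceptance
script, and it mirrors the known caveat that recent drift contaminates
historical LD-based estimates.  The decline is still plainly visible in
the *trajectory* — the deepest bin exceeds the unlinked bin in ≥ 80% of
replicates — and the false-positive side of the rule is well behaved
(2.5% at constant Ne 500).  Detecting it with honest (coverage-correct)
intervals at these sample sizes simply requires either temporal samples
or a crash young enough to postdate the deep bin's memory.

**Two-sample validation.**  With historical and recent samples of the
same population, each gets a single-time-point estimate from unlinked
pairs only and the same CI rules apply to the pair.  A 20-fold crash
between the samples is detected in the majority of replicates (the
historical Ne-2000 estimate is typically unbounded at S = 50 — branch
(a) by design).  The constant-Ne specificity check runs at Ne = 100,
where the estimator has the power to *bound* both estimates; at much
larger constant Ne the historical interval is frequently unbounded,
which the rule necessarily reads as decline when the recent interval
happens to be bounded.

## Decline-associated loci by partial RDA

Individual mode-imputed dosages form the response matrix; the
constraint is the 0/1 decline label inherited by every individual from
its population; latitude is partialled out (any extra covariates are
accepted).  Both genotypes (column-centered; unscaled by default —
covariance RDA is the common choice for dosage matrices, unit-variance
scaling is a flag) and the label are residualized on
[intercept, covariates] by least squares; the fitted matrix of the
regression of residual genotypes on the residual label has rank one, and
its SVD gives the single constrained axis: locus scores are the right
singular vector times the singular value, individual site scores the
left vector, signed so declining individuals sit on the positive side.
This reduces exactly to the per-locus covariance between residualized
label and residualized genotypes, which is the brute-force oracle the
tests compare against (correlation 1.0 to machine precision, and
identical to vegan's `rda(X ~ label + Condition(lat))` species scores up
to scale).

Outliers are loci more than 3 SD from the mean score (population SD,
divisor n; at panel sizes in the hundreds the divisor convention is
immaterial but fixed).  On standard-normal scores the rule flags 0.27%
— the tests check this tail mass — and on shifted panels (δ = 0.15 at
20 of 500 loci) causal loci are strongly enriched among outliers.

## Sweep contrast between groups

Each group's pooled genotypes are scanned on the *same* shared panel
(MAF > 0.01 across populations) with sliding windows of W consecutive
panel SNPs (step 1; W = 50 default, 20 on the sparse demo panel).  The
composite statistic is `µ = µ_var · µ_sfs · µ_ld` with all three factors
normalised to hover around 1 on a neutral genome:

* `µ_var` — local diversity reduction: genome-wide fraction of panel
  SNPs polymorphic in the group divided by the window's fraction
  (floored at 1/W).  On an array panel a completed sweep's signature is
  precisely this desert of group-fixed SNPs.
* `µ_sfs` — folded-SFS tail excess: fraction of window SNPs with minor
  allele count ≤ 2.5% of sampled chromosomes (never below singletons),
  *including* count 0, over the genome-wide fraction.  The tail class
  tames singleton shot noise at moderate sample sizes, and counting
  group-fixed SNPs keeps the factor informative for completed sweeps,
  where a mutationless panel regenerates no rare variants.
* `µ_ld` — LD structure among the window SNPs still polymorphic in the
  group: mean within-half r² over mean between-half r² (floor 1e−6), set
  to 1 when a half has fewer than two polymorphic SNPs.

Window µ values are averaged (optionally maximum) into fixed 1-Mbp bins
by window center, per group; `Δµ = mean µ(non-declining) − mean
µ(declining)` per bin, z-scored over bins; |z| > 3 flags an outlier and
the sign names the group carrying the signal.  Swapping the groups
negates Δµ exactly.  Decline-associated RDA loci are matched to outlier
windows within 1 Mbp of either edge (closed intervals, 1-based bp) —
SNP-driven windows are not pinned to round coordinates, so the same
slack is used when the tests score whether an injected sweep's bin
attains the genome-wide maximum |z| (65% of 20 replicates under the
s = 0.2 scenario at Ne 200, two populations per group).  The factor
formulas are this package's own design, printed in the output header;
they are canonical in spirit but not bit-compatible with any external
scanner.

## Polygenic risk of decline

RDA outliers are distance-thinned — the highest-|score| outlier per
1-Mbp window survives, ties broken by locus id — and capped at the top
100 by |score|.  A joint logistic regression of the individual decline
label on the selected dosages (intercept plus all loci) gives per-locus
log-odds weights β.  With ~100 predictors on a few hundred individuals
the likelihood often separates; separation is detected as optimizer
failure or any |β| ≥ 10 (odds ratios beyond e¹⁰ per allele copy are not
real dosage effects), and triggers an L2 refit with the smallest
power-of-ten penalty that produces a converged, bounded fit; the penalty
is recorded on the model and in output headers.  The closed-form check:
a one-locus 2×2 table with odds ratio 2 returns β = ln 2.

An individual's score is `Σⱼ βⱼ gᵢⱼ`, intercept excluded: scores are
compared between models and across populations, and a shared intercept
is a location shift that cancels in those comparisons.  Population
summaries report mean, median and quartiles.

Repeatability is leave-one-population-out: refit the weights (same locus
set — the selection stage is part of model *specification*, the weights
are the model *construction* being stress-tested) without population P,
score P's individuals under both models, and compare the two score
vectors with a two-sided Mann–Whitney test — exact when both sides have
≤ 20 tie-free observations, otherwise the normal approximation with tie
correction — at α = 0.05 divided by the number of populations.  On null
panels (no causal loci, 12 exchangeable populations) 8.3% of tests flag,
within the ≤ 10% calibration band; with few populations the rate
inflates because removing one population perturbs a large share of one
class, so the test is meaningful for cohorts of roughly ten or more
populations.

## Pipeline, seeds and problem sizes

`run_pipeline` executes simulate → QC → Ne → classify → RDA → sweep →
risk from one config whose defaults are the analysis protocol
(bin 0.05 M, MAF 0.05 and 0.01, generation time 5, start year 2010,
±3 SD, 1-Mbp windows, top-100 loci).  Every table carries the full
parameter echo in a header comment (the output directory is excluded so
reruns elsewhere are byte-identical); stage failures halt downstream
stages and leave a `FAILED` marker; if classification finds no declining
populations the downstream stages fall back to the simulated truth
labels so the chain remains exercisable, and the log says so.  The
master seed fans out to per-population streams keyed by name.

Test and acceptance problem sizes are chosen so the full suite runs on
one CPU in minutes while leaving the Monte-Carlo error well inside each
asserted band: constant-Ne recovery uses 300 mapped SNPs
(10 chromosomes × 30, 0.02 M spacing), S = 50, 50 generations, 20–50
replicates; classifier rates use 40 replicates per scenario; the sweep
scenario uses 1000 SNPs on two 10-Mbp chromosomes, four populations of
30, 20 replicates; the demo cohort is 12 populations × 30 individuals ×
500 SNPs and completes in well under a minute.

## Known limitations

* The `1/S̄` sampling correction is approximate; at very small S or
  extreme allele frequencies dedicated LD-Ne software with exact
  small-sample corrections will differ.
* Magnitude of decline is deliberately not estimated: recent drift
  contaminates the deep bins, so only the direction and significance of
  change are reported.
* The decline-call rule has little single-sample power against crashes
  older than the recent bin horizon but younger than the deep bins'
  memory (see above); trajectories and temporal samples remain
  informative there.
* The µ scan assumes a reasonably dense, evenly spaced panel; with W
  SNPs spanning several Mbp the 1-Mbp Δµ bins blur and localisation
  degrades.
* The LOPO test is a repeatability check, not a calibrated hypothesis
  test; its null rate depends on the number of populations.
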