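# Methods

`preemie-probiome` implements a longitudinal analysis of probiotic impact
on the preterm-infant gut microbiome: given species-level relative
abundance profiles, infant metadata and sample timing, it quantifies how
much compositional variance each clinical covariate explains over time,
compares diversity and ordination structure between gestational/weight
groups, assigns samples to community types, and classifies each
probiotic-receiving infant as an engraftment responder or non-responder.
A synthetic cohort generator with planted ground truth makes every stage
testable without access to clinical data.

## Cohort structure and exposure states

Infants are classified **EP/ELBW** when born before 28 weeks gestation
*or* under 1000 g, and **VP/VLBW** otherwise (within a <32-week / <1500-g
cohort). Samples carry a day of life (DOL) and are binned into nine
closed windows — days 0–9, 10–14, 15–19, 20–24, 25–29, 30–34, 35–39,
40–49 and 50–69 — chosen to track the clinically relevant exposure
period; samples after day 69 are kept in the dataset but excluded from
windowed analyses. Time-varying exposures (mother's own milk, breast milk
fortifier, formula, antibiotics) are recorded as closed day intervals per
infant and resolved per sample into one of `never / before / during /
after`; antibiotic exposure additionally yields a "within the last 7
days" flag, meaning any exposed day in `[DOL-7, DOL]`.

## PERMANOVA variance grid

The per-timepoint covariate analysis is a from-scratch permutational
multivariate ANOVA on Bray-Curtis distances. With `A = -D∘D/2` and the
centering projector `C = I - 11'/n`, the Gower matrix `G = CAC` has total
sum of squares `trace(G)`. Terms enter sequentially (Type I) in the
configured order; term q's SS is `trace((H_q - H_{q-1}) G)` for the hat
matrices of the growing design, giving pseudo-F
`(SS_q/df_q)/(SS_res/df_res)`. The null distribution permutes rows and
columns of `D` simultaneously; p-values use the `(1 + exceedances)/(1 +
n_perm)` convention (default 999 permutations), or exact enumeration of
all `n!` permutations on request, where the reported p is the proportion
of arrangements at least as extreme (the observed arrangement is part of
the enumeration, so p is never zero). A marginal one-covariate-at-a-time
mode is also available; which mode was used is recorded in the run
manifest.

Within each window, repeated measures are removed by keeping one sample
per infant: the sample closest to the window midpoint, ties broken to the
earlier day and then the smaller sample id. Windows with fewer than 15
retained samples (configurable) are skipped. Covariates with fewer than
two levels present in a window are dropped for that window. All
(covariate × timepoint) p-values are adjusted together by
Benjamini-Hochberg; cells with q < 0.05 are flagged.

The default covariate order for the grid is probiotic product, MOM state,
BMF state, formula state, antibiotics-in-last-7-days, season, birth mode
and sex. The pipeline prepends the EP/ELBW-vs-VP/VLBW group factor,
since its purpose is the between-group comparison.

## Diversity and ordination

Shannon diversity uses natural logarithm (the group contrast is invariant
to the base). The group comparison is a Gaussian linear mixed model of
per-sample Shannon diversity on group plus the grid covariates with a
random intercept per infant, fit by REML; the group coefficient's
two-sided Wald p is reported. When the fit is singular or non-convergent
(for example, zero residual variance), the model falls back to a seeded
infant-level permutation test on infant-mean diversity (999 permutations
by default), and the output records which method produced the p-value.

Ordination is non-metric MDS of Bray-Curtis distances (SMACOF
majorization with isotonic regression, Kruskal stress-1, best of several
seeded restarts; default 2 dimensions). Coordinates are column-centered,
and per-group centroids are arithmetic means. Because SMACOF cost is
quadratic in the number of samples, the pipeline subsamples (seeded) to
at most `nmds_max_samples` (default 400) during-use samples for the
ordination display. The implementation does not expose per-iteration
stress values; convergence is validated instead by embedding exact 2-D
configurations (stress < 0.01) and by bit-exact seeded reproducibility.

## Community typing

Community types are modelled as a K-component Dirichlet-multinomial
mixture (default K = 5, mirroring the five previously described preterm
gut community types, whose defining data are external to this package —
the mixture is an operational stand-in, and assignments are labelled as
such). Relative abundances are converted to integer pseudo-counts at a
fixed depth (default 10,000) by largest-remainder rounding, so each
sample sums exactly to the depth and per-taxon error is at most
1/depth. EM alternates posterior responsibilities with Minka fixed-point
updates of each component's Dirichlet parameters; the observed-data
log-likelihood is non-decreasing across iterations (asserted in tests),
components whose weight falls below 1/n² are pruned with a warning, and
the best of several seeded restarts is kept. New samples are assigned by
maximum posterior (ties to the lower type id). "Probiotic-associated"
types are those whose expected composition has a probiotic species as its
single most abundant taxon; per-group type proportions are reported for
samples during probiotic use.

## Engraftment responder classification

For each infant on a probiotic, the relative abundances of that product's
species (Infloran: *B. bifidum*, *L. acidophilus*; Labinic: those plus
*B. longum*) are summed per sample. Samples with DOL inside the recorded
`[start, last]` use interval are eligible. Duplicate days are averaged,
and the trapezoid rule gives the raw AUC (relative abundance × days); the
time-normalized AUC divides by the span between the first and last
sampled eligible days, yielding a time-averaged relative abundance in
[0, 1]. A single eligible sample (zero span) contributes its value as the
normalized AUC with raw AUC 0.

Within a stratum — per product by default, or a single combined stratum —
the responder threshold is the stratum mean minus one sample (n−1)
standard deviation, floored at 0; infants at or above the threshold are
responders (ties count as responders, with a 1e-12 guard so floating-point
round-off of mean − SD cannot flip an exact tie). Z-scores are the
standardized normalized AUCs within the stratum. Strata with fewer than
two infants fall back to the combined stratum with a warning. Groups are
compared with a two-sided Fisher exact test on the responder 2×2 table
and a two-sided Mann-Whitney test on z-scores — exact enumeration of all
group assignments (with midranks for ties) when the combined n is at most
20, and the tie-corrected normal approximation otherwise.

## Synthetic cohort generator

The generator emulates a two-group NICU cohort: 91 EP/ELBW and 32 VP/VLBW
infants by default, with gestational age and birthweight drawn from
truncated log-normal distributions matched to the group medians and IQRs
(EP/ELBW 26 weeks (25–27), 840 g (660–945); VP/VLBW 29 weeks (28–30),
1315 g (1170–1580)), rejection-sampled for consistency with the group
rule. Probiotic arms, sex, birth mode and season follow the per-group
frequencies of the emulated cohort; probiotic start/last days are
log-normal around start 7 (6–9) / last 50 (45–61) for EP/ELBW and start 6
/ last 28 for VP/VLBW. Each infant contributes ~9–15 samples at
early-weighted days over 0–120 (a Beta(1.2, 2.2) day distribution,
matching denser early NICU sampling), with at least four sample days
during probiotic use guaranteed (configurable) so the engraftment AUC is
defined for every treated infant.

Compositions are built from (i) K Dirichlet community-type components
over the background (non-probiotic) taxa, with a sticky per-infant type
chain; (ii) infant-level log-normal taxon weights (σ = 1) that create the
repeated-measures structure the analysis must absorb; (iii) optional
per-covariate multiplicative composition shifts (all zero by default —
the null cohort); and (iv) a planted engraftment trajectory for treated
infants: probiotic-species abundance rises as
`baseline + (plateau − baseline)(1 − e^{−rate·(t − start)})` from the
start day (rate 0.2/day), stays through the use interval, and decays back
after the last dose. Responders (probability 0.86) plateau at 0.5 summed
probiotic abundance — engrafted infants are typically dominated by the
administered *Bifidobacterium* — split over the product's species with
*B. bifidum* leading (0.6/0.4 for Infloran, 0.5/0.3/0.2 for Labinic);
non-responders plateau at 0.01. The observed sample is a Dirichlet draw
around the expected composition with concentration 50. All draws come
from a single seeded generator, so identical (config, seed) reproduce
byte-identical tables.

What the generator does **not** emulate: strain-level dynamics,
sequencing/profiling error beyond Dirichlet noise, abundance
autocorrelation within an infant beyond the infant-level weights and
sticky community type (the within-infant correlation scale is exposed as
parameters rather than asserted), clinical outcomes, and the exact
published community-type centroids. Consequently, passing recovery tests
demonstrates the estimators' correctness under the assumed generative
structure, not performance on real metagenomes; in particular the
generator's probiotic-associated type proportions during use (~55%) are
higher than the ~28% seen in the real cohort, because planted responders
sit at plateau for most of the use window.

## Numerical and design choices

- Degenerate inputs: all-identical samples give total SS 0 and are
  rejected; a covariate adding no degrees of freedom raises a
  rank-deficiency error naming the term; empty engraftment point sets
  exclude the infant with a log record; zero-variance strata classify
  everyone as responders with z = 0.
- Determinism: every stochastic stage takes a seed; the pipeline derives
  per-stage seeds from one global seed by hashing the stage name, so
  stages are independently reproducible and re-runs are byte-identical.
- Problem sizes: the bundled end-to-end analyses run the default
  123-infant cohort (~1400 samples) for recovery checks and a 500-infant
  group-null cohort (199 permutations per window) for the
  pipeline-shape check; both complete in seconds on one CPU.
- The five output tables (variance grid, NMDS coordinates, type
  proportions, engraftment table + summary, mixed-model summary) are the
  only inter-stage contract; figures are terminal artifacts.

## Known limitations

- Bray-Curtis is the only dissimilarity and no phylogenetic diversity is
  computed.
- The mixed model assumes Gaussian residuals for Shannon diversity; the
  permutation fallback covers degenerate fits but not general
  misspecification.
- The Dirichlet-multinomial mixture fixes the pseudo-count depth; model
  selection over K is not performed (K is user-set).
- Permutations are unrestricted within a window (valid because one
  sample per infant makes samples exchangeable); no strata-restricted
  permutation scheme is provided.
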