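# preemie-probiome

Longitudinal gut-microbiome probiotic-response analysis for preterm
infant cohorts.

Probiotic supplementation reduces necrotising enterocolitis in very
preterm / very low birthweight (VP/VLBW) infants, but whether the most
vulnerable infants — extremely preterm (<28 weeks) and/or extremely low
birthweight (<1000 g), EP/ELBW — show the same microbiome response is a
live clinical question. This package implements the analysis chain used
to answer it from species-level metagenomic profiles sampled over the
first weeks of life:

- **Exposure-state derivation** — per-sample `never/before/during/after`
  states for feeding and antibiotic exposures, nine day-of-life analysis
  windows (days 0–9 … 50–69), and the EP/ELBW vs VP/VLBW group rule
  (gestational age < 28 weeks OR birthweight < 1000 g).
- **PERMANOVA variance grid** — a from-scratch sequential (Type I)
  permutational MANOVA on Bray-Curtis distances, run cross-sectionally
  per window with one sample per infant, with Benjamini-Hochberg FDR
  across the whole covariate × timepoint grid. For term q with hat
  matrix increment `ΔH_q` on the Gower matrix `G = -½·C·D²·C`:
  `R²_q = tr(ΔH_q G)/tr(G)`, pseudo-F referenced to simultaneous
  row/column permutations of `D`.
- **Diversity & ordination** — Shannon diversity (nats) compared between
  groups by a linear mixed model with a random intercept per infant;
  non-metric MDS (Kruskal stress-1) of Bray-Curtis distances with
  per-group centroids.
- **Community typing** — a Dirichlet-multinomial mixture (default K = 5)
  fit by EM on fixed-depth pseudo-counts, as an operational stand-in for
  the previously described preterm gut community types (PGCTs), with
  identification of probiotic-associated types.
- **Engraftment responder classification** — the per-infant AUC of
  probiotic-species relative abundance during probiotic use, normalized
  by the sampled time span; infants below the stratum mean − 1 SD
  threshold are non-responders, z-scores are the standardized normalized
  AUCs, and groups are compared by Fisher exact and rank-sum tests.
- **Synthetic cohort generator** — a fully seeded simulator of a
  two-group NICU cohort (default 91 EP/ELBW + 32 VP/VLBW infants, three
  probiotic arms, planted responder trajectories and community types)
  that makes every stage testable end to end.

## Worked example

```python
import preemie_probiome as pp

# a fully synthetic cohort with the default two-group structure
cfg = pp.CohortConfig(seed=11)
infants, samples, profiles, truth = pp.generate_cohort(cfg)
print(len(infants), profiles.n_samples)       # 123 1384

# engraftment responder classification (per-product thresholds)
table = pp.engraftment_table(profiles, infants, samples)
comp = pp.compare_groups(table)
print(comp.responder_proportions.round(3))
# group
# EP/ELBW    0.877
# VP/VLBW    0.800
print(round(comp.fisher_p, 3))                # 0.464

# how much variance does each covariate explain per timepoint?
grid = pp.variance_grid(profiles, infants, samples, n_perm=199, seed=11)
print(grid.groupby("covariate")["R2"].mean().sort_values(ascending=False).head(3).round(3))
# covariate
# probiotic    0.174
# season       0.030
# mom          0.028
```

Probiotic receipt explains an order of magnitude more compositional
variance than any other covariate — the planted structure the generator
shares with the cohort it emulates — and responder proportions differ
between groups only within sampling noise.

The same analyses run from the shell:

```bash
preemie-probiome demo --outdir demo_out --seed 11
preemie-probiome run --config analysis.yaml
```

`demo` writes the cohort tables plus the full report bundle (variance
grid TSV + bubble plot, NMDS coordinates + centroid plot, community-type
proportions, engraftment table + group comparison, Shannon mixed-model
summary, and a manifest with the config hash and seed).

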