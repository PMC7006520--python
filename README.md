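# seawhip

Demographic analysis of branching octocoral colonies — built around the
sea whip *Leptogorgia virgulata*, a slow-growing gorgonian that forms
habitat on mid-Atlantic hard-bottom reefs and is easily damaged by
fishing gear. Managing such populations needs baseline demography:
how complex the colonies are, how old they are, and how fast they grow.
This package implements that analysis chain as a tested, reusable
library for anyone working with colony length, ring-count age, and
branch-architecture data:

* **Colony complexity** — Strahler-style branch ordering of rooted
  colony trees; the bifurcation ratio R_b (antilog of the slope of
  log₁₀ N_w on order w; exactly 2 for perfectly dichotomous branching)
  and tributary/source (T/S) ratios at primary and secondary order.
* **Ageing quality assurance** — double-reader ring counts
  cross-tabulated into an age-agreement table; McNemar, Evans–Hoenig
  and Bowker chi-squared tests of symmetry about the diagonal
  (systematic reader bias); percent agreement (PA), average percent
  error (APE) and average coefficient of variation (ACV = √2·APE for
  two readers); consensus ages by averaging.
* **Age-length keys** — observed (raw cross-tabulation) and smoothed
  (multinomial logistic regression on length-bin midpoint) proportion-
  at-age matrices over 5-cm length bins, and Isermann–Knight two-stage
  assignment of ages to colonies measured for length only.
* **Growth** — von Bertalanffy growth function
  E[L|t] = L∞(1 − e^(−K(t−t₀))) fitted by nonlinear least squares, with
  Wald tests and case-resampling bootstrap percentile confidence
  intervals, plus Walford-slope ↔ K conversion.
* **Site comparison** — all pairwise two-sample Kolmogorov–Smirnov
  tests with Bonferroni-adjusted critical α, one-way ANOVA, and Tukey
  HSD (Tukey–Kramer for unequal n).
* **Synthetic data** — seeded generators for branching trees with a
  target R_b and tributary rate, and multi-site age-length populations
  drawn from a VBGF with additive noise and ±1-year double-read
  disagreements, so the full pipeline runs without field data.

## Worked example

```python
import seawhip as sw

# a synthetic four-site population: 102 collected (double-read, aged)
# colonies and 119 in-situ length-only colonies, lengths from the VBGF
# (L∞ = 86.1 cm, K = 0.14 /y, t0 = 1.44 y) with 5 cm noise
ds = sw.gen_population(sw.PopulationGenSpec(seed=1))
aged = ds.aged_pairs()
pairs = list(zip(aged["read1_age"], aged["read2_age"]))

# reader agreement
prec = sw.precision_indices(pairs)
m = sw.mcnemar_symmetry(sw.build_agreement_table(pairs))
print(f"PA = {prec.pa:.2f}%  APE = {prec.ape:.2f}%  ACV = {prec.acv:.2f}%")
print(f"McNemar: chi2 = {m.statistic:.3f}, df = {m.df}, p = {m.p:.3f}")

# growth model on consensus ages
ages = sw.consensus_ages(pairs, "keep_fraction")
res = sw.VonBertalanffyModel(ages, aged["total_length_cm"].to_numpy()).fit()
ci = res.bootstrap(1000, seed=1)
print(res.summary(ci).round(4))
print(f"predicted length at age 10: {res.predict(10.0):.1f} cm")
```

prints

```
PA = 82.35%  APE = 1.32%  ACV = 1.87%
McNemar: chi2 = 0.889, df = 1, p = 0.346

       estimate      se        t    p     lo95      hi95
l_inf   93.4795  7.8764  11.8683  0.0  80.6956  115.0598
k        0.1210  0.0205   5.9025  0.0   0.0818    0.1634
t0       1.3828  0.2849   4.8539  0.0   0.6915    1.8501

predicted length at age 10: 60.5 cm
```

Reading it: the two readers agreed on 82% of colonies and the McNemar
test finds no systematic bias between them (p = 0.35); ACV < 5% marks
the ageing as precise. The fitted growth curve approaches an asymptotic
mean length of ~93 cm (bootstrap 95% CI 81–115, which covers the
generating 86.1 cm) at rate K ≈ 0.12 /y, predicting a ~60-cm colony at
age 10. One noisy sample of 102 colonies identifies L∞ only loosely —
exactly why the bootstrap intervals, not the point estimates, are the
quantity to report.

The same stages are available as CLI subcommands over CSV/Newick files:

```bash
seawhip simulate --out data --seed 1
seawhip complexity data/colonies.csv --trees data/trees --out out/complexity
seawhip ageqa data/colonies.csv --out out/ageqa
seawhip alk data/colonies.csv --out out/alk
seawhip growth data/colonies.csv --out out/growth
seawhip compare data/colonies.csv --variable length --context collected --out out/compare
```

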