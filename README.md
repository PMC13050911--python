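# pollenet

Analysis toolkit for **pollen microbiome** studies that ask how insect
visitation and host plant identity shape bacterial and fungal communities
on pollen.  It targets the common field design — several crop species, an
insect-exclusion ("bagging") versus natural ("open") treatment, and a few
replicates per cell — and covers the full downstream path from genus/OTU
count tables to:

* **alpha diversity** (bias-corrected Chao1, Shannon in nats, rooted
  Faith's PD) after without-replacement rarefaction, with two-way ANOVA and
  Welch/Games–Howell comparisons;
* **beta diversity** (Bray–Curtis on non-rarefied relative abundances,
  one-way PERMANOVA with permutation p-values);
* **co-occurrence networks** per pollination × treatment group
  (Spearman ρ with |ρ| ≥ 0.65 and Benjamini–Hochberg q < 0.05; per-domain
  prevalence/abundance filters; bacteria–fungi interaction networks retain
  cross-domain pairs only), with Louvain modules and topology summaries;
* **core (keystone) taxa** — nodes in the top 10 % by degree *or*
  betweenness centrality — and their taxonomic/predicted-functional
  contribution (mean ± SE of per-sample summed relative abundance);
* **insect-visitation statistics** — pollen remaining rate
  (100 · openᵢ / mean(bagging)), one-way ANOVA with Tukey letters, an
  unpaired bootstrap species-level Spearman correlation, and Cohen's *d*
  with pooled SD.

A first-class **synthetic-data generator** (`pollenet.synthetic`) emulates
the 4-species × 2-treatment × 5-replicate design with planted ground truth:
latent Gaussian-copula correlation blocks (so rank correlations are
plantable), a dominant cross-domain core guild in the cross-pollinated open
group, and pollen counts calibrated to per-species remaining-rate targets.
Every statistical stage can therefore be validated against known truth
(`pollenet.evaluation`).

## The statistics at the core

For genera *i*, *j* with relative-abundance profiles over a group's
samples, an edge is kept when

> |ρ̂ᵢⱼ| ≥ 0.65 and qᵢⱼ < 0.05,  q = BH step-up over the build's pair family,

with ρ̂ the tie-corrected Spearman coefficient and two-sided p from the
t approximation.  Core taxa are the union of the top ⌈0.1 N⌉ nodes by
degree and by betweenness.  PERMANOVA reports
R² = SS_among / SS_total and p = (1 + #{F* ≥ F}) / (1 + n_perm).
Cohen's *d* uses s_p = √(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)) with
s = SE·√n when dispersions are given as standard errors.

## Worked example

```bash
python examples/05_visitation.py
```

prints (seed 42):

```
remaining rate per species (mean +/- SE, Tukey letter):
  CA:  66.05 +/- 1.29  c
  LA:  81.59 +/- 2.09  b
  MC:  97.50 +/- 0.71  a
  SM:  93.10 +/- 0.69  a
one-way ANOVA p = 5.89e-11
Cohen's d (LA - MC) on simulated rates = -4.55
Cohen's d from published means/SEs (83.01+/-2.87 vs 97.23+/-0.59) = -3.07
```

CA loses the most pollen (lowest remaining rate, its own letter class);
the two high-retention species share a letter.  The final line reproduces
the published LA-vs-MC effect size from the printed means and SEs alone:
reading "±" as SE with n = 5 and pooling SDs gives *d* = −3.07.  The other
`examples/` scripts walk through simulation, diversity, networks and core
taxa the same way; each prints what it computes and says what the numbers
mean.

There is also a thin CLI (`pollenet simulate|diversity|network|core|
visitation|run-all`); `pollenet run-all --seed 0 --out run/` executes the
whole pipeline on a simulated dataset and writes TSV outputs plus a
provenance manifest.

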