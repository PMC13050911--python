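# Methods

This note documents the models, conventions and design choices behind
`pollenet`, in the spirit of the methods documentation of mature
statistical packages: what is computed, under which assumptions, and what
the synthetic validation does and does not demonstrate.

## Study design and data model

The package operates on genus/OTU count tables (taxa × samples, integer
reads) for two domains (bacteria, fungi), sample metadata
(species, treatment ∈ {open, bagging}, pollination ∈ {self, cross},
replicate), an optional rooted tree for phylogenetic diversity, a
per-genus predicted-function table, and per-replicate pollen grain counts.
Samples are grouped by pollination × treatment into Self_open,
Self_bagging, Cross_open and Cross_bagging.  Counts are integers
throughout; relative abundances (per-sample proportions) are the only
floating representation.  All-zero samples are kept (with a warning)
rather than dropped, so each downstream stage decides its own exclusions.

Taxonomy strings are Greengenes-style prefixed lineages
(`k__;p__;...;g__`); unprefixed strings are read positionally.  Taxa that
cannot be parsed at the requested rank are pooled under `unclassified`,
and such pooled pseudo-genera participate in networks by default.

## Diversity

* **Rarefaction** draws without replacement (multivariate hypergeometric),
  one seeded draw per sample, to 40,000 reads for bacteria and 39,000 for
  fungi by default.  Samples below the depth are excluded and listed —
  the depth is never lowered to rescue them.
* **Chao1** is the bias-corrected estimator
  S_obs + F₁(F₁−1)/(2(F₂+1)), defined for doubleton-free samples.
* **Shannon** uses natural logarithms (nats).
* **Faith's PD** is rooted: the branch path from every observed tip to the
  root is included, so a single observed tip already contributes its full
  root path.  This convention is pinned by closed-form tests (a star tree
  with unit branches gives PD = k for k observed tips).
* **Two-way ANOVA** (treatment × species) uses the classical decomposition
  (type-II sums of squares, identical to the balanced partition); when any
  cell has fewer than two replicates the interaction is flagged
  unavailable and an additive model is fitted.  **Welch's ANOVA** with
  Satterthwaite df and **Games–Howell** post-hoc tests (via pingouin)
  compare groups under unequal variances; compact letters are built with
  the insert-and-absorb algorithm at α = 0.05, ordered by group means.
* **Bray–Curtis** is computed on relative abundances from non-rarefied
  tables (robust to depth variation); pairs of all-zero samples are
  undefined and flagged.
* **PERMANOVA** is one-way on the composite group factor: pseudo-F from
  the among/within partition of squared dissimilarities,
  p = (1 + #{F* ≥ F})/(1 + n_perm) with 999 permutations by default, so
  the p-value has resolution 1/(n_perm+1) and is never 0.  The
  permutation loop is vectorised (einsum over one-hot group indicators),
  which makes the 1,000-simulation type-I calibration feasible on one
  CPU; the pseudo-F is cross-checked against scikit-bio's implementation
  in the test suite.

## Co-occurrence networks

Networks are built per group from genus relative abundances.  Bacterial
genera enter if nonzero in ≥ 5 of the group's samples **and** mean RA
≥ 0.05 % there; fungal genera only need mean RA ≥ 0.001 % (fungal tables
are sparser, so the occurrence gate is waived).  Edges require tie-
corrected Spearman |ρ| ≥ 0.65 (non-strict) and BH q < 0.05, with two-sided
p from the t approximation.  The FDR family is one network build: all
candidate pairs of that group × mode; constant-profile genera are excluded
from the family rather than assigned ρ = 0.  Cross-domain (bacteria–fungi
interaction) networks compute FDR over bacterium–fungus pairs only and
never admit within-domain edges, so they are bipartite by construction.
Isolated nodes are dropped.

Community detection runs seeded Louvain on the unweighted, sign-ignored
graph and reports Newman–Girvan modularity Q of the returned partition;
sign is kept for reporting (% positive edges).  On small graphs the
returned Q is verified against a closed-form evaluation of the same
partition and against exhaustive partition search (within 0.02 of the
optimum).  Path metrics (diameter, average path length) are computed over
unordered reachable pairs within components, so disconnected graphs still
report single values.

**Core (keystone) taxa** are the union of the top ⌈0.1 N⌉ nodes by degree
and by unweighted betweenness.  Betweenness is rounded to 10 decimals
before ranking so float summation order cannot break mathematical ties;
remaining ties at the cutoff are broken by the other centrality, then by
lexicographic id.  This deterministic rule is validated against an
exhaustive oracle (explicit BFS shortest-path enumeration) on corpora of
≤ 12-node random graphs.  Core contributions are per-sample sums of core
relative abundance (taxonomic, and weighted by per-genus function
weights), reported as mean ± SE (sd/√n) in percent.  In function tables,
fungal genera carry one trophic mode with weight 1 (so functional equals
taxonomic contribution — the FUNGuild-style identity), and bacterial
per-genus pathway weights sum to 1.

## Visitation statistics

The pollen remaining rate of an open replicate is
100 · openᵢ / mean(bagging); rates above 100 % are legitimate.  Species
are compared by one-way ANOVA with Tukey HSD letters, after reporting
Levene's homogeneity statistic.  Because sequencing and pollen-count
samples are unpaired, the species-level association between remaining
rate and core-taxon function uses a bootstrap: each iteration resamples
every species' x- and y-replicates independently with replacement, takes
species means, and computes Spearman ρ across species (5,000 iterations;
percentile 2.5/97.5 CI).  With four species and no ties, ρ is confined to
the 11-value lattice {0, ±0.2, …, ±1.0}; iterations with zero rank
variance are recorded as missing.  Cohen's *d* uses the pooled SD; "±"
values published as standard errors are converted via sd = SE·√n — the
convention is pinned by reproducing the published LA-vs-MC effect size
(−3.07) from printed means/SEs alone (a full-precision path; the one
rounding inconsistency between the published mean tables, 97.22 vs 97.23,
is resolved in favour of 97.23, consistent with the printed difference
−14.22).

## Synthetic data generator

The generator is the package's ground-truth instrument, not a fixture
dump.  Per sample, genus log-intensities are

μ_g + species shift + treatment shift + σ_z · z,  z ~ N(0, C),

with C carrying planted equicorrelated blocks; intensities are
exponentiated and reads drawn multinomially at a library size uniform on
[39,000, 90,000] (straddling the rarefaction depths).  A Gaussian copula
with multinomial reads was chosen over Dirichlet-multinomial because the
pipeline's edge statistic is Spearman's ρ, and rank correlations are
directly plantable in the latent field.  Defaults are desk-scale: 150
bacterial and 60 fungal genera, 4 species × 2 treatments × 5 replicates.

Choices that required calibration, and their rationale:

* **Planted-block correlation 0.99** (core guild 0.999).  A network build
  gates on BH q < 0.05 over ~10⁴ pairs with only 10 samples, so retained
  edges need p ≈ 10⁻⁴, i.e. observed |ρ̂| ≳ 0.9.  Blocks planted at the
  gate threshold itself would be undetectable by construction; blocks are
  therefore planted as strong guilds whose realised pairwise Spearman
  (~0.95 after read noise) sits clearly above the gate.  Block members are
  drawn from a non-rare abundance tier (log-mean 1.0 vs background 0.0)
  so multinomial noise does not erase their rank signal.
* **Blocks respond to hosts as units.**  Species/treatment shifts are
  drawn once per block (scaled by each member's domain shift magnitude),
  not per member; a genuinely co-occurring guild covaries across all
  drivers, and per-member shifts would destroy the planted rank
  correlation within mixed-species groups.
* **Community baseline (60 % of background latent variance).**  Background
  taxa share a per-sample overall-load factor.  It cancels out of their
  own relative abundances but makes the two domains' compositional
  denominators co-vary; without it, closure noise attenuates even a
  latent 0.99 cross-domain correlation to ~0.7, below the gate.  With it,
  genuinely co-varying cross-domain guilds remain detectable.
* **Core dominance.**  Core sets (8 bacterial genera targeting 37 %
  summed RA, 10 fungal genera targeting 85 %, both in Cross_open) are
  rescaled per sample to the target on the logit scale with a shared
  jitter (sd 0.5): one per-flower "visitation intensity" modulates core
  dominance in both domains.  This yields realistic between-sample
  variation in core shares, makes the Cross_open interaction network the
  richest with the planted core genera as its hubs, and produces the
  negative core-versus-background correlations characteristic of
  interaction networks.  The two core sets are additionally planted as
  one cross-domain guild (latent 0.999).
* **Fungal shifts exceed bacterial** (species sd 1.2 vs 0.4 on the log
  scale), so fungal communities separate more strongly between hosts —
  the study's headline asymmetry — which shows up as a larger fungal
  PERMANOVA R².
* **Pollen counts.**  Per species, bagging counts are normal with a 5 %
  CV (no bagging variance is published; 5 % is this package's default),
  and open counts are calibrated so remaining rates hit the published
  means/SEs (CA 64.94 ± 1.01, SM 90.04 ± 1.67, LA 83.01 ± 2.87,
  MC 97.23 ± 0.59; draws truncated at zero).  A 200-seed simulation
  confirms per-species means within 2 SE of the targets.

### What the generator does *not* emulate

Real pollen microbiomes have thousands of OTUs, stronger zero-inflation,
taxonomy errors, chimeras and batch effects; compositional coupling in
real data arises from biology rather than a planted baseline factor; and
real cross-domain correlations are not equicorrelated guilds.  Passing
the planted-recovery suites therefore demonstrates the *pipeline's*
correctness (filters, gates, FDR families, centrality ranks, estimators)
under a known truth — not that the thresholds would recover biology in
any particular real dataset.

## Numerical conventions

Seeded `numpy` Generators with a fixed draw order give byte-identical
outputs per seed across runs.  Rarefaction, Louvain, PERMANOVA
permutations and the bootstrap all take explicit seeds; the pipeline
manifest records version, seeds, thresholds and input checksums.
Degenerate inputs are contracts, not surprises: zero-variance groups make
Welch's ANOVA error (exact ties need different handling), edgeless
networks have undefined modularity and empty core sets (flagged), and
undefined correlations are excluded from FDR families.

## Problem sizes used in validation

The validation suites run at desk scale: 10 generator seeds for edge
recovery, a 200-graph ≤ 12-node corpus for the keystone oracle, 1,000
simulations (199 permutations each, 12 samples, 20 taxa) for PERMANOVA
type-I error, 5,000 bootstrap iterations, and 20 seeds for core-target
calibration.  These sizes give Monte-Carlo error comfortably inside the
asserted bands (e.g. a ±2 percentage-point band at 1,000 simulations for
a 5 % error rate).

## Known limitations

Group sizes of 10 leave the Spearman t-approximation anti-conservative in
the far tail, so the realised false-discovery fraction over *all*
background pairs can exceed the nominal 5 % even though BH is applied
faithfully; the cross-block false-edge rate (between planted blocks) is
the cleaner specificity measure and is ~0.  One-way PERMANOVA on the
composite group is reported rather than a factorial decomposition.
Trophic-mode breakdowns are descriptive (no inferential test attached).
NMDS ordination and network layout are out of scope: they are
visualisations of quantities (Bray–Curtis, edge lists) the package
already exports.
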