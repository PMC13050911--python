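"""Pollen remaining rate as a proxy for insect visitation.

The remaining rate of an open-treatment replicate is its pollen grain
count as a percentage of the species' mean bagged count (bagging excludes
insects, so lower rates mean more pollen removed).  Species are compared
with one-way ANOVA + Tukey letters; the species-level association with
core-taxon function uses an unpaired bootstrap Spearman; the LA-vs-MC
contrast uses Cohen's d with pooled SD (SE x sqrt(n) conversion).
"""

import numpy as np

from pollenet import (
    SynthSpec,
    bootstrap_species_spearman,
    cohens_d,
    generate_pollen_counts,
    visitation_analysis,
)

spec = SynthSpec(seed=42)
pollen = generate_pollen_counts(spec)
vis = visitation_analysis(pollen, n_iter=5000, seed=0)

print("remaining rate per species (mean +/- SE, Tukey letter):")
for _, row in vis.species_summary.iterrows():
    print(f"  {row.species}: {row['mean']:6.2f} +/- {row.se:4.2f}  {row.letter}")
print(f"one-way ANOVA p = {vis.anova.effects.loc['species', 'p']:.2e}")
print(f"Cohen's d (LA - MC) on simulated rates = {vis.cohens_d:.2f}")

# published-table worked example: SE -> SD conversion with n = 5
d = cohens_d(83.01, 2.87, 5, 97.23, 0.59, 5, dispersion="se")
print(f"Cohen's d from published means/SEs (83.01+/-2.87 vs 97.23+/-0.59) "
      f"= {d:.2f}")

# bootstrap Spearman between remaining rate and a made-up per-species trait
rng = np.random.default_rng(0)
x = {sp: pollen.loc[(pollen.species == sp) & (pollen.treatment == "open"),
                    "grains"].to_numpy() for sp in spec.species}
y = {sp: rng.normal(30 + 10 * i, 4, 5) for i, sp in enumerate(spec.species)}
boot = bootstrap_species_spearman(x, y, n_iter=5000, seed=0)
print(f"bootstrap Spearman: median {boot.median:.2f}, mean {boot.mean:.2f}, "
      f"95% CI [{boot.ci_low:.2f}, {boot.ci_high:.2f}]")
# With 4 species, rho can only take the 11 values 0, +/-0.2, ..., +/-1.0,
# so the CI endpoints always sit on that lattice.
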