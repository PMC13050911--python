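"""Alpha and beta diversity of the synthetic pollen microbiome.

Rarefies each domain to its depth (bacteria 40,000 reads, fungi 39,000),
computes Chao1 / Shannon / Faith's PD per sample, tests treatment and
species effects by two-way ANOVA, and quantifies community separation with
Bray-Curtis + PERMANOVA.
"""

import warnings

warnings.filterwarnings("ignore")

from pollenet import (
    SynthSpec,
    alpha_diversity,
    assign_groups,
    bray_curtis,
    generate_counts,
    generate_tree,
    permanova,
    to_relative_abundance,
    two_way_anova,
)

spec = SynthSpec(seed=42)
bacteria, fungi, meta = generate_counts(spec)
groups = assign_groups(meta)

for name, table, depth in (("bacteria", bacteria, 40000), ("fungi", fungi, 39000)):
    tree = generate_tree(table.taxon_ids, seed=1)
    div = alpha_diversity(table, depth=depth, tree=tree, seed=0)
    print(f"\n== {name} (rarefied to {depth} reads; "
          f"{len(div.excluded_samples)} samples excluded) ==")
    print(div.per_sample.describe().loc[["mean", "std"]].round(2).to_string())

    anova = two_way_anova(div.per_sample["shannon"], meta)
    print("two-way ANOVA on Shannon (F, p):")
    print(anova.effects.round(4).to_string())

    d = bray_curtis(to_relative_abundance(table))
    res = permanova(d, groups.reindex(d.index), n_permutations=999, seed=0)
    print(f"PERMANOVA on Bray-Curtis: R2={res.r2:.3f} "
          f"pseudo-F={res.pseudo_f:.2f} p={res.p_value:.3f}")
# A larger fungal R2 than bacterial R2 reproduces the study pattern:
# fungal communities separate more strongly by host and treatment.
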