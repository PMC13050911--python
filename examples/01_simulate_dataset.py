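"""Generate a synthetic pollen-microbiome study and inspect its design.

The dataset mimics a 4-crop x 2-treatment x 5-replicate survey: two
self-pollinated hosts (CA = pepper, SM = eggplant) and two cross-pollinated
hosts (LA = luffa, MC = bitter gourd), each sampled under insect exclusion
("bagging") and natural visitation ("open").  Planted structure — genus
correlation blocks, a dominant core guild in the cross-pollinated open
group, and calibrated pollen counts — provides ground truth for every
downstream stage.
"""

from pollenet import SynthSpec, assign_groups, generate_counts

spec = SynthSpec(seed=42)
bacteria, fungi, meta = generate_counts(spec)

print(f"bacterial table: {bacteria.shape[0]} genera x {bacteria.shape[1]} samples")
print(f"fungal table:    {fungi.shape[0]} genera x {fungi.shape[1]} samples")
print(f"library sizes:   {bacteria.library_sizes().min()}-"
      f"{bacteria.library_sizes().max()} reads")

groups = assign_groups(meta)
print("\nsamples per pollination x treatment group:")
print(groups.value_counts().to_string())

core = spec.core_specs[1]
print(f"\nplanted fungal core guild: {len(core.taxa)} genera targeting "
      f"{core.target:.0%} summed relative abundance in {core.group}")
# The group sizes (10 each) and the 85% fungal core target are the study
# conditions every later example builds on.
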