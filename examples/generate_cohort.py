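"""Generate a synthetic cohort and inspect its composition.

Draws lesions with the study-cohort prevalences (Spitz vs conventional
melanoma, grouped aberration and diagnostic-category mixes), builds one
feature bag, and prints the label proportions next to their targets.
"""

from collections import Counter

import spitzmil as sm

spec = sm.CohortSpec(n_lesions=772, bag_size_range=(32, 256), encoder_dim=64, seed=0)
records = sm.sample_cohort(spec)

n_spitz = sum(r.pathway == "spitz" for r in records)
print(f"lesions: {len(records)}, Spitz: {n_spitz} ({n_spitz / len(records):.1%}, target 50.9%)")

spitz = [r for r in records if r.pathway == "spitz"]
ab = Counter(r.aberration for r in spitz)
print("aberration mix (target ALK 15% / ROS1 27% / NTRK 28% / other 30%):")
for cls in sm.ABERRATIONS:
    print(f"  {cls:6s} {ab[cls] / len(spitz):.1%}")

bag = sm.sample_feature_bag(records[0], spec)
print(f"first bag: {bag.n_tiles} tiles x {bag.features.shape[1]} features, "
      f"{bag.signal_mask.mean():.0%} lesion tiles")
# The proportions fluctuate around the targets with multinomial noise;
# the bag is the unordered tile-feature set a classifier consumes.
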