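"""Generate a small synthetic plaque cohort and inspect its structure.

Each subject carries four grayscale ROIs (left/right carotid x
transverse/longitudinal section) with speckle texture; the symptomatic
class is darker (hypoechoic) and more heterogeneous than the asymptomatic
class in proportion to ``effect_size``.
"""

import numpy as np

from osfpnet import CohortSpec, generate_cohort

spec = CohortSpec(n_subjects=20, symptomatic_fraction=0.35, effect_size=1.5, seed=1)
records = generate_cohort(spec)

n_sym = sum(r.label for r in records)
print(f"{len(records)} subjects, {sum(len(r.images) for r in records)} images "
      f"({n_sym} symptomatic / {len(records) - n_sym} asymptomatic)")

for rec in records[:3]:
    shapes = {k: v.pixels.shape for k, v in rec.images.items()}
    print(f"  {rec.subject_id} label={rec.label} shapes={shapes}")

mean_by_class = {
    lab: np.mean([
        img.pixels.mean() for r in records if r.label == lab for img in r.images.values()
    ])
    for lab in (0, 1)
}
print(f"mean echogenicity: asymptomatic {mean_by_class[0]:.1f}, "
      f"symptomatic {mean_by_class[1]:.1f}")
# The gap between the two class means is the texture signal the four-path
# network is trained to pick up; transverse ROIs are near-square and
# longitudinal ROIs are elongated strips.
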