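"""Leave-one-subject-out recovery experiment on a tiny synthetic cohort.

Generates an 8-subject cohort with strong class contrast, evaluates the
proposed model and the temporal-only ablation (C1) with the standard
training recipe, and prints the metric triple for each next to the exact
binomial chance band.  On high-contrast data both variants should clear
the band; on a null cohort (try ``null_config``) neither may.
"""

from fnirscad import ModelConfig, TrainConfig, build_dataset, chance_band, generate_cohort, loso_cv
from fnirscad.synth import high_contrast_config

cfg = high_contrast_config(n_per_class=4, seed=7)
x, y, ids = build_dataset(generate_cohort(cfg))
lo, hi = chance_band(len(y))
print(f"{len(y)}-subject cohort; 95% chance band for accuracy: {lo:.0f}-{hi:.0f}%\n")

for variant in ("proposed", "c1"):
    s = loso_cv(x, y, ModelConfig(variant=variant), TrainConfig(), subject_ids=ids)
    print(f"{variant:>9}: accuracy {s.accuracy:5.1f}%  "
          f"sensitivity {s.sensitivity:5.1f}%  specificity {s.specificity:5.1f}%")

print("\nAccuracy above the band means the model recovered the injected "
      "class structure (hypoactivation + asymmetry) from held-out subjects.")
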