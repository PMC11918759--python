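"""Walk the feature-extraction blocks of every classifier variant.

Prints each variant's branch layers with output shapes and the width of
the concatenated flattened feature vector the shared classification block
receives.  The proposed model compresses 246 x 68 inputs to 14 x 17 per
indicator (1,428 features over six indicators); the temporal-only C1
keeps all 68 channels (5,712 features).
"""

from fnirscad import ModelConfig, VARIANTS, architecture_summary

for variant in VARIANTS:
    s = architecture_summary(ModelConfig(variant=variant))
    print(f"\n=== {variant} ===")
    for row in s["branch"]:
        desc = row["layer"]
        if "kernel" in row:
            desc += f" k={row['kernel']} s={row.get('stride')}"
        print(f"  {desc:<40} -> {row['output_shape']}")
    print(f"  concatenate over {s['n_branches']} indicators -> {s['concatenate_shape']}")
    print(f"  flatten -> {s['flatten']} features")
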