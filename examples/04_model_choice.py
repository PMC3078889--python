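"""Bayes-factor comparison: isolation-with-migration vs. secondary admixture.

Builds a reference table for each demographic model, simulates a
pseudo-observed dataset under the migration model, and reports the log10
Bayes factor together with its robustness across retained-simulation counts.
"""

import numpy as np

from temporalpop import (
    IMModelParams,
    bayes_factor,
    build_reference_table,
    default_study_scheme,
    simulate_dataset,
    summarize_dataset,
)

rng = np.random.default_rng(2)
scheme = default_study_scheme()

print("building reference tables (2 x 15,000 single-locus simulations)...")
ref_im = build_reference_table("im", 15_000, scheme, rng)
ref_adm = build_reference_table("admixture", 15_000, scheme, rng)

truth = IMModelParams(
    two_Nm=9.55, n_cr_now=271, ratio_old_now=61.7, n_ancestral=2547,
    n_western=22376, t_divergence=891, t_bottleneck=16, t_migration=21, mu=4e-4,
)
obs = summarize_dataset(simulate_dataset(truth, scheme, 8, rng, "im"))

res = bayes_factor(ref_im, ref_adm, obs, retained_counts=(300, 750, 1500, 3000))
print(f"\nlog10 Bayes factor (migration over admixture): {res.log10_bf:+.2f}")
print("robustness across retained-simulation counts:")
for m, bf in sorted(res.curve.items()):
    print(f"  retained {m:5d}: log10 BF = {bf:+.2f}")
print("\n(a positive value at every retained count is consistent support for "
      "divergence with ongoing gene flow)")
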