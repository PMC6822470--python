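"""Run-to-run stability of a stochastic phaser.

Fifteen independent corruptions of the same truth stand in for fifteen runs
of one stochastic tool on identical input.  The occurrence histogram shows
how often each observed switch-error site recurs across runs: a memoryless
error process puts most mass at 1 (run-specific errors), whereas a tool with
data-driven hard spots would pile mass at 15.
"""
import numpy as np

import phaseblocks as pb

n_ind, n_sites, s, R = 40, 301, 0.05, 15

r = np.random.default_rng(3)
copy1 = r.integers(0, 2, size=(n_ind, n_sites), dtype=np.int8)
truth = pb.HaplotypePanel(
    [f"i{k}" for k in range(n_ind)],
    pb.VariantMap.default(n_sites),
    np.stack([copy1, 1 - copy1], axis=2),
)
truths = pb.truth_from_haplotypes(truth)

runs, se_values = [], []
for k in range(R):
    est = pb.corrupt_phasing(truth, s, seed=500 + k)
    profiles = pb.panel_profiles(truths, est)
    runs.append(profiles)
    se_values.append(pb.switch_error(profiles)[0])

occurrence, dispersion = pb.stability_summary(runs, {"switch_error": se_values})
print("switch-site occurrence across 15 runs (% of observed error sites):")
for n_runs, pct in occurrence.items():
    if pct > 0.05:
        print(f"  seen in {n_runs:2d} run(s): {pct:5.1f}%")
print()
print(dispersion.round(4).to_string())
print()
print("errors concentrated at occurrence 1 are run-specific noise; identical")
print("runs would put 100% of the mass at 15 with zero metric dispersion")
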