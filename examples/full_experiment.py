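"""Run the complete three-arm reproducibility experiment.

Manual delineation vs. semi-automated active-contour segmentation vs. the
same contour on CLAHE-enhanced images, 15 subjects x 2 sessions, with
1.5 px observer boundary jitter.  Writes the per-feature ICC table, bin
counts and run manifest, and prints the per-arm summary.
"""

from radstab import ExperimentConfig, run_pipeline

config = ExperimentConfig(
    n_subjects=15,
    arms=("manual", "acm", "clahe_acm"),
    sessions=2,
    jitter_sigma=1.5,
    icc_model="A1",
    seed=17,
)
result = run_pipeline(config, out_dir="scratch/example_experiment")

print("mean +/- SD of ICC(A,1) per arm:")
for arm in config.arms:
    m = result.report.summary.loc[arm, "mean"]
    s = result.report.summary.loc[arm, "sd"]
    print(f"  {arm:10s} {m:.3f} +/- {s:.3f}")
print("\nreproducibility bin counts (of 36 features):")
print(result.report.group_counts.to_string())
print("\npairwise rank-sum p (per-feature ICC distributions):")
print(result.report.pairwise_wilcoxon.round(4).to_string())
print(f"\noutputs written to {result.out_dir}")
# the manual arm is most sensitive to boundary jitter; the active-contour
# arms re-derive the boundary from the image, which buys reproducibility
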