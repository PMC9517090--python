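"""Two-group cohort comparison on synthetic phantoms.

Generates a 5+5 cohort (splintless vs splint transfer, monobloc/segmental
subgroups) whose group-mean 3D errors are set to 1.22 and 1.63 mm, writes
STL + ROI + manifest files, runs every case through the pipeline, and
reports the three group contrasts (overall, monobloc-only, segmental-only).
"""

from tempfile import TemporaryDirectory

from maxalign import generate_cohort, run_cohort

with TemporaryDirectory() as tmp:
    manifest, truths = generate_cohort(
        tmp,
        n_per_group=5,
        group_effects=(1.22, 1.63),
        between_patient_sd=0.4,
        noise_sd=0.05,
        seed=11,
    )
    results, comparisons = run_cohort(manifest)

print(results[["case_id", "group", "subgroup", "rms_3d_error_mm", "acceptable"]]
      .to_string(index=False))
print()
for name, c in comparisons.items():
    print(
        f"[{name:9s}] {c.group_labels[0]} {c.means[0]:.3f}±{c.sds[0]:.3f} vs "
        f"{c.group_labels[1]} {c.means[1]:.3f}±{c.sds[1]:.3f} mm  "
        f"t={c.t_statistic:.3f} df={c.degrees_of_freedom:.0f} "
        f"p={c.p_value:.4f} significant={c.significant}"
    )
# The recovered group means land on the generating 1.22 / 1.63 mm targets
# to within the noise floor; with n=5 per arm a 0.4 mm difference is usually
# not significant at alpha=0.05 — small cohorts are underpowered for it.
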