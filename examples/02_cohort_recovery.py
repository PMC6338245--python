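"""Recovering implanted activations from a synthetic two-group cohort.

Generates the default desk-scale cohort (12x12x12 grid, 140 timepoints,
6 subjects per group, 2 runs each) with known active voxels, runs
per-subject selection at alpha = 3, fuses the per-subject sets by
group-wise intersection and union, and scores the recovered set S
against the implanted ground truth.
"""

from madvox import default_spec, evaluate_recovery, fuse_cohort, generate_cohort
from madvox.select import cohort_subject_masks

spec = default_spec(seed=0)
scans, truth = generate_cohort(spec)
print(f"cohort: {len(scans)} scans, grid {spec.grid}, {spec.n_timepoints} timepoints")
print(f"implanted: {len(truth['union'])} group-common voxels")

masks = cohort_subject_masks(scans, alpha=3.0)
counts = [m.count for m in masks.values()]
print(f"per-subject selections: {min(counts)}-{max(counts)} voxels "
      "(group-common voxels + a few idiosyncratic extras)")

groups = {s.subject_id: s.group for s in scans}
selection = fuse_cohort(masks, groups, consensus=1.0)
print(f"after group-wise intersection and union: |S| = {len(selection.union_set)}")

rec = evaluate_recovery(selection.union_set, truth["union"], spec.grid)
print(f"sensitivity = {rec.sensitivity:.3f}, specificity = {rec.specificity:.4f}")
print("\nThe intersection strips each subject's idiosyncratic voxels (they never")
print("coincide across all six subjects), leaving exactly the implanted set.")
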