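"""Classifying the two groups from features over the selected set S.

Generates the group-differential cohort (17 subjects per group, one run
each), in which both groups activate the same voxels but each group
responds more strongly at its own subset. Features are the selection
statistic itself (peak deviation / median deviation) at every voxel of
S, and both classifiers are scored by seeded stratified 10-fold CV.
"""

from madvox import build_feature_matrix, classification_spec, fuse_cohort, generate_cohort
from madvox.classify import ElmClassifier, cross_validate, svm_sigmoid_classifier
from madvox.select import cohort_subject_masks

spec = classification_spec(seed=0)
scans, _ = generate_cohort(spec)
masks = cohort_subject_masks(scans, alpha=3.0)
selection = fuse_cohort(masks, {s.subject_id: s.group for s in scans})

fm = build_feature_matrix(scans, selection.union_set)
print(f"feature matrix: {fm.X.shape[0]} subjects x {fm.X.shape[1]} voxels "
      f"({fm.feature_mode})")

elm = cross_validate(fm.X, fm.y, lambda: ElmClassifier(hidden_units=503, seed=0),
                     folds=10, seed=0, name="elm_sigmoid")
svm = cross_validate(fm.X, fm.y, lambda: svm_sigmoid_classifier(C=1.09),
                     folds=10, seed=0, name="svm_sigmoid")

for res in (elm, svm):
    print(f"{res.classifier}: pooled 10-fold CV accuracy {res.accuracy:.1f}%  "
          f"confusion {res.confusion.tolist()}")

print("\nThe groups differ only in response amplitude at their own common set")
print("(group_effect = 15 on top of a base amplitude of 40), which the")
print("peak-ratio features separate cleanly; with group_effect = 0 the same")
print("procedure falls to chance-level accuracy.")
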