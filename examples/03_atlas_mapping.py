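"""Mapping the selected set S to MNI/Talairach coordinates and regions.

Runs selection + fusion on a synthetic cohort, backtracks every voxel of
S to world coordinates through the scan affine, converts MNI to
Talairach mm with the two-branch linear approximation, and tallies the
bundled toy atlas's region labels at each hierarchy level.
"""

from madvox import default_spec, fuse_cohort, generate_cohort, region_summary, toy_atlas
from madvox.atlas import annotate_selection
from madvox.select import cohort_subject_masks

spec = default_spec(seed=0)
scans, truth = generate_cohort(spec)
masks = cohort_subject_masks(scans, alpha=3.0)
selection = fuse_cohort(masks, {s.subject_id: s.group for s in scans})

table = annotate_selection(selection, scans[0].affine, toy_atlas())
print("first rows of the coordinate table:")
print(table.head(3).to_string(index=False))

for level in ("hemisphere", "lobe", "gyrus"):
    print(f"\nvoxel counts per {level}:")
    print(region_summary(table, level).to_string(index=False))

print("\nEvery count sums to |S|; the dominant region is the one containing")
print("the implanted activation clusters (here the left posterior-inferior")
print("octant of the toy atlas).")
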