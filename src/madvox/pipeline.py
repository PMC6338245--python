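"""End-to-end orchestration: simulate → select → fuse → map → classify.

One :class:`RunConfig` drives the whole analysis; every stage writes its
artifacts under the output directory and records parameters (tagged by
origin: reference defaults vs package defaults), voxel counts after
every filter, and SHA-256 checksums in ``provenance.json``. Re-running
with an identical config and seed reproduces byte-identical JSON
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import atlas as atlas_mod
from . import classify as clf_mod
from . import fusion, io, select, simulate

log = logging.getLogger("madvox")

#: Which defaults come from the reference study versus this package.
PARAMETER_ORIGIN = {
    "alpha": "reference",
    "svm_C": "reference",
    "elm_hidden_units": "reference",
    "n_timepoints": "reference",
    "tr_seconds": "reference",
    "consensus": "package-default",
    "run_combine": "package-default",
    "feature_mode": "package-default",
    "folds": "package-default",
    "seed": "package-default",
    "eligibility_floor": "package-default",
    "mask_fraction": "package-default",
}


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    out_dir: str = "madvox_out"
    manifest: str | None = None  # CSV of existing scans; None -> simulate
    simulate: dict = field(default_factory=dict)  # SyntheticSpec overrides
    alpha: float = 3.0
    consensus: float = 1.0
    run_combine: str = "union"
    mask_fraction: float | None = None  # None -> no brain mask (full grid)
    atlas: str | None = None  # atlas CSV; None -> bundled toy atlas
    feature_mode: str = "peak_ratio"
    classifier: str = "both"  # elm | svm | both
    elm_hidden_units: int = 503
    svm_C: float = 1.09
    folds: int = 10
    seed: int = 0
    eligibility_floor: float = select.DEFAULT_ELIGIBILITY_FLOOR

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return a result bundle dictionary.

    The bundle contains the group selection, coordinate/region tables,
    classifier results (when S is non-empty and classification is
    feasible) and the provenance record; everything is also written
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict[str, int] = {}
    notices: list[str] = []

    # ---- inputs -----------------------------------------------------
    stage = "input"
    try:
        if config.manifest is not None:
            manifest = io.load_manifest(config.manifest)
            scans = io.load_cohort(manifest, base_dir=Path(config.manifest).parent)
            truth = None
        else:
            spec = simulate.SyntheticSpec(seed=config.seed, **config.simulate)
            scans, truth = simulate.generate_cohort(spec)
        grid = io.check_shared_grid(scans)
        affine = scans[0].affine
        counts["grid_voxels"] = io.n_voxels(grid)
        counts["scans"] = len(scans)
        log.info("input: %d scans on grid %s (%d voxels)", len(scans), grid, counts["grid_voxels"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- phase I: per-subject selection -----------------------------
    stage = "select"
    try:
        mask = None
        if config.mask_fraction is not None:
            mask = io.compute_brain_mask(scans[0], config.mask_fraction)
            counts["mask_voxels"] = int(mask.mask.sum())
        subject_masks = select.cohort_subject_masks(
            scans,
            alpha=config.alpha,
            mask=mask,
            run_combine=config.run_combine,
            eligibility_floor=config.eligibility_floor,
        )
        counts["per_subject_selected"] = {sid: m.count for sid, m in subject_masks.items()}
        for sid, m in subject_masks.items():
            log.info("select: subject %s -> %d voxels", sid, m.count)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- phase II: group fusion ------------------------------------
    stage = "fuse"
    try:
        groups = {s.subject_id: s.group for s in scans}
        selection = fusion.fuse_cohort(subject_masks, groups, consensus=config.consensus)
        counts["g1_set"] = len(selection.g1_set)
        counts["g2_set"] = len(selection.g2_set)
        counts["union_set"] = len(selection.union_set)
        log.info(
            "fuse: |G1 set|=%d |G2 set|=%d |S|=%d",
            counts["g1_set"], counts["g2_set"], counts["union_set"],
        )
        sel_path = out / "S.json"
        _write_json(selection.to_dict(), sel_path)
        written.append(sel_path)
        nii_path = out / "S.nii.gz"
        io.write_selection_nifti(selection.union_volume(), affine, nii_path)
        written.append(nii_path)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    bundle: dict = {"selection": selection, "truth": truth, "counts": counts}

    if truth is not None:
        rec = simulate.evaluate_recovery(selection.union_set, truth["union"], grid)
        bundle["recovery"] = rec
        _write_json(rec.to_dict(), out / "recovery.json")
        written.append(out / "recovery.json")
        log.info("recovery: sensitivity=%s specificity=%.6f", rec.sensitivity, rec.specificity)

    # ---- mapping ----------------------------------------------------
    stage = "map"
    try:
        if selection.union_set:
            atlas = atlas_mod.load_atlas(config.atlas) if config.atlas else atlas_mod.toy_atlas()
            coords = atlas_mod.annotate_selection(selection, affine, atlas)
            coords_path = out / "coordinates.csv"
            coords.to_csv(coords_path, index=False)
            written.append(coords_path)
            summaries = {}
            for level in atlas_mod.HIERARCHY_LEVELS:
                summary = atlas_mod.region_summary(coords, level)
                p = out / f"regions_{level}.csv"
                summary.to_csv(p, index=False)
                written.append(p)
                summaries[level] = summary
            bundle["coordinates"] = coords
            bundle["region_summaries"] = summaries
        else:
            notices.append("S is empty: mapping stage skipped")
            log.info("map: skipped (empty S)")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- classification --------------------------------------------
    stage = "classify"
    try:
        results = {}
        if not selection.union_set:
            notices.append("S is empty: classification stage skipped")
            log.info("classify: skipped (empty S)")
        else:
            features = clf_mod.build_feature_matrix(
                scans, selection.union_set, config.feature_mode, config.eligibility_floor
            )
            bundle["features"] = features
            _, class_counts = np.unique(features.y, return_counts=True)
            if class_counts.min() < config.folds:
                notices.append(
                    f"classification skipped: smallest class ({class_counts.min()} subjects) "
                    f"cannot support {config.folds}-fold stratified CV"
                )
                log.info("classify: skipped (%s)", notices[-1])
            else:
                if config.classifier in ("elm", "both"):
                    results["elm_sigmoid"] = clf_mod.cross_validate(
                        features.X, features.y,
                        lambda: clf_mod.ElmClassifier(config.elm_hidden_units, seed=config.seed),
                        folds=config.folds, seed=config.seed, name="elm_sigmoid",
                        params={"hidden_units": config.elm_hidden_units},
                    )
                if config.classifier in ("svm", "both"):
                    results["svm_sigmoid"] = clf_mod.cross_validate(
                        features.X, features.y,
                        lambda: clf_mod.svm_sigmoid_classifier(C=config.svm_C),
                        folds=config.folds, seed=config.seed, name="svm_sigmoid",
                        params={"C": config.svm_C},
                    )
                for nm, res in results.items():
                    log.info("classify: %s pooled CV accuracy %.2f%%", nm, res.accuracy)
        if results:
            _write_json({k: v.to_dict() for k, v in results.items()}, out / "classification.json")
            written.append(out / "classification.json")
        bundle["classification"] = results
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- provenance -------------------------------------------------
    params = {
        "alpha": config.alpha,
        "consensus": config.consensus,
        "run_combine": config.run_combine,
        "feature_mode": config.feature_mode,
        "elm_hidden_units": config.elm_hidden_units,
        "svm_C": config.svm_C,
        "folds": config.folds,
        "seed": config.seed,
        "eligibility_floor": config.eligibility_floor,
        "mask_fraction": config.mask_fraction,
        "n_timepoints": scans[0].n_timepoints,
        "tr_seconds": scans[0].tr_seconds,
    }
    provenance = {
        "parameters": {
            k: {"value": v, "origin": PARAMETER_ORIGIN.get(k, "package-default")}
            for k, v in params.items()
        },
        "counts": counts,
        "notices": notices,
        "artifacts": {p.name: _sha256(p) for p in written},
    }
    _write_json(provenance, out / "provenance.json")
    bundle["provenance"] = provenance
    bundle["notices"] = notices
    return bundle
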