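"""Cohort I/O, image preprocessing, and the end-to-end experiment pipeline.

Cohorts live on disk as one lossless image file per sample (float32 TIFF or
16-bit PNG for 2D, NIfTI with identity affine for 3D) plus a ``cohort.csv``
table (sample_id, subject_id, group, one column per label) and the generating
spec as ``spec.json``.

``run_experiment`` executes the full audit on a synthetic cohort:
simulate -> association tests -> demographic classification with/without
augmentation -> label detection with/without augmentation (thresholds, TTA,
fairness-gap reports) -> task-transfer probes, and writes a manifest that makes
the run reproducible from its config and seed alone.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import exposure
from skimage.transform import resize

from . import assoc, debias
from .augment import preset_policy
from .backend import preset_schedule, reference_small_cnn
from .harness import (
    distort_images,
    predict_with_tta,
    scoreset_from_cohort,
    select_thresholds,
    task_transfer_probe,
    train_demographic_classifier,
    train_label_detector,
)
from .metrics import BootstrapConfig, ScoreSet, gap_report, macro_ovr_auc
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort, split_by_subject

__all__ = [
    "save_cohort",
    "load_cohort",
    "preprocess",
    "RunManifest",
    "run_experiment",
    "default_config",
]


# ---------------------------------------------------------------------------
# cohort round-trip
# ---------------------------------------------------------------------------

def save_cohort(cohort: SyntheticCohort, directory, fmt: str = "auto") -> Path:
    """Write images + cohort.csv + spec.json.  2D defaults to float32 TIFF
    (lossless round trip); ``fmt='png'`` writes 16-bit PNG instead.  3D always
    writes .nii.gz with an identity affine."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    ndim = cohort.images.ndim - 1
    if fmt == "auto":
        fmt = "tiff" if ndim == 2 else "nifti"
    rows = []
    for i in range(len(cohort)):
        sid = int(cohort.sample_id[i])
        img = cohort.images[i]
        if ndim == 2 and fmt == "tiff":
            import tifffile

            fname = f"{sid}.tiff"
            tifffile.imwrite(directory / "images" / fname, img.astype(np.float32))
        elif ndim == 2 and fmt == "png":
            from PIL import Image

            fname = f"{sid}.png"
            arr = np.round(np.clip(img, 0, 1) * 65535).astype(np.uint16)
            Image.fromarray(arr).save(directory / "images" / fname)
        elif ndim == 3:
            import nibabel as nib

            fname = f"{sid}.nii.gz"
            nib.save(nib.Nifti1Image(img.astype(np.float32), affine=np.eye(4)),
                     directory / "images" / fname)
        else:
            raise ValueError(f"unsupported format {fmt!r} for {ndim}D images")
        row = {"sample_id": sid, "subject_id": int(cohort.subject_id[i]),
               "file": fname, "group": cohort.group[i]}
        for j, name in enumerate(cohort.spec.label_names):
            row[f"label_{name}"] = int(cohort.labels[i, j])
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "cohort.csv", index=False)
    (directory / "spec.json").write_text(cohort.spec.to_json())
    return directory


def load_cohort(directory) -> SyntheticCohort:
    """Load a cohort written by :func:`save_cohort`.

    Raises on duplicate sample ids, missing image files, or mixed 2D/3D images.
    Truth masks are not persisted; the loaded cohort carries empty masks.
    """
    directory = Path(directory)
    table = pd.read_csv(directory / "cohort.csv")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values: {dups}")
    missing = [f for f in table["file"] if not (directory / "images" / f).exists()]
    if missing:
        raise FileNotFoundError(f"images referenced by cohort.csv are missing: {missing}")
    spec = CohortSpec.from_json((directory / "spec.json").read_text())

    images, ndims = [], set()
    for f in table["file"]:
        path = directory / "images" / f
        if f.endswith((".tiff", ".tif")):
            import tifffile

            img = tifffile.imread(path).astype(np.float32)
        elif f.endswith(".png"):
            from PIL import Image

            img = np.asarray(Image.open(path), dtype=np.float32) / 65535.0
        elif f.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = np.asarray(nib.load(path).get_fdata(), dtype=np.float32)
        else:
            raise ValueError(f"unrecognised image format: {f}")
        ndims.add(img.ndim)
        images.append(img)
    if len(ndims) > 1:
        raise ValueError(f"cohort mixes image dimensionalities {sorted(ndims)}; "
                         "a cohort must be all-2D or all-3D")
    label_cols = [f"label_{n}" for n in spec.label_names]
    images = np.stack(images)
    zeros = np.zeros(images.shape, dtype=bool)
    return SyntheticCohort(
        images=images,
        subject_id=table["subject_id"].to_numpy(),
        group=table["group"].to_numpy(dtype=object),
        labels=table[label_cols].to_numpy().astype(np.int8),
        shortcut_masks=zeros,
        disease_masks=zeros.copy(),
        spec=spec,
        sample_id=table["sample_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(image: np.ndarray, target_shape, mode: str = "cxr",
               fg_threshold: float = 0.05) -> np.ndarray:
    """Standardise an image for the harness.

    ``cxr``: histogram equalisation then resize.  ``mri``: centre crop to the
    tight bounding box of above-threshold voxels, then resize (falls back to a
    full-volume resize with a warning if no voxel clears the threshold).
    Output values lie in [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    target_shape = tuple(int(t) for t in target_shape)
    if mode == "cxr":
        if image.max() > image.min():
            image = exposure.equalize_hist(image)
        out = resize(image, target_shape, order=1, mode="edge", anti_aliasing=False)
    elif mode == "mri":
        fg = image > fg_threshold
        if not fg.any():
            warnings.warn("no voxel above the foreground threshold; resizing the full volume")
            crop = image
        else:
            slices = tuple(slice(int(ax.min()), int(ax.max()) + 1)
                           for ax in map(np.asarray, np.nonzero(fg)))
            crop = image[slices]
        lo, hi = crop.min(), crop.max()
        if hi > lo:
            crop = (crop - lo) / (hi - lo)
        out = resize(crop, target_shape, order=1, mode="edge", anti_aliasing=False)
    else:
        raise ValueError(f"unknown preprocessing mode {mode!r}")
    return np.clip(out, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """The audit's default study conditions (desk scale, 2D)."""
    return {
        "cohort": CohortSpec().to_dict(),
        "splits": [0.6, 0.1, 0.3],
        "modality": "cxr",
        "channels": [16, 32, 64],
        "n_permutations": 1000,
        "alpha": 0.001,
        "bootstrap_iterations": 1000,
        "bootstrap_seed": 2021,
        "tta_reps_per_method": 3,
        "debias": "baseline",
        "seed": 2021,
    }


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict = field(default_factory=dict)      # stage -> status / outputs
    results: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    elapsed: float = 0.0

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "seed": self.seed,
                           "stages": self.stages, "results": self.results,
                           "elapsed": self.elapsed}, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def run_experiment(config: dict | None = None, out_dir=None, verbose: bool = False) -> RunManifest:
    """Run the four-experiment audit end to end on a synthetic cohort.

    Stages: simulate -> (A) association tests -> (B) demographic classification
    with and without augmentation -> (C) label detection with and without
    augmentation, weighted-F1 thresholds, TTA scores, fairness-gap reports ->
    (D) task-transfer probes.  Returns a manifest with per-stage results;
    writes ``manifest.json`` (and CSV reports) when ``out_dir`` is given.
    """
    cfg = default_config()
    if config:
        cfg.update(config)
    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, seed=seed)
    rng = np.random.default_rng(seed)

    def log(msg):
        if verbose:
            print(f"[shortcutaudit] {msg}", flush=True)

    # --- simulate -----------------------------------------------------------
    spec = CohortSpec.from_dict({**cfg["cohort"], "seed": seed})
    cohort = generate_cohort(spec)
    train, val, test = split_by_subject(cohort, tuple(cfg["splits"]), seed=seed)
    manifest.stages["simulate"] = {"status": "ok", "n_samples": len(cohort),
                                   "split_sizes": [len(train), len(val), len(test)]}
    log(f"simulated cohort: {len(cohort)} samples")

    policy = preset_policy(cfg["modality"])
    # desk-scale schedules; the detector gets a longer budget because the
    # distortion-invariant detection task converges more slowly
    schedule = preset_schedule(cfg.get("schedule", "desk"), seed=seed)
    schedule_det = preset_schedule(cfg.get("schedule", "desk"), seed=seed,
                                   max_epochs=int(cfg.get("detector_max_epochs", 60)),
                                   patience=int(cfg.get("detector_patience", 12)))
    boot = BootstrapConfig(iterations=int(cfg["bootstrap_iterations"]),
                           seed=int(cfg["bootstrap_seed"]))
    image_shape = spec.image_shape
    channels = tuple(cfg["channels"])
    n_groups = len(spec.group_names)

    # --- Experiment A: association -----------------------------------------
    onehot = np.eye(n_groups)[cohort.group_codes]
    assoc_rows = []
    pcfg = assoc.PermutationConfig(n_permutations=int(cfg["n_permutations"]),
                                   alpha=float(cfg["alpha"]), seed=seed)
    for j, label in enumerate(spec.label_names):
        y = cohort.labels[:, j]
        stat = p_chi = float("nan")
        try:
            stat, dof, p_chi = assoc.chi_square_test(
                assoc.contingency_table(cohort.group, y))
        except ValueError:
            dof = 0
        obs_auc, p_perm = assoc.permutation_auc_test(onehot, y, pcfg)
        assoc_rows.append({"label": label, "chi2": stat, "dof": dof,
                           "p_chi2": p_chi, "auc": obs_auc, "p_perm": p_perm,
                           "dependent": p_perm < pcfg.alpha})
    manifest.results["experiment_A"] = assoc_rows
    manifest.stages["assoc"] = {"status": "ok"}
    log("experiment A done")

    # --- Experiment B: demographic classification --------------------------
    exp_b = {}
    demo_models = {}
    for cond, pol in (("unaugmented", None), ("augmented", policy)):
        adapter = reference_small_cnn(image_shape, n_groups, head="softmax",
                                      channels=channels, seed=seed)
        train_demographic_classifier(train, val, adapter, schedule, policy=pol,
                                     rng=np.random.default_rng(seed + 1))
        # the distorted-image condition applies end to end: its test set is
        # distorted too ("trained and tested" on distorted images)
        test_images = test.images if pol is None else distort_images(
            test, pol, np.random.default_rng(seed + 4))
        scores = adapter.predict_scores(test_images)
        exp_b[cond] = {"auc": macro_ovr_auc(scores, test.group_codes),
                       "stopped_epoch": adapter.stopped_epoch_}
        demo_models[cond] = adapter
        log(f"experiment B ({cond}): AUC {exp_b[cond]['auc']:.3f}")
    manifest.results["experiment_B"] = exp_b
    manifest.stages["demographic_training"] = {"status": "ok"}

    # --- Experiment C: label detection + fairness gaps ----------------------
    exp_c = {}
    detectors = {}
    for cond, pol in (("unaugmented", None), ("augmented", policy)):
        adapter = reference_small_cnn(image_shape, len(spec.label_names),
                                      head="sigmoid", channels=channels, seed=seed)
        dbmethod = cfg.get("debias", "baseline")
        if dbmethod == "baseline" or cond == "augmented":
            tr_cohort = train
            train_label_detector(tr_cohort, val, adapter, schedule_det, policy=pol,
                                 rng=np.random.default_rng(seed + 2))
        elif dbmethod == "balanced":
            tr_cohort = debias.balanced_subsample(train, seed=seed)
            train_label_detector(tr_cohort, val, adapter, schedule_det, policy=pol,
                                 rng=np.random.default_rng(seed + 2))
        elif dbmethod == "adversarial":
            debias.adversarial_train(train, val, adapter, schedule_det, lam=1.0, policy=pol)
        elif dbmethod in ("distmatch_mmd", "distmatch_mean"):
            debias.distmatch_train(train, val, adapter, schedule_det,
                                   penalty=dbmethod.split("_")[1], gamma=1.0, policy=pol)
        elif dbmethod == "fairalm":
            debias.fairalm_train(train, val, adapter, schedule_det, policy=pol)
        else:
            raise ValueError(f"unsupported debias method in pipeline: {dbmethod}")
        detectors[cond] = adapter

        val_scores = adapter.predict_scores(val.images)
        thresholds = select_thresholds(scoreset_from_cohort(val, val_scores))
        test_scores = adapter.predict_scores(test.images)
        ss = scoreset_from_cohort(test, test_scores)
        reps = int(cfg["tta_reps_per_method"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = gap_report(ss, "group", thresholds, bootstrap=None)
            # the test-time-augmentation condition selects its own thresholds
            # from TTA validation scores (same inference condition throughout)
            tta_val = predict_with_tta(adapter, val, policy, reps,
                                       rng=np.random.default_rng(seed + 6))
            thresholds_tta = select_thresholds(scoreset_from_cohort(val, tta_val))
            tta_scores = predict_with_tta(adapter, test, policy, reps,
                                          rng=np.random.default_rng(seed + 3))
            tta_report = gap_report(scoreset_from_cohort(test, tta_scores),
                                    "group", thresholds_tta, bootstrap=None)
        label_auc = _macro_label_auc(ss)
        exp_c[cond] = {
            "thresholds": thresholds.per_label,
            "label_auc_macro": label_auc,
            "macro_gaps": report.macro_gaps,
            "macro_gaps_tta": tta_report.macro_gaps,
            "condition": ("baseline" if dbmethod == "baseline" else dbmethod)
            if cond == "unaugmented" else "augmented",
        }
        log(f"experiment C ({cond}): macro label AUC {label_auc:.3f}")
    manifest.results["experiment_C"] = exp_c
    manifest.stages["label_detection"] = {"status": "ok"}

    # --- Experiment D: task-transfer probes --------------------------------
    exp_d = {}
    for cond in ("unaugmented", "augmented"):
        probe = task_transfer_probe(detectors[cond], train, val, test,
                                    bootstrap=boot, seed=seed,
                                    policy=policy if cond == "augmented" else None,
                                    rng=np.random.default_rng(seed + 5))
        exp_d[cond] = {"auc": probe.auc, "ci": [probe.ci_low, probe.ci_high]}
        log(f"experiment D ({cond}): probe AUC {probe.auc:.3f}")
    manifest.results["experiment_D"] = exp_d
    manifest.stages["probe"] = {"status": "ok"}

    # --- interpretation: discordant cases + mean saliency --------------------
    from .interpret import mean_saliency, select_discordant_cases

    demo_scores = {c: demo_models[c].predict_scores(test.images)
                   for c in ("unaugmented", "augmented")}
    det_scores = {c: detectors[c].predict_scores(test.images)
                  for c in ("unaugmented", "augmented")}
    thr_arr = [exp_c["unaugmented"]["thresholds"][l] for l in spec.label_names]
    discordant = select_discordant_cases(
        test.sample_id, demo_scores["unaugmented"], demo_scores["augmented"],
        test.group_codes, det_scores["unaugmented"], det_scores["augmented"],
        test.labels, thr_arr)
    n_sal = int(cfg.get("interpret_samples", 8))
    saliency = {}
    for c in ("unaugmented", "augmented"):
        amap, _ = mean_saliency(detectors[c], test.images[:n_sal], target=0, steps=16)
        mask = test.shortcut_masks[:n_sal].any(axis=0)
        inside = float(amap.values[mask].sum() / max(amap.values.sum(), 1e-12)) \
            if mask.any() else float("nan")
        saliency[c] = {"shortcut_mass_fraction": inside}
    manifest.results["interpretation"] = {
        "n_discordant": int(len(discordant)),
        "discordant_sample_ids": discordant.tolist()[:50],
        "mean_saliency": saliency,
    }
    manifest.stages["interpret"] = {"status": "ok"}

    # --- summary -------------------------------------------------------------
    # the four (train-aug x test-aug) error-gap conditions; "best augmented" is
    # the lowest-disparity condition that uses augmentation in either phase,
    # the comparison the audit tables report
    err_gaps = {
        "wo_wo": exp_c["unaugmented"]["macro_gaps"]["error_rate"],
        "wo_w": exp_c["unaugmented"]["macro_gaps_tta"]["error_rate"],
        "w_wo": exp_c["augmented"]["macro_gaps"]["error_rate"],
        "w_w": exp_c["augmented"]["macro_gaps_tta"]["error_rate"],
    }
    manifest.results["summary"] = {
        "demographic_auc_unaugmented": exp_b["unaugmented"]["auc"],
        "demographic_auc_augmented": exp_b["augmented"]["auc"],
        "demographic_auc_drop": exp_b["unaugmented"]["auc"] - exp_b["augmented"]["auc"],
        "probe_auc_unaugmented": exp_d["unaugmented"]["auc"],
        "probe_auc_augmented": exp_d["augmented"]["auc"],
        "probe_auc_gap": exp_d["unaugmented"]["auc"] - exp_d["augmented"]["auc"],
        "label_auc_unaugmented": exp_c["unaugmented"]["label_auc_macro"],
        "label_auc_augmented": exp_c["augmented"]["label_auc_macro"],
        "label_auc_drop": exp_c["unaugmented"]["label_auc_macro"]
        - exp_c["augmented"]["label_auc_macro"],
        "error_rate_gaps": err_gaps,
        "error_rate_gap_baseline": err_gaps["wo_wo"],
        "error_rate_gap_best_augmented": min(err_gaps["wo_w"], err_gaps["w_wo"],
                                             err_gaps["w_w"]),
    }
    manifest.elapsed = time.time() - manifest.started

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(manifest.to_json())
        pd.DataFrame(assoc_rows).to_csv(out_dir / "experiment_A.csv", index=False)
    return manifest


def _macro_label_auc(ss: ScoreSet) -> float:
    from .metrics import auc as _auc

    vals = []
    for j in range(ss.scores.shape[1]):
        y = ss.truths[:, j]
        if 0 < y.sum() < len(y):
            vals.append(_auc(ss.scores[:, j], y))
    return float(np.mean(vals)) if vals else float("nan")
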