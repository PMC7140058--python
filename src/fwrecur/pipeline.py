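"""Pipeline stages: simulate -> train -> correct -> metrics -> roistats -> predict.

Each stage reads only the on-disk outputs of its upstream stages (verified
against the run manifest's checksums), writes its own outputs under the run
directory, and appends to the manifest.  Volumes are written as
uncompressed NIfTI-1 so identical configurations reproduce byte-identical
outputs (gzip embeds timestamps and would break checksum determinism).

Layout of a run directory::

    run/
      config.yaml, manifest.json, report.txt
      model.npz, model.json                 (fraction estimator)
      sub-000/ dwi.nii dwi.bval dwi.bvec labels.nii f_true.nii fa_truth.nii
               fvol.nii atten_fwc.nii exclusion.nii
               fa.nii fa_fwc.nii md.nii md_fwc.nii
      summaries.csv comparison.csv
      patches.csv cv_scores.csv roc_fwc.csv roc_uncorrected.csv
      models.json delong.json
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .freewater import (
    CorrectedDWI,
    FractionEstimator,
    FractionMap,
    correct_signal,
    estimate_fractions,
    make_training_set,
    train_fraction_estimator,
)
from .io import Manifest, load_nifti, load_study, save_nifti, save_study
from .phantom import simulate_cohort
from .recurrence import (
    crossval_scores,
    delong_compare,
    fit_mixed_logit,
    roc_auc,
    sample_patches,
)
from .roistats import build_comparison_table, summarize_cohort
from .schemes import make_scheme, read_fsl_gradients
from .signal import estimate_noise_sigma
from .tensors import ScalarMap, compute_fa, map_metrics, tensor_eigenvalues

__all__ = ["run_stage", "run_all", "STAGES"]


def _cohort_ids(outdir: Path) -> list[str]:
    with open(outdir / "cohort.json") as fh:
        return json.load(fh)["patients"]


def stage_simulate(config: RunConfig, outdir: Path) -> list[str]:
    scheme = make_scheme(
        config.n_directions, config.b_value, config.n_b0, seed=config.scheme_seed
    )
    cohort = simulate_cohort(
        config.n_patients,
        scheme,
        params=config.phantom,
        s0=config.s0,
        snr=config.snr,
        seed=config.seeds()["cohort"],
    )
    files = []
    ids = []
    for study, truth in cohort:
        pdir = outdir / study.patient_id
        save_study(study, pdir)
        save_nifti(truth.label, truth.voxel_size, pdir / "labels.nii", dtype=np.int16)
        save_nifti(truth.f_true, truth.voxel_size, pdir / "f_true.nii")
        fa_truth = compute_fa(tensor_eigenvalues(truth.tissue_tensor))
        save_nifti(fa_truth, truth.voxel_size, pdir / "fa_truth.nii")
        ids.append(study.patient_id)
        files += [
            f"{study.patient_id}/{n}"
            for n in ("dwi.nii", "dwi.bval", "dwi.bvec", "labels.nii",
                      "f_true.nii", "fa_truth.nii")
        ]
    with open(outdir / "cohort.json", "w") as fh:
        json.dump({"patients": ids}, fh, indent=2)
    return files + ["cohort.json"]


def stage_train(config: RunConfig, outdir: Path) -> list[str]:
    ids = _cohort_ids(outdir)
    scheme = read_fsl_gradients(
        outdir / ids[0] / "dwi.bval", outdir / ids[0] / "dwi.bvec"
    )
    train_set = make_training_set(
        scheme,
        config.n_training_samples,
        d_free=config.d_free,
        seed=config.seeds()["training"],
    )
    est = train_fraction_estimator(
        train_set, config.training, seed=config.seeds()["training"]
    )
    est.save(outdir / "model.npz")
    return ["model.npz", "model.json"]


def stage_correct(config: RunConfig, outdir: Path) -> list[str]:
    est = FractionEstimator.load(outdir / "model.npz")
    files = []
    for pid in _cohort_ids(outdir):
        pdir = outdir / pid
        study = load_study(pdir, pid)
        labels, _ = load_nifti(pdir / "labels.nii")
        fmap = estimate_fractions(est, study, labels > 0)
        corr = correct_signal(study, fmap, d_free=config.d_free, f_floor=config.f_floor)
        fvol = np.where(fmap.valid, fmap.values, np.nan)
        save_nifti(fvol, study.voxel_size, pdir / "fvol.nii")
        save_nifti(corr.attenuation, study.voxel_size, pdir / "atten_fwc.nii")
        save_nifti(corr.exclusion_reason, study.voxel_size, pdir / "exclusion.nii",
                   dtype=np.int8)
        files += [f"{pid}/{n}" for n in ("fvol.nii", "atten_fwc.nii", "exclusion.nii")]
    return files


def stage_metrics(config: RunConfig, outdir: Path) -> list[str]:
    files = []
    for pid in _cohort_ids(outdir):
        pdir = outdir / pid
        study = load_study(pdir, pid)
        labels, _ = load_nifti(pdir / "labels.nii")
        brain = labels > 0
        sigma = estimate_noise_sigma(study, labels == 0) if config.noise_debias else None
        atten, _ = load_nifti(pdir / "atten_fwc.nii")
        exclusion, _ = load_nifti(pdir / "exclusion.nii")
        fvol, _ = load_nifti(pdir / "fvol.nii")
        corr = CorrectedDWI(
            np.asarray(atten, float),
            study.scheme,
            np.asarray(exclusion) == 0,
            np.asarray(exclusion, np.int8),
            study.s0_map(),
            np.where(np.isfinite(fvol), fvol, 1.0).astype(float),
            study.voxel_size,
        )
        fa_u, md_u = map_metrics(
            study, mask=brain, method=config.fit_method,
            config=config.restore, noise_sigma=sigma,
        )
        fa_c, md_c = map_metrics(
            corr, mask=brain, method=config.fit_method,
            config=config.restore, noise_sigma=sigma,
        )
        for name, smap in (("fa", fa_u), ("md", md_u), ("fa_fwc", fa_c), ("md_fwc", md_c)):
            save_nifti(smap.values, study.voxel_size, pdir / f"{name}.nii")
            files.append(f"{pid}/{name}.nii")
    return files


_MAP_KINDS = {
    # file stem -> (kind, corrected)
    "fvol": ("tissue_fraction", True),
    "md": ("MD", False),
    "md_fwc": ("MD", True),
    "fa": ("FA", False),
    "fa_fwc": ("FA", True),
}


def _load_maps(outdir: Path, pid: str) -> dict:
    maps = {}
    for stem, (kind, corrected) in _MAP_KINDS.items():
        values, voxel_size = load_nifti(outdir / pid / f"{stem}.nii")
        maps[(kind, corrected)] = ScalarMap(
            np.asarray(values, float), kind, corrected, voxel_size
        )
    return maps


def stage_roistats(config: RunConfig, outdir: Path) -> list[str]:
    ids = _cohort_ids(outdir)
    maps_by_patient = {pid: _load_maps(outdir, pid) for pid in ids}
    labels_by_patient = {
        pid: np.asarray(load_nifti(outdir / pid / "labels.nii")[0]) for pid in ids
    }
    summaries = summarize_cohort(maps_by_patient, labels_by_patient)
    summaries.to_csv(outdir / "summaries.csv", index=False)
    table = build_comparison_table(summaries)
    table.to_csv(outdir / "comparison.csv", index=False)
    return ["summaries.csv", "comparison.csv"]


def stage_predict(config: RunConfig, outdir: Path) -> list[str]:
    ids = _cohort_ids(outdir)
    seeds = config.seeds()
    rng = np.random.default_rng(seeds["patches"])
    frames = []
    for pid in ids:
        maps = _load_maps(outdir, pid)
        labels = np.asarray(load_nifti(outdir / pid / "labels.nii")[0])
        frames.append(
            sample_patches(
                maps[("FA", True)],
                maps[("FA", False)],
                labels,
                pid,
                n_per_class=config.n_patches_per_class,
                patch_voxels=config.patch_voxels,
                seed=rng,
            )
        )
    patches = pd.concat(frames, ignore_index=True)
    patches.to_csv(outdir / "patches.csv", index=False)

    y = patches["label"].to_numpy()
    scores = {}
    rocs = {}
    for spec_name in ("fwc", "uncorrected"):
        s = crossval_scores(patches, spec_name, k=config.cv_folds, seed=seeds["cv"])
        auc, fpr, tpr, thr = roc_auc(s, y)
        scores[spec_name] = s
        rocs[spec_name] = {"auc": auc, "fpr": fpr, "tpr": tpr}
        pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
            outdir / f"roc_{spec_name}.csv", index=False
        )
    pd.DataFrame(
        {
            "patient_id": patches["patient_id"],
            "label": y,
            "score_fwc": scores["fwc"],
            "score_uncorrected": scores["uncorrected"],
        }
    ).to_csv(outdir / "cv_scores.csv", index=False)

    comparison = delong_compare(scores["fwc"], scores["uncorrected"], y)
    with open(outdir / "delong.json", "w") as fh:
        json.dump(
            {
                "auc_fwc": comparison.auc_a,
                "auc_uncorrected": comparison.auc_b,
                "z": comparison.z,
                "p_value": comparison.p_value,
                "degenerate": comparison.degenerate,
            },
            fh,
            indent=2,
        )

    model_info = {}
    for spec_name in ("fwc", "uncorrected", "both"):
        fit = fit_mixed_logit(patches, spec_name)
        model_info[spec_name] = {
            "predictors": fit.predictors,
            "beta": fit.beta.tolist(),
            "se": fit.se.tolist(),
            "wald_p": fit.wald_p.tolist(),
            "sigma_u2": fit.sigma_u2,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "separation": fit.separation,
        }
    with open(outdir / "models.json", "w") as fh:
        json.dump(model_info, fh, indent=2)
    return [
        "patches.csv", "cv_scores.csv", "roc_fwc.csv", "roc_uncorrected.csv",
        "delong.json", "models.json",
    ]


STAGES = {
    "simulate": (stage_simulate, []),
    "train": (stage_train, ["simulate"]),
    "correct": (stage_correct, ["simulate", "train"]),
    "metrics": (stage_metrics, ["simulate", "correct"]),
    "roistats": (stage_roistats, ["simulate", "metrics", "correct"]),
    "predict": (stage_predict, ["simulate", "metrics"]),
}


def run_stage(stage: str, config: RunConfig, outdir) -> list[str]:
    """Run one named stage, verifying upstream outputs first."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir / "manifest.json")
    fn, upstream = STAGES[stage]
    for dep in upstream:
        manifest.check_stage(dep, outdir)
    files = fn(config, outdir)
    manifest.record_stage(stage, outdir, files)
    return files


def _write_report(config: RunConfig, outdir: Path) -> None:
    lines = ["free-water recurrence pipeline report", "=" * 38, ""]
    table = pd.read_csv(outdir / "comparison.csv")
    lines.append("Edema-with-recurrence vs pure edema (rank-sum p-values):")
    for _, row in table.iterrows():
        p = "n/a" if pd.isna(row.p_value) else f"{row.p_value:.5f}"
        tag = " *" if (not pd.isna(row.p_value) and row.p_value < 0.05) else ""
        lines.append(
            f"  {row['kind']:>16} {row['level']:>5} "
            f"{'FWC' if row.corrected else 'raw':>4}: p={p}{tag}"
        )
    with open(outdir / "delong.json") as fh:
        dl = json.load(fh)
    lines += [
        "",
        f"Cross-validated AUC (FWC-FA):        {dl['auc_fwc']:.3f}",
        f"Cross-validated AUC (uncorrected FA): {dl['auc_uncorrected']:.3f}",
        f"DeLong comparison: z={dl['z']:.3f}, p={dl['p_value']:.5f}",
    ]
    with open(outdir / "models.json") as fh:
        models = json.load(fh)
    both = models["both"]
    lines += [
        "",
        "Both-predictor mixed model Wald p-values:",
        f"  FWC-FA:         {both['wald_p'][1]:.4g}",
        f"  uncorrected FA: {both['wald_p'][2]:.4g}",
    ]
    warn = [m for m, info in models.items() if info["separation"]]
    if warn:
        lines.append(f"  note: quasi-separation flagged in model(s): {', '.join(warn)}")
    with open(outdir / "report.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def analyze_cohort(
    cohort,
    estimator,
    n_patches_per_class: int = 4,
    cv_folds: int = 3,
    fit_method: str = "restore",
    seed: int = 0,
) -> dict:
    """In-memory analysis of a simulated cohort: maps, patches, CV, DeLong.

    Runs the same computation as the disk-based stages but on a list of
    (study, truth) pairs, returning the cross-validated AUCs of the
    free-water-corrected and uncorrected FA predictors, their DeLong
    comparison, and the three mixed-model fits.
    """
    from .phantom import LABEL_EDEMA_PURE, LABEL_EDEMA_RECUR

    rng = np.random.default_rng(seed)
    frames = []
    for study, truth in cohort:
        edema = (truth.label == LABEL_EDEMA_PURE) | (truth.label == LABEL_EDEMA_RECUR)
        fmap = estimate_fractions(estimator, study, truth.brain_mask())
        corr = correct_signal(study, fmap)
        sigma = estimate_noise_sigma(study, truth.label == 0)
        fa_c, _ = map_metrics(corr, mask=edema, method=fit_method, noise_sigma=sigma)
        fa_u, _ = map_metrics(study, mask=edema, method=fit_method, noise_sigma=sigma)
        frames.append(
            sample_patches(
                fa_c, fa_u, truth.label, study.patient_id,
                n_per_class=n_patches_per_class, seed=rng,
            )
        )
    patches = pd.concat(frames, ignore_index=True)
    y = patches["label"].to_numpy()
    scores_f = crossval_scores(patches, "fwc", k=cv_folds, seed=seed)
    scores_u = crossval_scores(patches, "uncorrected", k=cv_folds, seed=seed)
    auc_f, *_ = roc_auc(scores_f, y)
    auc_u, *_ = roc_auc(scores_u, y)
    return {
        "patches": patches,
        "auc_fwc": auc_f,
        "auc_uncorrected": auc_u,
        "delong": delong_compare(scores_f, scores_u, y),
        "model_both": fit_mixed_logit(patches, "both"),
    }


def run_all(config: RunConfig, outdir) -> Path:
    """Run every stage in order and write a summary report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for stage in ("simulate", "train", "correct", "metrics", "roistats", "predict"):
        run_stage(stage, config, outdir)
    _write_report(config, outdir)
    return outdir / "report.txt"
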