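"""End-to-end phantom experiment.

Generates a primary phantom cohort plus an independently generated,
parameter-shifted "external" cohort (noisier scans, slightly different
tumor geometry) to emulate multicentre heterogeneity, then runs the full
pipeline: preprocessing, habitat segmentation, training of every model
variant, discrimination metrics with DeLong comparisons, clinical and
combined models, survival stratification, and Grad-CAM examples.  All
stages derive their randomness from one global seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from sklearn.model_selection import train_test_split

from . import fusion as fu
from . import metrics as mx
from . import survival as sv
from .errors import DataError
from .habitats import compute_kinetic_maps, match_habitats_across_time, segment_habitats
from .network import AblationFlags, StiConfig, fit, grad_cam, save_model
from .preprocessing import PreprocConfig, extract_region_patches, resample_study
from .synthetic import (PhantomConfig, _pcr_intercept, generate_case)

logger = logging.getLogger("sti_response")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(n_patients=200))
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    model: StiConfig = field(default_factory=StiConfig)
    ga: fu.GaConfig = field(default_factory=lambda: fu.GaConfig(
        population_size=24, generations=12))
    strata: sv.StrataDefinition = field(default_factory=sv.StrataDefinition)
    habitat_K: int = 3
    n_external: int = 100
    eval_alpha: float = 0.05
    bootstrap_reps: int = 500
    output_dir: str = "sti_output"
    global_seed: int = 0

    def resolved(self) -> "ExperimentConfig":
        """Propagate the global seed into every stage."""
        g = self.global_seed
        return replace(
            self,
            phantom=replace(self.phantom, seed=g),
            model=replace(self.model, seed=g + 1),
            ga=replace(self.ga, seed=g + 2),
        )


# The model-variant lattice: six time/space combinations, the
# spatial-only longitudinal model, and the two attention ablations.
VARIANTS: dict[str, AblationFlags] = {
    "T0": AblationFlags(True, False, False, True, False, False),
    "T1": AblationFlags(False, True, False, True, False, False),
    "T0+T1": AblationFlags(True, True, False, True, False, False),
    "T0+Spatial": AblationFlags(True, False, True, True, True, False),
    "T1+Spatial": AblationFlags(False, True, True, True, True, False),
    "T0+T1+Spatial": AblationFlags(True, True, True, True, True, False),
    "No spatial attention": AblationFlags(True, True, True, True, False, True),
    "No time attention": AblationFlags(True, True, True, True, True, False),
    "STI": AblationFlags(True, True, True, True, True, True),
}


@dataclass
class PhantomDataset:
    x: np.ndarray  # (N, 2, K+1, D, H, W) float32 patch tensor
    y: np.ndarray
    patient_ids: list[str]
    records: list
    subtype: np.ndarray
    t_stage: np.ndarray
    survival: pd.DataFrame | None
    habitat_ari: np.ndarray  # per-case adjusted Rand vs planted habitats (T0)
    habitat_in_patch: np.ndarray  # (N, 2, D, H, W) int8 habitat labels in patch space
    latent: np.ndarray


def _case_patches(case, preproc: PreprocConfig, k: int, case_seed: int):
    """Preprocess one case: patch tensor (2, K+1, ...), habitat labels in
    whole-patch space (2, ...), and the T0 habitat-recovery ARI (nan when no
    planted truth is available)."""
    from scipy import ndimage

    shape = tuple(preproc.patch_shape)
    x = np.empty((2, k + 1, *shape), dtype=np.float32)
    hab_patch = np.zeros((2, *shape), dtype=np.int8)
    studies = [resample_study(case.study_T0, preproc),
               resample_study(case.study_T1, preproc)]
    kins = [compute_kinetic_maps(s) for s in studies]
    maps = [segment_habitats(kin, s.tumor_mask, k, seed=case_seed + j)
            for j, (kin, s) in enumerate(zip(kins, studies))]
    maps = list(match_habitats_across_time(maps[0], maps[1], kins[0], kins[1]))
    for j, (study, hmap) in enumerate(zip(studies, maps)):
        patches = extract_region_patches(study, hmap.labels, preproc, k=k)
        for r, patch in enumerate(patches):
            x[j, r] = patch.volume
        box = patches[0].bbox
        if box is not None:
            sl = tuple(slice(a, b) for a, b in box)
            sub = hmap.labels[sl].astype(np.float32)
            factors = np.asarray(shape) / np.asarray(sub.shape)
            hab_patch[j] = ndimage.zoom(sub, factors, order=0, mode="nearest",
                                        grid_mode=True).astype(np.int8)
    ari = np.nan
    if case.truth_habitats is not None:
        truth = case.truth_habitats
        spacing = case.study_T0.voxel_spacing_mm
        if not np.allclose(spacing, preproc.target_spacing_mm):
            from .preprocessing import resample_to_spacing

            truth = resample_to_spacing(truth.astype(np.float32), spacing,
                                        preproc.target_spacing_mm, is_mask=True)
            truth = np.rint(truth).astype(np.int16)
        seg = maps[0].labels
        sel = (seg > 0) & (truth > 0)
        if sel.sum() > 10:
            ari = adjusted_rand_score(truth[sel], seg[sel])
    return x, hab_patch, ari


def _assemble_dataset(cases_iter, n: int, preproc: PreprocConfig, k: int,
                      seed: int) -> PhantomDataset:
    shape = tuple(preproc.patch_shape)
    x = np.empty((n, 2, k + 1, *shape), dtype=np.float32)
    hab_patch = np.zeros((n, 2, *shape), dtype=np.int8)
    y = np.empty(n, dtype=np.float32)
    ari = np.full(n, np.nan)
    pids, records, subtype, t_stage, latent = [], [], [], [], []
    surv_rows = []
    for i, case in enumerate(cases_iter):
        x[i], hab_patch[i], ari[i] = _case_patches(case, preproc, k, seed + 17 * i)
        y[i] = float(case.pcr_label)
        pids.append(case.patient_id)
        records.append(case.clinical)
        subtype.append(case.clinical.molecular_subtype)
        t_stage.append(case.clinical.clinical_T_stage)
        latent.append(case.latent_response if case.latent_response is not None
                      else np.nan)
        if case.survival is not None:
            s = case.survival
            surv_rows.append(dict(patient_id=case.patient_id, rfs_months=s.rfs_time,
                                  rfs_event=int(s.rfs_event), os_months=s.os_time,
                                  os_event=int(s.os_event)))
        if (i + 1) % 50 == 0:
            logger.info("preprocessed %d/%d cases", i + 1, n)
    surv = pd.DataFrame(surv_rows) if surv_rows else None
    return PhantomDataset(x=x, y=y, patient_ids=pids, records=records,
                          subtype=np.asarray(subtype), t_stage=np.asarray(t_stage),
                          survival=surv, habitat_ari=ari, habitat_in_patch=hab_patch,
                          latent=np.asarray(latent))


def build_dataset(phantom: PhantomConfig, preproc: PreprocConfig, k: int,
                  seed: int) -> PhantomDataset:
    """Generate and preprocess a phantom cohort case by case (volumes are
    dropped as soon as their patches are extracted)."""
    phantom.validate()
    preproc.validate()
    intercept = _pcr_intercept(phantom)
    cases = (generate_case(phantom, i, intercept)
             for i in range(phantom.n_patients))
    return _assemble_dataset(cases, phantom.n_patients, preproc, k, seed)


def dataset_from_cases(cases: list, preproc: PreprocConfig, k: int,
                       seed: int) -> PhantomDataset:
    """Preprocess an already-loaded cohort (e.g. read from disk)."""
    preproc.validate()
    return _assemble_dataset(iter(cases), len(cases), preproc, k, seed)


def external_phantom(base: PhantomConfig, n: int, seed_offset: int = 5000,
                     ) -> PhantomConfig:
    """A parameter-shifted configuration emulating a different centre."""
    lo, hi = base.tumor_radius_mm
    return replace(base, n_patients=n, seed=base.seed + seed_offset,
                   noise_sigma=base.noise_sigma * 1.3,
                   tumor_radius_mm=(lo + 1.0, hi + 1.0),
                   scan_drift_sigma=base.scan_drift_sigma * 1.2)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, sv.KmCurve):
        return _to_jsonable(dataclasses.asdict(obj))
    return obj


def run_experiment(config: ExperimentConfig, variants: list[str] | None = None) -> dict:
    """Run the full pipeline; returns the summary dict (also persisted as
    ``summary.json`` with per-variant prediction CSVs next to it)."""
    cfg = config.resolved()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"global_seed": cfg.global_seed, "stages": []}
    variant_names = variants or list(VARIANTS)

    def stage(name):
        summary["stages"].append(name)
        logger.info("stage: %s (seed %d)", name, cfg.global_seed)

    try:
        stage("generate")
        primary = build_dataset(cfg.phantom, cfg.preproc, cfg.habitat_K,
                                cfg.global_seed)
        ext_cfg = external_phantom(cfg.phantom, cfg.n_external)
        external = build_dataset(ext_cfg, cfg.preproc, cfg.habitat_K,
                                 cfg.global_seed + 1)
        summary["cohort"] = {
            "n_primary": len(primary.y), "n_external": len(external.y),
            "pcr_rate_primary": float(primary.y.mean()),
            "pcr_rate_external": float(external.y.mean()),
            "habitat_ari_mean": float(np.nanmean(primary.habitat_ari)),
        }
    except Exception as exc:
        raise StageError("generate", exc) from exc

    try:
        stage("split")
        idx_tr, idx_va = train_test_split(
            np.arange(len(primary.y)), test_size=0.2, stratify=primary.y,
            random_state=cfg.global_seed)
    except Exception as exc:
        raise StageError("split", exc) from exc

    models, variant_results = {}, {}
    try:
        stage("train")
        for vi, name in enumerate(variant_names):
            mcfg = replace(cfg.model, ablation=VARIANTS[name],
                           seed=cfg.model.seed + 101 * vi)
            model = fit(mcfg, primary.x[idx_tr], primary.y[idx_tr])
            models[name] = model
            res = {}
            for split_name, xs, ys, ids in (
                ("validation", primary.x[idx_va], primary.y[idx_va],
                 [primary.patient_ids[i] for i in idx_va]),
                ("external", external.x, external.y, external.patient_ids),
            ):
                scores = model.predict_scores(xs)
                rep = mx.metrics_report(scores, ys, threshold=model.threshold,
                                        alpha=cfg.eval_alpha,
                                        ap_reps=cfg.bootstrap_reps,
                                        seed=cfg.global_seed)
                res[split_name] = rep.to_dict()
                pd.DataFrame({
                    "patient_id": ids, "score": scores,
                    "label_pred": (scores >= model.threshold).astype(int),
                    "threshold": model.threshold, "label_true": ys.astype(int),
                }).to_csv(out / f"predictions_{name.replace(' ', '_')}_{split_name}.csv",
                          index=False)
            variant_results[name] = res
            logger.info("variant %s: external AUC %.3f", name,
                        res["external"]["auc"])
        summary["variants"] = variant_results
        save_model(models["STI"], out / "sti_model.npz")
    except Exception as exc:
        raise StageError("train", exc) from exc

    try:
        stage("evaluate")
        ext_scores = {name: models[name].predict_scores(external.x)
                      for name in variant_names}
        if "STI" in ext_scores:
            comparisons = {}
            for name in variant_names:
                if name == "STI":
                    continue
                comparisons[name] = mx.delong_test(ext_scores["STI"],
                                                   ext_scores[name], external.y)
            summary["delong_vs_sti"] = comparisons
        improvements = {}
        pairs = [("T0", "T0+Spatial"), ("T1", "T1+Spatial"), ("T0", "T0+T1"),
                 ("T1", "T0+T1"), ("T0+T1", "STI"), ("T0+Spatial", "STI"),
                 ("T1+Spatial", "STI")]
        for ref, new in pairs:
            if ref in variant_results and new in variant_results:
                a = variant_results[ref]["external"]["auc"]
                b = variant_results[new]["external"]["auc"]
                if a is None or b is None or a <= 0:
                    continue  # degenerate tiny-cohort AUC: nothing to compare
                improvements[f"{new} vs {ref}"] = {
                    "relative_pct": mx.relative_improvement(a, b),
                    "absolute_points": mx.absolute_difference_points(a, b),
                }
        summary["auc_improvements_external"] = improvements
        if "STI" in models:
            sti = models["STI"]
            summary["subgroups"] = {
                "subtype": {k: v.to_dict() for k, v in mx.subgroup_report(
                    ext_scores["STI"], external.y, external.subtype,
                    sti.threshold, seed=cfg.global_seed).items()},
                "t_stage": {k: v.to_dict() for k, v in mx.subgroup_report(
                    ext_scores["STI"], external.y, external.t_stage,
                    sti.threshold, seed=cfg.global_seed).items()},
            }
    except Exception as exc:
        raise StageError("evaluate", exc) from exc

    if "STI" in models:
        try:
            stage("fuse")
            sti = models["STI"]
            clin_tr = fu.encode_clinical([primary.records[i] for i in idx_tr])
            clin_ext = fu.encode_clinical(external.records)
            selected, flagged = fu.screen_clinical_factors(
                clin_tr, primary.y[idx_tr], alpha=cfg.eval_alpha)
            clin_cols = selected or list(clin_tr.columns)
            deep_tr = sti.deep_features(primary.x[idx_tr])
            deep_ext = sti.deep_features(external.x)
            table = fu.FeatureTable(
                [primary.patient_ids[i] for i in idx_tr], deep_tr,
                clin_tr[clin_cols].to_numpy(float), clin_cols, primary.y[idx_tr])
            ga_idx, ga_info = fu.ga_select_features(table, cfg.ga)
            clinical_model, clin_cv = fu.fit_svm(
                clin_tr[clin_cols].to_numpy(float), primary.y[idx_tr],
                seed=cfg.ga.seed)
            comb_tr = np.hstack([deep_tr[:, ga_idx], clin_tr[clin_cols].to_numpy(float)])
            comb_ext = np.hstack([deep_ext[:, ga_idx], clin_ext[clin_cols].to_numpy(float)])
            combined_model, comb_cv = fu.fit_svm(comb_tr, primary.y[idx_tr],
                                                 seed=cfg.ga.seed)
            clin_scores = clinical_model.predict_proba(
                clin_ext[clin_cols].to_numpy(float))[:, 1]
            comb_scores = combined_model.predict_proba(comb_ext)[:, 1]
            summary["clinical_fusion"] = {
                "screened_factors": selected, "separation_flagged": flagged,
                "ga_selected_deep_features": ga_idx,
                "ga_best_fitness": ga_info["best_fitness"],
                "clinical_cv": clin_cv, "combined_cv": comb_cv,
                "clinical_external": mx.metrics_report(
                    clin_scores, external.y, seed=cfg.global_seed,
                    ap_reps=cfg.bootstrap_reps).to_dict(),
                "combined_external": mx.metrics_report(
                    comb_scores, external.y, seed=cfg.global_seed,
                    ap_reps=cfg.bootstrap_reps).to_dict(),
            }
            (out / "selected_features.json").write_text(json.dumps(
                {"clinical": clin_cols, "deep": ga_idx}, indent=1))
        except Exception as exc:
            raise StageError("fuse", exc) from exc

        try:
            stage("survival")
            if external.survival is not None:
                scores = ext_scores["STI"]
                surv = external.survival.set_index("patient_id").loc[external.patient_ids]
                res = {}
                for endpoint, tcol, ecol in (("rfs", "rfs_months", "rfs_event"),
                                             ("os", "os_months", "os_event")):
                    rep = sv.stratified_logrank_report(
                        scores, surv[tcol].to_numpy(), surv[ecol].to_numpy(),
                        cfg.strata)
                    cox = sv.cox_univariate(surv[tcol].to_numpy(),
                                            surv[ecol].to_numpy(), scores,
                                            standardize=True)
                    res[endpoint] = {
                        "logrank_chi2": rep["chi2"], "logrank_p": rep["p"],
                        "n_high": rep["n_high"], "n_low": rep["n_low"],
                        "cox_hr_per_sd": cox.hazard_ratio, "cox_ci": cox.ci,
                        "cox_p_wald": cox.p_wald, "cox_p_lr": cox.p_likelihood_ratio,
                    }
                    pd.DataFrame({
                        "time": rep["km_high"].times,
                        "survival": rep["km_high"].survival,
                    }).to_csv(out / f"km_{endpoint}_high.csv", index=False)
                    pd.DataFrame({
                        "time": rep["km_low"].times,
                        "survival": rep["km_low"].survival,
                    }).to_csv(out / f"km_{endpoint}_low.csv", index=False)
                summary["survival"] = res
        except Exception as exc:
            raise StageError("survival", exc) from exc

        try:
            stage("explain")
            import nibabel as nib

            scores = ext_scores["STI"]
            examples = {"pcr_like": int(np.argmax(scores)),
                        "non_pcr_like": int(np.argmin(scores))}
            for tag, i in examples.items():
                cams = grad_cam(models["STI"], external.x[i])
                for (tp, region), cam in cams.items():
                    img = nib.Nifti1Image(cam, np.eye(4))
                    nib.save(img, str(out / f"gradcam_{tag}_{tp}_{region}.nii.gz"))
            summary["gradcam_examples"] = {
                tag: external.patient_ids[i] for tag, i in examples.items()}
        except Exception as exc:
            raise StageError("explain", exc) from exc

    try:
        stage("verify")
        # every metric in the summary must be recomputable from persisted files
        for name in variant_names:
            f = out / f"predictions_{name.replace(' ', '_')}_external.csv"
            dfp = pd.read_csv(f)
            auc = mx.roc_auc(dfp["score"], dfp["label_true"])
            stored = summary["variants"][name]["external"]["auc"]
            if abs(auc - stored) > 1e-9:
                raise DataError(f"summary AUC for {name} not reproducible from {f.name}")
        summary["verified"] = True
    except Exception as exc:
        raise StageError("verify", exc) from exc

    (out / "summary.json").write_text(json.dumps(_to_jsonable(summary), indent=1))
    _write_report(out, summary)
    return summary


def _write_report(out: Path, summary: dict) -> None:
    lines = ["# Phantom experiment report", ""]
    c = summary.get("cohort", {})
    lines.append(f"Primary cohort n={c.get('n_primary')} "
                 f"(pCR rate {c.get('pcr_rate_primary', float('nan')):.3f}); "
                 f"external n={c.get('n_external')} "
                 f"(pCR rate {c.get('pcr_rate_external', float('nan')):.3f}).")
    lines.append(f"Mean habitat-recovery ARI: {c.get('habitat_ari_mean', float('nan')):.3f}")
    lines.append("")
    lines.append("| model | external AUC | sens | spec |")
    lines.append("|---|---|---|---|")
    for name, res in summary.get("variants", {}).items():
        e = res["external"]
        lines.append(f"| {name} | {e['auc']:.3f} | {e['sensitivity']:.3f} "
                     f"| {e['specificity']:.3f} |")
    if "survival" in summary:
        for ep, r in summary["survival"].items():
            lines.append(f"\n{ep.upper()}: log-rank p={r['logrank_p']:.4f}, "
                         f"Cox HR/SD={r['cox_hr_per_sd']:.3f}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
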