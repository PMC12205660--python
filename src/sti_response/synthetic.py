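"""Synthetic longitudinal DCE-MRI phantom cohorts.

Generates reproducible two-timepoint (pre-treatment T0, early-treatment T1)
multi-phase contrast-enhanced breast-tumor phantoms with

* an ellipsoid-like tumor whose boundary is perturbed by a smoothed random
  field, partitioned into K kinetic habitats (Voronoi cells of interior
  seed points),
* per-habitat contrast-enhancement kinetics (difference-of-exponentials
  wash-in / wash-out curves),
* a planted treatment response: pathological-complete-response (pCR) cases
  shrink and attenuate their habitats at T1 (the most-enhancing habitat
  attenuates most and develops a core-to-rim gradient), non-pCR cases show
  only scan-to-scan drift,
* clinical covariates (receptor status, molecular subtype, age, tumor long
  diameter) with subtype-dependent pCR odds, and
* survival times whose log-hazard is linear in the latent response.

The per-patient random substreams are derived from the master seed and the
patient index, so cohorts are extendable without reshuffling earlier
patients, and identical configurations reproduce bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .errors import CohortIOError, ConfigError

SUBTYPES = ("HR+/HER2-", "HER2+", "HR-/HER2-")
# Table-1-like molecular subtype mix of a neoadjuvant breast cancer cohort.
SUBTYPE_FREQS = (0.39, 0.42, 0.19)

_BACKGROUND = 55.0
_S0 = 100.0


@dataclass(frozen=True)
class ResponseEffect:
    """pCR-specific changes applied to the T1 study.

    volume_shrink: fraction of tumor volume lost at T1 for a full responder.
    attenuation: per-habitat multiplicative loss of enhancement at T1.
    t0_profile_tilt: relative increase of habitat-1 enhancement at baseline
        for responders (a weak pre-treatment correlate of response).
    core_gradient: extra attenuation of the habitat-1 core relative to its
        rim at T1, emulating central necrosis in responders.
    """

    volume_shrink: float = 0.4
    attenuation: tuple[float, ...] = (0.35, 0.2, 0.08)
    t0_profile_tilt: float = 0.10
    core_gradient: float = 0.3
    # fine-scale "mottled necrosis" of the most-enhancing habitat: every
    # tumor carries some baseline mottle; responders gain this much more at
    # the early-treatment scan (resolvable in the zoomed habitat patch but
    # largely averaged out at whole-tumor patch resolution)
    mottle_gain: float = 0.45


@dataclass(frozen=True)
class PhantomConfig:
    n_patients: int = 100
    pcr_prevalence: float = 0.30
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    n_phases: int = 5
    phase_times_s: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0, 300.0)
    n_habitats: int = 3
    # (wash_in 1/s, wash_out 1/s, peak enhancement ratio) per habitat
    habitat_kinetic_params: tuple[tuple[float, float, float], ...] = (
        (0.030, 0.004, 2.0),
        (0.018, 0.002, 1.1),
        (0.008, 0.0008, 0.5),
    )
    response_effect: ResponseEffect = field(default_factory=ResponseEffect)
    noise_sigma: float = 3.0
    # odds multipliers for achieving pCR, by molecular subtype
    subtype_pcr_odds: tuple[float, float, float] = (0.25, 3.0, 0.8)
    survival_link: float = -1.4
    tumor_radius_mm: tuple[float, float] = (9.0, 14.0)
    profile_jitter_sigma: float = 0.22
    scan_drift_sigma: float = 0.15
    texture_amplitude: float = 0.08
    # background parenchymal enhancement: amplitude of enhancing non-tumor
    # tissue and the scan-to-scan variability of its intensity
    background_enhancement: float = 0.2
    background_drift_sigma: float = 0.3
    mottle_baseline: tuple[float, float] = (0.02, 0.08)
    with_survival: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.pcr_prevalence < 1.0:
            raise ConfigError("pcr_prevalence must be in (0, 1)")
        t = np.asarray(self.phase_times_s, dtype=float)
        if len(t) != self.n_phases or self.n_phases < 3:
            raise ConfigError("need >= 3 phases with matching phase_times_s")
        if np.any(np.diff(t) <= 0):
            raise ConfigError("phase_times_s must be strictly increasing")
        if self.n_habitats < 1:
            raise ConfigError("n_habitats must be >= 1")
        if len(self.habitat_kinetic_params) != self.n_habitats:
            raise ConfigError("one kinetic triple per habitat required")
        if len(set(self.habitat_kinetic_params)) != self.n_habitats:
            raise ConfigError("habitat kinetic triples must be pairwise distinct")
        if not 0.0 <= self.response_effect.volume_shrink < 1.0:
            raise ConfigError("volume_shrink must be in [0, 1)")
        if len(self.response_effect.attenuation) != self.n_habitats:
            raise ConfigError("one attenuation entry per habitat required")
        extent = np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing_mm)
        if np.any(extent / 2.0 < self.tumor_radius_mm[1] + 4.0):
            raise ConfigError("grid too small to contain the configured tumor")


@dataclass
class DceStudy:
    patient_id: str
    timepoint: str  # "T0" | "T1"
    phases: np.ndarray  # (n_phases, D, H, W)
    phase_times_s: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    tumor_mask: np.ndarray  # uint8 {0,1}, (D, H, W)

    def __post_init__(self) -> None:
        if self.phases.shape[0] != len(self.phase_times_s):
            raise ConfigError("phase count must match phase_times_s length")
        if self.phases.shape[1:] != self.tumor_mask.shape:
            raise ConfigError("phases and mask must share the grid")
        if self.tumor_mask.sum() < 1:
            raise ConfigError("tumor_mask must have at least one foreground voxel")


@dataclass(frozen=True)
class ClinicalRecord:
    age: float
    menopause: str  # "pre" | "post"
    baseline_LD_mm: float
    clinical_T_stage: str  # "T1-T2" | "T3-T4"
    er: str
    pr: str
    her2: str
    ki67: str
    molecular_subtype: str

    def __post_init__(self) -> None:
        hr_pos = "positive" in (self.er, self.pr)
        if self.molecular_subtype == "HER2+" and self.her2 != "positive":
            raise ConfigError("HER2+ subtype requires HER2 positivity")
        if self.molecular_subtype == "HR+/HER2-" and not (hr_pos and self.her2 == "negative"):
            raise ConfigError("HR+/HER2- subtype requires HR+ and HER2-")
        if self.molecular_subtype == "HR-/HER2-" and (hr_pos or self.her2 == "positive"):
            raise ConfigError("triple-negative subtype requires ER-, PR- and HER2-")
        if self.baseline_LD_mm <= 0:
            raise ConfigError("baseline_LD_mm must be positive")


@dataclass(frozen=True)
class SurvivalRecord:
    rfs_time: float  # months
    rfs_event: bool
    os_time: float
    os_event: bool

    def __post_init__(self) -> None:
        if self.rfs_time < 0 or self.os_time < 0:
            raise ConfigError("survival times must be nonnegative")


@dataclass
class LongitudinalCase:
    patient_id: str
    study_T0: DceStudy
    study_T1: DceStudy
    clinical: ClinicalRecord
    pcr_label: bool
    survival: SurvivalRecord | None = None
    truth_habitats: np.ndarray | None = None  # T0 habitat labels, phantoms only
    latent_response: float | None = None  # phantom ground truth in [0, 1]


def enhancement_curve(t, wash_in: float, wash_out: float, pe: float):
    """Relative enhancement at time ``t`` (s) after contrast arrival.

    A difference-of-exponentials curve ``(1 - exp(-a t)) exp(-b t)``
    rescaled so its maximum equals ``pe``.  The closed-form time to peak is
    ``ln((a + b) / b) / a``; in the ``wash_out -> 0`` limit the curve is the
    monotone saturating ``pe (1 - exp(-a t))``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigError("time must be nonnegative")
    if wash_in <= 0 or wash_out < 0 or pe < 0:
        raise ConfigError("rates must be positive and pe nonnegative")
    a, b = wash_in, wash_out
    if b < 1e-12:
        return pe * (1.0 - np.exp(-a * t))
    t_peak = np.log((a + b) / b) / a
    f = (1.0 - np.exp(-a * t)) * np.exp(-b * t)
    f_peak = (1.0 - np.exp(-a * t_peak)) * np.exp(-b * t_peak)
    return pe * f / f_peak


def time_to_peak(wash_in: float, wash_out: float) -> float:
    """Closed-form argmax of :func:`enhancement_curve`."""
    if wash_out < 1e-12:
        return np.inf
    return float(np.log((wash_in + wash_out) / wash_out) / wash_in)


def _pcr_intercept(config: PhantomConfig) -> float:
    """Intercept of the subtype-tilted logistic label model such that the
    marginal pCR probability equals the configured prevalence."""
    odds = np.log(np.asarray(config.subtype_pcr_odds, dtype=float))
    freqs = np.asarray(SUBTYPE_FREQS)

    def marginal(x):
        return float(freqs @ (1.0 / (1.0 + np.exp(-(x + odds))))) - config.pcr_prevalence

    return brentq(marginal, -20.0, 20.0)


def _patient_rngs(seed: int, index: int):
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    clin, img, surv = [np.random.default_rng(s) for s in ss.spawn(3)]
    return clin, img, surv


def sample_clinical(config: PhantomConfig, index: int, intercept: float | None = None):
    """Draw the tabular part of one patient (no imaging).

    Returns ``(clinical, pcr, latent_response, axes_mm, survival)``, using the
    same random substream that :func:`generate_case` uses, so the tabular and
    imaging paths agree patient-for-patient.
    """
    if intercept is None:
        intercept = _pcr_intercept(config)
    rng, _, surv_rng = _patient_rngs(config.seed, index)
    s_idx = rng.choice(len(SUBTYPES), p=SUBTYPE_FREQS)
    subtype = SUBTYPES[s_idx]
    if subtype == "HR+/HER2-":
        er = "positive" if rng.random() < 0.9 else "negative"
        pr = "positive" if (rng.random() < 0.7 or er == "negative") else "negative"
        her2 = "negative"
    elif subtype == "HER2+":
        er = "positive" if rng.random() < 0.5 else "negative"
        pr = "positive" if rng.random() < 0.4 else "negative"
        her2 = "positive"
    else:
        er = pr = her2 = "negative"
    ki67 = "positive" if rng.random() < 0.7 else "negative"
    age = float(np.clip(rng.normal(51.0, 10.0), 25.0, 85.0))
    menopause = "post" if rng.random() < 1.0 / (1.0 + np.exp(-(age - 50.0) / 3.0)) else "pre"
    lo, hi = config.tumor_radius_mm
    axes_mm = rng.uniform(lo, hi, size=3)
    ld = float(2.0 * axes_mm.max() * (1.0 + rng.normal(0.0, 0.05)))
    t_stage = "T3-T4" if ld > 50.0 else "T1-T2"

    p = 1.0 / (1.0 + np.exp(-(intercept + np.log(config.subtype_pcr_odds[s_idx]))))
    pcr = bool(rng.random() < p)
    latent = float(rng.uniform(0.8, 1.0)) if pcr else float(rng.uniform(0.0, 0.12))

    survival = None
    if config.with_survival:
        lam_rfs = np.log(2.0) / 60.0 * np.exp(config.survival_link * latent)
        lam_os = np.log(2.0) / 90.0 * np.exp(config.survival_link * latent)
        t_rfs = surv_rng.exponential(1.0 / lam_rfs)
        t_os = surv_rng.exponential(1.0 / lam_os)
        c_rfs = surv_rng.uniform(24.0, 96.0)
        c_os = surv_rng.uniform(24.0, 96.0)
        survival = SurvivalRecord(
            rfs_time=float(min(t_rfs, c_rfs)), rfs_event=bool(t_rfs <= c_rfs),
            os_time=float(min(t_os, c_os)), os_event=bool(t_os <= c_os),
        )
    clinical = ClinicalRecord(
        age=age, menopause=menopause, baseline_LD_mm=ld, clinical_T_stage=t_stage,
        er=er, pr=pr, her2=her2, ki67=ki67, molecular_subtype=subtype,
    )
    return clinical, pcr, latent, axes_mm, survival


def _grid_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _tumor_mask(shape, spacing, center_mm, axes_mm, boundary_field):
    zz, yy, xx = _grid_mm(shape, spacing)
    q = (((zz - center_mm[0]) / axes_mm[0]) ** 2
         + ((yy - center_mm[1]) / axes_mm[1]) ** 2
         + ((xx - center_mm[2]) / axes_mm[2]) ** 2)
    mask = (q + 0.25 * boundary_field) <= 1.0
    if not mask.any():
        raise ConfigError("tumor mask is empty; grid too small for the tumor")
    return mask


def _voronoi_labels(mask, spacing, seeds_mm):
    pts = np.argwhere(mask).astype(float) * np.asarray(spacing)
    d = np.linalg.norm(pts[:, None, :] - seeds_mm[None, :, :], axis=2)
    lab = np.zeros(mask.shape, dtype=np.int16)
    lab[mask] = np.argmin(d, axis=1) + 1
    return lab


def generate_case(config: PhantomConfig, index: int,
                  intercept: float | None = None) -> LongitudinalCase:
    """Generate one patient of the phantom cohort (deterministic in seed+index)."""
    config.validate()
    if intercept is None:
        intercept = _pcr_intercept(config)
    clinical, pcr, latent, axes_mm, survival = sample_clinical(config, index, intercept)
    _, rng, _ = _patient_rngs(config.seed, index)
    pid = f"P{index:04d}"
    shape = tuple(config.grid_shape)
    spacing = tuple(config.voxel_spacing_mm)
    extent = np.asarray(shape) * np.asarray(spacing)
    center_mm = extent / 2.0 + rng.uniform(-2.0, 2.0, size=3)

    # habitat kinetics sorted by descending peak enhancement -> canonical order
    order = np.argsort([-p[2] for p in config.habitat_kinetic_params])
    kinetics = [config.habitat_kinetic_params[i] for i in order]
    attenuation = np.asarray(config.response_effect.attenuation, dtype=float)[order]

    boundary = gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    boundary /= max(boundary.std(), 1e-9)
    texture = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    texture /= max(texture.std(), 1e-9)
    # background parenchymal enhancement: blobby enhancing tissue outside the
    # tumor whose intensity drifts between scans
    bg_field = gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    bg_field = np.clip(bg_field / max(bg_field.std(), 1e-9), 0.0, None) ** 2
    bg_gain_tp = config.background_enhancement * np.exp(
        rng.normal(0.0, config.background_drift_sigma, size=2))
    # fine-scale mottle field and its per-patient baseline amplitude
    mottle_field = gaussian_filter(rng.standard_normal(shape), sigma=1.2)
    mottle_field /= max(mottle_field.std(), 1e-9)
    mottle_base = rng.uniform(*config.mottle_baseline)

    # per-patient habitat enhancement profile jitter (shared across timepoints)
    k = config.n_habitats
    profile = np.exp(rng.normal(0.0, config.profile_jitter_sigma, size=k))
    if pcr:
        profile[0] *= 1.0 + config.response_effect.t0_profile_tilt
    drift = np.exp(rng.normal(0.0, config.scan_drift_sigma, size=k))

    mask0 = _tumor_mask(shape, spacing, center_mm, axes_mm, boundary)
    shrink = 1.0 - config.response_effect.volume_shrink * latent
    nonresp_wobble = np.exp(rng.normal(0.0, 0.02))
    axes1 = axes_mm * (shrink ** (1.0 / 3.0)) * nonresp_wobble
    mask1 = _tumor_mask(shape, spacing, center_mm, axes1, boundary)

    vox0 = np.argwhere(mask0)
    seeds_idx = vox0[rng.choice(len(vox0), size=min(k, len(vox0)), replace=False)]
    seeds_mm = seeds_idx.astype(float) * np.asarray(spacing)
    if len(seeds_mm) < k:  # degenerate tiny mask: duplicate seeds
        seeds_mm = np.vstack([seeds_mm] * k)[:k]
    labels0 = _voronoi_labels(mask0, spacing, seeds_mm)
    seeds1 = center_mm + (seeds_mm - center_mm) * (shrink ** (1.0 / 3.0))
    labels1 = _voronoi_labels(mask1, spacing, seeds1)

    times = np.asarray(config.phase_times_s, dtype=float)
    curves = np.stack([enhancement_curve(times, *kin) for kin in kinetics])  # (k, P)

    # habitat-1 core-to-rim distance (for the responder necrosis gradient)
    zz, yy, xx = _grid_mm(shape, spacing)
    d1 = np.sqrt((zz - seeds1[0][0]) ** 2 + (yy - seeds1[0][1]) ** 2 + (xx - seeds1[0][2]) ** 2)

    bg_curve = curves[min(1, k - 1)]  # parenchyma enhances like a mid habitat

    def render(mask, labels, gains, necrosis: float, mottle: float,
               bg_gain: float) -> np.ndarray:
        mod = 1.0 + config.texture_amplitude * texture
        vols = np.empty((config.n_phases, *shape), dtype=np.float32)
        enh = np.zeros(shape, dtype=float)
        for p, t in enumerate(times):
            for h in range(k):
                sel = labels == h + 1
                enh[sel] = curves[h, p] * gains[h]
            sel1 = labels == 1
            if sel1.any():
                if necrosis > 0.0:
                    rho = d1 / max(d1[sel1].max(), 1e-9)
                    grad = 1.0 - necrosis * (1.0 - np.clip(rho, 0.0, 1.0))
                    enh[sel1] *= grad[sel1]
                if mottle > 0.0:
                    enh[sel1] *= np.clip(1.0 + mottle * mottle_field[sel1],
                                         0.05, None)
            vol = _BACKGROUND * (1.0 + bg_curve[p] * bg_gain * bg_field)
            vol[mask] = _S0 * (1.0 + enh[mask] * mod[mask])
            vol += rng.normal(0.0, config.noise_sigma, size=shape)
            vols[p] = vol.astype(np.float32)
            enh[:] = 0.0
        return vols

    gains0 = profile
    gains1 = profile * (1.0 - attenuation * latent) * drift
    necrosis1 = config.response_effect.core_gradient * latent
    mottle1 = mottle_base + config.response_effect.mottle_gain * latent
    phases0 = render(mask0, labels0, gains0, 0.0, mottle_base, bg_gain_tp[0])
    phases1 = render(mask1, labels1, gains1, necrosis1, mottle1, bg_gain_tp[1])

    study0 = DceStudy(pid, "T0", phases0, times.copy(), spacing, mask0.astype(np.uint8))
    study1 = DceStudy(pid, "T1", phases1, times.copy(), spacing, mask1.astype(np.uint8))
    return LongitudinalCase(
        patient_id=pid, study_T0=study0, study_T1=study1, clinical=clinical,
        pcr_label=pcr, survival=survival, truth_habitats=labels0,
        latent_response=latent,
    )


def generate_cohort(config: PhantomConfig) -> list[LongitudinalCase]:
    """Generate the full phantom cohort (see :func:`generate_case`)."""
    config.validate()
    intercept = _pcr_intercept(config)
    return [generate_case(config, i, intercept) for i in range(config.n_patients)]


# ---- serialization --------------------------------------------------------


def _nifti_affine(spacing) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


def _write_nifti(path: Path, data: np.ndarray, spacing) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _nifti_affine(spacing))
    nib.save(img, str(path))


def _read_nifti(path: Path, patient_id: str, timepoint: str):
    import nibabel as nib

    if not path.exists():
        raise CohortIOError(
            f"missing file {path.name} (patient {patient_id}, timepoint {timepoint})"
        )
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
    except Exception as exc:  # corrupt file
        raise CohortIOError(
            f"unreadable file {path.name} (patient {patient_id}, timepoint {timepoint}): {exc}"
        ) from exc
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return data, spacing


def write_cohort(cases: list[LongitudinalCase], directory) -> Path:
    """Serialize a cohort (NIfTI volumes + CSV tables + JSON manifest)."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    images: list[dict] = []
    truth_files: dict[str, str] = {}
    clin_rows, surv_rows = [], []
    for case in cases:
        for study in (case.study_T0, case.study_T1):
            for p in range(study.phases.shape[0]):
                fname = f"{case.patient_id}_{study.timepoint}_phase{p}.nii.gz"
                _write_nifti(directory / fname, study.phases[p], study.voxel_spacing_mm)
                images.append({
                    "file": fname, "patient_id": case.patient_id,
                    "timepoint": study.timepoint, "kind": "phase", "phase": p,
                    "time_s": float(study.phase_times_s[p]),
                })
            mname = f"{case.patient_id}_{study.timepoint}_mask.nii.gz"
            _write_nifti(directory / mname, study.tumor_mask, study.voxel_spacing_mm)
            images.append({
                "file": mname, "patient_id": case.patient_id,
                "timepoint": study.timepoint, "kind": "mask",
            })
        if case.truth_habitats is not None:
            tname = f"{case.patient_id}_truth_habitats.nii.gz"
            _write_nifti(directory / tname, case.truth_habitats,
                         case.study_T0.voxel_spacing_mm)
            truth_files[case.patient_id] = tname
        c = case.clinical
        clin_rows.append(dict(
            patient_id=case.patient_id, age=c.age, menopause=c.menopause,
            ld_mm=c.baseline_LD_mm, t_stage=c.clinical_T_stage, er=c.er, pr=c.pr,
            her2=c.her2, ki67=c.ki67, subtype=c.molecular_subtype,
            pcr=int(case.pcr_label),
        ))
        if case.survival is not None:
            s = case.survival
            surv_rows.append(dict(
                patient_id=case.patient_id, rfs_months=s.rfs_time,
                rfs_event=int(s.rfs_event), os_months=s.os_time,
                os_event=int(s.os_event),
            ))
    pd.DataFrame(clin_rows).to_csv(directory / "clinical.csv", index=False)
    if surv_rows:
        pd.DataFrame(surv_rows).to_csv(directory / "survival.csv", index=False)
    case0 = cases[0]
    manifest = {
        "n_patients": len(cases),
        "n_phases": int(case0.study_T0.phases.shape[0]),
        "phase_times_s": [float(t) for t in case0.study_T0.phase_times_s],
        "voxel_spacing_mm": list(case0.study_T0.voxel_spacing_mm),
        "images": images,
        "truth_habitats": truth_files,
        "clinical_csv": "clinical.csv",
        "survival_csv": "survival.csv" if surv_rows else None,
        "latent_response": {c.patient_id: c.latent_response for c in cases
                            if c.latent_response is not None},
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_cohort(directory) -> list[LongitudinalCase]:
    """Load a cohort written by :func:`write_cohort`."""
    import pandas as pd

    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise CohortIOError(f"missing file {mpath}")
    manifest = json.loads(mpath.read_text())
    clin = pd.read_csv(directory / manifest["clinical_csv"]).set_index("patient_id")
    surv = None
    if manifest.get("survival_csv"):
        surv = pd.read_csv(directory / manifest["survival_csv"]).set_index("patient_id")
    by_patient: dict[str, dict] = {}
    for entry in manifest["images"]:
        by_patient.setdefault(entry["patient_id"], []).append(entry)
    times = np.asarray(manifest["phase_times_s"], dtype=float)
    latents = manifest.get("latent_response", {})
    cases = []
    for pid, entries in by_patient.items():
        studies = {}
        for tp in ("T0", "T1"):
            phase_entries = sorted(
                (e for e in entries if e["timepoint"] == tp and e["kind"] == "phase"),
                key=lambda e: e["phase"],
            )
            vols, spacing = [], None
            for e in phase_entries:
                data, spacing = _read_nifti(directory / e["file"], pid, tp)
                vols.append(data)
            mask_entry = next(e for e in entries if e["timepoint"] == tp and e["kind"] == "mask")
            mask, _ = _read_nifti(directory / mask_entry["file"], pid, tp)
            studies[tp] = DceStudy(pid, tp, np.stack(vols), times.copy(),
                                   tuple(spacing), (mask > 0.5).astype(np.uint8))
        row = clin.loc[pid]
        clinical = ClinicalRecord(
            age=float(row.age), menopause=str(row.menopause),
            baseline_LD_mm=float(row.ld_mm), clinical_T_stage=str(row.t_stage),
            er=str(row.er), pr=str(row.pr), her2=str(row.her2), ki67=str(row.ki67),
            molecular_subtype=str(row.subtype),
        )
        survival = None
        if surv is not None and pid in surv.index:
            s = surv.loc[pid]
            survival = SurvivalRecord(float(s.rfs_months), bool(s.rfs_event),
                                      float(s.os_months), bool(s.os_event))
        truth = None
        tname = manifest.get("truth_habitats", {}).get(pid)
        if tname:
            tdata, _ = _read_nifti(directory / tname, pid, "T0")
            truth = np.rint(tdata).astype(np.int16)
        cases.append(LongitudinalCase(
            patient_id=pid, study_T0=studies["T0"], study_T1=studies["T1"],
            clinical=clinical, pcr_label=bool(row.pcr), survival=survival,
            truth_habitats=truth, latent_response=latents.get(pid),
        ))
    cases.sort(key=lambda c: c.patient_id)
    return cases
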