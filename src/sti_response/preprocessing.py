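"""Resampling, peak-phase selection, region cropping and normalization.

Turns each study into a fixed set of fixed-size region patches: one
whole-tumor patch plus one patch per habitat, at both timepoints.  Regions
are cropped independently per timepoint (the model compares embeddings, not
voxels, across time), so no registration is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DataError
from .synthetic import DceStudy

logger = logging.getLogger("sti_response")


@dataclass(frozen=True)
class PreprocConfig:
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patch_shape: tuple[int, int, int] = (32, 32, 32)
    mask_margin_mm: float = 4.0
    normalization: str = "zscore_within_mask"  # | "minmax_volume"
    peak_phase_rule: str = "max_mean_mask_enhancement"  # | "fixed_index"
    fixed_peak_index: int = 2
    enabled: bool = True  # ablation switch: raw first-phase crop when False

    def validate(self) -> None:
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ConfigError("target spacing must be positive")
        if any(s <= 0 for s in self.patch_shape):
            raise ConfigError("patch_shape must be positive")
        if self.normalization not in ("zscore_within_mask", "minmax_volume"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if self.peak_phase_rule not in ("max_mean_mask_enhancement", "fixed_index"):
            raise ConfigError(f"unknown peak phase rule {self.peak_phase_rule!r}")


@dataclass
class RegionPatch:
    patient_id: str
    timepoint: str
    region: str  # "whole" or "habitat_<k>"
    volume: np.ndarray  # patch_shape, float32
    mask_fraction: float
    bbox: tuple[tuple[int, int], ...] | None = None  # crop box in volume coords


def select_peak_phase(study: DceStudy, rule: str = "max_mean_mask_enhancement",
                      fixed_index: int = 2) -> int:
    """Index of the post-contrast phase with maximal mean within-mask
    enhancement relative to the first phase (ties -> earliest index)."""
    if study.phases.shape[0] < 2:
        raise DataError("need at least two phases")
    if rule == "fixed_index":
        return int(np.clip(fixed_index, 0, study.phases.shape[0] - 1))
    mask = study.tumor_mask > 0
    if not mask.any():
        raise DataError("empty tumor mask")
    ref = study.phases[0][mask].astype(np.float64)
    means = np.array([(study.phases[p][mask] - ref).mean()
                      for p in range(study.phases.shape[0])])
    return int(np.argmax(means))  # argmax returns the earliest maximum


def resample_to_spacing(volume: np.ndarray, spacing_in, spacing_out,
                        is_mask: bool = False) -> np.ndarray:
    """Trilinear (nearest-neighbor for masks) resampling to a new voxel size."""
    spacing_in = np.asarray(spacing_in, dtype=float)
    spacing_out = np.asarray(spacing_out, dtype=float)
    if np.any(spacing_in <= 0) or np.any(spacing_out <= 0):
        raise ConfigError("spacings must be positive")
    if np.allclose(spacing_in, spacing_out):
        return np.asarray(volume).copy()
    factors = spacing_in / spacing_out
    out_shape = np.rint(np.asarray(volume.shape) * factors).astype(int)
    if np.any(out_shape < 1):
        raise ConfigError("resampling would produce an empty volume")
    order = 0 if is_mask else 1
    exact = out_shape / np.asarray(volume.shape)
    out = ndimage.zoom(np.asarray(volume, dtype=np.float32), exact, order=order,
                       mode="nearest", grid_mode=True)
    return out


def resample_study(study: DceStudy, config: PreprocConfig) -> DceStudy:
    """Resample every phase (trilinear) and the mask (nearest) of a study."""
    config.validate()
    if np.allclose(study.voxel_spacing_mm, config.target_spacing_mm):
        return study
    phases = np.stack([
        resample_to_spacing(study.phases[p], study.voxel_spacing_mm,
                            config.target_spacing_mm)
        for p in range(study.phases.shape[0])
    ])
    mask = resample_to_spacing(study.tumor_mask, study.voxel_spacing_mm,
                               config.target_spacing_mm, is_mask=True)
    mask = (mask > 0.5).astype(np.uint8)
    if mask.sum() < 1:  # guard against a tumor vanishing at coarse spacing
        mask.flat[np.argmax(phases[-1])] = 1
    return DceStudy(study.patient_id, study.timepoint, phases,
                    study.phase_times_s.copy(), tuple(config.target_spacing_mm), mask)


def _bbox(mask: np.ndarray, margin_vox: np.ndarray) -> tuple[tuple[int, int], ...]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin_vox, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin_vox, mask.shape)
    return tuple((int(a), int(b)) for a, b in zip(lo, hi))


def crop_region(volume: np.ndarray, region_mask: np.ndarray, config: PreprocConfig,
                patient_id: str = "", timepoint: str = "", region: str = "whole",
                ) -> RegionPatch:
    """Crop the region bounding box (plus margin), resize to ``patch_shape``
    and normalize.  An empty habitat mask yields a zero patch with
    ``mask_fraction`` 0 so the region count stays fixed at K+1."""
    config.validate()
    shape = tuple(config.patch_shape)
    region_mask = np.asarray(region_mask) > 0
    if not region_mask.any():
        if region == "whole":
            raise DataError("whole-tumor mask is empty")
        logger.warning("empty region %s for %s %s: emitting zero patch",
                       region, patient_id, timepoint)
        return RegionPatch(patient_id, timepoint, region,
                           np.zeros(shape, dtype=np.float32), 0.0, None)
    margin_vox = np.rint(config.mask_margin_mm
                         / np.asarray(config.target_spacing_mm)).astype(int)
    box = _bbox(region_mask, margin_vox)
    sl = tuple(slice(a, b) for a, b in box)
    sub = np.asarray(volume, dtype=np.float32)[sl]
    sub_mask = region_mask[sl]
    factors = np.asarray(shape) / np.asarray(sub.shape)
    patch = ndimage.zoom(sub, factors, order=1, mode="nearest", grid_mode=True)
    pmask = ndimage.zoom(sub_mask.astype(np.float32), factors, order=0,
                         mode="nearest", grid_mode=True) > 0.5
    if config.normalization == "zscore_within_mask":
        vals = patch[pmask]
        mu = float(vals.mean()) if vals.size else 0.0
        sd = float(vals.std()) if vals.size else 1.0
        patch = (patch - mu) / max(sd, 1e-6)
    else:
        lo, hi = float(patch.min()), float(patch.max())
        patch = (patch - lo) / max(hi - lo, 1e-6)
    return RegionPatch(patient_id, timepoint, region, patch.astype(np.float32),
                       float(pmask.mean()), box)


def extract_region_patches(study: DceStudy, habitat_labels: np.ndarray,
                           config: PreprocConfig, k: int | None = None,
                           ) -> list[RegionPatch]:
    """One whole-tumor patch plus one patch per habitat for a study whose
    grid already matches ``habitat_labels`` (run :func:`resample_study`
    first).  Always returns K+1 patches, zero-filled for empty habitats."""
    config.validate()
    if config.enabled:
        peak = select_peak_phase(study, config.peak_phase_rule, config.fixed_peak_index)
        vol = study.phases[peak]
        norm_cfg = config
    else:  # preprocessing ablation: raw peak-less, unnormalized crop
        vol = study.phases[-1]
        norm_cfg = PreprocConfig(
            target_spacing_mm=config.target_spacing_mm,
            patch_shape=config.patch_shape, mask_margin_mm=config.mask_margin_mm,
            normalization="minmax_volume", peak_phase_rule="fixed_index",
            fixed_peak_index=study.phases.shape[0] - 1)
    k = int(habitat_labels.max()) if k is None else int(k)
    patches = [crop_region(vol, study.tumor_mask, norm_cfg, study.patient_id,
                           study.timepoint, "whole")]
    for h in range(1, k + 1):
        patches.append(crop_region(vol, habitat_labels == h, norm_cfg,
                                   study.patient_id, study.timepoint, f"habitat_{h}"))
    return patches
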