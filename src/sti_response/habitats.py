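"""Kinetic habitat segmentation.

Each tumor is partitioned into K "habitats" — subregions with similar
contrast-enhancement kinetics — by per-tumor k-means on three voxelwise
kinetic features (wash-in slope, wash-out slope, peak enhancement).
Habitats are relabeled canonically by descending mean peak enhancement
(habitat 1 = most enhancing), which makes labels comparable across patients
and, together with profile matching, across timepoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .errors import ConfigError, DataError
from .synthetic import DceStudy

logger = logging.getLogger("sti_response")

_EPS = 1e-6


@dataclass
class KineticMaps:
    """Voxelwise kinetic feature maps, defined on the tumor mask.

    Relative enhancement is E(t) = (S(t) - S(t0)) / max(S(t0), eps); the
    wash-in slope is the least-squares slope of E over the phases up to the
    per-voxel peak, the wash-out slope the (signed) slope after it.
    """

    wash_in_slope: np.ndarray
    wash_out_slope: np.ndarray
    peak_enhancement: np.ndarray
    time_to_peak: np.ndarray
    mask: np.ndarray


@dataclass
class HabitatMap:
    labels: np.ndarray  # int16, 0 background, 1..K habitats
    K: int

    def validate(self, mask: np.ndarray) -> None:
        if not np.array_equal(self.labels > 0, np.asarray(mask) > 0):
            raise DataError("habitat labels do not partition the tumor mask")


def compute_kinetic_maps(study: DceStudy) -> KineticMaps:
    """Derive wash-in/wash-out/peak/time-to-peak maps from a DCE series."""
    phases = study.phases
    times = np.asarray(study.phase_times_s, dtype=float)
    if phases.shape[0] < 3:
        raise DataError("need at least 3 phases for kinetic maps")
    if np.any(np.diff(times) <= 0):
        raise DataError("phase times must be strictly increasing")
    mask = study.tumor_mask > 0
    if not mask.any():
        raise DataError("empty tumor mask")
    s = phases[:, mask].astype(np.float64)  # (P, V)
    s0 = np.maximum(s[0], _EPS)
    e = (s - s[0]) / s0  # (P, V); e[0] = 0 so the peak is >= 0
    peak_idx = np.argmax(e, axis=0)
    peak = e[peak_idx, np.arange(e.shape[1])]
    ttp = times[peak_idx]

    wash_in = np.zeros(e.shape[1])
    wash_out = np.zeros(e.shape[1])
    for p in np.unique(peak_idx):
        sel = peak_idx == p
        if p >= 1:
            t_pre, e_pre = times[: p + 1], e[: p + 1][:, sel]
            tc = t_pre - t_pre.mean()
            wash_in[sel] = (tc[:, None] * (e_pre - e_pre.mean(axis=0))).sum(axis=0) \
                / (tc * tc).sum()
        if p <= len(times) - 2:
            t_post, e_post = times[p:], e[p:][:, sel]
            tc = t_post - t_post.mean()
            wash_out[sel] = (tc[:, None] * (e_post - e_post.mean(axis=0))).sum(axis=0) \
                / (tc * tc).sum()

    def full(v):
        out = np.zeros(mask.shape, dtype=np.float32)
        out[mask] = v
        return out

    return KineticMaps(full(wash_in), full(wash_out), full(np.maximum(peak, 0.0)),
                       full(ttp), mask.astype(np.uint8))


def _features(kin: KineticMaps, mask: np.ndarray) -> np.ndarray:
    return np.column_stack([
        kin.wash_in_slope[mask], kin.wash_out_slope[mask], kin.peak_enhancement[mask],
    ])


def segment_habitats(kinetics: KineticMaps, mask: np.ndarray, K: int,
                     seed: int = 0) -> HabitatMap:
    """Per-tumor k-means (10 restarts, fixed seed) on standardized kinetic
    features, relabeled by descending mean peak enhancement."""
    if K < 1:
        raise ConfigError("K must be >= 1")
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise DataError("empty tumor mask")
    feats = _features(kinetics, mask)
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    z = (feats - mu) / np.maximum(sd, _EPS)
    n_distinct = len(np.unique(np.round(z, 9), axis=0))
    k_eff = min(K, n_distinct)
    if k_eff < K:
        logger.warning("only %d distinct kinetic profiles; habitats %d..%d empty",
                       n_distinct, k_eff + 1, K)
    if k_eff == 1:
        raw = np.zeros(len(z), dtype=int)
    else:
        km = KMeans(n_clusters=k_eff, n_init=10, random_state=int(seed) % (2**31))
        raw = km.fit_predict(z)
    # canonical relabeling: habitat 1 has the highest mean peak enhancement
    pe = kinetics.peak_enhancement[mask]
    means = np.array([pe[raw == c].mean() for c in range(k_eff)])
    order = np.argsort(-means, kind="stable")
    relabel = np.empty(k_eff, dtype=np.int16)
    relabel[order] = np.arange(1, k_eff + 1)
    labels = np.zeros(mask.shape, dtype=np.int16)
    labels[mask] = relabel[raw]
    return HabitatMap(labels=labels, K=K)


def habitat_profiles(kinetics: KineticMaps, habitat_map: HabitatMap) -> np.ndarray:
    """Mean (wash_in, wash_out, peak) kinetic profile per habitat; empty
    habitats get NaN rows."""
    mask = kinetics.mask > 0
    feats = _features(kinetics, mask)
    labs = habitat_map.labels[mask]
    out = np.full((habitat_map.K, 3), np.nan)
    for h in range(1, habitat_map.K + 1):
        sel = labs == h
        if sel.any():
            out[h - 1] = feats[sel].mean(axis=0)
    return out


def match_habitats_across_time(map_t0: HabitatMap, map_t1: HabitatMap,
                               kin_t0: KineticMaps, kin_t1: KineticMaps,
                               ) -> tuple[HabitatMap, HabitatMap]:
    """Permute T1 habitat labels to best match the T0 habitat kinetic
    profiles (optimal assignment on the profile-distance matrix).  T0 keeps
    its canonical order."""
    if map_t0.K != map_t1.K:
        raise DataError("habitat maps must share K")
    k = map_t0.K
    if k == 1:
        return map_t0, map_t1
    p0 = habitat_profiles(kin_t0, map_t0)
    p1 = habitat_profiles(kin_t1, map_t1)
    scale = np.nanmax(np.abs(np.vstack([p0, p1])), axis=0)
    scale = np.where(np.isfinite(scale) & (scale > 0), scale, 1.0)
    cost = np.zeros((k, k))
    big = 1e6
    for i in range(k):
        for j in range(k):
            if np.isnan(p0[i]).any() or np.isnan(p1[j]).any():
                cost[i, j] = big  # empty habitats match arbitrarily, last
            else:
                cost[i, j] = np.linalg.norm((p0[i] - p1[j]) / scale)
    rows, cols = linear_sum_assignment(cost)
    perm = np.zeros(k + 1, dtype=np.int16)  # T1 old label -> new label
    for i, j in zip(rows, cols):
        perm[j + 1] = i + 1
    new_labels = perm[map_t1.labels]
    return map_t0, HabitatMap(labels=new_labels.astype(np.int16), K=k)
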