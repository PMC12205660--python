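"""The spatiotemporal interaction (STI) network.

A Siamese 3-D convolutional encoder (one set of weights shared by every
region patch at every timepoint) produces one token per region; multi-head
self-attention over the region tokens of a timepoint ("spatial attention")
pools them into a timepoint embedding; a transformer block over the
two-timepoint sequence ("temporal attention", T0 queries attend to T1 keys
and vice versa) fuses pre- and early-treatment embeddings; a two-layer head
maps the fused embedding to a pCR probability.

Every model variant is reachable through ablation flags:
single-timepoint models, whole-tumor-only models, mean pooling instead of
spatial attention, and concatenation or subtraction instead of temporal
attention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

from . import nn
from .errors import ConfigError, DataError
from .metrics import roc_auc, youden_threshold

REGION_WHOLE = 0  # index of the whole-tumor patch along the region axis


@dataclass(frozen=True)
class AblationFlags:
    use_T0: bool = True
    use_T1: bool = True
    use_subregions: bool = True
    use_whole_tumor: bool = True
    use_spatial_attention: bool = True
    use_temporal_attention: bool = True


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 25
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    class_weighting: bool = True
    folds: int = 5
    grid: dict | None = None  # e.g. {"learning_rate": [...], "weight_decay": [...]}
    layerwise_unfreeze: bool = False


@dataclass(frozen=True)
class StiConfig:
    K: int = 3
    patch_shape: tuple[int, int, int] = (32, 32, 32)
    embed_dim: int = 128
    encoder_channels: tuple[int, ...] = (8, 16, 32)
    n_heads_spatial: int = 4
    n_heads_temporal: int = 4
    stem_pool: int = 2  # fixed average-pool factor ahead of the conv stages
    dropout: float = 0.0
    ablation: AblationFlags = field(default_factory=AblationFlags)
    fusion_when_no_temporal_attention: str = "concatenate"  # | "subtract"
    seed: int = 0
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def validate(self) -> None:
        ab = self.ablation
        if not (ab.use_T0 or ab.use_T1):
            raise ConfigError("at least one timepoint must be enabled")
        if not (ab.use_subregions or ab.use_whole_tumor):
            raise ConfigError("at least one region source must be enabled")
        if self.embed_dim % self.n_heads_spatial or self.embed_dim % self.n_heads_temporal:
            raise ConfigError("attention head counts must divide embed_dim")
        if self.fusion_when_no_temporal_attention not in ("concatenate", "subtract"):
            raise ConfigError("unknown fusion mode")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")

    def region_indices(self) -> list[int]:
        idx = [REGION_WHOLE] if self.ablation.use_whole_tumor else []
        if self.ablation.use_subregions:
            idx += list(range(1, self.K + 1))
        return idx

    def timepoints(self) -> list[int]:
        return [t for t, on in enumerate((self.ablation.use_T0, self.ablation.use_T1)) if on]


@dataclass
class PredictionResult:
    patient_id: str
    score: float
    label_pred: bool
    threshold: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ConfigError("score must lie in [0, 1]")


class RegionEncoder(nn.Module):
    """Shared-weight (Siamese) 3-D conv encoder: stride-2 conv/ReLU stages,
    global average pooling, linear projection, layer norm."""

    def __init__(self, config: StiConfig, rng: np.random.Generator):
        super().__init__()
        chans = (1, *config.encoder_channels)
        self.stem_pool = config.stem_pool
        self.convs = [nn.Conv3d(chans[i], chans[i + 1], rng, stride=2)
                      for i in range(len(chans) - 1)]
        self.proj = nn.Linear(chans[-1], config.embed_dim, rng)
        self.norm = nn.LayerNorm(config.embed_dim)

    @staticmethod
    def pool_stem(x: np.ndarray, factor: int) -> np.ndarray:
        """Fixed (parameter-free) average pooling over the trailing three
        axes, one axis at a time to keep the reductions contiguous."""
        if factor <= 1:
            return x
        *lead, d, h, w = x.shape
        if d % factor or h % factor or w % factor:
            raise ConfigError("patch shape must be divisible by stem_pool")
        x = np.ascontiguousarray(x)
        x = x.reshape(*lead, d // factor, factor, h * w).mean(axis=-2)
        x = x.reshape(*lead, d // factor, h // factor, factor, w).mean(axis=-2)
        x = x.reshape(*lead, d // factor, h // factor, w // factor, factor).mean(axis=-1)
        return x

    def __call__(self, x: nn.Tensor, retain: list | None = None) -> nn.Tensor:
        h = x
        for conv in self.convs:
            h = conv(h).relu()
            if retain is not None:
                retain.append(h)
        h = h.mean(axis=(2, 3, 4))  # global average pool -> (N, C)
        return self.norm(self.proj(h))


class StiModel(nn.Module):
    def __init__(self, config: StiConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        e = config.embed_dim
        self.encoder = RegionEncoder(config, rng)
        # token-type embeddings: whole-tumor vs habitat (habitats share one
        # type so that spatial attention is permutation-invariant in them)
        self.region_type = nn.Parameter(rng.normal(0, 0.02, size=(2, e)))
        self.time_type = nn.Parameter(rng.normal(0, 0.02, size=(2, e)))
        self.spatial_norm = nn.LayerNorm(e)
        self.spatial_attn = nn.MultiHeadAttention(e, config.n_heads_spatial, rng)
        self.temporal_norm = nn.LayerNorm(e)
        self.temporal_attn = nn.MultiHeadAttention(e, config.n_heads_temporal, rng)
        self.temporal_proj = nn.Linear(2 * e, e, rng)
        self.concat_proj = nn.Linear(2 * e, e, rng)
        self.subtract_proj = nn.Linear(e, e, rng)
        self.head1 = nn.Linear(e, 64, rng)
        self.head2 = nn.Linear(64, 1, rng, zero_init=True)  # untrained score = 0.5
        self._drop_rng = np.random.default_rng(config.seed + 1)
        self.threshold = 0.5

    # -- stages -------------------------------------------------------------

    def pool_dataset(self, x: np.ndarray) -> np.ndarray:
        """Apply the fixed pooling stem to a patch tensor once up front."""
        return RegionEncoder.pool_stem(x.astype(np.float32, copy=False),
                                       self.config.stem_pool)

    def encode_regions(self, x: np.ndarray, retain: list | None = None,
                       pooled: bool = False) -> nn.Tensor:
        """Encode patches (M, D, H, W) -> (M, E) with the shared encoder."""
        if not pooled:
            x = RegionEncoder.pool_stem(x, self.config.stem_pool)
        t = nn.Tensor(x[:, None])  # leaf: no input gradient is computed
        return self.encoder(t, retain=retain)

    def spatial_pool(self, tokens: nn.Tensor, region_idx: list[int]) -> nn.Tensor:
        """Tokens (N, R, E) for one timepoint -> (N, E).

        With spatial attention disabled this is exactly the arithmetic mean
        of the tokens.
        """
        if tokens.shape[1] == 0:
            raise DataError("empty token set")
        if not self.config.ablation.use_spatial_attention:
            return tokens.mean(axis=1)
        type_ids = [0 if r == REGION_WHOLE else 1 for r in region_idx]
        tok = tokens + self.region_type[np.array(type_ids)]
        h = tok + self.spatial_attn(self.spatial_norm(tok), self.spatial_norm(tok))
        return h.mean(axis=1)

    def temporal_fuse(self, emb_t0: nn.Tensor, emb_t1: nn.Tensor) -> nn.Tensor:
        """Fuse the two timepoint embeddings (N, E) x 2 -> (N, E)."""
        cfg = self.config
        if not cfg.ablation.use_temporal_attention:
            if cfg.fusion_when_no_temporal_attention == "subtract":
                return self.subtract_proj(emb_t1 - emb_t0)
            return self.concat_proj(nn.concat([emb_t0, emb_t1], axis=-1))
        n, e = emb_t0.shape
        seq = nn.concat([
            (emb_t0 + self.time_type[0]).reshape(n, 1, e),
            (emb_t1 + self.time_type[1]).reshape(n, 1, e),
        ], axis=1)
        h = seq + self.temporal_attn(self.temporal_norm(seq), self.temporal_norm(seq))
        flat = nn.concat([h[:, 0, :], h[:, 1, :]], axis=-1)
        return self.temporal_proj(flat)

    # -- forward ------------------------------------------------------------

    def forward_logits(self, x: np.ndarray, retain: list | None = None,
                       return_embedding: bool = False, pooled: bool = False):
        """x: (N, 2, K+1, D, H, W) patch tensor; returns logits (N,)."""
        cfg = self.config
        regions = cfg.region_indices()
        tps = cfg.timepoints()
        n = x.shape[0]
        sel = x[:, tps][:, :, regions]  # (N, T, R, D, H, W)
        t_cnt, r_cnt = len(tps), len(regions)
        flat = sel.reshape(n * t_cnt * r_cnt, *sel.shape[3:])
        enc = self.encode_regions(flat, retain=retain, pooled=pooled)  # (N*T*R, E)
        tokens = enc.reshape(n, t_cnt, r_cnt, cfg.embed_dim)
        per_tp = [self.spatial_pool(tokens[:, t, :, :], regions) for t in range(t_cnt)]
        if t_cnt == 2:
            fused = self.temporal_fuse(per_tp[0], per_tp[1])
        else:
            fused = per_tp[0]
        if self.training and cfg.dropout > 0:
            keep = (self._drop_rng.random(fused.shape) >= cfg.dropout).astype(np.float32)
            fused = fused * nn.Tensor(keep / (1.0 - cfg.dropout))
        hidden = self.head1(fused).relu()
        logits = self.head2(hidden).reshape(n)
        if return_embedding:
            return logits, fused
        return logits

    def predict_scores(self, x: np.ndarray, batch_size: int = 64,
                       pooled: bool = False) -> np.ndarray:
        self.eval()
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(x[i : i + batch_size], pooled=pooled)
            out.append(1.0 / (1.0 + np.exp(-logits.data)))
        return np.concatenate(out) if out else np.empty(0)

    def deep_features(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Pre-classifier fused embeddings (N, E), the model's deep features."""
        self.eval()
        out = []
        for i in range(0, x.shape[0], batch_size):
            _, emb = self.forward_logits(x[i : i + batch_size], return_embedding=True)
            out.append(emb.data.copy())
        return np.concatenate(out)

    def predict(self, x: np.ndarray, patient_ids: list[str]) -> list[PredictionResult]:
        scores = self.predict_scores(x)
        return [PredictionResult(pid, float(s), bool(s >= self.threshold), self.threshold)
                for pid, s in zip(patient_ids, scores)]

    # -- parameter groups for layer-wise unfreezing --------------------------

    def stages(self) -> list[list[nn.Parameter]]:
        enc = self.encoder
        conv_stages = [[c.weight, c.bias] for c in enc.convs]
        top = [p for p in self.parameters()
               if all(id(p) not in {id(q) for q in s} for s in conv_stages)]
        return conv_stages + [top]


# ---- training --------------------------------------------------------------


def _class_weights(y: np.ndarray) -> np.ndarray:
    n, n_pos = len(y), y.sum()
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes are required for training")
    w = np.where(y > 0, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w.astype(np.float32)


def fit(config: StiConfig, x: np.ndarray, y: np.ndarray,
        x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
        epochs: int | None = None, verbose: bool = False) -> StiModel:
    """Train one STI model variant on a patch tensor.

    Adam on class-weighted binary cross-entropy; the decision threshold is
    set by the Youden index on the training scores.  With
    ``training.layerwise_unfreeze`` the encoder stages start frozen and are
    unfrozen one by one when the validation AUC stalls (< 0.005 improvement
    over 3 epochs).
    """
    config.validate()
    tr = config.training
    epochs = tr.epochs if epochs is None else epochs
    y = np.asarray(y, dtype=np.float32)
    model = StiModel(config)
    if epochs == 0:
        model.threshold = 0.5
        return model
    weights = _class_weights(y) if tr.class_weighting else np.ones_like(y)
    rng = np.random.default_rng(config.seed + 10_000)
    x = model.pool_dataset(x)  # fixed stem applied once, not per epoch
    if x_val is not None:
        x_val = model.pool_dataset(x_val)

    unfreeze = tr.layerwise_unfreeze
    stages = model.stages()
    active_stage = len(stages) - 1  # start from the top block only
    if unfreeze and x_val is None:
        raise ConfigError("layerwise_unfreeze requires a validation split")

    def make_opt():
        if unfreeze:
            params = [p for s in stages[active_stage:] for p in s]
        else:
            params = model.parameters()
        return nn.Adam(params, lr=tr.learning_rate, weight_decay=tr.weight_decay)

    opt = make_opt()
    val_history: list[float] = []
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(len(y))
        for i in range(0, len(y), tr.batch_size):
            idx = order[i : i + tr.batch_size]
            model.zero_grad()
            logits = model.forward_logits(x[idx], pooled=True)
            loss = nn.bce_with_logits(logits, y[idx], weights[idx])
            loss.backward()
            opt.step()
        if unfreeze:
            val_scores = model.predict_scores(x_val, pooled=True)
            try:
                val_auc = roc_auc(val_scores, y_val)
            except DataError:
                val_auc = 0.5
            val_history.append(val_auc)
            stalled = (len(val_history) >= 3
                       and val_history[-1] - val_history[-3] < 0.005)
            if stalled and active_stage > 0:
                active_stage -= 1
                opt = make_opt()
                val_history.clear()
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}")
    train_scores = model.predict_scores(x, pooled=True)
    model.threshold = youden_threshold(train_scores, y)
    return model


def train_model(x: np.ndarray, y: np.ndarray, config: StiConfig):
    """Grid search + stratified k-fold cross-validation, then a final refit.

    Returns ``(model, cv_report)`` where ``cv_report`` holds the grid of
    mean validation AUCs and the selected hyperparameters.
    """
    config.validate()
    y = np.asarray(y, dtype=np.float32)
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise DataError("need at least 2 cases per class")
    tr = config.training
    grid = tr.grid or {}
    keys = sorted(grid)
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))] \
        or [{}]
    skf = StratifiedKFold(n_splits=tr.folds, shuffle=True, random_state=config.seed)
    results = []
    for combo in combos:
        cfg = replace(config, training=replace(tr, **combo))
        aucs = []
        for tr_idx, va_idx in skf.split(np.zeros(len(y)), y):
            m = fit(cfg, x[tr_idx], y[tr_idx],
                    x_val=x[va_idx] if tr.layerwise_unfreeze else None,
                    y_val=y[va_idx] if tr.layerwise_unfreeze else None)
            try:
                aucs.append(roc_auc(m.predict_scores(x[va_idx]), y[va_idx]))
            except DataError:
                aucs.append(0.5)
        results.append({"params": combo, "mean_val_auc": float(np.mean(aucs)),
                        "fold_aucs": [float(a) for a in aucs]})
    best = max(results, key=lambda r: r["mean_val_auc"])
    final_cfg = replace(config, training=replace(tr, **best["params"],
                                                 layerwise_unfreeze=False))
    model = fit(final_cfg, x, y)
    return model, {"grid": results, "selected": best["params"],
                   "mean_val_auc": best["mean_val_auc"]}


# ---- Grad-CAM ---------------------------------------------------------------


def grad_cam(model: StiModel, x_case: np.ndarray, target_stage: int = 1) -> dict:
    """Gradient-weighted class-activation maps for one case.

    ``x_case``: (2, K+1, D, H, W).  Returns ``{(timepoint, region): map}``
    with maps upsampled to the patch grid and min-max normalized to [0, 1]
    (all-zero where no activation responds).  ``target_stage`` indexes the
    encoder convolution stage whose activations are explained.
    """
    cfg = model.config
    if not 0 <= target_stage < len(model.encoder.convs):
        raise ConfigError("target stage out of range")
    model.eval()
    retain: list[nn.Tensor] = []
    logits = model.forward_logits(x_case[None], retain=retain)
    logits.backward()
    act = retain[target_stage]
    grads = act.grad if act.grad is not None else np.zeros_like(act.data)
    if act.data.ndim != 5:
        raise ConfigError("target layer has no spatial extent")
    weights = grads.mean(axis=(2, 3, 4), keepdims=True)
    cams = np.maximum((weights * act.data).sum(axis=1), 0.0)  # (M, d, h, w)
    out = {}
    tps = cfg.timepoints()
    regions = cfg.region_indices()
    names = {0: "T0", 1: "T1"}
    m = 0
    for t in tps:
        for r in regions:
            cam = cams[m]
            m += 1
            zoom = np.asarray(cfg.patch_shape) / np.asarray(cam.shape)
            up = ndimage.zoom(cam, zoom, order=1, mode="nearest", grid_mode=True)
            peak = up.max()
            if peak > 0:
                up = (up - up.min()) / (peak - up.min())
            region = "whole" if r == REGION_WHOLE else f"habitat_{r}"
            out[(names[t], region)] = up.astype(np.float32)
    return out


# ---- checkpoints ------------------------------------------------------------


def save_model(model: StiModel, path) -> None:
    import dataclasses as dc
    import json

    cfg = model.config
    cfg_json = json.dumps({
        **dc.asdict(cfg),
        "ablation": dc.asdict(cfg.ablation),
        "training": dc.asdict(cfg.training),
    })
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             __threshold__=np.array([model.threshold]), **arrays)


def load_model(path) -> StiModel:
    import json

    with np.load(path) as data:
        cfg_d = json.loads(bytes(data["__config__"]).decode())
        cfg_d["ablation"] = AblationFlags(**cfg_d["ablation"])
        cfg_d["training"] = TrainingConfig(**cfg_d["training"])
        for tup in ("patch_shape", "encoder_channels"):
            cfg_d[tup] = tuple(cfg_d[tup])
        cfg = StiConfig(**cfg_d)
        model = StiModel(cfg)
        n = len(model.parameters())
        model.load_state_arrays([data[f"p{i}"] for i in range(n)])
        model.threshold = float(data["__threshold__"][0])
    return model
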