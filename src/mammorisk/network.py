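"""Multi-time-point, multi-level, multi-task risk network.

Architecture (all widths configurable; full-scale defaults in parentheses):

1. a weight-shared convolutional encoder maps each of the up-to-24 input
   mammograms (4 views x 6 time points) to a local feature vector (512);
2. a *side-specific* MLP fuses the ipsilateral CC+MLO features with a
   fixed-width encoding of that breast's prior-tumor record (128, so the MLP
   input is 512+512+128 = 1152) into a unilateral feature (512), with
   side-level task heads;
3. an *exam* MLP fuses (right, left) unilateral features into a per-exam
   global feature (512), with exam-level task heads;
4. a transformer encoder fuses local + global tokens from all time points,
   each token additively conditioned on a continuous sinusoidal embedding of
   its exam's interval-to-target in months, plus one risk-factor token;
   missing slots are zero-filled and excluded from attention and pooling.
   The pooled output concatenated with a risk-factor skip projection gives
   the fused feature tau (512 + 128 = 640);
5. multi-task heads on tau: a 16-class discrete-time risk head for the
   patient, a shared 16-class head per breast (conditioned on that side's
   unilateral feature), and auxiliary fused-level task heads.

The 16-class head realises the discrete-time cumulative risk: class 0 is
"cancer-free within 15 years", class ``i`` is "diagnosis in year ``i``";
``Risk_j`` is the prefix sum of the softmax over classes ``1..j``, which is
monotone in ``j`` by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from skimage.transform import resize

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .cohort import N_CLASSES, riskf_encoding_dim

# auxiliary classification tasks per level: name -> number of classes
SIDE_TASKS = {
    "history": 2, "loc_prior": 6, "loc_future": 6, "type_prior": 2,
    "type_future": 2, "pcr": 2, "pT": 5, "pN": 4,
    "er_future": 2, "pr_future": 2, "her2_future": 2,
}
EXAM_TASKS = {
    "history": 2, "age_bin": 9, "density": 4, "birads": 7, "manufacturer": 3,
    "loc_prior": 6, "loc_future": 6, "lat_prior": 2, "lat_future": 2,
    "type_prior": 2, "type_future": 2, "pcr": 2, "pT": 5, "pN": 4,
    "er_future": 2, "pr_future": 2, "her2_future": 2,
}
FUSED_TASKS = {
    "history": 2, "type_future": 2, "age_bin": 9, "density": 4, "birads": 7,
    "loc_future": 6, "lat_prior": 2, "lat_future": 2,
}


@dataclass
class ModelConfig:
    image_size: tuple[int, int] = (1024, 512)   # (H, W), 1:2 width:height
    backbone_channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    backbone_strides: tuple[int, ...] | None = None  # default: stride 2 per stage
    feature_dim: int = 512
    tumor_dim: int = 128                        # so the side MLP input is 1152
    riskf_skip_dim: int = 128                   # fused width 512+128 = 640
    time_freqs: int = 64
    transformer_layers: int = 2
    transformer_heads: int = 8
    dropout: float = 0.5
    max_timepoints: int = 6
    use_risk_factors: bool = True
    use_multitimepoint: bool = True

    @property
    def fused_dim(self) -> int:
        return self.feature_dim + self.riskf_skip_dim

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def tiny_config(**overrides) -> ModelConfig:
    """Desk-scale configuration used by the test-suite and the simulator
    experiments: same topology, small widths, 64x32 inputs."""
    cfg = ModelConfig(
        image_size=(64, 32), backbone_channels=(8, 16, 32),
        backbone_strides=(1, 2, 2),  # keep small bright structures resolvable
        feature_dim=64, tumor_dim=32, riskf_skip_dim=16, time_freqs=8,
        transformer_layers=1, transformer_heads=2, dropout=0.5,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class Batch:
    """Numeric arrays for one mini-batch of target samples."""

    images: np.ndarray          # (B, T, 4, H, W)
    slot_mask: np.ndarray       # (B, T) bool; slot 0 = target exam
    intervals: np.ndarray       # (B, T) months to target (slot 0 -> 0)
    riskf: np.ndarray           # (B, R)
    tumor: np.ndarray           # (B, 2, tumor_dim), order (right, left)
    labels: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.images.shape[0]


@dataclass
class ModelOutputs:
    tau: Tensor                          # (B, fused_dim)
    patient_logits: Tensor               # (B, 16)
    breast_logits: Tensor                # (B, 2, 16) order (right, left)
    side_risk_logits: Tensor             # (B, 2, 16) side-level head
    exam_risk_logits: Tensor             # (B, 16) exam-level head
    side_aux: dict                       # name -> (B, 2, C)
    exam_aux: dict                       # name -> (B, C)
    fused_aux: dict                      # name -> (B, C)
    side_features: Tensor                # (B, 2, d) target-exam unilateral
    exam_feature: Tensor                 # (B, d) target-exam global


class ConvBackbone(nn.Module):
    """Small residual CNN: stride-2 stages, global average pooling."""

    def __init__(self, channels: tuple[int, ...], out_dim: int,
                 rng: np.random.Generator, dropout: float = 0.0,
                 strides: tuple[int, ...] | None = None):
        super().__init__()
        self.convs = []
        cin = 1
        self.drop = nn.Dropout(dropout)
        if strides is None:
            strides = (2,) * len(channels)
        for cout, stride in zip(channels, strides):
            self.convs.append(nn.Conv2d(cin, cout, 3, rng, stride=stride, pad=1))
            cin = cout
        # global mean + max pooling of the conv maps, plus the raw image's own
        # spatial mean and max as identity channels: the mean carries overall
        # density / tissue mass, the max preserves small high-contrast
        # structures (masses), and the identity skip keeps both available to
        # the fusion stage even before the filters have specialised
        self.proj = nn.Linear(2 * cin + 2, out_dim, rng)
        self.norm = nn.LayerNorm(out_dim)  # stabilises token scale for fusion
        self.record_activations = False
        self.last_activation: Optional[Tensor] = None

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.convs:
            h = ad.relu(conv(h))
        if self.record_activations:
            self.last_activation = h
        n, c = h.shape[0], h.shape[1]
        flat = ad.reshape(h, (n, c, -1))
        raw = ad.reshape(x, (n, 1, -1))
        pooled = ad.concat([ad.tmean(flat, axis=2), ad.tmax(flat, axis=2),
                            ad.tmean(raw, axis=2), ad.tmax(raw, axis=2)], axis=1)
        # dropout is applied by the caller on the attention pathway only: the
        # longitudinal contrast needs clean features (dropout noise on a
        # within-patient difference dwarfs a slow-growth signal)
        return self.norm(self.proj(pooled))


class TimeEmbedding(nn.Module):
    """Continuous sinusoidal embedding of interval-to-target (months)."""

    def __init__(self, n_freqs: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        # periods from 2 to 480 months, geometrically spaced
        self.omegas = 2 * np.pi / np.geomspace(2.0, 480.0, n_freqs)
        self.proj = nn.Linear(2 * n_freqs, out_dim, rng)

    def features(self, intervals: np.ndarray) -> np.ndarray:
        ang = intervals[..., None] * self.omegas
        return np.concatenate([np.sin(ang), np.cos(ang)], axis=-1)

    def forward(self, intervals: np.ndarray) -> Tensor:
        if np.any(intervals < 0):
            raise ValueError("intervals must be non-negative")
        return self.proj(Tensor(self.features(intervals)))


class RiskModel(nn.Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11CE]))
        d = config.feature_dim
        self.backbone = ConvBackbone(config.backbone_channels, d, rng,
                                     dropout=config.dropout,
                                     strides=config.backbone_strides)
        self.trunk_drop = nn.Dropout(config.dropout)
        side_in = 2 * d + config.tumor_dim
        self.side_mlp = nn.MLP2(side_in, d, d, config.dropout, rng)
        self.exam_mlp = nn.MLP2(2 * d, d, d, config.dropout, rng)
        self.time_embed = TimeEmbedding(config.time_freqs, d, rng)
        self.riskf_token = nn.Linear(riskf_encoding_dim(), d, rng)
        self.riskf_skip = nn.Linear(riskf_encoding_dim(), config.riskf_skip_dim, rng)
        self.encoder_layers = [
            nn.TransformerEncoderLayer(d, config.transformer_heads, rng,
                                       dropout=config.dropout)
            for _ in range(config.transformer_layers)
        ]
        self.final_ln = nn.LayerNorm(d)
        # explicit longitudinal contrast channel: the normalised difference
        # between the target exam's tokens and the pooled prior tokens; static
        # anatomy cancels in the difference, so slow lesion growth becomes an
        # O(1) direction instead of a tiny perturbation
        self.contrast_norm = nn.BatchNorm1d(d)
        self.contrast_proj = nn.Linear(d, d, rng)
        fd = config.fused_dim
        self.patient_head = nn.Linear(fd, N_CLASSES, rng)
        self.breast_head = nn.Linear(fd + d, N_CLASSES, rng)  # shared across sides
        self.side_risk_head = nn.Linear(d, N_CLASSES, rng)
        self.exam_risk_head = nn.Linear(d, N_CLASSES, rng)
        self.side_heads = {k: nn.Linear(d, c, rng) for k, c in SIDE_TASKS.items()}
        self.exam_heads = {k: nn.Linear(d, c, rng) for k, c in EXAM_TASKS.items()}
        self.fused_heads = {k: nn.Linear(fd, c, rng) for k, c in FUSED_TASKS.items()}

    # ------------------------------------------------------------------
    def encode_images(self, images: np.ndarray, valid: np.ndarray) -> Tensor:
        """Shared-encoder pass over the valid slots only.

        ``images``: (B, T, 4, H, W); ``valid``: (B, T).  Returns (B, T, 4, d)
        with zero features in masked slots.
        """
        b, t, v, hh, ww = images.shape
        flat_valid = np.repeat(valid.reshape(-1), v)  # (B*T*4,)
        idx = np.flatnonzero(flat_valid)
        x = images.reshape(b * t * v, 1, hh, ww)[idx]
        feats = self.backbone(Tensor(x))  # (N, d)
        full = ad.scatter_rows(feats, idx, b * t * v)
        return ad.reshape(full, (b, t, v, self.config.feature_dim))

    def forward(self, batch: Batch) -> ModelOutputs:
        cfg = self.config
        b, t = batch.slot_mask.shape
        slot_mask = batch.slot_mask.copy()
        if not cfg.use_multitimepoint:
            slot_mask[:, 1:] = False
        images = batch.images * slot_mask[:, :, None, None, None]
        theta = self.encode_images(images, slot_mask)          # (B,T,4,d)
        d = cfg.feature_dim

        # side-specific module on every time point; view order (CC, MLO)
        # image axis order: (R-CC, R-MLO, L-CC, L-MLO)
        tumor = Tensor(batch.tumor)                            # (B,2,td)
        side_in = ad.concat([
            ad.reshape(tumor, (b, 1, 2, cfg.tumor_dim)) * np.ones((1, t, 1, 1)),
            ad.stack([theta[:, :, 0], theta[:, :, 2]], axis=2),
            ad.stack([theta[:, :, 1], theta[:, :, 3]], axis=2),
        ], axis=-1)                                            # (B,T,2,td+2d)
        eps = self.side_mlp(side_in)                           # (B,T,2,d)

        exam_in = ad.concat([eps[:, :, 0], eps[:, :, 1]], axis=-1)  # (right, left)
        delta = self.exam_mlp(exam_in)                         # (B,T,d)

        e_t = self.time_embed(batch.intervals)                 # (B,T,d)
        theta_tok = self.backbone.drop(theta) + ad.reshape(e_t, (b, t, 1, d))
        delta_tok = delta + e_t
        tokens = ad.concat([ad.reshape(theta_tok, (b, t * 4, d)), delta_tok], axis=1)
        token_mask = np.concatenate(
            [np.repeat(slot_mask, 4, axis=1), slot_mask], axis=1)

        riskf = Tensor(batch.riskf)
        if cfg.use_risk_factors:
            rf_tok = ad.reshape(self.riskf_token(riskf), (b, 1, d))
            tokens = ad.concat([tokens, rf_tok], axis=1)
            token_mask = np.concatenate(
                [token_mask, np.ones((b, 1), dtype=bool)], axis=1)

        # zero out masked token content so padding is inert end to end
        tokens = tokens * token_mask[:, :, None]
        h = tokens
        for layer in self.encoder_layers:
            h = layer(h, token_mask)
        h = self.final_ln(h)
        # pool over the *target exam's* tokens (slot 0: images 0..3 plus its
        # global token at index t*4); prior-exam information reaches them
        # through attention.  A residual from the target's global feature
        # keeps the single-exam pathway as fast to learn as in the STP
        # ablation, and an explicit normalised target-minus-priors contrast
        # disentangles change patterns from static breast tissue.  With no
        # valid priors the contrast is exactly zero, so the STP reduction is
        # bit-exact.
        target_token_idx = np.array([0, 1, 2, 3, t * 4])
        tpool = ad.tmean(h[:, target_token_idx], axis=1)
        # longitudinal contrast on the *clean* per-exam encoder features
        # (pre-dropout, pre-attention, pre-time-embedding): within one
        # patient the static anatomy cancels in the difference, leaving the
        # change signal; batch standardisation then brings it to O(1)
        raw_exam = ad.tmean(theta, axis=2)                     # (B,T,d)
        prior_mask = slot_mask[:, 1:]                          # (B, T-1)
        n_prior = prior_mask.sum(axis=1, keepdims=True)
        ppool = ad.tsum(raw_exam[:, 1:] * prior_mask[:, :, None], axis=1) \
            * (1.0 / np.maximum(n_prior, 1))
        has_prior = (n_prior > 0).astype(float)
        diff = (raw_exam[:, 0] - ppool) * has_prior  # zero for prior-free rows
        contrast = self.contrast_proj(self.contrast_norm(diff)) * has_prior
        # the contrast bypasses the trunk dropout: stochastic zeroing of a
        # low-magnitude channel would stall its learning entirely
        pooled = self.trunk_drop(tpool + delta[:, 0]) + contrast

        if cfg.use_risk_factors:
            skip = self.riskf_skip(riskf)
        else:
            skip = Tensor(np.zeros((b, cfg.riskf_skip_dim)))
        tau = ad.concat([pooled, skip], axis=-1)               # (B, fused)

        eps0 = eps[:, 0]                                       # (B,2,d) target exam
        delta0 = delta[:, 0]                                   # (B,d)
        breast_in = ad.concat([
            ad.stack([tau, tau], axis=1), eps0], axis=-1)      # (B,2,fd+d)
        outputs = ModelOutputs(
            tau=tau,
            patient_logits=self.patient_head(tau),
            breast_logits=self.breast_head(breast_in),
            side_risk_logits=self.side_risk_head(eps0),
            exam_risk_logits=self.exam_risk_head(delta0),
            side_aux={k: head(eps0) for k, head in self.side_heads.items()},
            exam_aux={k: head(delta0) for k, head in self.exam_heads.items()},
            fused_aux={k: head(tau) for k, head in self.fused_heads.items()},
            side_features=eps0,
            exam_feature=delta0,
        )
        return outputs


# ---------------------------------------------------------------------------
# cumulative risk head algebra
# ---------------------------------------------------------------------------

def cumulative_risk(logits: np.ndarray | Tensor, j: int) -> np.ndarray:
    """``Risk_j``: probability of diagnosis within ``j`` years (prefix sum of
    the softmax over year classes 1..j; class 0 is cancer-free)."""
    if not 1 <= int(j) <= N_CLASSES - 1:
        raise ValueError(f"horizon j must be in 1..{N_CLASSES - 1}")
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits, float)
    x = arr - arr.max(axis=-1, keepdims=True)
    p = np.exp(x)
    p /= p.sum(axis=-1, keepdims=True)
    return p[..., 1 : int(j) + 1].sum(axis=-1)


def risk_curve(logits: np.ndarray | Tensor) -> np.ndarray:
    """All fifteen cumulative risks, shape ``logits.shape[:-1] + (15,)``."""
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits, float)
    x = arr - arr.max(axis=-1, keepdims=True)
    p = np.exp(x)
    p /= p.sum(axis=-1, keepdims=True)
    return np.cumsum(p[..., 1:], axis=-1)


def cumulative_risk_tensor(logits: Tensor) -> Tensor:
    """Differentiable (B, 15) cumulative-risk curve used by the risk loss."""
    p = ad.softmax(logits, axis=-1)
    # prefix sums over classes 1..15 via matmul with a triangular map
    tri = np.tril(np.ones((N_CLASSES - 1, N_CLASSES - 1))).T
    return ad.matmul(p[:, 1:], tri)


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def gradcam_heatmaps(model: RiskModel, batch: Batch, target: str = "patient",
                     side: int = 0, horizon: int = 10) -> np.ndarray:
    """Class-activation maps for one sample (batch size must be 1).

    Returns an array (T, 4, H, W) of non-negative, per-image max-normalised
    maps at input resolution; masked slots are all-zero.
    ``target``: "patient" or "breast" (with ``side`` 0=right, 1=left).
    """
    if batch.size != 1:
        raise ValueError("Grad-CAM expects a single-sample batch")
    model.eval()
    model.backbone.record_activations = True
    try:
        out = model(batch)
    finally:
        model.backbone.record_activations = False
    act = model.backbone.last_activation
    model.backbone.last_activation = None
    if target == "patient":
        logits = out.patient_logits
    elif target == "breast":
        logits = out.breast_logits[:, side]
    else:
        raise ValueError(f"unknown target {target!r}")
    risk = cumulative_risk_tensor(logits)[:, horizon - 1]
    risk.sum().backward()

    grads = act.grad if act.grad is not None else np.zeros_like(act.data)
    weights = grads.mean(axis=(2, 3), keepdims=True)
    cams = np.maximum((weights * act.data).sum(axis=1), 0.0)   # (N, h, w)

    t = batch.slot_mask.shape[1]
    hh, ww = model.config.image_size
    slot_mask = batch.slot_mask.copy()
    if not model.config.use_multitimepoint:
        slot_mask[:, 1:] = False
    idx = np.flatnonzero(np.repeat(slot_mask.reshape(-1), 4))
    maps = np.zeros((t * 4, hh, ww))
    for row, cam in zip(idx, cams):
        m = resize(cam, (hh, ww), order=1, mode="constant",
                   anti_aliasing=False, preserve_range=True)
        peak = m.max()
        maps[row] = m / peak if peak > 0 else m
    return maps.reshape(t, 4, hh, ww)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: RiskModel, path) -> None:
    state = model.state_dict()
    meta = json.dumps({
        "config": asdict(model.config),
        "config_hash": model.config.config_hash(),
        "class_map": {"cancer_free": 0,
                      **{f"year_{i}": i for i in range(1, N_CLASSES)}},
    }, default=list)
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **state)


def load_checkpoint(path, config: ModelConfig | None = None, seed: int = 0) -> RiskModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    stored = meta["config"]
    for key in ("image_size", "backbone_channels"):
        stored[key] = tuple(stored[key])
    stored_cfg = ModelConfig(**stored)
    if config is not None and config.config_hash() != stored_cfg.config_hash():
        raise ValueError("checkpoint config hash does not match requested config")
    model = RiskModel(stored_cfg, seed=seed)
    model.load_state_dict(state)
    return model
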