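"""Multi-task training: censoring-aware risk loss, auxiliary cross-entropies,
level weighting, augmentation, and the fit loop.

Loss structure.  Each of the three classifier levels (side, exam, fused)
produces a risk term and auxiliary task terms; within a level the risk term
gets five times the weight of each auxiliary task, and the total is

    L_total = 0.2 * L_side + 0.2 * L_exam + 1.0 * L_fusion .

The risk term is a binary cross entropy on the *cumulative* risks: for each
horizon ``j`` in 1..15 the monotone curve ``Risk_j`` is compared with the
indicator "event within j years", and a horizon contributes only if it is
observable — the event occurred (so every indicator is known), or the sample
has at least ``j`` years of negative follow-up.  Censored horizons are
masked, not imputed, which keeps the term unbiased under independent
censoring while preserving the monotone 16-class parametrisation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .cohort import (
    MAX_PRIORS,
    MISSING,
    PatientTimeline,
    TargetSample,
    SIDES,
    encode_risk_factors,
    encode_tumor_record,
    interpolate_missing_density,
    make_target_samples,
    select_priors,
    tumor_for_side,
)
from .network import (
    Batch,
    ModelConfig,
    ModelOutputs,
    RiskModel,
    cumulative_risk_tensor,
)
from .preprocess import preprocess_image

N_HORIZONS = 15
_EPS = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    lr: float = 1e-4
    lr_decay: float = 0.1
    lr_step_epochs: int = 5
    weight_decay: float = 0.0
    max_priors: int = MAX_PRIORS
    use_risk_factors: bool = True
    use_multitask: bool = True
    use_multilevel: bool = True
    use_multitimepoint: bool = True
    prior_drop_prob: float = 0.3
    # photometric jitter is kept small relative to planted lesion contrast:
    # larger jitter injects between-exam intensity noise that erases the
    # longitudinal signal the fusion model is supposed to learn
    brightness_jitter: float = 0.02
    contrast_jitter: float = 0.02
    flip_prob: float = 0.5
    w_side: float = 0.2
    w_exam: float = 0.2
    w_fusion: float = 1.0
    risk_task_weight: float = 5.0
    seed: int = 0


@dataclass
class LossBreakdown:
    L_side: float
    L_exam: float
    L_fusion: float
    L_total: float
    per_task: dict = field(default_factory=dict)
    total_tensor: Tensor | None = None


# ---------------------------------------------------------------------------
# loss primitives
# ---------------------------------------------------------------------------

def observable_horizon_mask(classes: np.ndarray, followup_years: np.ndarray,
                            events: np.ndarray | None = None) -> np.ndarray:
    """(B, 15) mask of horizons whose event-within-j indicator is known.

    ``events`` marks samples with an observed diagnosis (any horizon is then
    observable); otherwise horizon ``j`` needs ``followup >= j`` years.
    A nonzero class always implies an observed event.
    """
    b = classes.shape[0]
    horizons = np.arange(1, N_HORIZONS + 1)
    if events is None:
        events = classes > 0
    mask = followup_years[:, None] >= horizons[None, :]
    mask[events.astype(bool)] = True
    return mask


def risk_targets(classes: np.ndarray) -> np.ndarray:
    """(B, 15) indicators: event occurred within horizon j (class 0 -> all 0)."""
    horizons = np.arange(1, N_HORIZONS + 1)
    cls = classes[:, None]
    return ((cls > 0) & (horizons[None, :] >= cls)).astype(float)


def risk_loss(logits: Tensor, classes: np.ndarray, followup_years: np.ndarray,
              events: np.ndarray | None = None) -> Tensor:
    """Censoring-masked BCE on the cumulative risk curve (scalar Tensor)."""
    classes = np.asarray(classes)
    followup_years = np.asarray(followup_years, dtype=float)
    mask = observable_horizon_mask(classes, followup_years, events)
    n_obs = mask.sum(axis=1)
    # rows with no observable horizon contribute nothing (e.g. the
    # contralateral breast of a woman diagnosed within a year)
    has_obs = n_obs > 0
    if not has_obs.any():
        return Tensor(0.0)
    y = risk_targets(classes)
    curve = cumulative_risk_tensor(logits)              # (B, 15)
    r = curve * (1.0 - 2 * _EPS) + _EPS                 # keep log() finite
    bce = (ad.tlog(r) * y + ad.tlog(1.0 - r) * (1.0 - y)) * (-1.0)
    per_sample = ad.tsum(bce * mask, axis=1) * (has_obs / np.maximum(n_obs, 1))
    return ad.tsum(per_sample) * (1.0 / has_obs.sum())


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean CE over entries with label >= 0; -1 labels are skipped.

    ``logits`` may be (B, C) or (B, S, C); labels match the leading shape.
    """
    labels = np.asarray(labels)
    c = logits.shape[-1]
    flat_logits = ad.reshape(logits, (-1, c))
    flat_labels = labels.reshape(-1)
    valid = flat_labels >= 0
    if not valid.any():
        return Tensor(0.0)
    ls = ad.log_softmax(flat_logits, axis=-1)
    idx = (np.arange(flat_labels.size), np.where(valid, flat_labels, 0))
    picked = ls[idx] * valid.astype(float)
    return ad.tsum(picked) * (-1.0 / valid.sum())


def level_loss(risk_term: Tensor, aux_terms: dict[str, Tensor],
               risk_weight: float = 5.0, use_multitask: bool = True) -> Tensor:
    """Within-level composition: risk weighted x5 against each auxiliary task."""
    total = risk_term * risk_weight
    if use_multitask:
        for term in aux_terms.values():
            total = total + term
    return total


def compute_losses(outputs: ModelOutputs, batch: Batch,
                   cfg: TrainConfig) -> LossBreakdown:
    labels = batch.labels
    per_task: dict[str, float] = {}

    def side_risk():
        terms = []
        for s in range(2):
            terms.append(risk_loss(outputs.side_risk_logits[:, s],
                                   labels["breast_class"][:, s],
                                   labels["breast_followup"][:, s]))
        return (terms[0] + terms[1]) * 0.5

    side_aux = {k: cross_entropy(v, labels["side"][k])
                for k, v in outputs.side_aux.items()}
    exam_aux = {k: cross_entropy(v, labels["exam"][k])
                for k, v in outputs.exam_aux.items()}
    fused_aux = {k: cross_entropy(v, labels["fused"][k])
                 for k, v in outputs.fused_aux.items()}

    l_side_risk = side_risk()
    l_exam_risk = risk_loss(outputs.exam_risk_logits, labels["patient_class"],
                            labels["followup"], labels["event"])
    l_patient = risk_loss(outputs.patient_logits, labels["patient_class"],
                          labels["followup"], labels["event"])
    l_breasts = [risk_loss(outputs.breast_logits[:, s],
                           labels["breast_class"][:, s],
                           labels["breast_followup"][:, s]) for s in range(2)]
    l_fused_risk = (l_patient + l_breasts[0] + l_breasts[1]) * (1.0 / 3.0)

    l_side = level_loss(l_side_risk, side_aux, cfg.risk_task_weight, cfg.use_multitask)
    l_exam = level_loss(l_exam_risk, exam_aux, cfg.risk_task_weight, cfg.use_multitask)
    l_fusion = level_loss(l_fused_risk, fused_aux, cfg.risk_task_weight, cfg.use_multitask)

    w_side = cfg.w_side if cfg.use_multilevel else 0.0
    w_exam = cfg.w_exam if cfg.use_multilevel else 0.0
    total = l_side * w_side + l_exam * w_exam + l_fusion * cfg.w_fusion

    for name, t in [("risk_side", l_side_risk), ("risk_exam", l_exam_risk),
                    ("risk_patient", l_patient)]:
        per_task[name] = float(t.data)
    for level, terms in [("side", side_aux), ("exam", exam_aux), ("fused", fused_aux)]:
        for k, t in terms.items():
            per_task[f"{level}.{k}"] = float(t.data)

    return LossBreakdown(
        L_side=float(l_side.data), L_exam=float(l_exam.data),
        L_fusion=float(l_fusion.data), L_total=float(total.data),
        per_task=per_task, total_tensor=total,
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_images(images: np.ndarray, rng: np.random.Generator,
                   cfg: TrainConfig, training: bool = True) -> np.ndarray:
    """Per-image random horizontal flip + brightness/contrast jitter.

    ``images``: (..., H, W) in [0, 1].  Flips are anatomically neutral for
    the labels (laterality labels refer to the breast, not the pixel side).
    Identity when ``training`` is False.
    """
    if not training:
        return images
    out = images.copy()
    flat = out.reshape(-1, *out.shape[-2:])
    for i in range(flat.shape[0]):
        img = flat[i]
        if rng.random() < cfg.flip_prob:
            img = img[:, ::-1]
        if cfg.brightness_jitter > 0:
            img = img + rng.uniform(-cfg.brightness_jitter, cfg.brightness_jitter)
        if cfg.contrast_jitter > 0:
            m = img.mean()
            img = (img - m) * rng.uniform(1 - cfg.contrast_jitter,
                                          1 + cfg.contrast_jitter) + m
        flat[i] = np.clip(img, 0.0, 1.0)
    return out


def drop_priors(slot_mask: np.ndarray, intervals: np.ndarray,
                rng: np.random.Generator, p: float) -> tuple[np.ndarray, np.ndarray]:
    """Randomly drop valid prior slots (never the target) with probability p."""
    mask = slot_mask.copy()
    ivals = intervals.copy()
    for j in range(1, mask.shape[-1]):
        if mask[j] and rng.random() < p:
            mask[j] = False
            ivals[j] = 0.0
    return mask, ivals


# ---------------------------------------------------------------------------
# label assembly
# ---------------------------------------------------------------------------

def _age_bin(age: float) -> int:
    if age == MISSING or age < 0:
        return -1
    return int(np.clip((age - 30) // 5, 0, 8))


def aux_label_sets(timeline: PatientTimeline, sample: TargetSample) -> dict:
    """Auxiliary task labels at the three levels; -1 marks "not applicable"."""
    rf = timeline.risk_factors
    exam = timeline.exams[sample.target_exam_index]
    event = timeline.has_event
    ft = timeline.future_tumor
    history = rf.personal_history_bc if rf.personal_history_bc != MISSING else -1
    type_future = (1 if history == 1 else 0) if event else -1
    lat_future = SIDES.index(timeline.diagnosis_laterality) if event else -1
    any_prior = timeline.prior_tumors[-1] if timeline.prior_tumors else None
    lat_prior = SIDES.index(any_prior.laterality) if any_prior else -1

    side: dict[str, list[int]] = {k: [] for k in
                                  ("history", "loc_prior", "loc_future", "type_prior",
                                   "type_future", "pcr", "pT", "pN",
                                   "er_future", "pr_future", "her2_future")}
    for s in SIDES:
        prior = tumor_for_side(timeline, s)
        is_event_side = event and timeline.diagnosis_laterality == s
        side["history"].append(1 if prior else (0 if history == 0 else history))
        side["loc_prior"].append(prior.location_c50 if prior else -1)
        side["type_prior"].append(0 if prior else -1)
        side["pcr"].append(prior.pcr if prior else -1)
        side["pT"].append(prior.pT if prior else -1)
        side["pN"].append(prior.pN if prior else -1)
        side["loc_future"].append(ft.location_c50 if (is_event_side and ft) else -1)
        side["type_future"].append(type_future if is_event_side else -1)
        side["er_future"].append(ft.er if (is_event_side and ft) else -1)
        side["pr_future"].append(ft.pr if (is_event_side and ft) else -1)
        side["her2_future"].append(ft.her2 if (is_event_side and ft) else -1)

    exam_labels = {
        "history": history, "age_bin": _age_bin(rf.age),
        "density": (exam.density_acr - 1) if exam.density_acr != MISSING else -1,
        "birads": exam.birads if exam.birads != MISSING else -1,
        "manufacturer": exam.manufacturer if exam.manufacturer != MISSING else -1,
        "loc_prior": any_prior.location_c50 if any_prior else -1,
        "loc_future": ft.location_c50 if (event and ft) else -1,
        "lat_prior": lat_prior, "lat_future": lat_future,
        "type_prior": 0 if any_prior else -1,
        "type_future": type_future,
        "pcr": any_prior.pcr if any_prior else -1,
        "pT": any_prior.pT if any_prior else -1,
        "pN": any_prior.pN if any_prior else -1,
        "er_future": ft.er if (event and ft) else -1,
        "pr_future": ft.pr if (event and ft) else -1,
        "her2_future": ft.her2 if (event and ft) else -1,
    }
    fused_labels = {k: exam_labels[k] for k in
                    ("history", "type_future", "age_bin", "density", "birads",
                     "loc_future", "lat_prior", "lat_future")}
    return {"side": side, "exam": exam_labels, "fused": fused_labels}


# ---------------------------------------------------------------------------
# cohort tensors and the fit loop
# ---------------------------------------------------------------------------

class CohortTensors:
    """Preprocessed image cache + eligible samples for a set of timelines."""

    def __init__(self, timelines: Sequence[PatientTimeline], model_cfg: ModelConfig):
        self.model_cfg = model_cfg
        self.timelines = {tl.patient_id: interpolate_missing_density(tl)
                          for tl in timelines}
        self.items: list[tuple[str, TargetSample]] = []
        self.image_store: dict = {}
        for pid, tl in self.timelines.items():
            for sample in make_target_samples(tl):
                self.items.append((pid, sample))
            for k, exam in enumerate(tl.exams):
                for (side, view), img in exam.images.items():
                    arr = img
                    if isinstance(arr, str):
                        from .preprocess import load_image
                        arr = load_image(arr)
                    self.image_store[(pid, k, side, view)] = preprocess_image(
                        np.asarray(arr, dtype=np.float64),
                        out_shape=model_cfg.image_size,
                        mirror=(side == "left"),
                    ).astype(np.float32)

    def exam_images(self, pid: str, exam_idx: int) -> np.ndarray:
        """(4, H, W) in encoder slot order (R-CC, R-MLO, L-CC, L-MLO)."""
        h, w = self.model_cfg.image_size
        out = np.zeros((4, h, w), dtype=np.float32)
        order = [("right", "CC"), ("right", "MLO"), ("left", "CC"), ("left", "MLO")]
        for i, (side, view) in enumerate(order):
            arr = self.image_store.get((pid, exam_idx, side, view))
            if arr is not None:
                out[i] = arr
        return out


def make_batch(data: CohortTensors, items: Sequence[tuple[str, TargetSample]],
               train_cfg: TrainConfig, mode: str = "eval",
               rng: np.random.Generator | None = None) -> Batch:
    cfg = data.model_cfg
    b = len(items)
    t = cfg.max_timepoints
    h, w = cfg.image_size
    images = np.zeros((b, t, 4, h, w))
    slot_mask = np.zeros((b, t), dtype=bool)
    intervals = np.zeros((b, t))
    riskf = np.zeros((b, encode_risk_factors(data.timelines[items[0][0]].risk_factors).size))
    tumor = np.zeros((b, 2, cfg.tumor_dim))
    labels = {
        "patient_class": np.zeros(b, dtype=int),
        "breast_class": np.zeros((b, 2), dtype=int),
        "followup": np.zeros(b),
        "breast_followup": np.zeros((b, 2)),
        "event": np.zeros(b, dtype=bool),
        "side": {}, "exam": {}, "fused": {},
    }
    side_acc: dict[str, list] = {}
    exam_acc: dict[str, list] = {}
    fused_acc: dict[str, list] = {}
    training = mode == "train"
    k = min(train_cfg.max_priors, MAX_PRIORS) if train_cfg.use_multitimepoint else 0
    for i, (pid, sample) in enumerate(items):
        tl = data.timelines[pid]
        filled = select_priors(tl, sample, k=k, mode="train" if training else "eval",
                               rng=rng)
        mask = filled.slot_mask.copy()
        ivals = filled.intervals_months.copy()
        if training and train_cfg.prior_drop_prob > 0:
            mask, ivals = drop_priors(mask, ivals, rng, train_cfg.prior_drop_prob)
        exam_indices = [sample.target_exam_index] + list(filled.prior_indices)
        slot = 0
        for slot, exam_idx in enumerate(exam_indices):
            if slot >= t or not mask[slot]:
                continue
            images[i, slot] = data.exam_images(pid, exam_idx)
        slot_mask[i, : len(mask)] = mask[:t]
        intervals[i, : len(ivals)] = ivals[:t]
        riskf[i] = encode_risk_factors(tl.risk_factors)
        for s_idx, s in enumerate(SIDES):
            tumor[i, s_idx] = encode_tumor_record(tumor_for_side(tl, s), cfg.tumor_dim)
        labels["patient_class"][i] = sample.patient_class
        labels["breast_class"][i] = [sample.breast_class[s] for s in SIDES]
        labels["followup"][i] = sample.followup_years
        labels["breast_followup"][i] = [sample.breast_followup_years[s] for s in SIDES]
        labels["event"][i] = sample.event
        aux = aux_label_sets(tl, sample)
        for k2, v in aux["side"].items():
            side_acc.setdefault(k2, []).append(v)
        for k2, v in aux["exam"].items():
            exam_acc.setdefault(k2, []).append(v)
        for k2, v in aux["fused"].items():
            fused_acc.setdefault(k2, []).append(v)
    if training:
        images = augment_images(images, rng, train_cfg, training=True)
    labels["side"] = {k2: np.asarray(v) for k2, v in side_acc.items()}
    labels["exam"] = {k2: np.asarray(v) for k2, v in exam_acc.items()}
    labels["fused"] = {k2: np.asarray(v) for k2, v in fused_acc.items()}
    return Batch(images=images, slot_mask=slot_mask, intervals=intervals,
                 riskf=riskf, tumor=tumor, labels=labels)


@dataclass
class FitResult:
    model: RiskModel
    log: list
    best_epoch: int
    best_val_mean_auc: float


def fit(train_timelines: Sequence[PatientTimeline],
        val_timelines: Sequence[PatientTimeline],
        model_cfg: ModelConfig, train_cfg: TrainConfig) -> FitResult:
    """Train with Adam and step-decayed learning rate; keep the epoch with the
    best mean validation AUC over the 1..10-year horizons."""
    from .evaluation import horizon_auc  # local import avoids a cycle

    train_ids = {tl.patient_id for tl in train_timelines}
    val_ids = {tl.patient_id for tl in val_timelines}
    if not train_ids or not val_ids:
        raise ValueError("empty train or validation split")
    if train_ids & val_ids:
        raise ValueError(f"patient overlap between splits: {sorted(train_ids & val_ids)[:3]}")

    model_cfg.use_risk_factors = train_cfg.use_risk_factors
    model_cfg.use_multitimepoint = train_cfg.use_multitimepoint
    model = RiskModel(model_cfg, seed=train_cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 0xF17]))
    nn.seed_dropout(model, np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 0xD0])))

    train_data = CohortTensors(train_timelines, model_cfg)
    val_data = CohortTensors(val_timelines, model_cfg)
    if not train_data.items:
        raise ValueError("no eligible training samples")

    opt = nn.Adam(model.parameters(), lr=train_cfg.lr,
                  weight_decay=train_cfg.weight_decay)
    log: list[dict] = []
    best = (-np.inf, 0, None)
    for epoch in range(train_cfg.epochs):
        opt.lr = train_cfg.lr * (train_cfg.lr_decay ** (epoch // train_cfg.lr_step_epochs))
        model.train()
        order = rng.permutation(len(train_data.items))
        epoch_losses = []
        for lo in range(0, len(order), train_cfg.batch_size):
            idx = order[lo: lo + train_cfg.batch_size]
            batch = make_batch(train_data, [train_data.items[i] for i in idx],
                               train_cfg, mode="train", rng=rng)
            out = model(batch)
            breakdown = compute_losses(out, batch, train_cfg)
            opt.zero_grad()
            breakdown.total_tensor.backward()
            opt.step()
            epoch_losses.append(breakdown.L_total)
        # validation: mean AUC over 1..10-year horizons
        records = score_cohort(model, val_data, train_cfg)
        aucs = [horizon_auc(records, j) for j in range(1, 11)]
        defined = [a for a in aucs if a is not None]
        mean_auc = float(np.mean(defined)) if defined else float("nan")
        log.append({"epoch": epoch, "lr": opt.lr,
                    "train_loss": float(np.mean(epoch_losses)),
                    "val_mean_auc_1_10": mean_auc})
        if defined and mean_auc > best[0]:
            best = (mean_auc, epoch, copy.deepcopy(model.state_dict()))
    if best[2] is not None:
        model.load_state_dict(best[2])
    model.eval()
    return FitResult(model=model, log=log, best_epoch=best[1],
                     best_val_mean_auc=best[0])


def score_cohort(model: RiskModel, data: CohortTensors,
                 train_cfg: TrainConfig, batch_size: int = 16):
    """Score every eligible exam; returns the evaluation-record DataFrame."""
    import pandas as pd
    from .network import risk_curve

    model.eval()
    rows = []
    with ad.no_grad():
        for lo in range(0, len(data.items), batch_size):
            chunk = data.items[lo: lo + batch_size]
            batch = make_batch(data, chunk, train_cfg, mode="eval")
            out = model(batch)
            curves = risk_curve(out.patient_logits)        # (B, 15)
            breast_curves = risk_curve(out.breast_logits)  # (B, 2, 15)
            for i, (pid, sample) in enumerate(chunk):
                tl = data.timelines[pid]
                exam = tl.exams[sample.target_exam_index]
                row = {
                    "patient_id": pid,
                    "exam_id": f"{pid}_e{sample.target_exam_index}",
                    "event": bool(sample.event),
                    "time_years": float(sample.time_years),
                    "age": float(tl.risk_factors.age),
                    "birads": int(exam.birads),
                    "prior_bc": bool(tl.prior_tumors),
                    "biopsy_benign_within_90d": bool(exam.biopsy_benign_within_90d),
                    "score": float(curves[i, 9]),          # 10-year risk
                }
                for j in range(1, 16):
                    row[f"risk_{j}"] = float(curves[i, j - 1])
                for s_idx, s in enumerate(SIDES):
                    row[f"risk_10_{s}"] = float(breast_curves[i, s_idx, 9])
                rows.append(row)
    return pd.DataFrame(rows)
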