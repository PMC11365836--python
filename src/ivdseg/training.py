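"""Dual-task optimisation: Dice + pretext cross-entropy on a shared encoder.

Each training iteration pairs one labeled source segmentation batch (batch
size 1) with one pretext batch (batch size 4) drawn round-robin from the
configured pretext domains.  Both losses are back-propagated before a single
Adam update, so their gradients accumulate on the shared encoder while the
decoder only ever receives segmentation gradients and each pretext head only
its own classification gradients.  The returned model is the checkpoint with
the lowest total validation loss ``L_total = L_seg + L_p`` on the source
validation split, with pretext validation samples generated under a frozen
seed so the criterion is comparable across epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import F32, Adam
from .network import DualTaskModel, NetworkSpec, build_model
from .phantom import DomainSample
from .transforms import (PretextSample, TransformParams,
                         apply_rotation_pretext, augment_pretext,
                         augment_segmentation, sample_pretext)

__all__ = ["TrainConfig", "LossRecord", "dice_loss", "pretext_loss",
           "train_step", "train", "predict", "pretext_accuracy"]

_EPS = 1e-6
_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule and the pretext-task configuration.

    ``pretext_domains`` names the datasets feeding the pretext task
    (subset of {"S", "T1", "T2", ...}); empty means plain single-task
    segmentation (the baseline).  ``pretext_kinds`` selects the head(s):
    "intensity" and/or "rotation".
    """

    learning_rate: float = 1e-3
    epochs: int = 100
    seg_batch_size: int = 1
    pretext_batch_size: int = 4
    pretext_domains: tuple[str, ...] = ()
    pretext_kinds: tuple[str, ...] = ("intensity",)
    optimizer: str = "adam"
    seed: int = 0
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (w_seg, w_pretext)
    augment: bool = True

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 1 and learning_rate > 0")
        unknown = set(self.pretext_kinds) - {"intensity", "rotation"}
        if unknown:
            raise ValueError(f"unknown pretext kinds: {sorted(unknown)}")
        object.__setattr__(self, "pretext_domains",
                           tuple(self.pretext_domains))
        object.__setattr__(self, "pretext_kinds", tuple(self.pretext_kinds))
        object.__setattr__(self, "loss_weights", tuple(self.loss_weights))

    @property
    def baseline(self) -> bool:
        return not self.pretext_domains

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class LossRecord:
    step: int
    l_seg: float
    l_p: float | None
    l_total: float

    def __post_init__(self):
        parts = [self.l_seg] + ([self.l_p] if self.l_p is not None else [])
        if not all(np.isfinite(parts)):
            raise ValueError(f"non-finite loss at step {self.step}")


# --------------------------------------------------------------------------
# losses

def _check_dice_inputs(pred, target):
    pred = np.asarray(pred, dtype=F32)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.min() < -1e-6 or pred.max() > 1 + 1e-6:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    tvals = np.unique(target)
    if not np.isin(tvals, (0, 1)).all():
        raise ValueError("target mask must be binary")
    return pred, target.astype(F32)


def dice_loss(pred_fg_prob, target_mask, eps: float = _EPS) -> float:
    """Soft Dice loss 1 - (2*sum(p*y)+eps) / (sum(p)+sum(y)+eps)."""
    loss, _ = _dice_loss_grad(pred_fg_prob, target_mask, eps)
    return loss


def _dice_loss_grad(pred, target, eps: float = _EPS):
    p, y = _check_dice_inputs(pred, target)
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum()) + eps
    num = 2.0 * inter + eps
    loss = 1.0 - num / denom
    # d/dp [1 - (2<p,y>+e)/(S+e)] with S = sum p + sum y
    grad = (num / denom ** 2 - 2.0 * y / denom).astype(F32)
    return float(loss), grad


def pretext_loss(pred_dist, label) -> float:
    """Cross-entropy -log p[label]; mean over the batch when batched."""
    loss, _ = _pretext_loss_grad(pred_dist, label)
    return loss


def _pretext_loss_grad(pred_dist, label):
    p = np.asarray(pred_dist, dtype=F32)
    if p.ndim == 1:
        p = p[None, :]
        labels = np.asarray([label], dtype=int)
    else:
        labels = np.asarray(label, dtype=int).reshape(-1)
    if p.ndim != 2 or len(labels) != p.shape[0]:
        raise ValueError("pred_dist/label shapes do not match")
    if (labels < 0).any() or (labels >= p.shape[1]).any():
        raise ValueError("label out of range")
    n = p.shape[0]
    picked = np.maximum(p[np.arange(n), labels], _PROB_FLOOR)
    loss = float(-np.log(picked).mean())
    grad = np.zeros_like(p)
    grad[np.arange(n), labels] = -1.0 / (picked * n)
    return loss, grad


# --------------------------------------------------------------------------
# one optimisation step

def _stack(volumes) -> np.ndarray:
    return np.stack([np.asarray(v, dtype=F32) for v in volumes])[..., None]


def _seg_pass(model, seg_batch, weight, backward=True):
    vols = _stack([s.volume for s in seg_batch])
    probs = model.forward_seg(vols)
    losses, grads = [], np.zeros_like(probs)
    for i, s in enumerate(seg_batch):
        loss, g = _dice_loss_grad(probs[i, ..., 1], s.mask)
        losses.append(loss)
        grads[i, ..., 1] = g
    l_seg = float(np.mean(losses))
    if backward:
        model.backward_seg(grads * F32(weight / len(seg_batch)))
    return l_seg


def _pretext_pass(model, head, batch, weight, backward=True):
    vols = _stack([s.volume for s in batch])
    labels = [s.label for s in batch]
    dist = model.forward_pretext(vols, head)
    loss, grad = _pretext_loss_grad(dist, labels)
    if backward:
        model.backward_pretext(grad * F32(weight), head)
    return loss


def train_step(model: DualTaskModel, seg_batch, pretext_batches,
               config: TrainConfig, optimizer: Adam, step: int = 0
               ) -> LossRecord:
    """One combined update: L_seg and L_p gradients accumulate, then Adam.

    ``pretext_batches`` maps head name -> list of PretextSamples; it must be
    empty/None exactly in baseline mode.
    """
    pretext_batches = pretext_batches or {}
    if config.baseline and pretext_batches:
        raise ValueError("baseline mode takes no pretext batch")
    if not config.baseline and not pretext_batches:
        raise ValueError("dual-task mode requires a pretext batch")
    w_seg, w_p = config.loss_weights
    optimizer.zero_grad()
    l_seg = _seg_pass(model, seg_batch, w_seg)
    l_p = None
    if pretext_batches:
        l_p = 0.0
        for head, batch in pretext_batches.items():
            l_p += _pretext_pass(model, head, batch, w_p)
    optimizer.step()
    l_total = w_seg * l_seg + (w_p * l_p if l_p is not None else 0.0)
    return LossRecord(step=step, l_seg=l_seg, l_p=l_p, l_total=l_total)


# --------------------------------------------------------------------------
# pretext sampling machinery

class _RoundRobinPool:
    """Cycle domains in fixed order; within a domain, cycle a shuffled order."""

    def __init__(self, pools: dict[str, list[DomainSample]], rng):
        if any(len(v) == 0 for v in pools.values()):
            raise ValueError("empty pretext domain pool")
        self.names = list(pools)
        self.pools = pools
        self.rng = rng
        self._dom = 0
        self._orders = {n: iter(()) for n in self.names}

    def take(self) -> DomainSample:
        name = self.names[self._dom % len(self.names)]
        self._dom += 1
        try:
            idx = next(self._orders[name])
        except StopIteration:
            self._orders[name] = iter(
                self.rng.permutation(len(self.pools[name])))
            idx = next(self._orders[name])
        return self.pools[name][int(idx)]


def _make_pretext_batch(pool: _RoundRobinPool, kind: str, size: int,
                        params: TransformParams, rng,
                        augment: bool) -> list[PretextSample]:
    batch = []
    for _ in range(size):
        sample = pool.take()
        vol = sample.volume
        seed = int(rng.integers(0, 2 ** 31 - 1))
        if augment:
            vol = augment_pretext(vol, seed)
        if kind == "intensity":
            ps = sample_pretext(
                DomainSample(vol, None, sample.domain_id, sample.sample_id),
                params, seed)
        else:  # rotation
            k = int(rng.integers(0, 4))
            ps = PretextSample(apply_rotation_pretext(vol, k), k,
                               sample.domain_id)
        batch.append(ps)
    return batch


# --------------------------------------------------------------------------
# full training loop

def _snapshot(model):
    return [p.value.copy() for p in model.params()]


def _restore(model, snap):
    for p, v in zip(model.params(), snap):
        p.value[...] = v


def _validation_losses(model, source_val, val_pretext, config):
    # validation runs with batch statistics (training mode, no update): the
    # frozen validation set then yields a smooth, deterministic selection
    # criterion that does not depend on recently-seen training batches
    l_segs = []
    for s in source_val:
        probs = model.forward_seg(_stack([s.volume]))
        l_segs.append(dice_loss(probs[0, ..., 1], s.mask))
    l_seg = float(np.mean(l_segs))
    l_p = None
    if val_pretext:
        l_p = 0.0
        for head, batch in val_pretext.items():
            vols = _stack([s.volume for s in batch])
            dist = model.forward_pretext(vols, head)
            l_p += pretext_loss(dist, [s.label for s in batch])
    w_seg, w_p = config.loss_weights
    l_total = w_seg * l_seg + (w_p * l_p if l_p is not None else 0.0)
    return l_seg, l_p, l_total


def train(source_train: list[DomainSample], source_val: list[DomainSample],
          target_sets: dict[str, list[DomainSample]], config: TrainConfig,
          network_spec: NetworkSpec | None = None,
          transform_params: TransformParams | None = None,
          model: DualTaskModel | None = None):
    """Run the full dual-task loop; returns (best model, history).

    One epoch is one shuffled pass over ``source_train``; every iteration
    takes one segmentation batch plus, unless in baseline mode, one pretext
    batch per configured head, drawn round-robin across pretext domains.
    ``history`` holds per-step LossRecords, per-epoch validation records and
    the index of the selected epoch.
    """
    if not source_train or not source_val:
        raise ValueError("training and validation sets must be non-empty")
    if any(s.mask is None for s in source_train + source_val):
        raise ValueError("source samples must be labeled")
    params = transform_params or TransformParams()
    if model is None:
        if network_spec is None:
            heads = []
            if "intensity" in config.pretext_kinds:
                heads.append({"name": "intensity", "n_classes": 4})
            if "rotation" in config.pretext_kinds:
                heads.append({"name": "rotation", "n_classes": 4})
            network_spec = NetworkSpec(pretext_heads=tuple(heads) or
                                       (dict(name="intensity", n_classes=4),))
        model = build_model(network_spec, init_seed=config.seed)

    pools = {}
    for name in config.pretext_domains:
        if name == "S":
            pools[name] = source_train
        elif name in target_sets:
            pools[name] = target_sets[name]
        else:
            raise ValueError(f"unknown pretext domain {name!r}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 41]))
    pool = _RoundRobinPool(pools, rng) if pools else None
    optimizer = Adam(model.params(), lr=config.learning_rate)

    # frozen validation pretext batches: same samples and draws every epoch
    val_pretext = {}
    if pool is not None:
        val_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 43]))
        val_pool = _RoundRobinPool({"S": source_val}, val_rng)
        for kind in config.pretext_kinds:
            val_pretext[kind] = _make_pretext_batch(
                val_pool, kind, 6 * config.pretext_batch_size, params,
                val_rng, augment=False)

    history = {"steps": [], "val": [], "best_epoch": None}
    best = (np.inf, None)
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(source_train))
        for start in range(0, len(order), config.seg_batch_size):
            idx = order[start:start + config.seg_batch_size]
            seg_batch = []
            for i in idx:
                s = source_train[int(i)]
                if config.augment:
                    s = augment_segmentation(
                        s, int(rng.integers(0, 2 ** 31 - 1)))
                seg_batch.append(s)
            pretext_batches = None
            if pool is not None:
                pretext_batches = {
                    kind: _make_pretext_batch(pool, kind,
                                              config.pretext_batch_size,
                                              params, rng, config.augment)
                    for kind in config.pretext_kinds}
            rec = train_step(model, seg_batch, pretext_batches, config,
                             optimizer, step=step)
            history["steps"].append(rec)
            step += 1
        l_seg, l_p, l_total = _validation_losses(
            model, source_val, val_pretext, config)
        history["val"].append(
            LossRecord(step=epoch, l_seg=l_seg, l_p=l_p, l_total=l_total))
        if l_total < best[0]:
            best = (l_total, _snapshot(model))
            history["best_epoch"] = epoch
    _restore(model, best[1])
    _calibrate_model(model, source_train, pools, config, params)
    return model, history


def _calibrate_model(model, source_train, pools, config, params):
    """Estimate inference batch-norm statistics for the selected weights.

    One deterministic frozen-weight pass over the model's own training
    streams: unaugmented source segmentation batches plus, for dual-task
    models, round-robin pretext batches from the configured domains.  The
    pass mirrors the training composition — one pretext batch per
    segmentation batch — so the averaged statistics match the regime the
    weights were optimised under.
    """
    seg_batches = [_stack([s.volume]) for s in source_train]
    pretext_batches = None
    if pools:
        cal_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 47]))
        cal_pool = _RoundRobinPool(pools, cal_rng)
        pretext_batches = {}
        for kind in config.pretext_kinds:
            batches = []
            for _ in range(len(seg_batches)):
                batch = _make_pretext_batch(
                    cal_pool, kind, config.pretext_batch_size, params,
                    cal_rng, augment=False)
                batches.append(_stack([s.volume for s in batch]))
            pretext_batches[kind] = batches
    model.calibrate(seg_batches, pretext_batches)


def predict(model: DualTaskModel, volume) -> np.ndarray:
    """Binary foreground mask by per-voxel argmax of the softmax output."""
    probs = model.segment(np.asarray(volume, dtype=F32))
    return (probs[..., 1] > probs[..., 0]).astype(np.uint8)


def pretext_accuracy(model: DualTaskModel, samples: list[PretextSample],
                     head: str = "intensity", batch_size: int = 8) -> float:
    """Fraction of pretext samples whose class the head identifies."""
    correct = 0
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        dist = model.classify(_stack([s.volume for s in chunk]), head)
        pred = dist.argmax(axis=1)
        correct += int((pred == [s.label for s in chunk]).sum())
    return correct / len(samples)
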