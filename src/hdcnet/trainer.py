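"""Training protocol: binary cross-entropy, Adam, per-dataset hyperparameters.

The published recipe trains every model from scratch with Adam and a BCE
loss at learning rate 0.008 and batch size 2, for 100 / 50 / 80 epochs on
DRIVE / CHASE-DB1 / STARE respectively, with DropBlock at block size 7 and
rate 0.15. Runs are fully seeded; checkpoints are self-describing (weights,
architecture config, seed and epoch in one ``.npz``).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _autograd as ag
from .arch_blocks import BlockConfig
from .data_pipeline import DatasetSpec, ImagePair, load_dataset, pad_to_target, restore_original
from .metrics import MetricReport, aggregate
from .networks import ModelConfig, SegmentationModel, build_model, predict

__all__ = [
    "DATASET_HYPERPARAMS",
    "RunRecord",
    "TrainConfig",
    "bce_loss",
    "cross_train",
    "evaluate",
    "load_checkpoint",
    "save_checkpoint",
    "train",
]

#: (epochs, learning rate, batch size) per benchmark dataset
DATASET_HYPERPARAMS = {
    "drive": (100, 0.008, 2),
    "chase_db1": (50, 0.008, 2),
    "stare": (80, 0.008, 2),
}

_EPS = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.008
    batch_size: int = 2
    seed: int = 0
    validation_fraction: float = 0.1
    dataset: DatasetSpec | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")


@dataclass
class RunRecord:
    """Per-epoch history plus everything needed to re-create the run."""

    config: TrainConfig
    seed: int
    epochs: list[dict] = field(default_factory=list)
    diverged: bool = False
    best_epoch: int | None = None
    final_checkpoint: str | None = None
    best_checkpoint: str | None = None
    model: SegmentationModel | None = None  # not serialized


def bce_loss(prob: np.ndarray, target: np.ndarray) -> float:
    """Mean binary cross-entropy of probabilities against a binary target.

    Probabilities are clamped away from {0, 1} so perfect predictions give a
    loss that tends to zero rather than a log-of-zero.
    """
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs target {target.shape}")
    p = np.clip(prob, _EPS, 1.0 - _EPS)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def _bce_tensor(prob: ag.Tensor, target: np.ndarray) -> ag.Tensor:
    y = ag.as_tensor(target)
    one_minus_y = ag.as_tensor(1.0 - target)
    p = ag.clip(prob, _EPS, 1.0 - _EPS)
    one_minus_p = ag.add(ag.as_tensor(1.0), ag.mul(p, ag.as_tensor(-1.0)))
    ll = ag.add(ag.mul(y, ag.log(p)), ag.mul(one_minus_y, ag.log(one_minus_p)))
    return ag.mul(ag.mean(ll), ag.as_tensor(-1.0))


class Adam:
    """Adam with the conventional beta/epsilon defaults."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: SegmentationModel, cfg: ModelConfig,
                    seed: int, epoch: int) -> None:
    meta = {
        "format": "hdcnet-checkpoint-v1",
        "model": asdict(cfg),
        "seed": seed,
        "epoch": epoch,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[SegmentationModel, ModelConfig, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta.get("format") != "hdcnet-checkpoint-v1":
        raise ValueError(f"{path} is not a recognised checkpoint")
    mdict = dict(meta["model"])
    bdict = mdict.pop("block")
    bdict["hdc_dilations"] = tuple(bdict["hdc_dilations"])
    cfg = ModelConfig(block=BlockConfig(**bdict), **mdict)
    model = build_model(cfg, seed=meta["seed"])
    model.load_state_dict(state)
    return model, cfg, meta


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _prepare(pairs: list[ImagePair], target: tuple[int, int] | None, depth: int):
    """Pad pairs so spatial dims are divisible by 2^depth."""
    div = 2**depth
    out = []
    for p in pairs:
        h, w = p.mask.shape
        if target is not None:
            th, tw = target
        else:
            th, tw = -(-h // div) * div, -(-w // div) * div
        out.append(pad_to_target(p, (th, tw)) if (th, tw) != (h, w) else p)
    return out

def _batch(pairs: list[ImagePair]):
    x = np.stack([p.image.transpose(2, 0, 1) for p in pairs])
    y = np.stack([p.mask[None].astype(np.float64) for p in pairs])
    return x, y


def _iter_modules(module):
    yield module
    for _, child in module._children():
        yield from _iter_modules(child)


def _refresh_bn_stats(model: SegmentationModel, pairs: list[ImagePair], batch_size: int) -> None:
    """Re-estimate batch-norm running statistics with DropBlock disabled.

    DropBlock zeroes contiguous patches before the norm, which inflates the
    variance the norm sees during training relative to the clean activations
    seen at inference. After optimization, one sweep over the training set
    with the regularizer off replaces the running statistics by the exact
    average of clean batch statistics, aligning train and eval behaviour.
    """
    from .arch_blocks import DropBlock2d
    from .layers import BatchNorm2d

    drops = [m for m in _iter_modules(model) if isinstance(m, DropBlock2d)]
    bns = [m for m in _iter_modules(model) if isinstance(m, BatchNorm2d)]
    saved_rates = [d.drop_rate for d in drops]
    for d in drops:
        d.drop_rate = 0.0
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    try:
        k = 0
        for start in range(0, len(pairs), batch_size):
            k += 1
            for bn in bns:
                bn.momentum = 1.0 / k  # arithmetic averaging of batch stats
            x, _ = _batch(pairs[start : start + batch_size])
            model.forward(ag.as_tensor(x), training=True)
    finally:
        for d, r in zip(drops, saved_rates):
            d.drop_rate = r
        for bn in bns:
            bn.momentum = 0.1


def train(cfg: TrainConfig, data: list[ImagePair]) -> RunRecord:
    """Seeded from-scratch optimization of the configured model.

    Logs per-epoch training loss/accuracy (and validation metrics when a
    validation split is held out); aborts with ``diverged=True`` on a
    non-finite loss. The returned record carries the trained model and, when
    ``checkpoint_dir`` is set, paths to the final and best-validation
    checkpoints.
    """
    if not data:
        raise ValueError("training requires at least one image pair")
    rng = np.random.default_rng(cfg.seed)
    target = cfg.dataset.target_size if cfg.dataset else None
    pairs = _prepare(data, target, cfg.model.depth)

    n_val = int(round(cfg.validation_fraction * len(pairs)))
    if n_val and len(pairs) - n_val >= 1:
        perm = rng.permutation(len(pairs))
        val_pairs = [pairs[i] for i in perm[:n_val]]
        train_pairs = [pairs[i] for i in perm[n_val:]]
    else:
        val_pairs, train_pairs = [], list(pairs)

    model = build_model(cfg.model, seed=cfg.seed)
    opt = Adam(model.parameters(), cfg.learning_rate)
    record = RunRecord(config=cfg, seed=cfg.seed, model=model)
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    best_f1 = -np.inf
    best_state = None

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_pairs))
        losses, accs = [], []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_pairs[i] for i in order[start : start + cfg.batch_size]]
            x, y = _batch(batch)
            out = model.forward(ag.as_tensor(x), training=True, rng=rng)
            loss = _bce_tensor(out, y)
            if not math.isfinite(loss.data):
                record.diverged = True
                record.epochs.append({"epoch": epoch + 1, "train_loss": float(loss.data)})
                return record
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            accs.append(float(((out.data > 0.5) == (y > 0.5)).mean()))
        entry = {"epoch": epoch + 1, "train_loss": float(np.mean(losses)),
                 "train_acc": float(np.mean(accs))}
        if val_pairs:
            _refresh_bn_stats(model, train_pairs, cfg.batch_size)
            x, y = _batch(val_pairs)
            out = model.forward(ag.as_tensor(x), training=False)
            entry["val_loss"] = bce_loss(out.data, y)
            entry["val_acc"] = float(((out.data > 0.5) == (y > 0.5)).mean())
            rep = aggregate([(out.data[i, 0], y[i, 0]) for i in range(len(val_pairs))])
            entry["val_f1"] = rep.f1
            if not math.isnan(rep.f1) and rep.f1 > best_f1:
                best_f1 = rep.f1
                record.best_epoch = epoch + 1
                best_state = model.state_dict()
        record.epochs.append(entry)

    _refresh_bn_stats(model, train_pairs, cfg.batch_size)
    if ckpt_dir:
        final = ckpt_dir / "final.npz"
        save_checkpoint(final, model, cfg.model, cfg.seed, cfg.epochs)
        record.final_checkpoint = str(final)
        if best_state is not None:
            model_best = build_model(cfg.model, seed=cfg.seed)
            model_best.load_state_dict(best_state)
            best = ckpt_dir / "best.npz"
            save_checkpoint(best, model_best, cfg.model, cfg.seed, record.best_epoch)
            record.best_checkpoint = str(best)
    return record


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _resolve_model(checkpoint) -> tuple[SegmentationModel, ModelConfig]:
    if isinstance(checkpoint, (str, Path)):
        model, cfg, _ = load_checkpoint(checkpoint)
        return model, cfg
    if isinstance(checkpoint, SegmentationModel):
        return checkpoint, checkpoint.cfg
    raise TypeError("checkpoint must be a path or a SegmentationModel")


def evaluate(checkpoint, spec: DatasetSpec, root: str | Path | None = None,
             pairs: list[ImagePair] | None = None, threshold: float = 0.5) -> MetricReport:
    """Pad -> predict -> restore -> globally pooled metrics on a test partition."""
    model, mcfg = _resolve_model(checkpoint)
    if pairs is None:
        if root is None:
            raise ValueError("provide either loaded pairs or a dataset root")
        everything = {p.source_id: p for p in load_dataset(spec, root)}
        ids = spec.test_ids or sorted(everything)
        pairs = [everything[i] for i in ids]
    if not pairs:
        raise ValueError("empty test partition")
    scored = []
    for p in pairs:
        padded = pad_to_target(p, spec.target_size)
        prob = predict(model, padded.image, mcfg)
        prob = restore_original(prob, padded)
        scored.append((prob, p.mask))
    return aggregate(scored, threshold)


def cross_train(train_spec: DatasetSpec, test_spec: DatasetSpec, cfg: TrainConfig,
                train_pairs: list[ImagePair] | None = None,
                test_pairs: list[ImagePair] | None = None,
                train_root=None, test_root=None) -> MetricReport:
    """Train on one dataset's training partition, evaluate on another dataset
    at its own resolution (the model is fully convolutional, so padded sizes
    may differ between the two)."""
    if train_pairs is None:
        everything = {p.source_id: p for p in load_dataset(train_spec, train_root)}
        ids = train_spec.train_ids or sorted(everything)
        train_pairs = [everything[i] for i in ids]
    run_cfg = TrainConfig(**{**asdict_shallow(cfg), "dataset": train_spec})
    record = train(run_cfg, train_pairs)
    if record.diverged:
        raise RuntimeError("training diverged; see RunRecord")
    return evaluate(record.model, test_spec, root=test_root, pairs=test_pairs)


def asdict_shallow(cfg: TrainConfig) -> dict:
    return {
        "epochs": cfg.epochs, "learning_rate": cfg.learning_rate,
        "batch_size": cfg.batch_size, "seed": cfg.seed,
        "validation_fraction": cfg.validation_fraction, "dataset": cfg.dataset,
        "model": cfg.model, "checkpoint_dir": cfg.checkpoint_dir,
    }
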