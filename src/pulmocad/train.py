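"""Training: Adam/SGD updates, masked cross-entropy, 6x augmentation,
transfer-learning freeze schedules and training-quality metrics.

The Adam update follows the bias-corrected form

    m_t = mu * m_{t-1} + (1 - mu) * g_t
    n_t = upsilon * n_{t-1} + (1 - upsilon) * g_t^2
    m̂ = m_t / (1 - mu^t),  n̂ = n_t / (1 - upsilon^t)
    Δθ = -eta * m̂ / (sqrt(n̂) + eps)

with defaults mu = 0.9, upsilon = 0.9999, eta = 0.01, eps = 1e-8.  eps is
the denominator offset in the update rule (it is not weight decay).

Training quality is summarized by TrainAcc = correct / total and the
overfitting ratio OverRatio = TrainAcc / ValAcc; values above 1 indicate
overfitting.  At desk scale an image counts as correctly detected when the
Dice of its thresholded prediction against the truth is >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from pulmocad import _autograd as ag
from pulmocad._autograd import Tensor
from pulmocad.lungseg import dice
from pulmocad.netarch import ArchTable, Network

__all__ = [
    "AdamHyper",
    "AdamState",
    "TrainConfig",
    "Metrics",
    "FREEZE_GROUPS",
    "adam_step",
    "masked_cross_entropy",
    "augment_six",
    "train_acc",
    "over_ratio",
    "resolve_freeze_group",
    "fit",
]


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

@dataclass
class AdamHyper:
    """Adam hyper-parameters: mu/upsilon the momentum factors of the first
    and second moment estimates, eta the learning rate, eps the denominator
    offset."""

    mu: float = 0.9
    upsilon: float = 0.9999
    eta: float = 0.01
    eps: float = 1e-8

    def __post_init__(self):
        if not (0 <= self.mu < 1 and 0 <= self.upsilon < 1):
            raise ValueError("momentum factors must lie in [0, 1)")
        if self.eta <= 0 or self.eps <= 0:
            raise ValueError("eta and eps must be > 0")


@dataclass
class AdamState:
    """Per-parameter first/second moment estimates and the step counter."""

    m: np.ndarray | float = 0.0
    n: np.ndarray | float = 0.0
    t: int = 0


def adam_step(state: AdamState, grad, hyper: Optional[AdamHyper] = None):
    """One Adam update.  Returns (new state, parameter delta).

    The step counter increments first, so at t = 1 the bias corrections
    make m̂ = g and n̂ = g², giving Δθ ≈ -eta * sign(g).
    """
    hyper = hyper or AdamHyper()
    g = np.asarray(grad, dtype=np.float64)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient")
    t = state.t + 1
    m = hyper.mu * state.m + (1.0 - hyper.mu) * g
    n = hyper.upsilon * state.n + (1.0 - hyper.upsilon) * g * g
    m_hat = m / (1.0 - hyper.mu**t)
    n_hat = n / (1.0 - hyper.upsilon**t)
    delta = -hyper.eta * m_hat / (np.sqrt(n_hat) + hyper.eps)
    return AdamState(m=m, n=n, t=t), delta


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def masked_cross_entropy(pred, target, ignore_mask=None):
    """Mean binary cross-entropy over voxels not covered by the ignore mask.

    Accepts either plain numpy arrays (returns a float) or an autodiff
    Tensor prediction (returns a scalar Tensor for backprop).  With no
    ignore mask this is the plain mean BCE.
    """
    if isinstance(pred, Tensor):
        return ag.masked_bce(pred, target, ignore_mask)
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    kept = np.ones_like(p, dtype=bool) if ignore_mask is None else ~np.asarray(ignore_mask, dtype=bool)
    nkept = int(kept.sum())
    if nkept == 0:
        raise ValueError("all voxels ignored: loss undefined")
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    ll = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
    return float(ll[kept].mean())


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _transforms():
    """The six enhancement transforms, acting on the trailing (y, x) axes."""
    return [
        ("original", lambda a: a),
        ("hflip", lambda a: a[..., ::-1]),
        ("vflip", lambda a: a[..., ::-1, :]),
        ("rot90", lambda a: np.rot90(a, 1, axes=(-2, -1))),
        ("rot180", lambda a: np.rot90(a, 2, axes=(-2, -1))),
        ("rot270", lambda a: np.rot90(a, 3, axes=(-2, -1))),
    ]


def augment_six(items: Sequence) -> list:
    """Emit exactly 6 items per input: original, horizontal and vertical
    flips, and 90/180/270-degree in-plane rotations, labels transformed
    identically.

    ``items`` is a sequence of arrays or of (image, label) pairs; the
    in-plane (trailing two) dims must be square for the rotations.
    """
    out = []
    for item in items:
        if isinstance(item, tuple):
            img, lab = item
        else:
            img, lab = item, None
        img = np.asarray(img)
        if img.shape[-1] != img.shape[-2]:
            raise ValueError(
                f"in-plane dims {img.shape[-2:]} not square: rotations undefined"
            )
        for _, f in _transforms():
            ai = np.ascontiguousarray(f(img))
            if lab is None:
                out.append(ai)
            else:
                out.append((ai, np.ascontiguousarray(f(np.asarray(lab)))))
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def train_acc(correct: int, total: int) -> float:
    """Fraction of correctly detected images."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= correct <= total:
        raise ValueError(f"need 0 <= correct <= total, got {correct}/{total}")
    return correct / total


def over_ratio(train_accuracy: float, val_accuracy: float) -> float:
    """Overfitting ratio TrainAcc / ValAcc (> 1 indicates overfitting)."""
    if val_accuracy <= 0:
        raise ValueError("val accuracy must be > 0")
    return train_accuracy / val_accuracy


# ---------------------------------------------------------------------------
# freeze schedules
# ---------------------------------------------------------------------------

_BLOCK_ORDER = [
    "Conv1", "Conv2", "Conv3", "Conv4", "Conv5",
    "Up6", "Up7", "Up8", "Up9", "Up10", "Up11", "Up12",
]

#: The eight fine-tuning layer groups: each resolves to a contiguous span
#: of architecture blocks left trainable (all other layers frozen).
FREEZE_GROUPS = {
    "conv1-up12": ("Conv1", "Up12"),
    "conv2-up10": ("Conv2", "Up10"),
    "conv3-up8": ("Conv3", "Up8"),
    "conv4-up6": ("Conv4", "Up6"),
    "conv5": ("Conv5", "Conv5"),
    "up6-up8": ("Up6", "Up8"),
    "up9-up11": ("Up9", "Up11"),
    "up12": ("Up12", "Up12"),
}


def _normalize_group(name: str) -> str:
    n = name.strip().lower().replace(" ", "")
    n = n.replace("convl", "conv1")  # OCR-style variant
    return n


def resolve_freeze_group(table: ArchTable, group: str) -> set:
    """Names of the table layers left trainable under a fine-tuning group.

    The group spans are contiguous in the block order Conv1..Conv5,
    Up6..Up12; a span ending at Up12 includes the output head (which
    belongs to the Up12 block), so 'conv1-Up12' is the full network.
    """
    key = _normalize_group(group)
    if key not in FREEZE_GROUPS:
        raise ValueError(f"unknown freeze group {group!r}; known: {sorted(FREEZE_GROUPS)}")
    start, end = FREEZE_GROUPS[key]
    lo, hi = _BLOCK_ORDER.index(start), _BLOCK_ORDER.index(end)
    span = set(_BLOCK_ORDER[lo : hi + 1])
    names = {l.name for l in table.layers if l.block in span}
    if not names:
        raise ValueError(f"freeze group {group!r} matches no layer of table {table.name!r}")
    return names


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training configuration.

    lr defaults to 0.001 (middle of the {0.00075, 0.001, 0.005} grid);
    dropout 0.5; batch_size small at desk scale.  checkpoint_every records
    a checkpoint snapshot; eval_every recomputes TrainAcc/ValAcc on an
    eval_subset of images; early stopping triggers after
    overfit_patience consecutive evaluations with
    OverRatio > overfit_bound.  stop_at_train_dice, when set, ends
    training once the evaluation-subset mean Dice reaches the target.
    """

    lr: float = 0.001
    dropout: float = 0.5
    batch_size: int = 2
    max_steps: int = 500
    checkpoint_every: int = 10000
    eval_every: int = 100
    eval_subset: int = 20
    augment: bool = False
    freeze_group: Optional[str] = None
    seed: int = 0
    momentum: float = 0.0  # SGD only
    overfit_bound: float = 1.15
    overfit_patience: int = 3
    dice_correct_threshold: float = 0.5
    stop_at_train_dice: Optional[float] = None
    checkpoint_dir: Optional[str] = None  # write .npz + sidecar JSON when set

    def __post_init__(self):
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must lie in [0, 1]")


@dataclass
class Metrics:
    """Final training metrics with full histories."""

    train_accuracy: float = 0.0
    val_accuracy: float = 0.0
    overfit_ratio: float = 0.0
    loss_history: list = field(default_factory=list)
    dice_history: list = field(default_factory=list)  # (step, mean train dice)
    checkpoints: list = field(default_factory=list)  # (step, loss)
    steps_run: int = 0
    stopped_early: bool = False


def _as_batch(x: np.ndarray) -> np.ndarray:
    """Coerce a (z, y, x) or (C, z, y, x) sample to (1, C, z, y, x)."""
    a = np.asarray(x, dtype=np.float32)
    if a.ndim == 3:
        a = a[None]
    if a.ndim == 4:
        a = a[None]
    return a


def predict(network: Network, image: np.ndarray) -> np.ndarray:
    """Probability map for one (z, y, x) image, channel squeezed away."""
    out = network.forward(_as_batch(image), training=False)
    return out.data[0, 0]


def _mean_dice(network: Network, dataset, indices, threshold=0.5) -> float:
    scores = []
    for i in indices:
        img, lab = dataset[i]
        pred = predict(network, img) > threshold
        scores.append(dice(pred, np.asarray(lab, dtype=bool)))
    return float(np.mean(scores))


def _accuracy(network: Network, dataset, indices, dice_threshold) -> float:
    correct = 0
    for i in indices:
        img, lab = dataset[i]
        pred = predict(network, img) > 0.5
        if dice(pred, np.asarray(lab, dtype=bool)) >= dice_threshold:
            correct += 1
    return train_acc(correct, len(indices))


def _write_checkpoint(network: Network, directory: str, step: int, loss: float) -> None:
    """Parameter arrays as .npz with a sidecar JSON (step, loss)."""
    import json
    import os

    os.makedirs(directory, exist_ok=True)
    state = network.get_state()
    np.savez(os.path.join(directory, f"step{step:08d}.npz"),
             **{f"p{i}": arr for i, arr in enumerate(state)})
    with open(os.path.join(directory, f"step{step:08d}.json"), "w") as fh:
        json.dump({"step": step, "loss": loss}, fh)


def load_checkpoint(network: Network, path: str) -> Network:
    """Restore parameters from a checkpoint .npz written by fit."""
    data = np.load(path)
    network.set_state([data[f"p{i}"] for i in range(len(data.files))])
    return network


def fit(
    network: Network,
    dataset: Sequence,
    config: Optional[TrainConfig] = None,
    optimizer: str = "adam",
    val_dataset: Optional[Sequence] = None,
):
    """Mini-batch training of a built network on (image, label) pairs.

    images/labels are (z, y, x) arrays.  The chosen optimizer ('adam' or
    'sgd') updates only the layers left trainable by config.freeze_group
    (default: all).  Checkpoints (step, loss) are recorded every
    checkpoint_every steps; TrainAcc/ValAcc every eval_every steps, with
    early stopping once OverRatio exceeds the configured bound for
    overfit_patience consecutive evaluations.

    Returns (network, Metrics).
    """
    config = config or TrainConfig()
    if optimizer not in ("adam", "sgd"):
        raise ValueError(f"optimizer must be 'adam' or 'sgd', got {optimizer!r}")
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    if config.augment:
        dataset = augment_six(dataset)
    val_dataset = list(val_dataset) if val_dataset is not None else None

    if config.freeze_group is not None:
        network.set_trainable(resolve_freeze_group(network.table, config.freeze_group))
    else:
        network.set_trainable([l.name for l in network.table.layers])
    network.set_dropout(config.dropout)

    rng = np.random.default_rng(config.seed)
    named = list(network.named_params())
    trainable_idx = [i for i, (name, _) in enumerate(named) if network.trainable[name]]
    hyper = AdamHyper(eta=config.lr)
    states = {i: AdamState() for i in trainable_idx}
    velocity = {i: 0.0 for i in trainable_idx}

    metrics = Metrics()
    eval_idx = list(rng.permutation(len(dataset))[: config.eval_subset])
    overfit_streak = 0

    for step in range(1, config.max_steps + 1):
        batch_ids = rng.integers(0, len(dataset), size=config.batch_size)
        imgs = np.stack([_as_batch(dataset[i][0])[0] for i in batch_ids])
        labs = np.stack([_as_batch(dataset[i][1])[0] for i in batch_ids])
        pred = network.forward(imgs, training=True, rng=rng)
        loss = ag.masked_bce(pred, labs)
        for _, p in named:
            p.grad = None
        loss.backward()
        for i in trainable_idx:
            _, p = named[i]
            if p.grad is None:
                continue
            if optimizer == "adam":
                states[i], delta = adam_step(states[i], p.grad, hyper)
                p.data = p.data + delta.astype(np.float32)
            else:
                velocity[i] = config.momentum * velocity[i] - config.lr * p.grad
                p.data = p.data + np.asarray(velocity[i], dtype=np.float32)
        metrics.loss_history.append(float(loss.data))
        metrics.steps_run = step

        if config.checkpoint_every and step % config.checkpoint_every == 0:
            metrics.checkpoints.append((step, float(loss.data)))
            if config.checkpoint_dir:
                _write_checkpoint(network, config.checkpoint_dir, step,
                                  float(loss.data))

        do_eval = config.eval_every and step % config.eval_every == 0
        if do_eval:
            tacc = _accuracy(network, dataset, eval_idx, config.dice_correct_threshold)
            if val_dataset:
                v_idx = range(min(len(val_dataset), config.eval_subset))
                vacc = _accuracy(network, val_dataset, v_idx, config.dice_correct_threshold)
            else:
                vacc = tacc
            metrics.train_accuracy = tacc
            metrics.val_accuracy = vacc
            if vacc > 0:
                metrics.overfit_ratio = over_ratio(tacc, vacc)
                overfit_streak = overfit_streak + 1 if metrics.overfit_ratio > config.overfit_bound else 0
                if overfit_streak >= config.overfit_patience:
                    metrics.stopped_early = True
                    break
            if config.stop_at_train_dice is not None:
                md = _mean_dice(network, dataset, eval_idx)
                metrics.dice_history.append((step, md))
                if md >= config.stop_at_train_dice:
                    metrics.stopped_early = True
                    break

    if metrics.train_accuracy == 0.0 and dataset:
        metrics.train_accuracy = _accuracy(
            network, dataset, eval_idx, config.dice_correct_threshold
        )
        if val_dataset:
            v_idx = range(min(len(val_dataset), config.eval_subset))
            metrics.val_accuracy = _accuracy(
                network, val_dataset, v_idx, config.dice_correct_threshold
            )
        else:
            metrics.val_accuracy = metrics.train_accuracy
        if metrics.val_accuracy > 0:
            metrics.overfit_ratio = over_ratio(metrics.train_accuracy, metrics.val_accuracy)
    return network, metrics
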