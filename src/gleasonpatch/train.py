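"""Training recipe for one one-vs-all sub-classifier.

Fine-tuning recipe: Adam at base LR 1e-3, dropped by a factor 0.1 every
15 epochs, with the fresh classification head training at 10x the
backbone rate; class-weighted cross-entropy against the one-vs-all
targets; L2 1e-2 on conv/FC weights; resize/rotate/translate/flip
augmentation on training patches; up to 50 epochs with early stopping
once the validation loss has risen for 8 consecutive epochs, restoring
the best-validation-loss weights.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .io_formats import GradeCode, Manifest, LabelPolicy, TrainConfig, read_image, read_mask
from .nn import Adam, ArchitectureSpec, TruncatedResNet18, build_model
from .nn.losses import default_class_weights, weighted_cross_entropy
from .relabel import binary_targets, multilabel_from_mask


def lr_at_epoch(config: TrainConfig, epoch: int, layer_group: str = "backbone") -> float:
    """Learning rate at a 1-based epoch for a layer group.

    backbone: base_lr * drop_factor^floor((epoch-1)/drop_every);
    head: 10x (head_lr_multiplier) the backbone rate.
    """
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    rate = config.base_lr * config.lr_drop_factor ** ((epoch - 1) // config.lr_drop_every)
    if layer_group == "head":
        return config.head_lr_multiplier * rate
    if layer_group != "backbone":
        raise ValueError(f"unknown layer group {layer_group!r}")
    return rate


class EarlyStopper:
    """Stop after `patience` consecutive epochs of strictly rising
    validation loss; tracks the best (lowest-loss) epoch for weight
    restoration.  Cannot trigger before epoch patience+1."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.prev: float | None = None
        self.rises = 0
        self.best_loss = np.inf
        self.best_epoch = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        self.epoch += 1
        if self.prev is not None and val_loss > self.prev:
            self.rises += 1
        else:
            self.rises = 0
        self.prev = val_loss
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
        return self.rises >= self.patience


@dataclasses.dataclass
class TrainHistory:
    """Per-epoch trace of one training run."""

    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    val_f1: list[float] = dataclasses.field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""  # "max_epochs" | "early_stop"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# data loading and augmentation
# ---------------------------------------------------------------------------

def load_patch_batch(manifest: Manifest, rows: list[int], input_size: int) -> np.ndarray:
    """Load and resize patches to the network input.

    Images are bilinearly resized (with anti-aliasing) to
    input_size x input_size, scaled to [0,1] and centred at 0.5; returned
    as an (N, 3, S, S) float array.
    """
    out = np.empty((len(rows), 3, input_size, input_size))
    for i, ridx in enumerate(rows):
        img = read_image(manifest.resolve(manifest.frame.iloc[ridx]["patch_path"]))
        img = img.astype(np.float64) / 255.0
        if img.shape[0] != input_size or img.shape[1] != input_size:
            img = resize(img, (input_size, input_size), order=1, anti_aliasing=True)
        out[i] = np.moveaxis(img - 0.5, -1, 0)
    return out


def augment_batch(x: np.ndarray, rng: np.random.Generator, rotation_deg: float,
                  translate_frac: float) -> np.ndarray:
    """Random rotation (+-rotation_deg), translation (+-translate_frac of
    the side) and horizontal/vertical flips, each flip with p=0.5."""
    n, _, h, w = x.shape
    out = np.empty_like(x)
    for i in range(n):
        img = x[i]
        if rng.random() < 0.5:
            img = img[:, :, ::-1]
        if rng.random() < 0.5:
            img = img[:, ::-1, :]
        angle = rng.uniform(-rotation_deg, rotation_deg)
        img = ndimage.rotate(img, angle, axes=(1, 2), reshape=False, order=1, mode="reflect")
        dy = rng.uniform(-translate_frac, translate_frac) * h
        dx = rng.uniform(-translate_frac, translate_frac) * w
        img = ndimage.shift(img, (0.0, dy, dx), order=1, mode="reflect")
        out[i] = img
    return out


def _positive_f1(scores: np.ndarray, targets: np.ndarray, threshold: float = 0.5) -> float:
    pred = scores > threshold
    tp = int(np.sum(pred & (targets == 1)))
    fp = int(np.sum(pred & (targets == 0)))
    fn = int(np.sum(~pred & (targets == 1)))
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def _softmax_pos(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e[:, 1] / e.sum(axis=1)


def predict_logits(model: TruncatedResNet18, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    chunks = [model.forward(x[i : i + batch_size], train=False)
              for i in range(0, len(x), batch_size)]
    return np.concatenate(chunks, axis=0)


def train_sub_classifier(
    manifest: Manifest,
    grade: GradeCode,
    policy: LabelPolicy,
    config: TrainConfig,
    seed: int = 0,
) -> tuple[TruncatedResNet18, TrainHistory]:
    """Train the one-vs-all sub-classifier for one grade.

    Patches in ``config.train_folds`` train the model, those in
    ``config.val_fold`` drive early stopping and the per-epoch F1 trace.
    Sub-threshold-cancer patches (no grade clears tau yet not benign)
    are excluded.  Deterministic given (manifest, config, seed).
    """
    frame = manifest.frame
    labels = [
        multilabel_from_mask(read_mask(manifest.resolve(row["mask_path"])), policy)
        for _, row in frame.iterrows()
    ]
    statuses = dict(binary_targets(manifest, policy, grade, labels=labels))

    def fold_rows(folds) -> tuple[list[int], np.ndarray]:
        rows = [i for i in range(len(frame))
                if frame.iloc[i]["fold"] in folds and statuses[i] != "excluded"]
        y = np.array([1 if statuses[i] == "positive" else 0 for i in rows], dtype=np.int64)
        return rows, y

    train_rows, y_train = fold_rows(set(config.train_folds))
    val_rows, y_val = fold_rows({config.val_fold})
    if len(train_rows) == 0 or y_train.sum() == 0:
        raise ValueError(f"no positive training examples for grade {grade.name}")
    if y_train.sum() == len(y_train):
        raise ValueError(f"no negative training examples for grade {grade.name}")
    if len(val_rows) == 0:
        raise ValueError(f"validation fold {config.val_fold} is empty")

    weights = np.asarray(config.class_weights if config.class_weights is not None
                         else default_class_weights(y_train))

    rng = np.random.default_rng(seed)
    model = build_model(ArchitectureSpec(input_size=config.input_size),
                        init=config.init, seed=int(rng.integers(2**31)))
    optimizer = Adam(model.params, l2=config.l2, head_multiplier=config.head_lr_multiplier)

    x_train = load_patch_batch(manifest, train_rows, config.input_size)
    x_val = load_patch_batch(manifest, val_rows, config.input_size)

    history = TrainHistory()
    stopper = EarlyStopper(config.early_stop_patience)
    best_state = model.state_dict()
    for epoch in range(1, config.max_epochs + 1):
        lr = lr_at_epoch(config, epoch, "backbone")
        order = rng.permutation(len(train_rows))
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_train[idx]
            if config.augment:
                xb = augment_batch(xb, rng, config.rotation_deg, config.translate_frac)
            yb = y_train[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = weighted_cross_entropy(logits, yb, weights)
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step(lr)
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        history.train_loss.append(epoch_loss / n_seen)

        val_logits = predict_logits(model, x_val)
        val_loss, _ = weighted_cross_entropy(val_logits, y_val, weights)
        history.val_loss.append(val_loss)
        history.val_f1.append(_positive_f1(_softmax_pos(val_logits), y_val))

        stop = stopper.update(val_loss)
        if stopper.best_epoch == epoch:
            best_state = model.state_dict()
        if stop:
            history.stop_epoch = epoch
            history.stop_reason = "early_stop"
            model.load_state_dict(best_state)
            break
    else:
        history.stop_epoch = config.max_epochs
        history.stop_reason = "max_epochs"
        model.load_state_dict(best_state)
    return model, history
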