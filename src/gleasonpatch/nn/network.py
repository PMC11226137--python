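"""The truncated ResNet18-variant binary classifier.

The architecture keeps the ResNet18 stem (7x7/64 stride-2 conv, BN, ReLU,
2x2 max-pool), the conv2 basic block (two 3x3/64 convs with identity
skip), the conv3 basic block (3x3/128, first conv stride 2, projection
skip), and only the first half of the conv4 group: a single 3x3/256
stride-1 conv with its projection skip, ending in a ReLU.  The conv5
group and the second conv4 block are removed to curb overfitting on
small, imbalanced patch datasets.  Global average pooling over the final
256-channel feature maps feeds a fully connected 2-way softmax head.

For a 224x224x3 input the activation sizes are 112x112x64 after the stem
conv, 56x56x64 through conv2, 28x28x128 through conv3, 28x28x256 after
the truncated conv4 (1x1x256 after pooling) and 2 output logits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .layers import BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2, Param, ReLU


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """Fixed layer plan of the truncated network; only the input side is
    configurable (224 for the standard recipe, smaller for fast tests)."""

    input_size: int = 224
    stem_channels: int = 64
    block_channels: tuple[int, int, int] = (64, 128, 256)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.input_size < 16 or self.input_size % 8:
            raise ValueError("input_size must be >= 16 and divisible by 8")

    def rows(self) -> list[tuple[str, tuple[int, ...]]]:
        """Analytic activation sizes (H, W, C) per named stage."""
        s = self.input_size
        c1, c2, c3 = self.block_channels
        stem = (s + 2 * 3 - 7) // 2 + 1          # 7x7 stride-2, pad 3
        pooled = stem // 2                        # 2x2 max-pool
        conv3 = (pooled + 2 * 1 - 3) // 2 + 1     # 3x3 stride-2, pad 1
        return [
            ("input", (s, s, 3)),
            ("conv1", (stem, stem, self.stem_channels)),
            ("conv2a", (pooled, pooled, c1)),
            ("conv2b", (pooled, pooled, c1)),
            ("conv3a", (conv3, conv3, c2)),
            ("conv3b", (conv3, conv3, c2)),
            ("conv4a_gap", (1, 1, c3)),
            ("fc", (self.n_classes,)),
        ]


class BasicBlock:
    """Standard ResNet basic block: two 3x3 convs with BN, a skip
    connection (1x1 projection when shape changes), and a final ReLU."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng, name: str):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng, f"{name}.conv1")
        self.bn1 = BatchNorm2d(c_out, f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng, f"{name}.conv2")
        self.bn2 = BatchNorm2d(c_out, f"{name}.bn2")
        self.relu_out = ReLU()
        self.proj = None
        self.proj_bn = None
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride, 0, rng, f"{name}.proj")
            self.proj_bn = BatchNorm2d(c_out, f"{name}.proj_bn")
        self.layers = [self.conv1, self.bn1, self.conv2, self.bn2] + (
            [self.proj, self.proj_bn] if self.proj else []
        )
        self.params = [p for l in self.layers for p in l.params]

    def forward(self, x, train=True):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.proj:
            skip = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            skip = x
        return self.relu_out.forward(out + skip, train)

    def backward(self, dy):
        dsum = self.relu_out.backward(dy)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(dsum)))))
        if self.proj:
            dskip = self.proj.backward(self.proj_bn.backward(dsum))
        else:
            dskip = dsum
        return dmain + dskip


class HalfBlock:
    """The truncated conv4 stage: a single 3x3 conv with BN plus a 1x1
    projection skip, summed and passed through the final ReLU whose output
    feeds global average pooling (and serves as the Grad-CAM target)."""

    def __init__(self, c_in: int, c_out: int, rng, name: str):
        self.conv = Conv2d(c_in, c_out, 3, 1, 1, rng, f"{name}.conv")
        self.bn = BatchNorm2d(c_out, f"{name}.bn")
        self.proj = Conv2d(c_in, c_out, 1, 1, 0, rng, f"{name}.proj")
        self.proj_bn = BatchNorm2d(c_out, f"{name}.proj_bn")
        self.relu_out = ReLU()
        self.layers = [self.conv, self.bn, self.proj, self.proj_bn]
        self.params = [p for l in self.layers for p in l.params]

    def forward(self, x, train=True):
        out = self.bn.forward(self.conv.forward(x, train), train)
        skip = self.proj_bn.forward(self.proj.forward(x, train), train)
        return self.relu_out.forward(out + skip, train)

    def backward(self, dy):
        dsum = self.relu_out.backward(dy)
        return self.conv.backward(self.bn.backward(dsum)) + self.proj.backward(
            self.proj_bn.backward(dsum)
        )


class TruncatedResNet18:
    """One one-vs-all sub-classifier mapping NCHW images to 2 logits."""

    CHECKPOINT_VERSION = 1

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        c1, c2, c3 = spec.block_channels
        self.conv1 = Conv2d(3, spec.stem_channels, 7, 2, 3, rng, "stem.conv")
        self.bn1 = BatchNorm2d(spec.stem_channels, "stem.bn")
        self.relu1 = ReLU()
        self.pool = MaxPool2()
        self.block2 = BasicBlock(spec.stem_channels, c1, 1, rng, "block2")
        self.block3 = BasicBlock(c1, c2, 2, rng, "block3")
        self.block4 = HalfBlock(c2, c3, rng, "block4")
        self.gap = GlobalAvgPool()
        self.fc = Linear(c3, spec.n_classes, rng, "fc", head=True)
        self._units = [self.conv1, self.bn1, self.block2, self.block3, self.block4, self.fc]
        self.params: list[Param] = [p for u in self._units for p in u.params]
        self._features: np.ndarray | None = None

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Forward pass on an (N, 3, H, W) batch; returns (N, 2) logits.

        Caches the final convolutional feature maps (post block4 ReLU) in
        ``feature_maps`` for Grad-CAM.
        """
        x = np.asarray(x, dtype=np.float64)
        out = self.pool.forward(self.relu1.forward(self.bn1.forward(
            self.conv1.forward(x, train), train), train), train)
        out = self.block2.forward(out, train)
        out = self.block3.forward(out, train)
        out = self.block4.forward(out, train)
        self._features = out
        return self.fc.forward(self.gap.forward(out, train), train)

    @property
    def feature_maps(self) -> np.ndarray:
        """Final conv feature maps (N, 256, h, w) from the last forward."""
        if self._features is None:
            raise RuntimeError("run forward() before accessing feature maps")
        return self._features

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Full backward pass; accumulates parameter gradients."""
        dfeat = self.gap.backward(self.fc.backward(dlogits))
        d = self.block4.backward(dfeat)
        d = self.block3.backward(d)
        d = self.block2.backward(d)
        d = self.conv1.backward(self.bn1.backward(self.relu1.backward(self.pool.backward(d))))
        return d

    def feature_gradients(self, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of a scalar in the logits w.r.t. the cached feature
        maps — the head-only backward needed by Grad-CAM.  Does not touch
        parameter gradients."""
        return self.gap.backward(dlogits @ self.fc.w.data)

    def features_and_logits(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logits = self.forward(x, train=False)
        return self.feature_maps, logits

    # -- state --------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.params}
        for unit, tag in ((self.bn1, "stem.bn"), (self.block2, "block2"),
                          (self.block3, "block3"), (self.block4, "block4")):
            bns = [unit] if isinstance(unit, BatchNorm2d) else [
                l for l in unit.layers if isinstance(l, BatchNorm2d)]
            for i, bn in enumerate(bns):
                state[f"{tag}.bn{i}.running_mean"] = bn.running_mean.copy()
                state[f"{tag}.bn{i}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params:
            p.data[...] = state[p.name]
        for unit, tag in ((self.bn1, "stem.bn"), (self.block2, "block2"),
                          (self.block3, "block3"), (self.block4, "block4")):
            bns = [unit] if isinstance(unit, BatchNorm2d) else [
                l for l in unit.layers if isinstance(l, BatchNorm2d)]
            for i, bn in enumerate(bns):
                bn.running_mean[...] = state[f"{tag}.bn{i}.running_mean"]
                bn.running_var[...] = state[f"{tag}.bn{i}.running_var"]


def build_model(spec: ArchitectureSpec, init: str = "random",
                seed: int = 0) -> TruncatedResNet18:
    """Construct the binary classifier.

    ``init="random"`` uses He-normal initialization from ``seed``.
    ``init="pretrained"`` would copy ImageNet ResNet18 weights into the
    retained layers; no weight archive ships with this package, so it
    raises with instructions to fall back to random initialization.
    """
    if init == "pretrained":
        raise RuntimeError(
            "pretrained ImageNet weights are not bundled; place a checkpoint "
            "and load it via load_checkpoint(), or use init='random'"
        )
    if init != "random":
        raise ValueError(f"init must be 'random' or 'pretrained', got {init!r}")
    return TruncatedResNet18(spec, np.random.default_rng(seed))


def save_checkpoint(path: str | Path, model: TruncatedResNet18, *,
                    train_config=None, history=None, seed: int | None = None) -> None:
    """Write a versioned .npz checkpoint: weights + JSON metadata
    (architecture spec, training config, history, seed)."""
    meta = {
        "version": TruncatedResNet18.CHECKPOINT_VERSION,
        "spec": dataclasses.asdict(model.spec),
        "train_config": dataclasses.asdict(train_config) if train_config else None,
        "history": history.to_dict() if history is not None else None,
        "seed": seed,
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(Path(path), __meta__=np.frombuffer(
        json.dumps(meta, default=list).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[TruncatedResNet18, dict]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != TruncatedResNet18.CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        spec_doc = dict(meta["spec"])
        spec_doc["block_channels"] = tuple(spec_doc["block_channels"])
        spec = ArchitectureSpec(**spec_doc)
        model = build_model(spec, init="random", seed=0)
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model, meta
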