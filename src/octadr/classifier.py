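"""Phase classifiers: architecture plan, dihedral augmentation, training.

One CNN is trained per analysis level (full frame, quarters,
sixteenths, fovea crop).  All share the same plan — four 3x3 "valid"
convolution blocks with channel widths 16/32/64/128, each followed by
2x2 max-pooling, then two 128-wide fully connected layers and a
2-class soft-max — applied to whatever input side the level provides.
``build_architecture`` reports per-layer output shapes and weight
counts (biases tallied separately, since the conventional per-layer
count is the bias-free kernel product).

Augmentation draws uniformly from the 8-element dihedral group of the
square (identity, three rotations, four reflections): the transforms
that keep an en-face angiogram's class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ShallowCNN, cross_entropy_loss

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "LayerInfo",
    "build_architecture",
    "cross_entropy_loss",
    "augment",
    "apply_dihedral",
    "DIHEDRAL_SIZE",
    "train_phase",
    "TrainedPhase",
    "CLASS_ORDER",
]

#: class index order: probs[:, 1] is the DR probability
CLASS_ORDER = ("NDR", "DR")

DIHEDRAL_SIZE = 8


@dataclass(frozen=True)
class ArchitectureSpec:
    """The shallow-CNN layer plan for a given input side."""

    input_side: int
    in_channels: int = 3
    conv_filters: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 3
    conv_stride: int = 1
    fc_widths: tuple[int, ...] = (128, 128)
    n_classes: int = 2
    dropout_rate: float = 0.2
    convs_per_block: int = 1

    def validate(self) -> None:
        if self.input_side < 8:
            raise ValueError(f"input_side must be >= 8, got {self.input_side}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.convs_per_block not in (1, 2):
            raise ValueError(f"convs_per_block must be 1 or 2, got {self.convs_per_block}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, cross-entropy)."""

    batch_size: int = 32
    learning_rate: float = 0.001
    epochs: int = 50
    dropout_rate: float = 0.2
    seed: int = 0
    augmentation: bool = True
    validation_frac: float = 0.1

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if not 0 <= self.validation_frac < 0.5:
            raise ValueError(f"validation_frac must be in [0, 0.5), got {self.validation_frac}")


@dataclass
class LayerInfo:
    name: str
    out_shape: tuple  # (H, W, C) or (length,)
    weights: int  # kernel/matrix parameters, biases excluded
    biases: int


def build_architecture(spec: ArchitectureSpec) -> list[LayerInfo]:
    """Propagate shapes through the plan and census the parameters.

    Valid 3x3 convolutions shrink the side by 2; 2x2 stride-2 pooling
    floors the halved side.  Raises if any block would leave a
    non-positive side.
    """
    spec.validate()
    plan = [LayerInfo("input", (spec.input_side, spec.input_side, spec.in_channels), 0, 0)]
    side = spec.input_side
    cin = spec.in_channels
    k = spec.kernel
    li = 1
    for bi, f in enumerate(spec.conv_filters):
        for _ in range(spec.convs_per_block):
            side = (side - (k - 1)) // spec.conv_stride
            if side < 1:
                raise ValueError(
                    f"input too small: conv block {bi + 1} leaves spatial side {side}"
                )
            plan.append(LayerInfo(f"{li}. Conv", (side, side, f), k * k * cin * f, f))
            cin = f
            li += 1
        side = side // 2
        if side < 1:
            raise ValueError(f"input too small: pool of block {bi + 1} leaves side {side}")
        plan.append(LayerInfo(f"{li}. Max-pool", (side, side, cin), 0, 0))
        li += 1
    flat = side * side * cin
    plan.append(LayerInfo(f"{li}. Concat", (flat,), 0, 0))
    li += 1
    win = flat
    for w in spec.fc_widths:
        plan.append(LayerInfo(f"{li}. Full", (w,), win * w, w))
        win = w
        li += 1
    plan.append(LayerInfo(f"{li}. Softmax", (spec.n_classes,), win * spec.n_classes, spec.n_classes))
    return plan


def apply_dihedral(arr: np.ndarray, k: int) -> np.ndarray:
    """Element k (0..7) of the square's symmetry group applied to axes (0, 1).

    0..3 are rotations by 0/90/180/270 degrees; 4..7 are the
    horizontal flip composed with those rotations.
    """
    if not 0 <= k < 8:
        raise ValueError(f"dihedral index must be in 0..7, got {k}")
    a = np.asarray(arr)
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"rotations need a square input, got shape {a.shape[:2]}")
    if k >= 4:
        a = a[:, ::-1]  # horizontal flip (columns reversed)
    return np.rot90(a, k % 4, axes=(0, 1))


def augment(sample: np.ndarray, seed_or_rng) -> np.ndarray:
    """A seeded uniform draw from the 8 label-preserving symmetries."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    k = int(rng.integers(0, DIHEDRAL_SIZE))
    return np.ascontiguousarray(apply_dihedral(sample, k))


@dataclass
class TrainedPhase:
    """Model artifact plus training provenance and per-epoch curves."""

    model: ShallowCNN
    curves: dict[str, list[float]]  # train_loss, train_acc, val_loss, val_acc
    spec: ArchitectureSpec
    cfg: TrainConfig
    seed: int

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities ordered (NDR, DR); rows sum to 1."""
        return self.model.predict_proba(x)


def _to_index_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        return np.asarray([CLASS_ORDER.index(str(v)) for v in arr], dtype=np.int64)
    return arr.astype(np.int64)


def _stratified_split(y: np.ndarray, frac: float, rng: np.random.Generator):
    val_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(frac * idx.size))) if frac > 0 and idx.size > 1 else 0
        val_idx.extend(idx[:n_val].tolist())
    val = np.asarray(sorted(val_idx), dtype=np.int64)
    train = np.setdiff1d(np.arange(y.size), val)
    return train, val


def train_phase(
    images: np.ndarray,
    labels,
    spec: ArchitectureSpec | None = None,
    cfg: TrainConfig | None = None,
) -> TrainedPhase:
    """Train one phase CNN on (N, H, W, 3) composites.

    A stratified ``validation_frac`` split is held out to track
    per-epoch validation loss/accuracy; augmentation (when enabled)
    re-draws a dihedral transform for every training sample every
    epoch.  Fully deterministic for a fixed config seed.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    x = np.asarray(images, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError(f"expected (N, H, W, C) images, got shape {x.shape}")
    y = _to_index_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    if spec is None:
        spec = ArchitectureSpec(input_side=x.shape[1], in_channels=x.shape[3],
                                dropout_rate=cfg.dropout_rate)
    spec.validate()
    if x.shape[1] != spec.input_side or x.shape[2] != spec.input_side:
        raise ValueError(
            f"images are {x.shape[1]}x{x.shape[2]} but spec.input_side={spec.input_side}"
        )

    rng = np.random.default_rng(cfg.seed)
    model = ShallowCNN(
        input_side=spec.input_side,
        in_channels=spec.in_channels,
        conv_filters=spec.conv_filters,
        fc_widths=spec.fc_widths,
        n_classes=spec.n_classes,
        dropout_rate=cfg.dropout_rate,
        convs_per_block=spec.convs_per_block,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    tr_idx, va_idx = _stratified_split(y, cfg.validation_frac, rng)
    xtr, ytr = x[tr_idx], y[tr_idx]
    xva, yva = x[va_idx], y[va_idx]
    n_classes = spec.n_classes
    eye = np.eye(n_classes)

    curves: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    for _epoch in range(cfg.epochs):
        order = rng.permutation(xtr.shape[0])
        ep_loss, ep_correct, ep_n = 0.0, 0, 0
        for i in range(0, order.size, cfg.batch_size):
            bidx = order[i : i + cfg.batch_size]
            xb = xtr[bidx]
            if cfg.augmentation:
                xb = np.stack([augment(im, rng) for im in xb])
            yb = eye[ytr[bidx]]
            probs, cache = model.forward(xb, train=True, rng=rng)
            loss = cross_entropy_loss(yb, probs)
            grads = model.backward(probs, yb, cache)
            model.adam_step(grads, lr=cfg.learning_rate)
            ep_loss += loss * bidx.size
            ep_correct += int((probs.argmax(axis=1) == ytr[bidx]).sum())
            ep_n += bidx.size
        curves["train_loss"].append(ep_loss / ep_n)
        curves["train_acc"].append(ep_correct / ep_n)
        if va_idx.size:
            pv = model.predict_proba(xva)
            curves["val_loss"].append(cross_entropy_loss(eye[yva], pv))
            curves["val_acc"].append(float((pv.argmax(axis=1) == yva).mean()))
        else:
            curves["val_loss"].append(float("nan"))
            curves["val_acc"].append(float("nan"))
    return TrainedPhase(model=model, curves=curves, spec=spec, cfg=cfg, seed=cfg.seed)
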