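"""Four-branch 1-D CNN classifying 200x3 sEMG segments into the four
occupational-therapy actions.

Architecture (per branch i of 4): a 32-filter valid convolution with
kernel lengths (20, 16, 12, 8) over the 200-sample axis (the 3-channel
width is preserved), non-overlapping max pooling of window 12, a
64-filter second convolution, a second non-overlapping pooling stage,
then the four branches are flattened and concatenated into 1728
features feeding two fully connected layers (with dropout) and 4
output nodes.

The published per-layer map sizes fix the second-stage wiring: the
second-convolution kernels must pair against the first-pool outputs in
reverse order (2 on 15 -> 14, 3 on 15 -> 13, 4 on 15 -> 12, 5 on
16 -> 12), and no assignment of the nominal second-pool windows
(5, 4, 3, 2) reproduces the published output lengths (2, 2, 2, 3), so
the shipped default derives the windows (7, 6, 6, 4) from those output
lengths and :func:`compute_feature_shapes` records the discrepancy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from otassess import _nn

__all__ = [
    "ArchitectureSpec",
    "ShapeTable",
    "LabeledSegment",
    "EvalReport",
    "compute_feature_shapes",
    "build_model",
    "FourBranchCNN",
    "split_dataset",
    "train_classifier",
    "evaluate",
]

ACTION_IDS = (1, 2, 3, 4)

# map sizes as published, used for the discrepancy audit
_PUBLISHED = {
    "conv1": (181, 185, 189, 193),
    "pool1": (15, 15, 15, 16),
    "conv2": (14, 13, 12, 12),
    "pool2": (2, 2, 2, 3),
    "flatten": (384, 384, 384, 576),
    "total": 1728,
    "pool2_windows_nominal": (5, 4, 3, 2),
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the four-branch CNN."""

    input_len: int = 200
    input_channels: int = 3
    n_branches: int = 4
    conv1_filters: int = 32
    conv1_kernels: tuple[int, ...] = (20, 16, 12, 8)
    pool1_window: int = 12
    conv2_filters: int = 64
    # per-branch second-convolution kernels; the published kernel set
    # (5, 4, 3, 2) paired in reverse order against the branches
    conv2_kernels: tuple[int, ...] = (2, 3, 4, 5)
    # None -> derive windows from pool2_targets
    pool2_windows: tuple[int, ...] | None = None
    pool2_targets: tuple[int, ...] = (2, 2, 2, 3)
    fc_hidden: int = 128
    n_classes: int = 4

    def __post_init__(self) -> None:
        if len(self.conv1_kernels) != self.n_branches:
            raise ValueError("need one conv1 kernel per branch")
        if len(self.conv2_kernels) != self.n_branches:
            raise ValueError("need one conv2 kernel per branch")
        for name in ("conv1_kernels", "conv2_kernels"):
            if any(k < 1 for k in getattr(self, name)):
                raise ValueError(f"{name} must all be >= 1")
        if self.pool1_window < 1:
            raise ValueError("pool1_window must be >= 1")


@dataclass
class ShapeTable:
    """Per-branch, per-layer feature-map lengths and flattened totals."""

    conv1_len: tuple[int, ...]
    pool1_len: tuple[int, ...]
    conv2_len: tuple[int, ...]
    pool2_window: tuple[int, ...]
    pool2_len: tuple[int, ...]
    flat_per_branch: tuple[int, ...]
    total_flat: int
    discrepancies: list[str] = field(default_factory=list)


def compute_feature_shapes(spec: ArchitectureSpec) -> ShapeTable:
    """Propagate shape arithmetic through the four branches.

    Valid convolutions (``out = in - kernel + 1``), non-overlapping
    pooling (``out = in // window``), per-branch flattening of
    ``filters x length x channels``.  Any disagreement with the
    published map sizes or nominal pooling windows is recorded in
    ``discrepancies`` rather than silently forced.
    """
    conv1, pool1, conv2, windows, pool2, flat = [], [], [], [], [], []
    for i in range(spec.n_branches):
        k1 = spec.conv1_kernels[i]
        if k1 > spec.input_len:
            raise ValueError(
                f"conv1 branch {i}: kernel {k1} exceeds input length {spec.input_len}"
            )
        c1 = spec.input_len - k1 + 1
        p1 = c1 // spec.pool1_window
        if p1 < 1:
            raise ValueError(
                f"pool1 branch {i}: window {spec.pool1_window} exceeds map length {c1}"
            )
        k2 = spec.conv2_kernels[i]
        if k2 > p1:
            raise ValueError(
                f"conv2 branch {i}: kernel {k2} exceeds map length {p1}"
            )
        c2 = p1 - k2 + 1
        if spec.pool2_windows is not None:
            w = spec.pool2_windows[i]
        else:
            w = max(1, c2 // spec.pool2_targets[i])
        p2 = c2 // w
        if p2 < 1:
            raise ValueError(
                f"pool2 branch {i}: window {w} exceeds map length {c2}"
            )
        conv1.append(c1)
        pool1.append(p1)
        conv2.append(c2)
        windows.append(w)
        pool2.append(p2)
        flat.append(spec.conv2_filters * p2 * spec.input_channels)

    table = ShapeTable(
        conv1_len=tuple(conv1),
        pool1_len=tuple(pool1),
        conv2_len=tuple(conv2),
        pool2_window=tuple(windows),
        pool2_len=tuple(pool2),
        flat_per_branch=tuple(flat),
        total_flat=int(sum(flat)),
    )
    for layer in ("conv1", "pool1", "conv2", "pool2", "flatten"):
        got = {
            "conv1": table.conv1_len,
            "pool1": table.pool1_len,
            "conv2": table.conv2_len,
            "pool2": table.pool2_len,
            "flatten": table.flat_per_branch,
        }[layer]
        if got != _PUBLISHED[layer]:
            table.discrepancies.append(
                f"{layer}: computed {got} != published {_PUBLISHED[layer]}"
            )
    if table.pool2_window != _PUBLISHED["pool2_windows_nominal"]:
        table.discrepancies.append(
            "pool2 windows: nominal "
            f"{_PUBLISHED['pool2_windows_nominal']} cannot produce the "
            f"published output lengths {_PUBLISHED['pool2']}; using derived "
            f"windows {table.pool2_window}"
        )
    return table


class FourBranchCNN:
    """Numpy implementation of the four-branch CNN with manual backprop.

    The 3-channel width axis is folded into the batch so every
    convolution is a plain 1-D valid convolution along the 200-sample
    axis, matching the ``k x 1`` kernel geometry.
    """

    def __init__(self, spec: ArchitectureSpec, dropout_p: float = 0.5, seed: int = 0):
        self.spec = spec
        self.shapes = compute_feature_shapes(spec)
        self.dropout_p = dropout_p
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        for i in range(spec.n_branches):
            k1 = spec.conv1_kernels[i]
            p[f"W1_{i}"] = _nn.he_init(rng, (spec.conv1_filters, 1, k1), k1)
            p[f"b1_{i}"] = np.zeros(spec.conv1_filters)
            k2 = spec.conv2_kernels[i]
            fan2 = spec.conv1_filters * k2
            p[f"W2_{i}"] = _nn.he_init(
                rng, (spec.conv2_filters, spec.conv1_filters, k2), fan2
            )
            p[f"b2_{i}"] = np.zeros(spec.conv2_filters)
        total = self.shapes.total_flat
        p["Wf1"] = _nn.he_init(rng, (total, spec.fc_hidden), total)
        p["bf1"] = np.zeros(spec.fc_hidden)
        p["Wf2"] = _nn.he_init(rng, (spec.fc_hidden, spec.n_classes), spec.fc_hidden)
        p["bf2"] = np.zeros(spec.n_classes)
        self.params = p
        self._cache = None

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """x: (B, input_len, channels) -> logits (B, n_classes)."""
        spec = self.spec
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        B, L, C = x.shape
        if (L, C) != (spec.input_len, spec.input_channels):
            raise ValueError(
                f"expected input ({spec.input_len}, {spec.input_channels}), got ({L}, {C})"
            )
        if train and rng is None:
            rng = np.random.default_rng(0)
        # fold channel width into the batch: (B*C, 1, L)
        h0 = x.transpose(0, 2, 1).reshape(B * C, 1, L)
        branch_caches = []
        flats = []
        for i in range(spec.n_branches):
            c1, cc1 = _nn.conv1d_forward(h0, self.params[f"W1_{i}"], self.params[f"b1_{i}"])
            r1, m1 = _nn.relu_forward(c1)
            p1, cp1 = _nn.maxpool_forward(r1, spec.pool1_window)
            c2, cc2 = _nn.conv1d_forward(p1, self.params[f"W2_{i}"], self.params[f"b2_{i}"])
            r2, m2 = _nn.relu_forward(c2)
            p2, cp2 = _nn.maxpool_forward(r2, self.shapes.pool2_window[i])
            flats.append(p2.reshape(B, -1))
            branch_caches.append((cc1, m1, cp1, cc2, m2, cp2, p2.shape))
        flat = np.concatenate(flats, axis=1)
        d0, md0 = _nn.dropout_forward(flat, self.dropout_p, train, rng)
        f1, cf1 = _nn.linear_forward(d0, self.params["Wf1"], self.params["bf1"])
        rf1, mf1 = _nn.relu_forward(f1)
        d1, md1 = _nn.dropout_forward(rf1, self.dropout_p, train, rng)
        logits, cf2 = _nn.linear_forward(d1, self.params["Wf2"], self.params["bf2"])
        self._cache = (B, C, branch_caches, md0, cf1, mf1, md1, cf2)
        return logits

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        B, C, branch_caches, md0, cf1, mf1, md1, cf2 = self._cache
        grads: dict[str, np.ndarray] = {}
        dd1, grads["Wf2"], grads["bf2"] = _nn.linear_backward(dlogits, cf2)
        if md1 is not None:
            dd1 = dd1 * md1
        df1 = _nn.relu_backward(dd1, mf1)
        dflat, grads["Wf1"], grads["bf1"] = _nn.linear_backward(df1, cf1)
        if md0 is not None:
            dflat = dflat * md0
        offset = 0
        for i, cache in enumerate(branch_caches):
            cc1, m1, cp1, cc2, m2, cp2, p2_shape = cache
            size = self.shapes.flat_per_branch[i]
            dp2 = dflat[:, offset : offset + size].reshape(p2_shape)
            offset += size
            dr2 = _nn.maxpool_backward(dp2, cp2)
            dc2 = _nn.relu_backward(dr2, m2)
            dp1, grads[f"W2_{i}"], grads[f"b2_{i}"] = _nn.conv1d_backward(dc2, cc2)
            dr1 = _nn.maxpool_backward(dp1, cp1)
            dc1 = _nn.relu_backward(dr1, m1)
            _, grads[f"W1_{i}"], grads[f"b1_{i}"] = _nn.conv1d_backward(dc1, cc1)
        return grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted action ids (1-4) for a batch of segments."""
        logits = self.forward(x, train=False)
        return logits.argmax(axis=1) + 1

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = json.dumps({"spec": asdict(self.spec), "dropout_p": self.dropout_p})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "FourBranchCNN":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_d = meta["spec"]
        for key in ("conv1_kernels", "conv2_kernels", "pool2_targets"):
            spec_d[key] = tuple(spec_d[key])
        if spec_d.get("pool2_windows") is not None:
            spec_d["pool2_windows"] = tuple(spec_d["pool2_windows"])
        model = cls(ArchitectureSpec(**spec_d), dropout_p=meta["dropout_p"], seed=0)
        for k in model.params:
            model.params[k] = data[k]
        return model


def build_model(
    spec: ArchitectureSpec | None = None,
    dropout_p: float = 0.5,
    seed: int = 0,
) -> FourBranchCNN:
    """Initialize a four-branch CNN (deterministic under ``seed``)."""
    return FourBranchCNN(spec or ArchitectureSpec(), dropout_p=dropout_p, seed=seed)


@dataclass
class LabeledSegment:
    """A fixed-length classifier input with its action label."""

    matrix: np.ndarray  # (200, 3)
    label: int  # action id 1-4
    participant_id: int = -1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.label not in ACTION_IDS:
            raise ValueError(f"label must be in {ACTION_IDS}")


@dataclass
class EvalReport:
    """Test-set evaluation: overall accuracy, 4x4 confusion counts
    (rows = true class 0-3 for actions 1-4, columns = predicted), and
    per-class accuracies."""

    accuracy: float
    confusion: np.ndarray
    per_class_accuracy: np.ndarray


def _labels_of(data) -> np.ndarray:
    if hasattr(data[0], "label"):
        return np.array([d.label for d in data])
    return np.asarray(data)


def split_dataset(
    data,
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified, reproducible train/test index split.

    ``data`` is a sequence of :class:`LabeledSegment` or an array of
    action-id labels.  The test set holds ``floor(n * (1-train_frac))``
    items, allocated across classes by largest remainder so stratification
    is as exact as integer counts allow.  Returns (train_idx, test_idx):
    disjoint, exhaustive.
    """
    labels = _labels_of(data)
    n = labels.size
    if n < 4:
        raise ValueError("need at least 4 items")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    for a in ACTION_IDS:
        if not np.any(labels == a):
            raise ValueError(f"class {a} absent from dataset")
    rng = np.random.default_rng(seed)
    test_frac = 1.0 - train_frac
    # epsilon guards against 1 - 0.8 = 0.19999... dropping a whole item
    n_test = int(np.floor(n * test_frac + 1e-9))
    classes = sorted(np.unique(labels))
    exact = {c: np.sum(labels == c) * test_frac for c in classes}
    base = {c: int(np.floor(exact[c] + 1e-9)) for c in classes}
    remainder = n_test - sum(base.values())
    order = sorted(classes, key=lambda c: (-(exact[c] - base[c]), c))
    for c in order[:remainder]:
        base[c] += 1
    test_idx = []
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        perm = rng.permutation(idx.size)
        test_idx.append(idx[perm[: base[c]]])
    test_idx = np.sort(np.concatenate(test_idx))
    mask = np.ones(n, dtype=bool)
    mask[test_idx] = False
    train_idx = np.nonzero(mask)[0]
    return train_idx, test_idx


def train_classifier(
    model: FourBranchCNN,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 40,
    lr: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> list[dict]:
    """Train with Adam on softmax cross-entropy; returns the per-epoch
    history (loss and training accuracy).  ``y`` holds action ids 1-4.
    Deterministic under a fixed seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    targets = y - 1
    for a in ACTION_IDS:
        if not np.any(y == a):
            raise ValueError(f"class {a} absent from training set")
    rng = np.random.default_rng(seed)
    opt = _nn.Adam(model.params, lr=lr)
    history = []
    n = X.shape[0]
    for epoch in range(epochs):
        perm = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, batch_size):
            sel = perm[start : start + batch_size]
            logits = model.forward(X[sel], train=True, rng=rng)
            loss, dlogits = _nn.softmax_cross_entropy(logits, targets[sel])
            grads = model.backward(dlogits)
            opt.step(grads)
            losses.append(loss * sel.size)
            correct += int((logits.argmax(axis=1) == targets[sel]).sum())
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.sum(losses) / n),
                "train_accuracy": correct / n,
            }
        )
    return history


def evaluate(model: FourBranchCNN, X: np.ndarray, y: np.ndarray) -> EvalReport:
    """Evaluate on a held-out set; ``y`` holds action ids 1-4."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    pred = model.predict(X)
    k = model.spec.n_classes
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y - 1, pred - 1):
        confusion[t, p] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion)) / total
    row = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, np.diag(confusion) / row, np.nan)
    return EvalReport(accuracy=accuracy, confusion=confusion, per_class_accuracy=per_class)
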