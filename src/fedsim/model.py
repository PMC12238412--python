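"""Miniature trainable segmentation model (the collaborator computation).

The federated simulator needs a segmentation model that is (a) small
enough that whole federations train in minutes on one CPU, (b) exposes
its parameters as a flat vector so aggregation algorithms can combine
them, and (c) is bitwise reproducible.  This module provides a tiny
two-level encoder–decoder with residual connections, written directly
in numpy with analytic gradients (verified against finite differences
in the test suite):

    conv3(4→w) → ReLU → residual conv3(w→w) → mean-pool ↓2
        → conv3(w→2w) → ReLU → nearest-upsample ↑2
        → conv3(2w→w) → ReLU → (+ skip) → conv1(w→K logits)

The per-voxel output covers the four tissue classes (background, NCR,
ED, ET), and the local loss is the field's dominant combination:
cross-entropy plus soft Dice, weighted 1:1.  Local training is plain
SGD (no momentum by default), with batch order seeded per
(client, round) so simulations are exactly repeatable across
aggregators.

A :class:`PerfectOracleModel` that simply returns the reference labels
is provided so that metric and ranking code can be exercised without
any training.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .metrics import LabelMap, mean_region_dsc
from .phantoms import Case, ClientDataset

__all__ = [
    "ModelParameters",
    "LocalTrainConfig",
    "LocalMetrics",
    "TinySegNet",
    "PerfectOracleModel",
    "build_model",
    "local_train",
    "local_validate",
    "save_params",
    "load_params",
]

_CLASS_TO_LABEL = np.array([0, 1, 2, 4], dtype=np.int16)
_LABEL_TO_CLASS = {0: 0, 1: 1, 2: 2, 4: 3}
_DICE_EPS = 1e-7


@dataclass(frozen=True)
class ModelParameters:
    """Flat real vector view of a trainable model.

    ``values`` folds into model tensors according to ``layout``, an
    ordered list of ``(tensor_name, shape)`` pairs identical across all
    clients and rounds — any two vectors from the same build config can
    be combined linearly and folded back losslessly.
    """

    values: np.ndarray
    layout: tuple[tuple[str, tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        expected = sum(int(np.prod(shape)) for _, shape in self.layout)
        if values.ndim != 1 or values.size != expected:
            raise ValueError(
                f"parameter vector length {values.size} does not match layout "
                f"total {expected}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self,
            "layout",
            tuple((str(n), tuple(int(d) for d in s)) for n, s in self.layout),
        )

    def unpack(self) -> dict[str, np.ndarray]:
        """Fold the flat vector into named tensors (views are copies)."""
        tensors = {}
        offset = 0
        for name, shape in self.layout:
            size = int(np.prod(shape))
            tensors[name] = self.values[offset : offset + size].reshape(shape).copy()
            offset += size
        return tensors

    @staticmethod
    def pack(
        tensors: dict[str, np.ndarray],
        layout: Sequence[tuple[str, tuple[int, ...]]],
    ) -> "ModelParameters":
        values = np.concatenate([np.asarray(tensors[n], dtype=np.float64).ravel() for n, _ in layout])
        return ModelParameters(values=values, layout=tuple(layout))


@dataclass(frozen=True)
class LocalTrainConfig:
    """Hyperparameters of one client's local training in one round."""

    learning_rate: float = 0.05
    epochs_per_round: int = 1
    batch_size: int = 8
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs_per_round < 1 or self.batch_size < 1:
            raise ValueError("epochs_per_round and batch_size must be >= 1")


@dataclass(frozen=True)
class LocalMetrics:
    """Per-client metrics reported to the aggregation server."""

    val_dsc: float
    val_loss: float
    train_dsc: float
    n_train: int
    n_val: int

    def __post_init__(self) -> None:
        if np.isfinite(self.val_dsc) and not 0.0 <= self.val_dsc <= 1.0:
            raise ValueError("val_dsc must lie in [0, 1]")
        if np.isfinite(self.train_dsc) and not 0.0 <= self.train_dsc <= 1.0:
            raise ValueError("train_dsc must lie in [0, 1]")


# ---------------------------------------------------------------------------
# numpy conv-net primitives (dimension-agnostic: 2-D or 3-D grids)
# ---------------------------------------------------------------------------


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded convolution with a 3^d kernel; x is (N, C, *grid)."""
    nd = x.ndim - 2
    pad = [(0, 0), (0, 0)] + [(1, 1)] * nd
    xp = np.pad(x, pad)
    grid = x.shape[2:]
    out = np.empty((x.shape[0], w.shape[0]) + grid, dtype=np.float64)
    out[:] = b.reshape((1, -1) + (1,) * nd)
    for off in np.ndindex(*w.shape[2:]):
        sl = tuple(slice(o, o + g) for o, g in zip(off, grid))
        out += np.einsum(
            "oc,nc...->no...", w[(slice(None), slice(None)) + off], xp[(slice(None), slice(None)) + sl],
            optimize=True,
        )
    return out


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-padded 3^d convolution wrt input, weight, bias."""
    nd = x.ndim - 2
    pad = [(0, 0), (0, 0)] + [(1, 1)] * nd
    xp = np.pad(x, pad)
    grid = x.shape[2:]
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for off in np.ndindex(*w.shape[2:]):
        sl = tuple(slice(o, o + g) for o, g in zip(off, grid))
        widx = (slice(None), slice(None)) + off
        xidx = (slice(None), slice(None)) + sl
        dw[widx] = np.einsum("no...,nc...->oc", dout, xp[xidx], optimize=True)
        dxp[xidx] += np.einsum("oc,no...->nc...", w[widx], dout, optimize=True)
    core = (slice(None), slice(None)) + tuple(slice(1, 1 + g) for g in grid)
    db = dout.sum(axis=(0,) + tuple(range(2, dout.ndim)))
    return dxp[core], dw, db


def _pool2(x: np.ndarray) -> np.ndarray:
    """Mean-pool by 2 along every spatial axis."""
    nd = x.ndim - 2
    for ax in range(2, 2 + nd):
        shape = x.shape
        new = shape[:ax] + (shape[ax] // 2, 2) + shape[ax + 1 :]
        x = x.reshape(new).mean(axis=ax + 1)
    return x


def _pool2_backward(dout: np.ndarray, nd: int) -> np.ndarray:
    for ax in range(2, 2 + nd):
        dout = np.repeat(dout, 2, axis=ax)
    return dout / (2**nd)


def _upsample2(x: np.ndarray, nd: int) -> np.ndarray:
    for ax in range(2, 2 + nd):
        x = np.repeat(x, 2, axis=ax)
    return x


def _upsample2_backward(dout: np.ndarray, nd: int) -> np.ndarray:
    for ax in range(2, 2 + nd):
        shape = dout.shape
        new = shape[:ax] + (shape[ax] // 2, 2) + shape[ax + 1 :]
        dout = dout.reshape(new).sum(axis=ax + 1)
    return dout


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TinySegNet:
    """Two-level residual encoder–decoder for phantom segmentation.

    Parameters
    ----------
    in_channels
        Image channels (4 for the simulated MRI sequences).
    width
        Base feature width ``w``; the bottleneck uses ``2w``.
    n_classes
        Output classes (4: background, NCR, ED, ET).
    ndim
        Spatial dimensionality of the inputs (2 or 3).
    """

    def __init__(self, in_channels: int = 4, width: int = 8, n_classes: int = 4, ndim: int = 2):
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if width < 1 or in_channels < 1:
            raise ValueError("width and in_channels must be >= 1")
        self.in_channels = in_channels
        self.width = width
        self.n_classes = n_classes
        self.ndim = ndim
        k = (3,) * ndim
        w = width
        self.layout: tuple[tuple[str, tuple[int, ...]], ...] = (
            ("conv1_w", (w, in_channels) + k),
            ("conv1_b", (w,)),
            ("res1_w", (w, w) + k),
            ("res1_b", (w,)),
            ("conv2_w", (2 * w, w) + k),
            ("conv2_b", (2 * w,)),
            ("conv3_w", (w, 2 * w) + k),
            ("conv3_b", (w,)),
            ("head_w", (n_classes, w)),
            ("head_b", (n_classes,)),
        )

    # -- parameters ---------------------------------------------------------

    def init_params(self, seed: int = 0) -> ModelParameters:
        """Deterministic He-style initialization for a fixed seed."""
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 0x1417]))
        tensors = {}
        for name, shape in self.layout:
            if name.endswith("_b"):
                tensors[name] = np.zeros(shape)
            else:
                fan_in = int(np.prod(shape[1:]))
                tensors[name] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        return ModelParameters.pack(tensors, self.layout)

    def check_geometry(self, grid: tuple[int, ...]) -> None:
        if len(grid) != self.ndim:
            raise ValueError(
                f"model is {self.ndim}-D but input grid is {len(grid)}-D"
            )
        if any(g % 2 or g < 4 for g in grid):
            raise ValueError(
                f"incompatible geometry {grid}: spatial dims must be even and >= 4"
            )

    # -- forward / backward -------------------------------------------------

    def forward(self, tensors: dict[str, np.ndarray], x: np.ndarray):
        """Compute per-voxel class logits; returns (logits, cache)."""
        self.check_geometry(x.shape[2:])
        nd = self.ndim
        a1 = _conv_forward(x, tensors["conv1_w"], tensors["conv1_b"])
        r1 = np.maximum(a1, 0.0)
        a2 = _conv_forward(r1, tensors["res1_w"], tensors["res1_b"])
        r2 = np.maximum(a2, 0.0)
        h1 = r2 + r1  # residual block output / skip source
        p = _pool2(h1)
        a3 = _conv_forward(p, tensors["conv2_w"], tensors["conv2_b"])
        r3 = np.maximum(a3, 0.0)
        u = _upsample2(r3, nd)
        a4 = _conv_forward(u, tensors["conv3_w"], tensors["conv3_b"])
        r4 = np.maximum(a4, 0.0)
        s = r4 + h1  # decoder + encoder skip
        logits = np.einsum("kc,nc...->nk...", tensors["head_w"], s, optimize=True)
        logits += tensors["head_b"].reshape((1, -1) + (1,) * nd)
        cache = (x, a1, r1, a2, r1, h1, p, a3, u, a4, s)
        return logits, cache

    def backward(self, tensors, cache, dlogits) -> dict[str, np.ndarray]:
        x, a1, r1, a2, _, h1, p, a3, u, a4, s = cache
        nd = self.ndim
        grads: dict[str, np.ndarray] = {}
        grads["head_w"] = np.einsum("nk...,nc...->kc", dlogits, s, optimize=True)
        grads["head_b"] = dlogits.sum(axis=(0,) + tuple(range(2, dlogits.ndim)))
        ds = np.einsum("kc,nk...->nc...", tensors["head_w"], dlogits, optimize=True)
        # skip: s = r4 + h1
        dr4 = ds
        dh1_skip = ds
        da4 = dr4 * (a4 > 0)
        du, grads["conv3_w"], grads["conv3_b"] = _conv_backward(u, tensors["conv3_w"], da4)
        dr3 = _upsample2_backward(du, nd)
        da3 = dr3 * (a3 > 0)
        dp, grads["conv2_w"], grads["conv2_b"] = _conv_backward(p, tensors["conv2_w"], da3)
        dh1 = _pool2_backward(dp, nd) + dh1_skip
        # residual block: h1 = relu(a2) + r1
        da2 = dh1 * (a2 > 0)
        dr1_res, grads["res1_w"], grads["res1_b"] = _conv_backward(r1, tensors["res1_w"], da2)
        dr1 = dr1_res + dh1
        da1 = dr1 * (a1 > 0)
        _, grads["conv1_w"], grads["conv1_b"] = _conv_backward(x, tensors["conv1_w"], da1)
        return grads

    # -- loss ---------------------------------------------------------------

    def loss_and_grad(self, logits: np.ndarray, classes: np.ndarray):
        """Cross-entropy + soft-Dice loss (1:1) and its logit gradient.

        ``classes`` holds class indices 0..3 with shape (N, *grid).  The
        cross-entropy is averaged over voxels; the soft Dice is computed
        per foreground class over the whole batch and averaged over the
        three foreground classes.
        """
        n_classes = logits.shape[1]
        probs = _softmax(logits)
        onehot = np.moveaxis(np.eye(n_classes)[classes], -1, 1)
        n_vox = classes.size
        p_true = np.take_along_axis(probs, classes[:, None], axis=1)
        ce = float(-np.log(np.clip(p_true, 1e-12, None)).mean())
        dlogits_ce = (probs - onehot) / n_vox

        # soft Dice over foreground classes, batch-global sums
        sum_axes = (0,) + tuple(range(2, logits.ndim))
        inter = (probs * onehot).sum(axis=sum_axes)
        psum = probs.sum(axis=sum_axes)
        gsum = onehot.sum(axis=sum_axes)
        num = 2.0 * inter + _DICE_EPS
        den = psum + gsum + _DICE_EPS
        fg = slice(1, None)
        n_fg = n_classes - 1
        dice = float((num[fg] / den[fg]).mean())
        dice_loss = 1.0 - dice
        # d(dice)/dp_c = (2 g - num/den) / den for foreground classes
        dnum = np.zeros(n_classes)
        dnum[1:] = 1.0
        shape = (1, n_classes) + (1,) * (logits.ndim - 2)
        ddice_dp = (
            dnum.reshape(shape)
            * (2.0 * onehot * den.reshape(shape) - num.reshape(shape))
            / (den.reshape(shape) ** 2)
        ) / n_fg
        dloss_dp = -ddice_dp
        inner = (dloss_dp * probs).sum(axis=1, keepdims=True)
        dlogits_dice = probs * (dloss_dp - inner)

        return ce + dice_loss, dlogits_ce + dlogits_dice

    def batch_loss(self, params: ModelParameters, cases: Sequence[Case]) -> float:
        tensors = params.unpack()
        x, classes = _stack_cases(cases)
        logits, _ = self.forward(tensors, x)
        loss, _ = self.loss_and_grad(logits, classes)
        return float(loss)

    # -- prediction ---------------------------------------------------------

    def predict_batch(self, params: ModelParameters, images: np.ndarray) -> np.ndarray:
        """Predicted label maps (BraTS values) for a stack of images."""
        tensors = params.unpack()
        logits, _ = self.forward(tensors, images)
        return _CLASS_TO_LABEL[np.argmax(logits, axis=1)]

    def predict_case(self, params: ModelParameters, case: Case) -> LabelMap:
        labels = self.predict_batch(params, case.image[None])[0]
        return LabelMap(values=labels, spacing=case.labels.spacing)


class PerfectOracleModel:
    """Stub model that returns the reference labels of each case.

    Used to exercise metric and ranking code without training; its
    validation DSC is exactly 1 and its loss 0 on any dataset.
    """

    layout: tuple = ()

    def predict_case(self, params, case: Case) -> LabelMap:
        return case.labels

    def batch_loss(self, params, cases) -> float:
        return 0.0


def _stack_cases(cases: Sequence[Case]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([c.image for c in cases])
    labels = np.stack([c.labels.values for c in cases])
    classes = np.zeros_like(labels, dtype=np.int64)
    for label, cls in _LABEL_TO_CLASS.items():
        classes[labels == label] = cls
    return x, classes


def build_model(
    in_channels: int = 4,
    width: int = 8,
    n_classes: int = 4,
    ndim: int = 2,
    seed: int = 0,
) -> tuple[TinySegNet, ModelParameters]:
    """Construct the reference model and its deterministic initialization."""
    model = TinySegNet(in_channels=in_channels, width=width, n_classes=n_classes, ndim=ndim)
    return model, model.init_params(seed=seed)


def _client_stream(site_id: str, seed: int) -> np.random.Generator:
    # batch order seeded per (client, round) for exact repeatability
    tag = zlib.crc32(site_id.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, tag, 0xB41C]))


def local_train(
    model: TinySegNet,
    params: ModelParameters,
    client: ClientDataset,
    cfg: LocalTrainConfig,
) -> tuple[ModelParameters, LocalMetrics]:
    """Run seeded local SGD on the client's training split.

    Performs ``epochs_per_round`` passes over the train split in
    shuffled mini-batches, minimizing cross-entropy + soft Dice.  The
    input parameters are never modified; with ``learning_rate=0`` the
    returned vector equals the input bitwise.  Returns the updated
    parameters and post-training metrics (training DSC on the train
    split, validation DSC/loss on the validation split).
    """
    if not client.train_cases:
        raise ValueError(f"client {client.site_id!r} has no training cases")
    tensors = params.unpack()
    velocity = {n: np.zeros_like(t) for n, t in tensors.items()} if cfg.momentum else None
    rng = _client_stream(client.site_id, cfg.seed)
    train_cases = client.train_cases
    n = len(train_cases)
    for _ in range(cfg.epochs_per_round):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = [train_cases[i] for i in order[start : start + cfg.batch_size]]
            x, classes = _stack_cases(batch)
            logits, cache = model.forward(tensors, x)
            if not np.all(np.isfinite(logits)):
                raise FloatingPointError(
                    f"non-finite activations during local training on client "
                    f"{client.site_id!r}"
                )
            _, dlogits = model.loss_and_grad(logits, classes)
            grads = model.backward(tensors, cache, dlogits)
            for name in tensors:
                if velocity is not None:
                    velocity[name] = cfg.momentum * velocity[name] + grads[name]
                    step = velocity[name]
                else:
                    step = grads[name]
                tensors[name] = tensors[name] - cfg.learning_rate * step
    new_params = ModelParameters.pack(tensors, model.layout)
    train_dsc = float(
        np.mean(
            [mean_region_dsc(model.predict_case(new_params, c), c.labels) for c in train_cases]
        )
    )
    val = local_validate(model, new_params, client)
    return new_params, LocalMetrics(
        val_dsc=val.val_dsc,
        val_loss=val.val_loss,
        train_dsc=train_dsc,
        n_train=client.n_train,
        n_val=client.n_val,
    )


def local_validate(model, params, client: ClientDataset) -> LocalMetrics:
    """Evaluate a model on the client's validation split (pure function).

    ``val_dsc`` is the mean over validation cases of the mean DSC over
    the WT/TC/ET regions; ``val_loss`` is the configured training loss
    (cross-entropy + soft Dice) on the same split.
    """
    if not client.val_cases:
        raise ValueError(f"client {client.site_id!r} has no validation cases")
    val_cases = client.val_cases
    val_dsc = float(
        np.mean(
            [mean_region_dsc(model.predict_case(params, c), c.labels) for c in val_cases]
        )
    )
    val_loss = float(model.batch_loss(params, val_cases))
    return LocalMetrics(
        val_dsc=val_dsc,
        val_loss=val_loss,
        train_dsc=float("nan"),
        n_train=client.n_train,
        n_val=client.n_val,
    )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_params(params: ModelParameters, path: str | Path) -> None:
    """Write a flat binary array plus a JSON layout sidecar."""
    path = Path(path)
    params.values.astype(np.float64).tofile(path)
    sidecar = path.with_suffix(path.suffix + ".layout.json")
    sidecar.write_text(
        json.dumps([[n, list(s)] for n, s in params.layout], indent=1)
    )


def load_params(path: str | Path) -> ModelParameters:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".layout.json")
    layout = tuple((n, tuple(s)) for n, s in json.loads(sidecar.read_text()))
    values = np.fromfile(path, dtype=np.float64)
    return ModelParameters(values=values, layout=layout)
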