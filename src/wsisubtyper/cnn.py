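"""Patch-level SCC-vs-AC classifier: a small CPU-trainable CNN plus Grad-CAM.

The built-in ``tinycnn`` backbone is a three-block convolutional network
(3x3 convolutions, ReLU, 2x2 max-pooling, global average pooling, linear
head) implemented directly on NumPy so the whole pipeline trains on a
single CPU core in seconds.  The optimization recipe follows the study
protocol: Adam, batch size 64, L2 regularization λ=0.001, initial
learning rate 1e-4 with per-epoch exponential decay, 50 epochs — every
knob is a :class:`TrainingConfig` field.  Larger named architectures
(AlexNet, VGG19, ResNet-50, Inception-v3) are registry names users can
bind to their own GPU implementations via :func:`register_backbone`;
they are not bundled.

Class convention: AC (adenocarcinoma, the minority subtype) is the
positive class; ``p_ac >= 0.5`` predicts AC (ties go to AC).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from skimage.transform import resize

from .slides import PatchCoord

__all__ = [
    "TrainingConfig", "PatchPrediction", "TinyCNN", "train_patch_model",
    "predict_patches", "select_backbone", "gradcam", "register_backbone",
    "load_model", "CLASSES",
]

CLASSES = ("SCC", "AC")  # index 0 / 1; AC is the positive class


@dataclass
class TrainingConfig:
    """Optimization recipe for patch-level training."""

    backbone: str = "tinycnn"
    batch_size: int = 64
    weight_decay: float = 0.001   # L2 regularization λ
    lr0: float = 0.0001
    lr_gamma: float = 0.95        # per-epoch exponential decay factor
    epochs: int = 50
    seed: int = 0
    class_weighting: bool = False
    input_size: int = 64          # patches are downscaled to this before the net

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0 < self.lr_gamma <= 1:
            raise ValueError("lr_gamma must lie in (0, 1]")


@dataclass
class PatchPrediction:
    """Per-patch output: AC probability plus the thresholded label."""

    p_ac: float
    label: str
    slide_id: Optional[str] = None
    coord: Optional[PatchCoord] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.p_ac):
            raise ValueError("p_ac must be finite")
        if self.label != ("AC" if self.p_ac >= 0.5 else "SCC"):
            raise ValueError("label inconsistent with p_ac and the 0.5 threshold")


# Fixed standardization constants on the [0, 1] intensity scale, roughly the
# global mean/spread of H&E tissue patches; centering keeps the first-layer
# activations well-scaled so short training runs converge reliably.
_INPUT_MEAN = 0.65
_INPUT_STD = 0.22


def _prepare(patches: Sequence[np.ndarray], input_size: int) -> np.ndarray:
    """Stack patches into a standardized float batch resized to the net input."""
    out = np.empty((len(patches), input_size, input_size, 3), dtype=np.float64)
    for i, p in enumerate(patches):
        p = np.asarray(p)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"patch {i}: expected HxWx3, got {p.shape}")
        if p.shape[0] != input_size:
            p = resize(p, (input_size, input_size), anti_aliasing=True,
                       preserve_range=True)
        out[i] = p
    return (out / 255.0 - _INPUT_MEAN) / _INPUT_STD


def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3 stride-1 same-padding patches: (N,H,W,C) -> (N,H,W,9C)."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (N,H,W,C,3,3) -> (N,H,W,3,3,C)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n, h, w, 9 * c)


def _col2im(dcols: np.ndarray, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter (N,H,W,9C) gradients back to (N,H,W,C)."""
    n, h, w, _ = dcols.shape
    d = dcols.reshape(n, h, w, 3, 3, c)
    dxp = np.zeros((n, h + 2, w + 2, c))
    for ki in range(3):
        for kj in range(3):
            dxp[:, ki:ki + h, kj:kj + w] += d[:, :, :, ki, kj]
    return dxp[:, 1:h + 1, 1:w + 1]


class TinyCNN:
    """Three conv blocks + global average pooling + linear head, pure NumPy.

    Channels 8/16/32; about 6k parameters.  Deterministic given its seed
    under single-threaded BLAS.
    """

    CHANNELS = (8, 16, 32)

    def __init__(self, input_size: int = 64, seed: int = 0):
        self.input_size = input_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 3
        for i, c_out in enumerate(self.CHANNELS):
            fan_in = 9 * c_in
            self.params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, c_out))
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        self.params["Wf"] = rng.normal(0, np.sqrt(1.0 / c_in), (c_in, 2))
        self.params["bf"] = np.zeros(2)

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits for a prepared batch; optionally returns the backprop cache."""
        cache = {"pool_args": [], "cols": [], "relu": [], "shapes": []}
        a = x
        for i in range(3):
            cols = _im2col(a)
            z = cols @ self.params[f"W{i}"] + self.params[f"b{i}"]
            r = np.maximum(z, 0.0)
            n, h, w, c = r.shape
            rp = r.reshape(n, h // 2, 2, w // 2, 2, c)
            flat = rp.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
            arg = flat.argmax(axis=-1)
            a = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
            if want_cache:
                cache["cols"].append(cols)
                cache["relu"].append(z > 0)
                cache["pool_args"].append(arg)
                cache["shapes"].append(r.shape)
        cache["conv_out"] = a  # final pooled conv activations (N,h,w,32)
        gap = a.mean(axis=(1, 2))
        cache["gap_in_shape"] = a.shape
        cache["gap"] = gap
        logits = gap @ self.params["Wf"] + self.params["bf"]
        return (logits, cache) if want_cache else logits

    # -- backward ----------------------------------------------------------
    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        grads["Wf"] = cache["gap"].T @ dlogits
        grads["bf"] = dlogits.sum(axis=0)
        dgap = dlogits @ self.params["Wf"].T
        n, h, w, c = cache["gap_in_shape"]
        da = np.broadcast_to(dgap[:, None, None, :] / (h * w), (n, h, w, c))
        for i in reversed(range(3)):
            rn, rh, rw, rc = cache["shapes"][i]
            arg = cache["pool_args"][i]
            dflat = np.zeros((rn, rh // 2, rw // 2, rc, 4))
            np.put_along_axis(dflat, arg[..., None], da[..., None], axis=-1)
            dr = dflat.reshape(rn, rh // 2, rw // 2, rc, 2, 2) \
                      .transpose(0, 1, 4, 2, 5, 3).reshape(rn, rh, rw, rc)
            dz = dr * cache["relu"][i]
            cols = cache["cols"][i]
            dz2 = dz.reshape(-1, rc)
            grads[f"W{i}"] = cols.reshape(-1, cols.shape[-1]).T @ dz2
            grads[f"b{i}"] = dz2.sum(axis=0)
            dcols = dz @ self.params[f"W{i}"].T
            da = _col2im(dcols, cols.shape[-1] // 9)
        return grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, columns ordered (SCC, AC)."""
        logits = self.forward(x)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- persistence -------------------------------------------------------
    def save(self, path, config: Optional[TrainingConfig] = None) -> None:
        meta = {"input_size": self.input_size, "seed": self.seed,
                "backbone": "tinycnn",
                "config": asdict(config) if config else None}
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "TinyCNN":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        model = cls(input_size=meta["input_size"], seed=meta["seed"])
        for k in model.params:
            model.params[k] = data[k]
        return model


_BACKBONES: dict[str, Callable[..., TinyCNN]] = {"tinycnn": TinyCNN}
_UNBUNDLED = ("alexnet", "vgg19", "resnet50", "inception_v3")


def register_backbone(name: str, factory: Callable) -> None:
    """Bind a backbone name to a factory ``(input_size, seed) -> model``.

    The model must expose ``forward/backward/predict_proba/params`` like
    :class:`TinyCNN`.
    """
    _BACKBONES[name] = factory


def _make_backbone(cfg: TrainingConfig):
    if cfg.backbone in _BACKBONES:
        return _BACKBONES[cfg.backbone](input_size=cfg.input_size, seed=cfg.seed)
    if cfg.backbone in _UNBUNDLED:
        raise NotImplementedError(
            f"backbone {cfg.backbone!r} is a GPU-scale architecture and is not "
            f"bundled; bind an implementation with register_backbone()"
        )
    raise ValueError(f"unknown backbone {cfg.backbone!r}")


def train_patch_model(patches: Sequence[np.ndarray], labels: Sequence[str],
                      cfg: Optional[TrainingConfig] = None,
                      verbose: bool = False):
    """Train a patch classifier with Adam + L2 and exponential LR decay.

    ``labels`` are "SCC"/"AC" strings.  Returns the trained model, which
    records its loss trajectory in ``model.loss_history``.
    """
    cfg = cfg or TrainingConfig()
    y = np.array([CLASSES.index(l) for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes (SCC and AC)")
    x = _prepare(patches, cfg.input_size)
    model = _make_backbone(cfg)
    rng = np.random.default_rng(cfg.seed)

    if cfg.class_weighting:
        counts = np.bincount(y, minlength=2)
        cw = len(y) / (2.0 * counts)
    else:
        cw = np.ones(2)

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    losses = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr0 * cfg.lr_gamma ** epoch
        order = rng.permutation(len(y))
        epoch_loss = 0.0
        for start in range(0, len(y), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            wb = cw[yb]
            logits, cache = model.forward(xb, want_cache=True)
            zmax = logits.max(axis=1, keepdims=True)
            logp = logits - zmax - np.log(np.exp(logits - zmax).sum(axis=1, keepdims=True))
            loss = -(wb * logp[np.arange(len(yb)), yb]).sum() / wb.sum()
            probs = np.exp(logp)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits *= (wb / wb.sum())[:, None]
            grads = model.backward(cache, dlogits)
            t += 1
            for k, p in model.params.items():
                g = grads[k] + cfg.weight_decay * p
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mh = m[k] / (1 - beta1 ** t)
                vh = v[k] / (1 - beta2 ** t)
                p -= lr * mh / (np.sqrt(vh) + eps)
            epoch_loss += loss * len(yb)
        losses.append(epoch_loss / len(y))
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}  loss {losses[-1]:.4f}  lr {lr:.2e}")
    model.loss_history = losses
    model.config = cfg
    return model


def predict_patches(model, patches: Sequence[np.ndarray],
                    slide_id: Optional[str] = None,
                    coords: Optional[Sequence[PatchCoord]] = None,
                    batch_size: int = 256) -> list[PatchPrediction]:
    """Run the classifier over patches, preserving input order."""
    input_size = getattr(model, "input_size", 64)
    preds: list[PatchPrediction] = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start:start + batch_size]
        x = _prepare(chunk, input_size)
        p = model.predict_proba(x)[:, 1]
        for j, p_ac in enumerate(p):
            i = start + j
            preds.append(PatchPrediction(
                p_ac=float(p_ac),
                label="AC" if p_ac >= 0.5 else "SCC",
                slide_id=slide_id,
                coord=coords[i] if coords is not None else None))
    return preds


def select_backbone(models: Sequence, validation_aurocs: Sequence[float]):
    """Pick the backbone with the best validation AUROC; ties go to the
    model with fewer parameters."""
    if len(models) == 0:
        raise ValueError("no candidate models")
    if len(models) != len(validation_aurocs):
        raise ValueError("one validation AUROC per candidate is required")
    ranked = sorted(range(len(models)),
                    key=lambda i: (-validation_aurocs[i],
                                   getattr(models[i], "n_params", np.inf)))
    return models[ranked[0]]


def gradcam(model, patch: np.ndarray, target_class: str = "AC") -> np.ndarray:
    """Gradient-weighted class activation map for one patch.

    Channel weights are the spatial means of the class-score gradient on
    the final convolutional activations; the heatmap is the ReLU of the
    weighted activation sum, upsampled to the patch size and min-max
    normalized to [0, 1] (identically zero maps stay zero).
    """
    if not hasattr(model, "forward"):
        raise ValueError("model does not expose convolutional activations")
    c = CLASSES.index(target_class)
    input_size = getattr(model, "input_size", 64)
    x = _prepare([patch], input_size)
    logits, cache = model.forward(x, want_cache=True)
    a = cache["conv_out"][0]                      # (h, w, C)
    h, w, _ = a.shape
    # d logit_c / d a = Wf[:, c] / (h*w), spatially uniform through GAP
    alpha = model.params["Wf"][:, c] / (h * w)    # channel weights
    cam = np.maximum((a * alpha).sum(axis=-1), 0.0)
    cam = resize(cam, patch.shape[:2], anti_aliasing=True, preserve_range=True)
    top = cam.max()
    if top <= 0:
        return np.zeros(patch.shape[:2])
    return (cam - cam.min()) / (top - cam.min())


def load_model(path) -> TinyCNN:
    return TinyCNN.load(path)
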