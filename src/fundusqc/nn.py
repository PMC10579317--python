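"""Desk-scale CNN backend: small binary conv-nets trained per quality head.

One independent binary classifier per task mirrors the one-model-per-task
layout of the full system (1 location model, 6 posterior-aspect models, 3
peripheral-aspect models). The default ``tiny_cnn`` backbone is a three-block
convolutional network (conv-relu-pool ×2, conv-relu, global average pool,
linear head) implemented directly in NumPy so training runs CPU-only and
bit-reproducibly; ``inception_v3``/``densenet`` remain accepted backbone
names for full-fidelity runs but are not available in this build and raise.

Training follows the reference recipe: Adam, initial learning rate 1e-3
halved when validation accuracy has not improved for 3 epochs, pixel values
normalised to [0, 1], checkpoint chosen by best validation accuracy. The
published defaults (50 epochs, batch 64, 299-pixel inputs) are the
TrainConfig defaults; desk-scale runs shrink them explicitly.

Grad-CAM heatmaps come from the gradient of a head's logit with respect to
the last convolutional block: with a global-average-pool head that gradient
is constant per channel (w_k / HW), so the map is relu(sum_k alpha_k A_k),
upsampled to the input size and max-normalised.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .assessment import AspectProbabilities, _check_rgb
from .synthetic import FundusImage, ValidationError, aspects_for


@dataclass(frozen=True)
class TrainConfig:
    input_size: int = 299
    learning_rate: float = 0.001
    lr_decay_factor: float = 2.0
    lr_patience_epochs: int = 3
    epochs: int = 50
    batch_size: int = 64
    backbone: str = "tiny_cnn"
    val_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in ("tiny_cnn", "inception_v3", "densenet"):
            raise ValidationError(f"unknown backbone {self.backbone!r}")
        min_size = 64
        if self.input_size < min_size:
            raise ValidationError(f"input_size must be >= {min_size}")


def desk_scale_config(**overrides) -> TrainConfig:
    """TrainConfig shrunk for CPU-only runs on synthetic fixtures."""
    base = dict(input_size=64, epochs=10, batch_size=32, learning_rate=0.005)
    base.update(overrides)
    return TrainConfig(**base)


# -- tiny_cnn parameters and numerics -------------------------------------

_CHANNELS = (8, 16, 32)


def _init_params(rng: np.random.Generator) -> dict[str, np.ndarray]:
    params = {}
    c_in = 3
    for i, c_out in enumerate(_CHANNELS):
        fan_in = 9 * c_in
        params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in),
                                     size=(3, 3, c_in, c_out))
        params[f"b{i}"] = np.zeros(c_out)
        c_in = c_out
    # linear head over concatenated global average + global max pooling;
    # the max branch carries localized signals (small bright/dark blobs)
    # that plain averaging washes out
    params["Wd"] = rng.normal(0, np.sqrt(1.0 / (2 * c_in)), size=(2 * c_in,))
    params["bd"] = np.zeros(1)
    return params


def _conv_forward(x, w, b):
    # valid 3x3 convolution via im2col
    patches = sliding_window_view(x, (3, 3), axis=(1, 2))  # N,Ho,Wo,C,3,3
    n, ho, wo = patches.shape[:3]
    cols = patches.transpose(0, 1, 2, 4, 5, 3).reshape(n, ho, wo, -1)
    wmat = w.transpose(0, 1, 2, 3).reshape(-1, w.shape[3])
    out = cols @ wmat + b
    return out, cols


def _conv_backward(dout, cols, w, x_shape):
    n, ho, wo, c_out = dout.shape
    wmat = w.reshape(-1, c_out)
    dcols = dout @ wmat.T                              # N,Ho,Wo,9*Cin
    dw = (cols.reshape(-1, cols.shape[-1]).T
          @ dout.reshape(-1, c_out)).reshape(w.shape)
    db = dout.sum(axis=(0, 1, 2))
    c_in = x_shape[3]
    dx = np.zeros(x_shape)
    dcols = dcols.reshape(n, ho, wo, 3, 3, c_in)
    for dy in range(3):
        for dx_ in range(3):
            dx[:, dy:dy + ho, dx_:dx_ + wo, :] += dcols[:, :, :, dy, dx_, :]
    return dx, dw, db


def _pool_forward(x):
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xr = x[:, :h2 * 2, :w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
    out = xr.max(axis=(2, 4))
    mask = xr == out[:, :, None, :, None, :]
    return out, (mask, x.shape)


def _pool_backward(dout, cache):
    mask, x_shape = cache
    n, h2, _, w2, _, c = mask.shape
    dx = np.zeros(x_shape)
    spread = mask * dout[:, :, None, :, None, :]
    # split ties evenly so the gradient stays exact
    counts = mask.sum(axis=(2, 4), keepdims=True)
    spread = spread / counts
    dx[:, :h2 * 2, :w2 * 2, :] = spread.reshape(n, h2 * 2, w2 * 2, c)
    return dx


def _forward(params, x, want_cache=False):
    caches = []
    a = x
    for i in range(3):
        z, cols = _conv_forward(a, params[f"W{i}"], params[f"b{i}"])
        r = np.maximum(z, 0)
        cache = {"cols": cols, "z": z, "x_shape": a.shape}
        if i < 2:
            p, pcache = _pool_forward(r)
            cache["pool"] = pcache
            a = p
        else:
            a = r
        caches.append(cache)
    feat = a                                  # N,Hc,Wc,32 (post-relu)
    gavg = feat.mean(axis=(1, 2))
    gmax = feat.max(axis=(1, 2))
    gap = np.concatenate([gavg, gmax], axis=1)
    logit = gap @ params["Wd"] + params["bd"][0]
    if want_cache:
        return logit, feat, gap, caches
    return logit, feat


def _backward(params, x, dlogit, feat, gap, caches):
    grads = {}
    grads["Wd"] = gap.T @ dlogit
    grads["bd"] = np.array([dlogit.sum()])
    n, hc, wc, c = feat.shape
    w_avg, w_max = params["Wd"][:c], params["Wd"][c:]
    dfeat = (dlogit[:, None] * w_avg[None, :])[:, None, None, :] \
        * np.ones((1, hc, wc, 1)) / (hc * wc)
    # max-branch gradient routes to the arg-max position per channel
    gmax = feat.max(axis=(1, 2))
    at_max = feat == gmax[:, None, None, :]
    counts = at_max.sum(axis=(1, 2), keepdims=True)
    dfeat = dfeat + at_max / counts * (dlogit[:, None]
                                       * w_max[None, :])[:, None, None, :]
    da = dfeat
    for i in (2, 1, 0):
        cache = caches[i]
        if i < 2:
            da = _pool_backward(da, cache["pool"])
        dz = da * (cache["z"] > 0)
        da, dw, db = _conv_backward(dz, cache["cols"], params[f"W{i}"],
                                    cache["x_shape"])
        grads[f"W{i}"] = dw
        grads[f"b{i}"] = db
    return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedHead:
    """One trained binary head plus its validation trace."""

    params: dict[str, np.ndarray]
    task: str
    val_accuracy: float
    history: list = field(default_factory=list)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def train_head(x: np.ndarray, y: np.ndarray, task: str,
               cfg: TrainConfig) -> TrainedHead:
    """Train one binary head with Adam + reduce-on-plateau.

    ``x`` is (N, S, S, 3) float in [0, 1]; ``y`` is 0/1. The checkpoint is
    the parameter set with the best validation accuracy.
    """
    if cfg.backbone != "tiny_cnn":
        raise ValidationError(
            f"backbone {cfg.backbone!r} is not available in this build; "
            "use tiny_cnn"
        )
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    xtr, ytr = x[tr_idx], y[tr_idx]
    xval, yval = x[val_idx], y[val_idx]

    params = _init_params(rng)
    opt = _Adam(params, cfg.learning_rate)
    best = {k: v.copy() for k, v in params.items()}
    best_acc, since_improve = -1.0, 0
    history = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(xtr))
        for s in range(0, len(xtr), cfg.batch_size):
            idx = perm[s:s + cfg.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            logit, feat, gap, caches = _forward(params, xb, want_cache=True)
            p = _sigmoid(logit)
            dlogit = (p - yb) / len(yb)       # BCE gradient
            grads = _backward(params, xb, dlogit, feat, gap, caches)
            opt.step(params, grads)
        vlogit, _ = _forward(params, xval)
        vacc = float((( _sigmoid(vlogit) >= 0.5) == (yval == 1)).mean())
        history.append({"epoch": epoch, "val_accuracy": vacc, "lr": opt.lr})
        if vacc > best_acc:
            best_acc = vacc
            best = {k: v.copy() for k, v in params.items()}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.lr_patience_epochs:
                opt.lr /= cfg.lr_decay_factor
                since_improve = 0
    return TrainedHead(best, task, best_acc, history)


def _prepare(images, size: int) -> np.ndarray:
    out = np.empty((len(images), size, size, 3))
    for i, img in enumerate(images):
        px = img.pixels if isinstance(img, FundusImage) else np.asarray(img)
        px = px.astype(float) / 255.0        # normalise to [0, 1]
        if px.shape[0] != size or px.shape[1] != size:
            px = resize(px, (size, size, 3), anti_aliasing=True)
        out[i] = px
    return out


@dataclass
class CNNBackend:
    """Assessment backend built from trained per-task heads.

    ``heads`` maps task name ('location', or an aspect name) to a
    TrainedHead; the location head scores "posterior" as the positive
    class, aspect heads score "poor" as positive.
    """

    heads: dict[str, TrainedHead]
    input_size: int
    name: str = "tiny_cnn"

    def _predict(self, task: str, x: np.ndarray) -> float:
        logit, _ = _forward(self.heads[task].params, x)
        return float(_sigmoid(logit)[0])

    def assess(self, image: FundusImage,
               location_override: str | None = None) -> AspectProbabilities:
        _check_rgb(image)
        x = _prepare([image], self.input_size)
        if "location" in self.heads:
            p_post = self._predict("location", x)
        elif location_override is None:
            raise ValidationError(
                "backend has no location head; pass location_override"
            )
        else:
            p_post = 1.0 if location_override == "posterior" else 0.0
        location = location_override or (
            "posterior" if p_post >= 0.5 else "peripheral"
        )
        probs = {}
        for aspect in aspects_for(location):
            if aspect not in self.heads:
                raise ValidationError(f"no trained head for aspect {aspect!r}")
            probs[aspect] = self._predict(aspect, x)
        return AspectProbabilities(location, p_post, probs)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"input_size": self.input_size, "backbone": self.name,
                "tasks": {}}
        for task, head in self.heads.items():
            fname = f"head_{task}.npz"
            np.savez(directory / fname, **head.params)
            meta["tasks"][task] = {"file": fname,
                                   "val_accuracy": head.val_accuracy}
        (directory / "backend.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CNNBackend":
        directory = Path(directory)
        meta = json.loads((directory / "backend.json").read_text())
        heads = {}
        for task, info in meta["tasks"].items():
            with np.load(directory / info["file"]) as npz:
                params = {k: npz[k] for k in npz.files}
            heads[task] = TrainedHead(params, task, info["val_accuracy"])
        return cls(heads, meta["input_size"], meta.get("backbone", "tiny_cnn"))


def train_cnn_backend(records, cfg: TrainConfig,
                      tasks: list[str] | None = None) -> CNNBackend:
    """Train a backend from synthetic records (or (image, labels) pairs).

    Trains a location head when both locations are present, plus one head
    per requested aspect (default: every aspect with both classes present
    among matching-location records). Heads whose training labels are
    single-class are skipped with a warning. The train/validation split is
    by image id with no overlap.
    """
    images = [r.image for r in records]
    x_all = _prepare(images, cfg.input_size)
    heads: dict[str, TrainedHead] = {}

    locs = np.array([r.image.location for r in records])
    if tasks is None or "location" in tasks:
        y = (locs == "posterior").astype(float)
        if 0 < y.sum() < len(y):
            heads["location"] = train_head(x_all, y, "location", cfg)
        elif tasks is not None:
            warnings.warn("location head skipped: single-class labels")

    aspect_tasks = set()
    for r in records:
        aspect_tasks.update(r.truth_labels)
    if tasks is not None:
        aspect_tasks &= set(tasks)
    for i, aspect in enumerate(sorted(aspect_tasks)):
        sel = np.array([aspect in r.truth_labels for r in records])
        y = np.array([
            1.0 if r.truth_labels.get(aspect) == "poor" else 0.0
            for r in records
        ])[sel]
        if y.sum() == 0 or y.sum() == len(y):
            warnings.warn(f"head {aspect!r} skipped: single-class labels")
            continue
        head_cfg = replace(cfg, seed=cfg.seed + 1 + i)
        heads[aspect] = train_head(x_all[sel], y, aspect, head_cfg)
    return CNNBackend(heads, cfg.input_size)


# -- Grad-CAM --------------------------------------------------------------

@dataclass
class Heatmap:
    values: np.ndarray
    target_head: str


def gradcam(image: FundusImage, backend, head: str) -> Heatmap:
    """Gradient-weighted class-activation map for one head.

    Only CNN backends expose convolutional activations; the classical
    backend raises. The map is relu of the alpha-weighted last-block
    activations, upsampled to the input size and normalised so its maximum
    is 1 (unless identically zero).
    """
    if not isinstance(backend, CNNBackend):
        raise ValidationError("gradcam requires a CNN backend")
    if head not in backend.heads:
        raise ValidationError(f"no head named {head!r}")
    params = backend.heads[head].params
    x = _prepare([image], backend.input_size)
    _, feat = _forward(params, x)
    hc, wc = feat.shape[1:3]
    c = feat.shape[3]
    # spatial mean of d logit / d A_k: averaged over positions, the avg
    # branch contributes w_avg_k/HW and the max branch w_max_k/HW
    alphas = (params["Wd"][:c] + params["Wd"][c:]) / (hc * wc)
    cam = np.maximum((feat[0] * alphas[None, None, :]).sum(axis=-1), 0.0)
    h, w = image.shape
    cam = resize(cam, (h, w), anti_aliasing=True)
    cam = np.maximum(cam, 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    return Heatmap(cam, head)
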