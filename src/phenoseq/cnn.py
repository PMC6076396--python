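"""Per-frame CNN trained on area-split sub-classes; deep feature extraction.

A genotype's frames span seedling to full rosette, which makes the raw
genotype a visually incoherent training class.  The classifier is therefore
trained on (genotype, area-bin) sub-classes: within each genotype the plant
area (foreground pixel count) is split at its 20/40/60/80% quantiles into
five bins, giving L x 5 training classes.  Deep features are the activations
of the last fully connected layer before the classification head.

The backbone is a compact 3-block convnet (3x3 conv, ReLU, 2x2 max-pool;
widths 16/32/64) followed by a 128-unit dense feature layer, trained with SGD
(learning rate 0.001, momentum 0.9, weight decay 1e-6, mini-batches of 32).
An ``alexnet-finetune`` backbone hook exists for externally supplied
pretrained weights but is not bundled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import _nnops as nn

__all__ = [
    "SubclassLabel", "CNNConfig", "CNNModel",
    "augment_rotations", "assign_area_subclasses", "subclass_flat_labels",
    "train_cnn", "extract_deep_features",
]

N_AREA_BINS = 5


@dataclass(frozen=True)
class SubclassLabel:
    """(genotype, area-bin) training label; flat index = genotype*5 + bin."""
    genotype: int
    area_bin: int

    def flat(self, n_bins: int = N_AREA_BINS) -> int:
        return self.genotype * n_bins + self.area_bin


@dataclass
class CNNConfig:
    backbone: str = "small"
    n_outputs: int = 20          # 5L sub-classes
    feature_dim: int = 128
    widths: tuple[int, int, int] = (16, 32, 64)
    input_size: int = 32
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-6
    batch_size: int = 32
    epochs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in ("small", "alexnet-finetune"):
            raise ValueError("backbone must be 'small' or 'alexnet-finetune'")
        if min(self.n_outputs, self.feature_dim, self.input_size,
               self.batch_size, self.epochs) <= 0 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.input_size % 8:
            raise ValueError("input_size must be divisible by 8 (three 2x poolings)")


def augment_rotations(images: np.ndarray, labels: np.ndarray):
    """Each image plus its 90/180/270-degree rotations, labels copied.

    Images must be square so centre rotation keeps the frame.  Output order is
    deterministic: for each input image, the original then the three rotations.
    """
    imgs = np.asarray(images)
    if imgs.shape[1] != imgs.shape[2]:
        raise ValueError("rotation augmentation requires square images")
    labels = np.asarray(labels)
    rots = np.stack([imgs, np.rot90(imgs, 1, axes=(1, 2)),
                     np.rot90(imgs, 2, axes=(1, 2)),
                     np.rot90(imgs, 3, axes=(1, 2))], axis=1)
    out = rots.reshape(-1, *imgs.shape[1:])
    return out, np.repeat(labels, 4)


def assign_area_subclasses(
    areas: np.ndarray,
    genotypes: np.ndarray,
    n_bins: int = N_AREA_BINS,
) -> list[SubclassLabel]:
    """Quantile-bin each genotype's areas into ``n_bins`` sub-classes.

    Bin edges are the within-genotype area quantiles at 20/40/60/80% (for the
    default 5 bins); ties fall to the lower bin.  A genotype with fewer
    samples than bins gets a reduced bin count (with a warning); flat indices
    still use the global ``n_bins`` stride.
    """
    areas = np.asarray(areas, dtype=float)
    genotypes = np.asarray(genotypes)
    if areas.shape != genotypes.shape:
        raise ValueError("areas and genotypes must have the same length")
    if (areas < 0).any():
        raise ValueError("areas must be non-negative")
    out = [None] * len(areas)
    for g in np.unique(genotypes):
        sel = np.flatnonzero(genotypes == g)
        k = n_bins
        if len(sel) < n_bins:
            k = max(1, len(sel))
            warnings.warn(
                f"genotype {g}: only {len(sel)} samples; reducing to {k} area bins",
                stacklevel=2)
        edges = np.quantile(areas[sel], np.linspace(0, 1, k + 1)[1:-1])
        for i in sel:
            out[i] = SubclassLabel(int(g), int(np.sum(areas[i] > edges)))
    return out


def subclass_flat_labels(labels: list[SubclassLabel], n_bins: int = N_AREA_BINS) -> np.ndarray:
    return np.array([lab.flat(n_bins) for lab in labels])


class CNNModel:
    """Trained compact CNN with penultimate-layer feature access."""

    def __init__(self, config: CNNConfig, params: dict[str, np.ndarray],
                 norm_mean: np.ndarray, norm_std: np.ndarray,
                 history: list[float]) -> None:
        self.config = config
        self.params = params
        self.norm_mean = norm_mean
        self.norm_std = norm_std
        self.history = history  # mean training loss per epoch

    # -- forward ----------------------------------------------------------
    def _forward(self, x: np.ndarray, want_cache: bool = False):
        p = self.params
        caches = []
        h = x
        for i in (1, 2, 3):
            h, c_conv = nn.conv3x3_forward(h, p[f"wc{i}"], p[f"bc{i}"])
            h, c_relu = nn.relu_forward(h)
            h, c_pool = nn.maxpool2_forward(h)
            caches.append((c_conv, c_relu, c_pool))
        flat = h.reshape(h.shape[0], -1)
        z1, c_d1 = nn.dense_forward(flat, p["wd1"], p["bd1"])
        feat, c_r1 = nn.relu_forward(z1)
        logits, c_d2 = nn.dense_forward(feat, p["wd2"], p["bd2"])
        if want_cache:
            return logits, feat, (caches, h.shape, c_d1, c_r1, c_d2)
        return logits, feat

    def _backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        caches, pooled_shape, c_d1, c_r1, c_d2 = cache
        grads: dict[str, np.ndarray] = {}
        dfeat, grads["wd2"], grads["bd2"] = nn.dense_backward(dlogits, c_d2)
        dz1 = nn.relu_backward(dfeat, c_r1)
        dflat, grads["wd1"], grads["bd1"] = nn.dense_backward(dz1, c_d1)
        dh = dflat.reshape(pooled_shape)
        for i in (3, 2, 1):
            c_conv, c_relu, c_pool = caches[i - 1]
            dh = nn.maxpool2_backward(dh, c_pool)
            dh = nn.relu_backward(dh, c_relu)
            dh, grads[f"wc{i}"], grads[f"bc{i}"] = nn.conv3x3_backward(dh, c_conv)
        return grads

    def preprocess(self, frames: np.ndarray) -> np.ndarray:
        """uint8 (N, H, W, 3) -> normalised float32 (N, 3, s, s)."""
        s = self.config.input_size
        frames = np.asarray(frames)
        if frames.ndim != 4 or frames.shape[3] != 3:
            raise ValueError("expected (N, H, W, 3) RGB frames")
        if frames.shape[1] != s or frames.shape[2] != s:
            frames = np.stack([
                resize(f, (s, s), anti_aliasing=True, preserve_range=True)
                for f in frames])
        x = frames.astype(np.float32) / 255.0
        x = (x - self.norm_mean) / self.norm_std
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def logits(self, frames: np.ndarray, batch: int = 256) -> np.ndarray:
        x = self.preprocess(frames)
        return np.concatenate([self._forward(x[i:i + batch])[0]
                               for i in range(0, len(x), batch)])

    def features(self, frames: np.ndarray, batch: int = 256) -> np.ndarray:
        """Penultimate-layer (deep) features, one row per frame."""
        x = self.preprocess(frames)
        return np.concatenate([self._forward(x[i:i + batch])[1]
                               for i in range(0, len(x), batch)])

    def genotype_scores(self, frames: np.ndarray, n_genotypes: int,
                        n_bins: int = N_AREA_BINS) -> np.ndarray:
        """Per-frame genotype scores: softmax over sub-classes summed per genotype."""
        p = nn.softmax(self.logits(frames))
        return p.reshape(len(p), n_genotypes, n_bins).sum(axis=2)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights to ``<path>.npz`` with a JSON sidecar (config, norm,
        training history) at ``<path>.json``."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {
            "config": asdict(self.config),
            "norm_mean": self.norm_mean.tolist(),
            "norm_std": self.norm_std.tolist(),
            "history": self.history,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CNNModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = sidecar["config"]
        cfg["widths"] = tuple(cfg["widths"])
        with np.load(path.with_suffix(".npz")) as npz:
            params = {k: npz[k] for k in npz.files}
        return cls(CNNConfig(**cfg), params,
                   np.array(sidecar["norm_mean"], dtype=np.float32),
                   np.array(sidecar["norm_std"], dtype=np.float32),
                   list(sidecar["history"]))


def _init_params(cfg: CNNConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    w1, w2, w3 = cfg.widths
    flat_dim = w3 * (cfg.input_size // 8) ** 2
    p = {
        "wc1": nn.glorot(rng, (w1, 3, 3, 3), 27, w1 * 9),
        "bc1": np.zeros(w1, dtype=np.float32),
        "wc2": nn.glorot(rng, (w2, w1, 3, 3), w1 * 9, w2 * 9),
        "bc2": np.zeros(w2, dtype=np.float32),
        "wc3": nn.glorot(rng, (w3, w2, 3, 3), w2 * 9, w3 * 9),
        "bc3": np.zeros(w3, dtype=np.float32),
        "wd1": nn.glorot(rng, (flat_dim, cfg.feature_dim), flat_dim, cfg.feature_dim),
        "bd1": np.zeros(cfg.feature_dim, dtype=np.float32),
        "wd2": nn.glorot(rng, (cfg.feature_dim, cfg.n_outputs), cfg.feature_dim, cfg.n_outputs),
        "bd2": np.zeros(cfg.n_outputs, dtype=np.float32),
    }
    return p


def train_cnn(frames: np.ndarray, flat_labels: np.ndarray, config: CNNConfig) -> CNNModel:
    """Train the sub-class CNN with SGD; seed-reproducible.

    ``frames`` are uint8 RGB of one common size; ``flat_labels`` are the
    (genotype, area-bin) flat indices in ``0..n_outputs-1``.
    """
    if config.backbone == "alexnet-finetune":
        raise NotImplementedError(
            "alexnet-finetune requires externally downloaded pretrained weights; "
            "use backbone='small'")
    labels = np.asarray(flat_labels)
    if labels.min() < 0 or labels.max() >= config.n_outputs:
        raise ValueError("label outside 0..n_outputs-1")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 distinct labels to train")

    rng = np.random.default_rng(config.seed)
    model = CNNModel(config, _init_params(config, rng),
                     norm_mean=np.zeros(3, dtype=np.float32),
                     norm_std=np.ones(3, dtype=np.float32), history=[])
    # per-channel normalisation fitted on the training frames only
    x_probe = np.asarray(frames).astype(np.float32) / 255.0
    model.norm_mean = x_probe.mean(axis=(0, 1, 2)).astype(np.float32)
    model.norm_std = np.maximum(x_probe.std(axis=(0, 1, 2)), 1e-3).astype(np.float32)

    x = model.preprocess(frames)
    opt = nn.SGDMomentum(model.params, config.learning_rate, config.momentum,
                         config.weight_decay)
    n = len(x)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits, _, cache = model._forward(x[idx], want_cache=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
            grads = model._backward(dlogits, cache)
            opt.step(grads)
            losses.append(loss)
        model.history.append(float(np.mean(losses)))
    return model


def extract_deep_features(model: CNNModel, frames: np.ndarray) -> np.ndarray:
    """Deterministic penultimate-layer features for one or more frames."""
    frames = np.asarray(frames)
    single = frames.ndim == 3
    feats = model.features(frames[None] if single else frames)
    return feats[0] if single else feats
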