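"""Patch-level MSI likelihood estimation under multiple-instance learning.

Every patch inherits the MS label of its slide (the MIL weak-label scheme);
a small convolutional network is trained with binary cross-entropy and
mini-batch SGD to emit a per-patch MSI likelihood (sigmoid of a single
logit).  The slide-level aggregators consume these likelihoods.

Two backbones are exposed: ``tinycnn`` — a compact, dependency-free NumPy
CNN (2 conv blocks + 1 dense logit) sized for 64-pixel tiles — and
``resnet18``, available when torch is installed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import TinyCNN, SGDMomentum, bce_with_logits, sigmoid
from .cohort_io import MSI, SlideRecord
from .roi_tiling import PreprocessConfig, channel_statistics, preprocess_patch


@dataclass
class PatchModelConfig:
    """Training configuration for the patch-level classifier."""

    backbone: str = "tinycnn"
    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 0.02
    momentum: float = 0.9
    patches_per_slide_per_epoch: int | None = 16  # None = all patches
    seed: int = 0
    input_size: int = 64

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.backbone not in ("tinycnn", "resnet18"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


class PatchStore:
    """In-memory store of tiles keyed by (slide_id, grid_x, grid_y).

    Tiles are uint8 HxWx3 arrays.  A directory of PNGs named
    ``{slide_id}_{gx}_{gy}.png`` can be loaded with :meth:`from_directory`.
    """

    def __init__(self):
        self.images: list[np.ndarray] = []
        self.keys: list[tuple[str, int, int]] = []

    def add(self, slide_id: str, grid_x: int, grid_y: int, image: np.ndarray):
        self.images.append(np.asarray(image, dtype=np.uint8))
        self.keys.append((slide_id, grid_x, grid_y))

    def __len__(self):
        return len(self.images)

    def slide_ids(self) -> list[str]:
        return sorted({k[0] for k in self.keys})

    def subset(self, slide_ids) -> "PatchStore":
        wanted = set(slide_ids)
        out = PatchStore()
        for img, key in zip(self.images, self.keys):
            if key[0] in wanted:
                out.add(key[0], key[1], key[2], img)
        return out

    @classmethod
    def from_directory(cls, path: str | Path) -> "PatchStore":
        from PIL import Image

        store = cls()
        for f in sorted(Path(path).glob("*.png")):
            sid, gx, gy = f.stem.rsplit("_", 2)
            store.add(sid, int(gx), int(gy), np.asarray(Image.open(f).convert("RGB")))
        return store

    def write_directory(self, path: str | Path) -> None:
        from PIL import Image

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for img, (sid, gx, gy) in zip(self.images, self.keys):
            Image.fromarray(img).save(path / f"{sid}_{gx}_{gy}.png")


@dataclass
class PatchModel:
    """Fitted patch classifier plus the preprocessing statistics it was trained with."""

    net: TinyCNN
    cfg: PatchModelConfig
    channel_mean: np.ndarray
    channel_std: np.ndarray
    loss_trace: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.net.get_weights())
        (path / "config.json").write_text(json.dumps(asdict(self.cfg), indent=2))
        (path / "channel_stats.json").write_text(
            json.dumps(
                {"mean": self.channel_mean.tolist(), "std": self.channel_std.tolist()}
            )
        )
        pd.DataFrame({"epoch": range(1, len(self.loss_trace) + 1),
                      "mean_bce": self.loss_trace}).to_csv(
            path / "loss_trace.csv", index=False
        )

    @classmethod
    def load(cls, path: str | Path) -> "PatchModel":
        path = Path(path)
        cfg = PatchModelConfig(**json.loads((path / "config.json").read_text()))
        stats = json.loads((path / "channel_stats.json").read_text())
        net = TinyCNN(cfg.input_size, seed=cfg.seed)
        with np.load(path / "weights.npz") as z:
            net.set_weights(dict(z))
        trace = pd.read_csv(path / "loss_trace.csv")["mean_bce"].tolist()
        return cls(net, cfg, np.array(stats["mean"]), np.array(stats["std"]), trace)


def _prepare_tensors(store: PatchStore, mean, std, input_size: int,
                     augment: bool = False, rng=None) -> np.ndarray:
    cfg = PreprocessConfig(
        crop_size=input_size, channel_mean=mean, channel_std=std, augment=augment
    )
    return np.stack([preprocess_patch(img, cfg, rng=rng) for img in store.images])


def train_patch_model(
    patches: PatchStore,
    labels: list[SlideRecord],
    cfg: PatchModelConfig | None = None,
) -> PatchModel:
    """Train the patch classifier under MIL label inheritance.

    Each patch's target is its slide's MS label (MSI = 1).  Per epoch, up to
    ``patches_per_slide_per_epoch`` patches are drawn per slide and sample
    weights are inverse class frequencies, so large slides and the majority
    class do not dominate.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or PatchModelConfig()
    if cfg.backbone == "resnet18":
        raise ImportError(
            "the resnet18 backbone requires torch; use backbone='tinycnn'"
        )
    if len(patches) == 0:
        raise ValueError("empty patch store")
    label_of = {r.slide_id: 1 if r.ms_label == MSI else 0 for r in labels}
    missing = [k[0] for k in patches.keys if k[0] not in label_of]
    if missing:
        raise ValueError(f"unlabeled slide(s) in patch store: {sorted(set(missing))[:3]}")
    slide_y = {k[0]: label_of[k[0]] for k in patches.keys}
    if len(set(slide_y.values())) < 2:
        raise ValueError("single-class training set")

    mean, std = channel_statistics(patches.images)
    rng = np.random.default_rng(cfg.seed)
    net = TinyCNN(cfg.input_size, seed=cfg.seed)
    opt = SGDMomentum(cfg.learning_rate, cfg.momentum)

    by_slide: dict[str, list[int]] = {}
    for i, key in enumerate(patches.keys):
        by_slide.setdefault(key[0], []).append(i)
    class_count = {c: sum(1 for v in slide_y.values() if v == c) for c in (0, 1)}

    y_all = np.array([label_of[k[0]] for k in patches.keys], dtype=float)
    trace = []
    for _ in range(cfg.epochs):
        # per-epoch MIL sample: cap patches per slide, weight by class rarity
        idx, wts = [], []
        for sid in sorted(by_slide):
            pool = by_slide[sid]
            k = len(pool) if cfg.patches_per_slide_per_epoch is None else min(
                cfg.patches_per_slide_per_epoch, len(pool)
            )
            take = rng.choice(len(pool), size=k, replace=False)
            idx.extend(pool[t] for t in take)
            wts.extend([1.0 / class_count[slide_y[sid]]] * k)
        idx = np.array(idx)
        wts = np.array(wts)
        order = rng.permutation(len(idx))
        idx, wts = idx[order], wts[order]

        sub = PatchStore()
        for i in idx:
            sub.add(*patches.keys[i], patches.images[i])
        x = _prepare_tensors(sub, mean, std, cfg.input_size, augment=True, rng=rng)
        y = y_all[idx]

        losses = []
        for start in range(0, len(idx), cfg.batch_size):
            sl = slice(start, start + cfg.batch_size)
            z = net.forward(x[sl])
            loss, dz = bce_with_logits(z, y[sl], wts[sl])
            net.backward(dz)
            opt.step(net.all_layers)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return PatchModel(net=net, cfg=cfg, channel_mean=mean, channel_std=std,
                      loss_trace=trace)


def predict_patch_likelihoods(model: PatchModel, patches: PatchStore) -> pd.DataFrame:
    """Per-patch sigmoid MSI likelihoods as a (slide_id, grid_x, grid_y, likelihood) table."""
    if len(patches) == 0:
        raise ValueError("empty patch store")
    x = _prepare_tensors(
        patches, model.channel_mean, model.channel_std, model.cfg.input_size
    )
    if x.shape[1] != model.cfg.input_size:
        raise ValueError("patch size does not match model input size")
    probs = sigmoid(model.net.predict_logits(x))
    rows = [
        (sid, gx, gy, float(p))
        for (sid, gx, gy), p in zip(patches.keys, probs)
    ]
    return pd.DataFrame(rows, columns=["slide_id", "grid_x", "grid_y", "likelihood"])


def render_heatmap(table: pd.DataFrame, slide_id: str, path: str | Path) -> Path:
    """Render the per-patch likelihood grid of one slide as a heatmap image.

    One cell per patch at its grid position, color monotone in likelihood
    (fixed 0-1 scale), colorbar included; cells without a patch are blank.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[table["slide_id"] == slide_id]
    if sub.empty:
        raise ValueError(f"slide {slide_id!r} not present in likelihood table")
    gx = sub["grid_x"].to_numpy()
    gy = sub["grid_y"].to_numpy()
    grid = np.full((gy.max() - gy.min() + 1, gx.max() - gx.min() + 1), np.nan)
    grid[gy - gy.min(), gx - gx.min()] = sub["likelihood"].to_numpy()
    fig, ax = plt.subplots()
    im = ax.imshow(grid, cmap="inferno", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label="MSI likelihood")
    ax.set_title(slide_id)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
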