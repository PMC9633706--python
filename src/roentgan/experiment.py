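"""Augmentation / anonymization experiment: dataset construction, the VGG16
transfer-learning classifier variant, and best-validation-loss training.

Six datasets are built from a scarce real pool: a baseline of 200 real
training images (100 per class) with 132-image validation and test sets
(66 per class), four augmented sets that recursively add generated images to
the training set (+50%, +100%, +150%, +200% of the baseline count), and a
"replace" set whose training images are generated only (anonymization by
replacement) while validation and test stay real.

The transfer classifier is a VGG16 convolutional base sized so the final
feature map is 6×6×512, with convolutional blocks 1–4 frozen and block 5 plus
a 256-unit ELU dense head and sigmoid output trainable. A small stand-in CNN
with the same contract is used for desk-scale training runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import (
    Adam, Conv2D, Dense, Dropout, ELU, Flatten, MaxPool2D, ReLU, Sequential,
    Sigmoid,
)

__all__ = [
    "DatasetPlan", "TransferSpec", "TABLE5_PLANS",
    "build_datasets", "build_transfer_model", "build_desk_classifier",
    "run_experiment",
]


# --------------------------------------------------------------------------
# Dataset plans
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetPlan:
    """Counts per class for one dataset of the experiment."""

    name: str
    n_train_real: int          # per class
    n_train_fake: int          # per class
    n_val: int = 66            # per class, always real
    n_test: int = 66           # per class, always real

    @property
    def n_train_total(self) -> int:
        return 2 * (self.n_train_real + self.n_train_fake)


TABLE5_PLANS = (
    DatasetPlan("real", 100, 0),
    DatasetPlan("real+50%fakes", 100, 50),
    DatasetPlan("real+100%fakes", 100, 100),
    DatasetPlan("real+150%fakes", 100, 150),
    DatasetPlan("real+200%fakes", 100, 200),
    DatasetPlan("replace", 0, 100),
)


def build_datasets(real_pool: pd.DataFrame, fake_sampler, seed: int = 0,
                   plans=TABLE5_PLANS) -> dict[str, pd.DataFrame]:
    """Construct the experiment's dataset manifests from a real image pool.

    ``real_pool`` needs columns ``id`` and ``class`` (labels "A"/"B" or
    KL01/KL234 — any two labels). ``fake_sampler(class_label, n, rng)``
    returns n identifiers of freshly generated images for that class.

    Real train/val/test assignments are disjoint and shared by every plan;
    the augmented training sets are built recursively, so each one is a
    superset of the previous, and the replace plan's training set holds no
    real image. Raises if the pool cannot cover 100 + 66 + 66 per class.
    """
    rng = np.random.default_rng(seed)
    classes = sorted(real_pool["class"].unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")

    base = max(p.n_train_real for p in plans)
    n_val = plans[0].n_val
    n_test = plans[0].n_test
    need = base + n_val + n_test
    splits: dict[str, dict[str, list]] = {"train": {}, "val": {}, "test": {}}
    for cls in classes:
        ids = real_pool.loc[real_pool["class"] == cls, "id"].tolist()
        if len(ids) < need:
            raise ValueError(f"real pool shortfall for class {cls}: "
                             f"need {need}, have {len(ids)}")
        chosen = rng.permutation(ids)[:need]
        splits["train"][cls] = list(chosen[:base])
        splits["val"][cls] = list(chosen[base:base + n_val])
        splits["test"][cls] = list(chosen[base + n_val:need])

    # recursive fake pools: each augmentation level extends the previous draws
    fake_ids: dict[str, list] = {cls: [] for cls in classes}
    max_fakes = max(p.n_train_fake for p in plans)

    def ensure_fakes(cls, n):
        while len(fake_ids[cls]) < n:
            fake_ids[cls].extend(
                fake_sampler(cls, n - len(fake_ids[cls]), rng))

    for cls in classes:
        ensure_fakes(cls, max_fakes)

    manifests = {}
    for plan in plans:
        rows = []
        for cls in classes:
            for rid in splits["train"][cls][:plan.n_train_real]:
                rows.append({"id": rid, "class": cls, "source": "real",
                             "split": "train"})
            for fid in fake_ids[cls][:plan.n_train_fake]:
                rows.append({"id": fid, "class": cls, "source": "fake",
                             "split": "train"})
            for rid in splits["val"][cls]:
                rows.append({"id": rid, "class": cls, "source": "real",
                             "split": "val"})
            for rid in splits["test"][cls]:
                rows.append({"id": rid, "class": cls, "source": "real",
                             "split": "test"})
        manifests[plan.name] = pd.DataFrame(rows)
    return manifests


# --------------------------------------------------------------------------
# Transfer classifier
# --------------------------------------------------------------------------

# VGG16 convolutional base: (block, filters, n_convs)
_VGG16_BLOCKS = ((1, 64, 2), (2, 128, 2), (3, 256, 3), (4, 512, 3), (5, 512, 3))


@dataclass(frozen=True)
class TransferSpec:
    input_size: int = 210        # yields a 6x6x512 feature map after 5 pools
    dense_units: int = 256
    frozen_blocks: tuple[int, ...] = (1, 2, 3, 4)
    epochs: int = 22

    @property
    def feature_map_size(self) -> int:
        s = self.input_size
        for _ in _VGG16_BLOCKS:
            s //= 2
        return s


def build_transfer_model(spec: TransferSpec | None = None, seed: int = 0) -> Sequential:
    """VGG16 backbone (headless) + flatten + dense-ELU head + sigmoid output.

    Convolution layers in ``spec.frozen_blocks`` have their parameters marked
    non-trainable. Weights are randomly initialised; the architecture and its
    parameter tallies do not depend on pretrained values.
    """
    spec = spec or TransferSpec()
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 3
    frozen = set(spec.frozen_blocks)
    for block, filters, n_convs in _VGG16_BLOCKS:
        for j in range(n_convs):
            conv = Conv2D(in_ch, filters, 3, stride=1, padding="same",
                          use_bias=True, rng=rng, name=f"block{block}_conv{j + 1}")
            if block in frozen:
                for p in conv.params():
                    p.trainable = False
            layers += [conv, ReLU(name=f"block{block}_relu{j + 1}")]
            in_ch = filters
        layers.append(MaxPool2D(2, name=f"block{block}_pool"))
    fm = spec.feature_map_size
    flat = fm * fm * 512
    layers += [
        Flatten(),
        Dense(flat, spec.dense_units, use_bias=True, rng=rng, name="head_dense"),
        ELU(1.0, name="head_elu"),
        Dense(spec.dense_units, 1, use_bias=True, rng=rng, name="head_out"),
        Sigmoid(),
    ]
    return Sequential(layers, name="vgg16_transfer")


def build_desk_classifier(input_size: int = 32, seed: int = 0) -> Sequential:
    """Small CNN stand-in for desk-scale training of the same binary task."""
    rng = np.random.default_rng(seed)
    layers = [
        Conv2D(1, 8, 3, stride=2, padding="same", rng=rng, name="c1"),
        ELU(1.0, name="e1"),
        Conv2D(8, 16, 3, stride=2, padding="same", rng=rng, name="c2"),
        ELU(1.0, name="e2"),
        Flatten(),
        Dense((input_size // 4) ** 2 * 16, 32, rng=rng, name="fc1"),
        ELU(1.0, name="e3"),
        Dense(32, 1, rng=rng, name="fc2"),
        Sigmoid(),
    ]
    return Sequential(layers, name="desk_classifier")


# --------------------------------------------------------------------------
# Training / evaluation
# --------------------------------------------------------------------------

def _bce(probs: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(probs.ravel(), eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).mean())


def _evaluate(model: Sequential, x: np.ndarray, y: np.ndarray,
              batch: int = 64) -> tuple[float, float]:
    probs = np.concatenate([model.forward(x[i:i + batch], training=False).ravel()
                            for i in range(0, len(x), batch)])
    loss = _bce(probs, y)
    acc = float(((probs >= 0.5).astype(int) == y).mean() * 100.0)
    return acc, loss


def run_experiment(datasets: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]],
                   model_builder=None, epochs: int = 5, batch_size: int = 16,
                   lr: float = 1e-4, seed: int = 0) -> pd.DataFrame:
    """Train one classifier per dataset with best-validation-loss checkpointing.

    ``datasets`` maps dataset name → {"train"|"val"|"test": (X, y)} with X as
    (N, H, W, 1) float arrays in [−1, 1] and y as 0/1 labels. For each
    dataset the model is trained with Adam + binary cross-entropy, the epoch
    with the lowest validation loss is checkpointed, and the result row
    reports test accuracy and loss at that checkpoint together with the best
    validation accuracy and loss. Deterministic under a fixed seed.
    """
    rows = []
    for name, splits in datasets.items():
        for key in ("train", "val", "test"):
            if key not in splits or len(splits[key][0]) == 0:
                raise ValueError(f"dataset {name!r} is missing a non-empty {key} split")
        x_tr, y_tr = splits["train"]
        x_val, y_val = splits["val"]
        x_te, y_te = splits["test"]
        x_tr = np.asarray(x_tr, dtype=np.float32)
        y_tr = np.asarray(y_tr).astype(np.float64).ravel()

        builder = model_builder or (
            lambda s: build_desk_classifier(input_size=x_tr.shape[1], seed=s))
        model = builder(seed)
        opt = Adam(model.trainable_params(), lr=lr, beta1=0.9, beta2=0.999, decay=0.0)
        rng = np.random.default_rng(seed)

        best = {"val_loss": np.inf, "val_acc": np.nan, "state": None, "val_acc_best": -np.inf}
        for epoch in range(epochs):
            order = rng.permutation(len(x_tr))
            for i in range(0, len(order) - batch_size + 1, batch_size):
                idx = order[i:i + batch_size]
                xb, yb = x_tr[idx], y_tr[idx]
                model.zero_grad()
                probs = model.forward(xb, training=True,
                                      rng=np.random.default_rng(rng.integers(2 ** 31)))
                loss = _bce(probs, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss on {name} epoch {epoch}")
                p = np.clip(probs.ravel(), 1e-7, 1 - 1e-7)
                dprobs = ((p - yb) / (p * (1 - p)) / len(yb)).astype(np.float32)
                model.backward(dprobs.reshape(probs.shape))
                opt.step()
            val_acc, val_loss = _evaluate(model, x_val, np.asarray(y_val).ravel())
            best["val_acc_best"] = max(best["val_acc_best"], val_acc)
            if val_loss < best["val_loss"]:
                best.update(val_loss=val_loss, val_acc=val_acc,
                            state=model.state_dict())
        model.load_state_dict(best["state"])
        test_acc, test_loss = _evaluate(model, np.asarray(x_te, dtype=np.float32),
                                        np.asarray(y_te).ravel())
        rows.append({
            "dataset": name,
            "test_accuracy_at_best_val_loss": test_acc,
            "test_loss_at_best_val_loss": test_loss,
            "val_accuracy_best": best["val_acc_best"],
            "val_loss_best": best["val_loss"],
        })
    return pd.DataFrame(rows)
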