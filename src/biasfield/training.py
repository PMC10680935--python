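"""Procedural training API: dataset splitting, the training entry point,
and versioned checkpoints.

These functions are thin wrappers around
:class:`biasfield.estimator.BiasFieldCorrector`, which owns the actual
optimization loop.  Everything is seeded: given (seed, config, data) the
entire per-epoch history is reproducible, and checkpoints carry weights,
Adam moments and the RNG state so a resumed run continues the exact loss
trajectory of an uninterrupted one.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import BiasFieldCorrector
from .unet import UNetConfig

__all__ = [
    "TrainConfig",
    "split_dataset",
    "train_model",
    "save_checkpoint",
    "load_checkpoint",
    "history_to_csv",
]

CHECKPOINT_VERSION = 1


@dataclasses.dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The learning rate default follows the published protocol (Adam,
    1e-4); epoch count and batch size are desk-scale defaults since the
    original protocol does not report them.  Model selection is always
    lowest validation total loss.
    """

    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 1
    seed: int = 0
    smoothing_in_loss: bool = False
    smoothing: str = "G"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def split_dataset(items, fractions=(0.90, 0.05, 0.05), seed: int = 0):
    """Seeded disjoint/exhaustive train-validation-test split of ids.

    Sizes are floors of ``fraction * n`` with the remainder distributed
    to the splits with the largest fractional parts (ties to the earlier
    split), so 100 items under the default 90/5/5% give exactly 90/5/5.
    """
    items = list(items)
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if len(items) < 3:
        raise ValueError("need at least 3 items to split three ways")
    n = len(items)
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [items[i] for i in perm]
    out, start = [], 0
    for c in counts:
        out.append(shuffled[start:start + c])
        start += c
    return tuple(out)


def _estimator_from_configs(unet_cfg: UNetConfig,
                            train_cfg: TrainConfig) -> BiasFieldCorrector:
    return BiasFieldCorrector(
        levels=unet_cfg.levels, base_channels=unet_cfg.base_channels,
        learning_rate=train_cfg.learning_rate, epochs=train_cfg.epochs,
        batch_size=train_cfg.batch_size, seed=train_cfg.seed,
        smoothing=train_cfg.smoothing,
        smoothing_in_loss=train_cfg.smoothing_in_loss,
    )


def train_model(train, val, unet_cfg: UNetConfig, train_cfg: TrainConfig,
                resume=None, verbose: int = 0):
    """Train on ``train``, select best-on-``val`` weights.

    Returns ``(estimator, history)`` where ``history`` is a DataFrame
    with one row per epoch (train/val total loss and both components).
    The estimator's ``net_`` holds the weights of the epoch with the
    lowest validation loss.
    """
    if not train or not val:
        raise ValueError("train and val sets must be nonempty")
    est = _estimator_from_configs(unet_cfg, train_cfg)
    est.verbose = verbose
    est.fit(train, X_val=val, resume=resume)
    return est, pd.DataFrame(est.history_)


def history_to_csv(history, path) -> None:
    df = history if isinstance(history, pd.DataFrame) else pd.DataFrame(history)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, est: BiasFieldCorrector) -> None:
    """Serialize weights, optimizer state, RNG state and config.

    Written atomically (temp file + rename) so a crash cannot leave a
    half-written checkpoint behind.
    """
    state = est.training_state()
    arrays = {}
    for k, v in state["weights"].items():
        arrays[f"w::{k}"] = v
    for k, v in state["best_weights"].items():
        arrays[f"bw::{k}"] = v
    for k, v in state["optimizer"].items():
        arrays[f"opt::{k}"] = v
    meta = {
        "version": CHECKPOINT_VERSION,
        "params": est.get_params(),
        "epoch": state["epoch"],
        "best_val": state["best_val"],
        "best_epoch": state["best_epoch"],
        "rng_state": state["rng_state"],
        "history": state["history"],
    }
    arrays["meta"] = np.frombuffer(
        json.dumps(meta, default=int).encode(), dtype=np.uint8)
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".npz")
    os.close(fd)
    try:
        with open(tmp, "wb") as fh:
            np.savez(fh, **arrays)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def load_checkpoint(path):
    """Restore ``(estimator, resume_state)`` from :func:`save_checkpoint`.

    The estimator's ``net_`` carries the best-on-validation weights;
    ``resume_state`` can be passed to ``fit(..., resume=...)`` to
    continue training.  A checkpoint written by a different format
    version raises an explicit incompatibility error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such checkpoint: {path}")
    try:
        with np.load(path, allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files}
    except Exception as exc:  # zip/corruption errors surface explicitly
        raise IOError(f"cannot read checkpoint {path}: {exc}") from exc
    if "meta" not in arrays:
        raise IOError(f"checkpoint {path} has no metadata block")
    meta = json.loads(bytes(arrays["meta"]).decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"incompatible checkpoint version {meta.get('version')} "
            f"(this build reads version {CHECKPOINT_VERSION})")

    est = BiasFieldCorrector(**meta["params"])
    from .unet import UNet3D

    weights = {k[len("w::"):]: v for k, v in arrays.items()
               if k.startswith("w::")}
    best = {k[len("bw::"):]: v for k, v in arrays.items()
            if k.startswith("bw::")}
    optstate = {k[len("opt::"):]: v for k, v in arrays.items()
                if k.startswith("opt::")}
    resume_state = {
        "weights": weights,
        "best_weights": best,
        "optimizer": optstate,
        "rng_state": meta["rng_state"],
        "epoch": meta["epoch"],
        "best_val": meta["best_val"],
        "best_epoch": meta["best_epoch"],
        "history": meta["history"],
    }
    net = UNet3D(est._unet_config())
    net.load_state_dict(best)
    est.net_ = net
    est.history_ = [dict(r) for r in meta["history"]]
    est.best_epoch_ = int(meta["best_epoch"])
    est.best_val_loss_ = float(meta["best_val"])
    est._last_state = resume_state
    return est, resume_state
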