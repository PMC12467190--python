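"""Patient-level splitting, paired augmentation, MSE training, and
hyperparameter search.

Training minimises the mean squared error between the network output and
the full-dose reference on 8-bit images rescaled to [0, 1], using Adam.
Augmentation (random rotations within +/-10 degrees and horizontal/vertical
flips with probability 0.5 each) applies the *same* geometric transform to
both members of a pair — paired supervision must stay aligned — and is
restricted to the training subset.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dicom_io import CTImage, DoseTag, Image8, ImagePair, hu_to_uint8, SOFT_TISSUE_WINDOW
from .model import ErisNet, ErisNetConfig, build_erisnet
from .nn import Adam
from .phantom import BACKGROUND_HU

__all__ = [
    "TrainConfig",
    "SearchSpace",
    "TrainingDiverged",
    "split_by_patient",
    "augment_pair",
    "augment_training_set",
    "pairs_to_arrays",
    "train",
    "hyperparameter_search",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation and augmentation settings.

    The defaults are the final tuned values: batch size 6, learning rate
    3e-3, dropout handled by the model config.  ``split_counts`` defaults
    to the 15/4/4 patient allocation.
    """

    batch_size: int = 6
    learning_rate: float = 3e-3
    epochs: int = 10
    augmentation_factor: int = 4
    rotation_range_deg: float = 10.0
    flip_prob: float = 0.5
    split_counts: tuple[int, int, int] = (15, 4, 4)
    window: tuple[float, float] = SOFT_TISSUE_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")
        if self.augmentation_factor < 1:
            raise ValueError("augmentation_factor must be >= 1")


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def split_by_patient(
    dataset: list[ImagePair],
    split_counts: tuple[int, int, int] = (15, 4, 4),
    seed: int = 0,
) -> tuple[list[ImagePair], list[ImagePair], list[ImagePair]]:
    """Partition pairs into train/val/test with no patient crossing subsets."""
    patients = sorted({p.hq.patient_id for p in dataset})
    if sum(split_counts) != len(patients):
        raise ValueError(
            f"split counts {split_counts} must sum to the number of patients ({len(patients)})"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    n_tr, n_va, n_te = split_counts
    groups = (set(order[:n_tr]), set(order[n_tr : n_tr + n_va]), set(order[n_tr + n_va :]))
    return tuple([p for p in dataset if p.hq.patient_id in g] for g in groups)  # type: ignore[return-value]


def _transform(pixels: np.ndarray, angle: float, flip_h: bool, flip_v: bool) -> np.ndarray:
    out = pixels
    if angle != 0.0:
        # bilinear, air fill outside the support: CT-plausible padding
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="constant", cval=BACKGROUND_HU)
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment_pair(
    pair: ImagePair,
    seed: int = 0,
    augmentation_factor: int = 4,
    rotation_range_deg: float = 10.0,
    flip_prob: float = 0.5,
) -> list[ImagePair]:
    """Derive ``augmentation_factor`` geometrically transformed copies.

    Each derived pair applies one rotation/flip draw identically to hq and
    lq, and is marked ``augmented=True`` so data-hygiene checks can keep it
    out of validation and test sets.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(augmentation_factor):
        angle = float(rng.uniform(-rotation_range_deg, rotation_range_deg))
        flip_h = bool(rng.random() < flip_prob)
        flip_v = bool(rng.random() < flip_prob)
        hq = pair.hq.with_pixels(_transform(pair.hq.pixels, angle, flip_h, flip_v))
        lq = pair.lq.with_pixels(_transform(pair.lq.pixels, angle, flip_h, flip_v))
        out.append(ImagePair(hq=hq, lq=lq, dose_fraction=pair.dose_fraction, augmented=True))
    return out


def augment_training_set(pairs: list[ImagePair], cfg: TrainConfig) -> list[ImagePair]:
    """Expand a training set by the configured augmentation factor."""
    rng = np.random.default_rng(cfg.seed)
    out: list[ImagePair] = []
    for pair in pairs:
        out.extend(
            augment_pair(
                pair,
                seed=int(rng.integers(0, 2**31 - 1)),
                augmentation_factor=cfg.augmentation_factor,
                rotation_range_deg=cfg.rotation_range_deg,
                flip_prob=cfg.flip_prob,
            )
        )
    return out


def pairs_to_arrays(
    pairs: list[ImagePair], window: tuple[float, float] = SOFT_TISSUE_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """Stack pairs into (N, 1, H, W) float32 arrays in [0, 1]: (lq, hq)."""
    lq = np.stack([hu_to_uint8(p.lq, window).pixels for p in pairs]).astype(np.float32) / 255.0
    hq = np.stack([hu_to_uint8(p.hq, window).pixels for p in pairs]).astype(np.float32) / 255.0
    return lq[:, None], hq[:, None]


def _val_loss(model: ErisNet, lq: np.ndarray, hq: np.ndarray, batch: int) -> float:
    total, n = 0.0, 0
    for i in range(0, len(lq), batch):
        pred = model.forward(lq[i : i + batch], training=False)
        total += float(((pred - hq[i : i + batch]) ** 2).sum())
        n += pred.size
    return total / n


def _snapshot(model: ErisNet) -> list[np.ndarray]:
    state = [p.value.copy() for p in model.parameters()]
    from .nn import BatchNorm2D

    for layer in model._layers():
        if isinstance(layer, BatchNorm2D):
            state.append(layer.running_mean.copy())
            state.append(layer.running_var.copy())
    return state


def _restore(model: ErisNet, state: list[np.ndarray]) -> None:
    params = model.parameters()
    for p, v in zip(params, state):
        p.value[...] = v
    from .nn import BatchNorm2D

    i = len(params)
    for layer in model._layers():
        if isinstance(layer, BatchNorm2D):
            layer.running_mean[...] = state[i]
            layer.running_var[...] = state[i + 1]
            i += 2


def train(
    model: ErisNet,
    train_pairs: list[ImagePair],
    val_pairs: list[ImagePair],
    cfg: TrainConfig,
    augment: bool = True,
) -> tuple[ErisNet, list[dict]]:
    """Fit the model by MSE; return the best-on-validation checkpoint.

    ``history`` holds one record per epoch with train/val loss.  Raises
    :class:`TrainingDiverged` on a non-finite loss with the offending epoch
    and step in the message.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    if any(p.augmented for p in val_pairs):
        raise ValueError("validation set contains augmented pairs; data hygiene violated")

    work = augment_training_set(train_pairs, cfg) if augment else list(train_pairs)
    x_tr, y_tr = pairs_to_arrays(work, cfg.window)
    x_va, y_va = pairs_to_arrays(val_pairs, cfg.window)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[dict] = []
    best_val = math.inf
    best_state = _snapshot(model)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        epoch_loss, n_batches = 0.0, 0
        for b0 in range(0, len(order), cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            opt.zero_grad()
            pred = model.forward(xb, training=True)
            err = pred - yb
            loss = float((err**2).mean())
            if not math.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}, batch {b0 // cfg.batch_size} "
                    f"(learning rate {cfg.learning_rate})"
                )
            model.backward(2.0 * err / err.size)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val = _val_loss(model, x_va, y_va, cfg.batch_size)
        history.append({"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_loss": val})
        if val < best_val:
            best_val = val
            best_state = _snapshot(model)

    _restore(model, best_state)
    return model, history


# ---------------------------------------------------------------------------
# Hyperparameter search


@dataclass(frozen=True)
class SearchSpace:
    """Fine-tuning search space.

    Defaults: dropout uniform on [0.4, 0.5]; encoder channels from
    {64, 96, 112}; middle from {96, 112, 128}; decoder from {64, 96, 112};
    DnCNN blocks from {3, 4, 5}; learning rate log-uniform on
    [1e-5, 1e-4]; batch size from {4, 6, 8}.
    """

    dropout: tuple[float, float] = (0.4, 0.5)
    enc_channels: tuple[int, ...] = (64, 96, 112)
    mid_channels: tuple[int, ...] = (96, 112, 128)
    dec_channels: tuple[int, ...] = (64, 96, 112)
    dncnn_blocks: tuple[int, ...] = (3, 4, 5)
    learning_rate: tuple[float, float] = (1e-5, 1e-4)
    batch_size: tuple[int, ...] = (4, 6, 8)

    def __post_init__(self) -> None:
        for name in ("enc_channels", "mid_channels", "dec_channels", "dncnn_blocks", "batch_size"):
            if not getattr(self, name):
                raise ValueError(f"search space dimension {name} is empty")
        if not (0 < self.learning_rate[0] <= self.learning_rate[1]):
            raise ValueError("learning_rate bounds must be positive and ordered")

    def sample(self, rng: np.random.Generator) -> dict:
        lo, hi = self.learning_rate
        return {
            "dropout_rate": float(rng.uniform(*self.dropout)),
            "enc_channels": int(rng.choice(self.enc_channels)),
            "mid_channels": int(rng.choice(self.mid_channels)),
            "dec_channels": int(rng.choice(self.dec_channels)),
            "n_dncnn_blocks": int(rng.choice(self.dncnn_blocks)),
            "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            "batch_size": int(rng.choice(self.batch_size)),
        }

    def contains(self, cand: dict) -> bool:
        lo, hi = self.learning_rate
        return (
            self.dropout[0] <= cand["dropout_rate"] <= self.dropout[1]
            and cand["enc_channels"] in self.enc_channels
            and cand["mid_channels"] in self.mid_channels
            and cand["dec_channels"] in self.dec_channels
            and cand["n_dncnn_blocks"] in self.dncnn_blocks
            and lo <= cand["learning_rate"] <= hi
            and cand["batch_size"] in self.batch_size
        )


def _default_objective_factory(train_pairs, val_pairs, cfg: TrainConfig):
    def objective(cand: dict, seed: int) -> float:
        model_cfg = ErisNetConfig(
            enc_channels=cand["enc_channels"],
            mid_channels=cand["mid_channels"],
            dec_channels=cand["dec_channels"],
            n_dncnn_blocks=cand["n_dncnn_blocks"],
            dropout_rate=cand["dropout_rate"],
        )
        model = build_erisnet(model_cfg, seed=seed)
        run_cfg = replace(
            cfg,
            learning_rate=cand["learning_rate"],
            batch_size=cand["batch_size"],
            seed=seed,
        )
        _, history = train(model, train_pairs, val_pairs, run_cfg)
        return min(h["val_loss"] for h in history)

    return objective


def hyperparameter_search(
    space: SearchSpace,
    budget: int,
    seed: int = 0,
    objective=None,
    train_pairs: list[ImagePair] | None = None,
    val_pairs: list[ImagePair] | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[dict, list[dict]]:
    """Seeded random search over the space, minimising validation MSE.

    ``objective(candidate, seed) -> float`` may be supplied directly (e.g.
    for testing); otherwise it is built from the given train/val pairs.
    Returns the argmin candidate and the full trial log (replayable from
    the seed); the running best in the log is non-increasing.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if objective is None:
        if train_pairs is None or val_pairs is None:
            raise ValueError("provide either an objective or train/val pairs")
        objective = _default_objective_factory(train_pairs, val_pairs, train_config or TrainConfig())
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    best: dict | None = None
    best_obj = math.inf
    for trial in range(budget):
        cand = space.sample(rng)
        trial_seed = int(rng.integers(0, 2**31 - 1))
        value = float(objective(cand, trial_seed))
        if value < best_obj:
            best_obj, best = value, cand
        log.append(
            {"trial": trial, "candidate": cand, "seed": trial_seed, "objective": value, "best_so_far": best_obj}
        )
    assert best is not None
    return best, log
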