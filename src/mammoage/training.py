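"""Patient-wise splitting, the training loop, prediction and ensembling.

Splitting is at the patient level: 20% of patients form a held-out test
partition and the remainder are shuffled into five cross-validation folds,
so no patient's exams ever leak across partitions.

Training follows the standard schedule for this model family: Adam, an
initial learning rate decayed by a factor of 10 every 20 epochs, early
stopping when the validation loss has not decreased for 10 consecutive
epochs, and model selection by the best validation MAE (two distinct
criteria, kept separate on purpose).

Ensembling averages the per-exam predicted ages of several trained
backbones; the weights are inverse-validation-MAE ratios, normalized
within each fold and then averaged across folds.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam
from .model import MammoAgeModel, ModelConfig, compute_losses
from .preprocess import PreprocessConfig, augment, preprocess_exam
from .synthetic import ExamRecord

__all__ = ["SplitPlan", "TrainConfig", "EnsembleSpec", "split_patients",
           "load_exam_arrays", "train_model", "predict",
           "derive_ensemble_weights", "ensemble_predict", "desk_profile"]


@dataclass
class SplitPlan:
    test_patients: list[str]
    folds: list[list[str]]            # five cross-validation folds
    seed: int

    def __post_init__(self):
        all_cv = [p for fold in self.folds for p in fold]
        if set(self.test_patients) & set(all_cv):
            raise ValueError("test and cross-validation partitions overlap")
        if len(all_cv) != len(set(all_cv)):
            raise ValueError("a patient appears in more than one fold")

    def train_val_patients(self, val_fold: int) -> tuple[list[str], list[str]]:
        val = self.folds[val_fold]
        train = [p for i, fold in enumerate(self.folds) if i != val_fold for p in fold]
        return train, val


@dataclass
class TrainConfig:
    max_epochs: int = 100
    initial_lr: float = 1e-4
    lr_decay_every: int = 20          # epochs between x0.1 decays
    early_stop_patience: int = 10     # epochs without val-loss decrease
    dropout: float = 0.5
    batch_size: int = 8
    augment: bool = True
    grad_clip_norm: float = 5.0       # global-norm clip; 0 disables
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 0 or self.initial_lr <= 0 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if self.max_epochs > 0 and self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")

    def lr_at_epoch(self, epoch: int) -> float:
        return self.initial_lr * 10.0 ** (-(epoch // self.lr_decay_every))


@dataclass
class EnsembleSpec:
    member_ids: list[str]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("ensemble weights must be nonnegative and sum to 1")
        if len(self.member_ids) != self.weights.size:
            raise ValueError("one weight per member required")


def split_patients(manifest: pd.DataFrame, seed: int, n_folds: int = 5,
                   test_fraction: float = 0.2) -> SplitPlan:
    """Patient-level 80/20 test split plus five CV folds of the remainder."""
    patients = sorted(manifest["patient_id"].unique().tolist())
    if len(patients) < 10:
        raise ValueError("need at least 10 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    shuffled = [patients[i] for i in order]
    n_test = int(round(test_fraction * len(patients)))
    test = shuffled[:n_test]
    rest = shuffled[n_test:]
    folds = [list(chunk) for chunk in np.array_split(np.asarray(rest, dtype=object), n_folds)]
    return SplitPlan(test_patients=sorted(test), folds=[sorted(f) for f in folds],
                     seed=seed)


def _records_for(records: list[ExamRecord], patients: list[str]) -> list[ExamRecord]:
    keep = set(patients)
    return [r for r in records if r.patient_id in keep]


def load_exam_arrays(records: list[ExamRecord], pp: PreprocessConfig
                     ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Preprocess every exam once: (N, 4, H, W) images, ages, densities, ids."""
    X = np.stack([preprocess_exam(r.views, pp) for r in records])
    ages = np.array([r.chronological_age for r in records], dtype=np.float64)
    densities = [r.density_category for r in records]
    ids = [r.exam_id for r in records]
    return X, ages, densities, ids


def _clip_grad_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(p.grad ** 2)) for p in params
                        if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def _eval_model(model: MammoAgeModel, X: np.ndarray, ages: np.ndarray,
                densities: list[str], batch_size: int) -> tuple[float, float]:
    """Validation total loss and MAE (deterministic eval forward)."""
    losses, sizes, preds = [], [], []
    for lo in range(0, len(X), batch_size):
        sl = slice(lo, lo + batch_size)
        out = model.forward(X[sl], training=False)
        bundle = compute_losses(out, ages[sl], densities[sl], model.config)
        losses.append(bundle.total)
        sizes.append(len(ages[sl]))
        preds.append(out["exam_age"])
    preds = np.concatenate(preds)
    val_loss = float(np.average(losses, weights=sizes))
    return val_loss, float(np.mean(np.abs(preds - ages)))


def train_model(train_records: list[ExamRecord], val_records: list[ExamRecord],
                model_config: ModelConfig, train_config: TrainConfig,
                pp: PreprocessConfig | None = None,
                ) -> tuple[MammoAgeModel, pd.DataFrame]:
    """Train one model; returns the weights of the best-validation-MAE epoch.

    Early stopping watches the validation *loss* (patience epochs without a
    decrease); the returned checkpoint is the epoch with minimum validation
    *MAE*.  ``max_epochs=0`` returns the initial weights and empty history.
    """
    if not train_records or not val_records:
        raise ValueError("train and validation sets must be nonempty")
    tr_pat = {r.patient_id for r in train_records}
    va_pat = {r.patient_id for r in val_records}
    if tr_pat & va_pat:
        raise ValueError(f"patient leakage between train and val: {sorted(tr_pat & va_pat)}")

    pp = pp or PreprocessConfig()
    model_config = copy.deepcopy(model_config)
    model_config.dropout = train_config.dropout
    model = MammoAgeModel(model_config, seed=train_config.seed)
    rng = np.random.default_rng(train_config.seed)

    Xtr, ytr, dtr, _ = load_exam_arrays(train_records, pp)
    Xva, yva, dva, _ = load_exam_arrays(val_records, pp)

    history: list[dict] = []
    if train_config.max_epochs == 0:
        return model, pd.DataFrame(history,
                                   columns=["epoch", "lr", "train_loss", "val_loss", "val_mae"])

    opt = Adam(model.parameters(), lr=train_config.initial_lr)
    best_mae, best_params = np.inf, None
    best_val_loss, stale = np.inf, 0

    for epoch in range(train_config.max_epochs):
        opt.lr = train_config.lr_at_epoch(epoch)
        order = rng.permutation(len(Xtr))
        epoch_losses = []
        for lo in range(0, len(order), train_config.batch_size):
            idx = order[lo:lo + train_config.batch_size]
            batch = Xtr[idx]
            if train_config.augment:
                batch = np.stack([
                    np.stack([augment(v, pp.augmentation_policy, rng) for v in exam])
                    for exam in batch])
            out = model.forward(batch, training=True, rng=rng)
            bundle = compute_losses(out, ytr[idx], [dtr[i] for i in idx],
                                    model.config, rng=rng)
            if not np.isfinite(bundle.total):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}: "
                                   f"{bundle.terms}")
            opt.zero_grad()
            bundle.total_tensor.backward()
            if train_config.grad_clip_norm > 0:
                _clip_grad_norm(model.parameters(), train_config.grad_clip_norm)
            opt.step()
            epoch_losses.append(bundle.total)
        val_loss, val_mae = _eval_model(model, Xva, yva, dva, train_config.batch_size)
        history.append({"epoch": epoch, "lr": opt.lr,
                        "train_loss": float(np.mean(epoch_losses)),
                        "val_loss": val_loss, "val_mae": val_mae})
        if val_mae < best_mae:
            best_mae = val_mae
            best_params = {k: v.data.copy() for k, v in model.named_parameters().items()}
        if val_loss < best_val_loss - 1e-12:
            best_val_loss, stale = val_loss, 0
        else:
            stale += 1
            if stale >= train_config.early_stop_patience:
                break

    if best_params is not None:
        for k, p in model.named_parameters().items():
            p.data = best_params[k]
    return model, pd.DataFrame(history)


def predict(model: MammoAgeModel, records: list[ExamRecord],
            pp: PreprocessConfig | None = None, batch_size: int = 16) -> pd.DataFrame:
    """Deterministic inference: per-exam predicted age (mean of the four
    per-view expected ages), per-view ages, and density probabilities."""
    pp = pp or PreprocessConfig()
    X, ages, _, ids = load_exam_arrays(records, pp)
    rows = []
    for lo in range(0, len(X), batch_size):
        sl = slice(lo, lo + batch_size)
        out = model.forward(X[sl], training=False)
        for i, exam_idx in enumerate(range(lo, min(lo + batch_size, len(X)))):
            r = records[exam_idx]
            row = {"exam_id": r.exam_id, "patient_id": r.patient_id,
                   "age": r.chronological_age,
                   "predicted_age": float(out["exam_age"][i])}
            for v, key in enumerate(("RCC", "RMLO", "LCC", "LMLO")):
                row[f"age_{key}"] = float(out["view_ages"][i, v])
            for c, cat in enumerate("ABCD"):
                row[f"density_p{cat}"] = float(out["density_probs"].data[i, c])
            rows.append(row)
    return pd.DataFrame(rows)


def derive_ensemble_weights(fold_maes: dict[str, list[float]]) -> EnsembleSpec:
    """Inverse-MAE weights, normalized per fold, averaged across folds.

    ``fold_maes`` maps member id -> per-fold validation MAEs (same fold
    count for every member).
    """
    members = sorted(fold_maes)
    maes = np.array([fold_maes[m] for m in members], dtype=np.float64)
    if maes.ndim != 2 or len({len(v) for v in fold_maes.values()}) != 1:
        raise ValueError("every member needs the same number of fold MAEs")
    if np.any(maes <= 0):
        raise ValueError("validation MAEs must be positive")
    inv = 1.0 / maes                          # (members, folds)
    per_fold = inv / inv.sum(axis=0, keepdims=True)
    weights = per_fold.mean(axis=1)
    weights = weights / weights.sum()
    return EnsembleSpec(member_ids=members, weights=weights)


def ensemble_predict(member_predictions: dict[str, pd.DataFrame],
                     spec: EnsembleSpec) -> pd.DataFrame:
    """Weighted average of member predicted ages, joined on exam_id."""
    missing = [m for m in spec.member_ids if m not in member_predictions]
    if missing:
        raise ValueError(f"missing member predictions: {missing}")
    base = member_predictions[spec.member_ids[0]][["exam_id", "patient_id", "age"]].copy()
    acc = np.zeros(len(base))
    for m, w in zip(spec.member_ids, spec.weights):
        df = member_predictions[m].set_index("exam_id")
        if set(df.index) != set(base["exam_id"]):
            raise ValueError(f"member {m!r} does not cover every exam")
        acc = acc + w * df.loc[base["exam_id"], "predicted_age"].to_numpy()
    base["predicted_age"] = acc
    return base


#: loss weighting of the desk preset: cross-entropy as the main term with
#: the canonical mean/variance weights of the mean-variance formulation
#: (0.2 / 0.05) and a small KL weight so the ordinal embedding is shaped,
#: not crushed, by its Gaussian prior.
DESK_LOSS_WEIGHTS = {"ce_age": 1.0, "mean": 0.2, "variance": 0.05,
                     "poe_ordinal": 1.0, "poe_kl": 0.01, "density_ce": 1.0}


def desk_profile(seed: int = 0):
    """Desk-scale preset: a 60-patient cohort at 64x32 pixels and a
    tiny_cnn trained for up to 30 epochs — sized for a single CPU.

    Optimization is scaled to the few hundred gradient steps such a run
    affords: learning rate 1e-2, batch size 4, dropout 0.2 (the 32-channel
    pooled feature is too narrow for the full-scale 0.5).

    Returns (CohortConfig, PreprocessConfig, ModelConfig, TrainConfig).
    """
    from .synthetic import CohortConfig
    cohort = CohortConfig(n_patients=60, exams_per_patient=(1, 2),
                          image_shape=(64, 32), noise_sd=0.01,
                          cancer_fraction=0.0, seed=seed)
    pp = PreprocessConfig(target_shape=(64, 32),
                          augmentation_policy={"flip": {"prob": 0.5}})
    mc = ModelConfig(backbone_id="tiny_cnn", loss_weights=dict(DESK_LOSS_WEIGHTS))
    tc = TrainConfig(max_epochs=30, initial_lr=1e-2, batch_size=4,
                     early_stop_patience=10, dropout=0.2, seed=seed)
    return cohort, pp, mc, tc
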