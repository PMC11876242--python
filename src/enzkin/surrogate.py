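"""MLP surrogate mapping experimental conditions to MM parameters.

A fully connected feed-forward regressor takes condition features (enzyme
one-hot, pH, temperature, substrate one-hot, substrate concentration) and
predicts log(K_M) and log(k_cat). Labels are posterior medians from the
Bayesian inversion, so the surrogate amortizes the inversion across the
condition space. Hidden layers use the rectifier; the output layer is a
logistic squashed onto per-parameter [log min, log max] ranges, so
predictions can never leave the declared parameter ranges. Training is
full-batch (or mini-batch) gradient descent with the adaptive-moment (Adam)
optimizer on the mean-squared error of the bounded log-parameters, with an
80/20 train/test split stratified by enzyme.

All numerics are plain numpy; the forward pass, gradients and optimizer are
explicit so the model serializes to JSON and reruns bit-identically from its
seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .inference import Posterior
from .synthetic_data import ExperimentSet

__all__ = [
    "FEATURE_NAMES",
    "LABEL_NAMES",
    "SurrogateModel",
    "TrainingReport",
    "TrainingConfig",
    "features_from_condition",
    "build_training_table",
    "train_surrogate",
    "predict_parameters",
    "regression_diagnostics",
]

FEATURE_NAMES = (
    "enzyme_HRP",
    "enzyme_heme",
    "pH",
    "temperature_C",
    "substrate_ABTS",
    "substrate_H2O2",
    "substrate_conc_uM",
)
LABEL_NAMES = ("log_K_M", "log_kcat")

#: Fallback output ranges in log space; generous envelopes around the prior
#: support, used when ranges are neither configured nor derivable from data.
DEFAULT_RANGES = {"log_K_M": (0.0, np.log(1e4)), "log_kcat": (np.log(1e-2), np.log(1e3))}


def features_from_condition(cond) -> np.ndarray:
    """Numeric feature vector for one ExperimentCondition."""
    return np.array(
        [
            1.0 if cond.enzyme == "HRP" else 0.0,
            1.0 if cond.enzyme == "heme" else 0.0,
            cond.pH,
            cond.temperature_C,
            1.0 if cond.substrate == "ABTS" else 0.0,
            1.0 if cond.substrate == "H2O2" else 0.0,
            cond.substrate_conc_uM,
        ]
    )


def build_training_table(
    expset: ExperimentSet, posteriors: Dict[str, Posterior]
) -> pd.DataFrame:
    """Aligned feature/label table, one row per condition.

    ``posteriors`` maps condition_id to its posterior (conditions from the
    same assay series may share one object). Labels are the posterior medians
    of K_M and k_cat, log-transformed. Alignment is by condition_id, so the
    mapping's ordering is irrelevant.
    """
    missing = [c.condition_id for c in expset.conditions if c.condition_id not in posteriors]
    if missing:
        raise KeyError(f"missing posterior for conditions: {missing}")
    rows = []
    for cond in expset.conditions:
        post = posteriors[cond.condition_id]
        feats = features_from_condition(cond)
        row = {name: val for name, val in zip(FEATURE_NAMES, feats)}
        row["condition_id"] = cond.condition_id
        row["log_K_M"] = float(np.log(post.median("K_M")))
        row["log_kcat"] = float(np.log(post.median("k_cat")))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrainingConfig:
    hidden_sizes: tuple = (64, 64)
    lr: float = 5e-3
    lr_final_frac: float = 0.1  # geometric lr decay over the run
    weight_decay: float = 1e-4  # decoupled L2; keeps extrapolation smooth
    epochs: int = 800
    batch: Optional[int] = None  # None => full batch
    split_seed: int = 0
    init_seed: int = 0
    test_fraction: float = 0.2
    #: None => derive each label's [low, high] from the training labels with
    #: a 50% margin (a tight envelope makes the bounded logistic output
    #: well-resolved); still a hard output bound either way.
    ranges: Optional[Dict[str, tuple]] = None

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.lr <= 0 or not 0 < self.test_fraction < 1:
            raise ValueError("epochs, lr and test_fraction must be positive (fraction < 1)")
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")


@dataclass
class SurrogateModel:
    """Trained MLP with its normalization and output-range bounds."""

    weights: List[np.ndarray]
    biases: List[np.ndarray]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    out_low: np.ndarray  # per-label lower bound (log space)
    out_high: np.ndarray
    config: TrainingConfig

    def _forward(self, X: np.ndarray) -> Tuple[np.ndarray, List[np.ndarray]]:
        Z = (X - self.feature_mean) / self.feature_sd
        cache = [Z]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            Z = np.maximum(Z @ W + b, 0.0)  # rectifier
            cache.append(Z)
        logits = np.clip(Z @ self.weights[-1] + self.biases[-1], -500.0, 500.0)
        sig = 1.0 / (1.0 + np.exp(-logits))
        out = self.out_low + (self.out_high - self.out_low) * sig
        cache.append(sig)
        return out, cache

    def predict_log(self, X: np.ndarray) -> np.ndarray:
        """Bounded log-parameter predictions for a feature matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(FEATURE_NAMES) or not np.all(np.isfinite(X)):
            raise ValueError("malformed feature matrix")
        return self._forward(X)[0]

    def to_json(self) -> str:
        payload = {
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "out_low": self.out_low.tolist(),
            "out_high": self.out_high.tolist(),
            "config": {
                "hidden_sizes": list(self.config.hidden_sizes),
                "lr": self.config.lr,
                "lr_final_frac": self.config.lr_final_frac,
                "weight_decay": self.config.weight_decay,
                "epochs": self.config.epochs,
                "batch": self.config.batch,
                "split_seed": self.config.split_seed,
                "init_seed": self.config.init_seed,
                "test_fraction": self.config.test_fraction,
                "ranges": {
                    k: [float(self.out_low[j]), float(self.out_high[j])]
                    for j, k in enumerate(LABEL_NAMES)
                },
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModel":
        d = json.loads(text)
        cfg = d["config"]
        config = TrainingConfig(
            hidden_sizes=tuple(cfg["hidden_sizes"]),
            lr=cfg["lr"],
            lr_final_frac=cfg.get("lr_final_frac", 0.01),
            weight_decay=cfg.get("weight_decay", 1e-4),
            epochs=cfg["epochs"],
            batch=cfg["batch"],
            split_seed=cfg["split_seed"],
            init_seed=cfg["init_seed"],
            test_fraction=cfg["test_fraction"],
            ranges={k: tuple(v) for k, v in cfg["ranges"].items()},
        )
        return cls(
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            feature_mean=np.asarray(d["feature_mean"]),
            feature_sd=np.asarray(d["feature_sd"]),
            out_low=np.asarray(d["out_low"]),
            out_high=np.asarray(d["out_high"]),
            config=config,
        )


@dataclass(frozen=True)
class TrainingReport:
    train_idx: np.ndarray
    test_idx: np.ndarray
    epoch_rmse_train: np.ndarray
    epoch_rmse_test: np.ndarray
    final_test_rmse: Dict[str, float]
    final_test_r2: Dict[str, float]
    optimizer: str = "adam"


def _stratified_split(
    table: pd.DataFrame, test_fraction: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """80/20-style partition stratified by enzyme indicator."""
    rng = np.random.default_rng(seed)
    test: List[int] = []
    strata = table["enzyme_HRP"].to_numpy() if "enzyme_HRP" in table else np.zeros(len(table))
    for value in np.unique(strata):
        idx = np.flatnonzero(strata == value)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test.extend(idx[:n_test].tolist())
    test_idx = np.sort(np.array(test, dtype=int))
    train_idx = np.setdiff1d(np.arange(len(table)), test_idx)
    return train_idx, test_idx


def _rmse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def _derive_ranges(Y_train: np.ndarray) -> Dict[str, tuple]:
    """Per-label [low, high] envelope around the training labels.

    Half a label-span of margin on each side (at least one log unit, so
    degenerate constant labels still get a usable envelope).
    """
    ranges = {}
    for j, name in enumerate(LABEL_NAMES):
        lo, hi = float(Y_train[:, j].min()), float(Y_train[:, j].max())
        margin = max(0.5 * (hi - lo), 1.0)
        ranges[name] = (lo - margin, hi + margin)
    return ranges


def train_surrogate(
    table: pd.DataFrame, config: TrainingConfig = TrainingConfig()
) -> Tuple[SurrogateModel, TrainingReport]:
    """Train the MLP on a feature/label table from ``build_training_table``.

    Raises a training-failure error (with the epoch index) if the loss goes
    non-finite; both seeds fix the split and the weight initialization, so
    identical configs give identical RMSE histories.
    """
    if len(table) < 20:
        raise ValueError("need >= 20 rows to train")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    Y = table[list(LABEL_NAMES)].to_numpy(dtype=float)

    train_idx, test_idx = _stratified_split(table, config.test_fraction, config.split_seed)
    mean = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0)
    sd[sd == 0] = 1.0

    ranges = config.ranges or _derive_ranges(Y[train_idx])
    out_low = np.array([ranges[k][0] for k in LABEL_NAMES])
    out_high = np.array([ranges[k][1] for k in LABEL_NAMES])

    sizes = [len(FEATURE_NAMES), *config.hidden_sizes, len(LABEL_NAMES)]
    rng = np.random.default_rng(config.init_seed)
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    model = SurrogateModel(
        weights=weights,
        biases=biases,
        feature_mean=mean,
        feature_sd=sd,
        out_low=out_low,
        out_high=out_high,
        config=config,
    )

    # Adam state
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0

    Xtr, Ytr = X[train_idx], Y[train_idx]
    Xte, Yte = X[test_idx], Y[test_idx]
    batch = len(Xtr) if config.batch is None else min(config.batch, len(Xtr))
    batch_rng = np.random.default_rng(config.init_seed + 1)

    hist_train = np.empty(config.epochs)
    hist_test = np.empty(config.epochs)
    span = out_high - out_low

    for epoch in range(config.epochs):
        frac = epoch / max(config.epochs - 1, 1)
        lr = config.lr * config.lr_final_frac**frac
        order = batch_rng.permutation(len(Xtr)) if batch < len(Xtr) else np.arange(len(Xtr))
        for start in range(0, len(Xtr), batch):
            idx = order[start : start + batch]
            xb, yb = Xtr[idx], Ytr[idx]
            out, cache = model._forward(xb)
            err = out - yb  # (n, 2)
            if not np.all(np.isfinite(err)):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            n = len(xb)
            sig = cache[-1]
            # d loss / d logits through the bounded logistic output
            delta = (2.0 / n) * err * span * sig * (1.0 - sig)
            grads_w = []
            grads_b = []
            for layer in range(len(weights) - 1, -1, -1):
                act = cache[layer]
                grads_w.append(act.T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (cache[layer] > 0)
            grads_w.reverse()
            grads_b.reverse()
            t_step += 1
            for i in range(len(weights)):
                m_w[i] = beta1 * m_w[i] + (1 - beta1) * grads_w[i]
                v_w[i] = beta2 * v_w[i] + (1 - beta2) * grads_w[i] ** 2
                m_b[i] = beta1 * m_b[i] + (1 - beta1) * grads_b[i]
                v_b[i] = beta2 * v_b[i] + (1 - beta2) * grads_b[i] ** 2
                mh_w = m_w[i] / (1 - beta1**t_step)
                vh_w = v_w[i] / (1 - beta2**t_step)
                mh_b = m_b[i] / (1 - beta1**t_step)
                vh_b = v_b[i] / (1 - beta2**t_step)
                weights[i] -= lr * (mh_w / (np.sqrt(vh_w) + eps) + config.weight_decay * weights[i])
                biases[i] -= lr * mh_b / (np.sqrt(vh_b) + eps)
        hist_train[epoch] = _rmse(model.predict_log(Xtr), Ytr)
        hist_test[epoch] = _rmse(model.predict_log(Xte), Yte)

    pred_te = model.predict_log(Xte)
    final_rmse = {}
    final_r2 = {}
    for j, name in enumerate(LABEL_NAMES):
        final_rmse[name] = _rmse(pred_te[:, j], Yte[:, j])
        ss_res = float(np.sum((Yte[:, j] - pred_te[:, j]) ** 2))
        ss_tot = float(np.sum((Yte[:, j] - Yte[:, j].mean()) ** 2))
        final_r2[name] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    report = TrainingReport(
        train_idx=train_idx,
        test_idx=test_idx,
        epoch_rmse_train=hist_train,
        epoch_rmse_test=hist_test,
        final_test_rmse=final_rmse,
        final_test_r2=final_r2,
    )
    return model, report


def predict_parameters(model: SurrogateModel, features) -> Tuple[float, float]:
    """(K_M μM, k_cat 1/s) for one condition or feature vector.

    Outputs are always inside the configured parameter ranges (the output
    logistic guarantees it). Deterministic given the trained weights.
    """
    if hasattr(features, "enzyme"):
        features = features_from_condition(features)
    x = np.asarray(features, dtype=float).ravel()
    if x.shape != (len(FEATURE_NAMES),):
        raise ValueError(f"feature vector must have length {len(FEATURE_NAMES)}")
    log_pred = model.predict_log(x[None, :])[0]
    return float(np.exp(log_pred[0])), float(np.exp(log_pred[1]))


def regression_diagnostics(model: SurrogateModel, table: pd.DataFrame,
                           report: Optional[TrainingReport] = None) -> pd.DataFrame:
    """Per-row (label, prediction) pairs with R²/RMSE annotations.

    Mirrors a predicted-vs-Bayesian scatter: one row per condition and
    parameter, plus a split-membership flag when a report is supplied.
    """
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    pred = model.predict_log(X)
    in_test = np.zeros(len(table), dtype=bool)
    if report is not None:
        in_test[report.test_idx] = True
    frames = []
    for j, name in enumerate(LABEL_NAMES):
        y = table[name].to_numpy(dtype=float)
        ss_res = float(np.sum((y - pred[:, j]) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        frames.append(
            pd.DataFrame(
                {
                    "condition_id": table.get("condition_id", pd.RangeIndex(len(table))),
                    "parameter": name,
                    "label": y,
                    "prediction": pred[:, j],
                    "in_test_split": in_test,
                    "r2": r2,
                    "rmse": _rmse(pred[:, j], y),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
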