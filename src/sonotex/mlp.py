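"""Two-layer sigmoid MLP trained by scaled conjugate gradient (SCG).

The classifier is presented statsmodels-style: :class:`TextureMLP` is built
from data (``TextureMLP(X, y, ...)`` or ``TextureMLP.from_dataframe``), its
``fit`` runs Moller's SCG — a conjugate-gradient scheme that replaces the
line search with a second-order step-size estimate controlled by a
Levenberg-Marquardt-style damping parameter lambda — and returns an
:class:`MLPResults` carrying the weights, the per-epoch train/validation/
test MSE trace, the stop reason and prediction/summary methods.

Architecture and conventions
    input (min-max normalized to [-1, 1] on the training partition)
    -> n_hidden sigmoid units -> 2 sigmoid output units (one-hot targets,
    index 0 = normal, 1 = abnormal), mean-squared-error loss.  Hard labels
    take the argmax of the two output scores; exact ties resolve to
    abnormal (the safer call for a disease screen).  ROC analysis uses the
    abnormal unit's score.

Early stopping follows the classic pattern-recognition recipe: training
halts when the validation MSE has risen for ``max_validation_failures``
consecutive epochs, and the best-validation weights are restored.
``fit_until`` / ``retrain_until`` repeat training with incremented seeds
until a validation-accuracy bar is met, mirroring the retrain-on-poor-fit
loop of interactive neural-network tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import table_to_arrays

__all__ = [
    "TrainConfig",
    "SplitAssignment",
    "TextureMLP",
    "MLPResults",
    "split_data",
    "forward",
    "scg_train",
    "predict",
    "retrain_until",
]

PARTITIONS = ("train", "validation", "test")


@dataclass
class TrainConfig:
    n_hidden: int = 10
    max_epochs: int = 1000
    max_validation_failures: int = 6
    min_gradient_norm: float = 1e-6
    seed: int = 0
    sigma_scg: float = 5e-5
    lambda_init: float = 5e-7

    def validate(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class SplitAssignment:
    """Per-case partition labels from a stratified random split."""

    labels: np.ndarray           # array of "train" / "validation" / "test"
    proportions: tuple[float, float, float]
    seed: int
    stratified: bool = True

    def indices(self, partition: str) -> np.ndarray:
        return np.flatnonzero(self.labels == partition)


def split_data(table: pd.DataFrame,
               proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
               seed: int = 0) -> SplitAssignment:
    """Stratified random train/validation/test assignment.

    Within each class, counts are allocated by largest remainder so the
    partition is exact; a partition with positive proportion that would
    receive zero cases in some class raises.
    """
    if abs(sum(proportions) - 1.0) > 1e-9 or min(proportions) < 0:
        raise ValueError("proportions must be non-negative and sum to 1")
    y = table["class"].to_numpy()
    labels = np.empty(len(y), dtype=object)
    rng = np.random.default_rng(seed)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = len(idx)
        quota = np.array([p * n for p in proportions])
        counts = np.floor(quota).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(quota - counts))
        for j in range(rem):
            counts[order[j % 3]] += 1
        for part, prop, cnt in zip(PARTITIONS, proportions, counts):
            if prop > 0 and cnt == 0:
                raise ValueError(
                    f"infeasible proportions: class {cls!r} gets no "
                    f"{part} cases at n={n}"
                )
        pos = 0
        for part, cnt in zip(PARTITIONS, counts):
            labels[idx[pos:pos + cnt]] = part
            pos += cnt
    return SplitAssignment(labels=labels, proportions=tuple(proportions),
                           seed=seed, stratified=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class TextureMLP:
    """Two-layer sigmoid network for normal-vs-abnormal classification.

    Parameters
    ----------
    X : (n_cases, n_features) feature matrix.
    y : length-n labels, strings "normal"/"abnormal" or 0/1 (1 = abnormal).
    feature_names : names aligned with X's columns.
    n_hidden : hidden-layer width (the classic pattern-recognition default
        of 10 unless overridden).
    """

    def __init__(self, X, y, feature_names=None, n_hidden: int = 10):
        self.X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if y.dtype.kind in "USO":
            self.y = (y == "abnormal").astype(int)
        else:
            self.y = y.astype(int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n_cases, n_features) aligned with y")
        self.n_features = self.X.shape[1]
        self.feature_names = (list(feature_names) if feature_names is not None
                              else [f"x{i}" for i in range(self.n_features)])
        if len(self.feature_names) != self.n_features:
            raise ValueError("feature_names length must match X columns")
        self.n_hidden = int(n_hidden)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, n_hidden: int = 10,
                       feature_subset: list[str] | None = None) -> "TextureMLP":
        """Build from a feature table with a ``class`` column."""
        X, y, names = table_to_arrays(table)
        if feature_subset is not None:
            cols = [names.index(f) for f in feature_subset]
            X = X[:, cols]
            names = list(feature_subset)
        return cls(X, y, feature_names=names, n_hidden=n_hidden)

    # -- parameter vector helpers -------------------------------------------

    def _shapes(self):
        h, n = self.n_hidden, self.n_features
        return [(h, n), (h,), (2, h), (2,)]

    def _unpack(self, w: np.ndarray):
        parts = []
        pos = 0
        for shp in self._shapes():
            size = int(np.prod(shp))
            parts.append(w[pos:pos + size].reshape(shp))
            pos += size
        return parts  # W1, b1, W2, b2

    def _n_params(self) -> int:
        return sum(int(np.prod(s)) for s in self._shapes())

    # -- forward / loss / gradient ------------------------------------------

    def _forward(self, w: np.ndarray, Xn: np.ndarray):
        W1, b1, W2, b2 = self._unpack(w)
        A = _sigmoid(Xn @ W1.T + b1)
        Y = _sigmoid(A @ W2.T + b2)
        return A, Y

    def _loss(self, w: np.ndarray, Xn: np.ndarray, T: np.ndarray) -> float:
        _, Y = self._forward(w, Xn)
        return float(np.mean((Y - T) ** 2))

    def _grad(self, w: np.ndarray, Xn: np.ndarray, T: np.ndarray) -> np.ndarray:
        """Backpropagated gradient of the mean squared error."""
        W1, b1, W2, b2 = self._unpack(w)
        A = _sigmoid(Xn @ W1.T + b1)
        Y = _sigmoid(A @ W2.T + b2)
        n = Xn.shape[0]
        scale = 2.0 / (n * T.shape[1])
        dZ2 = scale * (Y - T) * Y * (1 - Y)          # (n, 2)
        gW2 = dZ2.T @ A
        gb2 = dZ2.sum(axis=0)
        dA = dZ2 @ W2                                 # (n, h)
        dZ1 = dA * A * (1 - A)
        gW1 = dZ1.T @ Xn
        gb1 = dZ1.sum(axis=0)
        return np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])

    # -- fitting -------------------------------------------------------------

    def fit(self, split: SplitAssignment | None = None,
            config: TrainConfig | None = None, seed: int | None = None) -> "MLPResults":
        """Train by scaled conjugate gradient; returns :class:`MLPResults`.

        Deterministic for a fixed seed and input ordering.  Stop reasons:
        ``max_epochs``, ``gradient`` (norm below ``min_gradient_norm``) or
        ``validation`` (patience exhausted; best-validation weights
        restored).
        """
        config = config or TrainConfig()
        if seed is not None:
            config = replace(config, seed=seed)
        config.validate()

        if split is None:
            labels = np.array(["train"] * len(self.y), dtype=object)
            split = SplitAssignment(labels=labels, proportions=(1.0, 0.0, 0.0),
                                    seed=config.seed)
        idx_tr = split.indices("train")
        if len(np.unique(self.y[idx_tr])) < 2:
            raise ValueError("training partition must contain both classes")

        # normalization to [-1, 1] from the training partition
        lo = self.X[idx_tr].min(axis=0)
        hi = self.X[idx_tr].max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)

        def norm(X):
            return np.clip(2.0 * (X - lo) / span - 1.0, -1.0, 1.0)

        T_all = np.column_stack([1.0 - self.y, self.y]).astype(float)
        Xn = {p: norm(self.X[split.indices(p)]) for p in PARTITIONS}
        T = {p: T_all[split.indices(p)] for p in PARTITIONS}

        rng = np.random.default_rng(config.seed)
        w = rng.uniform(-0.5, 0.5, size=self._n_params())

        trace, stop_reason, epochs = self._scg(w, Xn, T, config)

        results = MLPResults(
            model=self, weights=w.copy(), normalization=(lo.copy(), hi.copy()),
            split=split, config=config, trace=trace, stop_reason=stop_reason,
            epochs_run=epochs,
        )
        return results

    def _scg(self, w: np.ndarray, Xn: dict, T: dict, config: TrainConfig):
        """Moller's SCG on the training partition; mutates ``w`` in place and
        returns (trace DataFrame, stop_reason, epochs_run)."""
        Xtr, Ttr = Xn["train"], T["train"]
        has_val = len(Xn["validation"]) > 0
        has_test = len(Xn["test"]) > 0

        sigma0 = config.sigma_scg
        lam = config.lambda_init
        lam_bar = 0.0
        success = True
        N = w.size

        r = -self._grad(w, Xtr, Ttr)
        p = r.copy()
        f_w = self._loss(w, Xtr, Ttr)
        delta = 1.0
        mu = 0.0

        best_val = np.inf
        best_w = w.copy()
        fail_streak = 0
        rows = []
        stop_reason = "max_epochs"
        epochs = 0

        def record(epoch: int) -> None:
            rows.append({
                "epoch": epoch,
                "train_mse": self._loss(w, Xtr, Ttr),
                "validation_mse": self._loss(w, Xn["validation"], T["validation"]) if has_val else np.nan,
                "test_mse": self._loss(w, Xn["test"], T["test"]) if has_test else np.nan,
            })

        record(0)
        if has_val:
            best_val = rows[0]["validation_mse"]

        for epoch in range(1, config.max_epochs + 1):
            epochs = epoch
            p_norm2 = float(p @ p)
            if p_norm2 == 0:
                stop_reason = "gradient"
                break
            if success:
                sigma = sigma0 / np.sqrt(p_norm2)
                g_plus = self._grad(w + sigma * p, Xtr, Ttr)
                g_now = -r
                s = (g_plus - g_now) / sigma
                delta = float(p @ s)
            delta_adj = delta + (lam - lam_bar) * p_norm2
            if delta_adj <= 0:
                lam_bar = 2.0 * (lam - delta_adj / p_norm2)
                delta_adj = -delta_adj + lam * p_norm2
                lam = lam_bar
            mu = float(p @ r)
            alpha = mu / delta_adj
            f_new = self._loss(w + alpha * p, Xtr, Ttr)
            Delta = 2.0 * delta_adj * (f_w - f_new) / mu**2

            if Delta >= 0:
                w += alpha * p
                f_w = f_new
                r_new = -self._grad(w, Xtr, Ttr)
                lam_bar = 0.0
                success = True
                if epoch % N == 0:
                    p = r_new.copy()          # periodic restart
                else:
                    beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                    p = r_new + beta * p
                r = r_new
                if Delta >= 0.75:
                    lam = max(lam / 4.0, 1e-20)
            else:
                lam_bar = lam
                success = False
            if Delta < 0.25:
                lam = lam + delta_adj * (1.0 - Delta) / p_norm2
            lam = min(lam, 1e20)

            record(epoch)
            grad_norm = float(np.linalg.norm(r))
            if has_val:
                val = rows[-1]["validation_mse"]
                if val < best_val - 1e-15:
                    best_val = val
                    best_w = w.copy()
                    fail_streak = 0
                else:
                    fail_streak += 1
                    if fail_streak >= config.max_validation_failures:
                        stop_reason = "validation"
                        break
            if grad_norm < config.min_gradient_norm:
                stop_reason = "gradient"
                break
        else:
            stop_reason = "max_epochs"

        if has_val:
            w[:] = best_w
        return pd.DataFrame(rows), stop_reason, epochs

    def fit_until(self, split: SplitAssignment | None = None,
                  config: TrainConfig | None = None,
                  min_accuracy: float = 0.9, max_restarts: int = 5) -> "MLPResults":
        """Retrain with incremented seeds until validation accuracy reaches
        ``min_accuracy`` or restarts are exhausted; returns the
        best-validation-accuracy model (best effort)."""
        if max_restarts < 1:
            raise ValueError("max_restarts must be >= 1")
        config = config or TrainConfig()
        best: MLPResults | None = None
        best_acc = -1.0
        attempts = []
        for k in range(max_restarts):
            res = self.fit(split=split, config=replace(config, seed=config.seed + k))
            acc = res.validation_accuracy()
            attempts.append({"restart": k, "seed": config.seed + k,
                             "validation_accuracy": acc})
            if acc > best_acc:
                best, best_acc = res, acc
            if acc >= min_accuracy:
                break
        best.restart_log = pd.DataFrame(attempts)
        return best


@dataclass
class MLPResults:
    """Fitted network: weights, normalization, training trace and
    prediction utilities."""

    model: TextureMLP
    weights: np.ndarray
    normalization: tuple[np.ndarray, np.ndarray]   # per-feature (min, max)
    split: SplitAssignment
    config: TrainConfig
    trace: pd.DataFrame
    stop_reason: str
    epochs_run: int
    restart_log: pd.DataFrame | None = field(default=None, compare=False)

    @property
    def final_mse(self) -> float:
        return float(self.trace["train_mse"].iloc[-1])

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.normalization
        span = np.where(hi > lo, hi - lo, 1.0)
        return np.clip(2.0 * (np.asarray(X, dtype=float) - lo) / span - 1.0, -1.0, 1.0)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) array of (score_normal, score_abnormal) in (0, 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.model.n_features:
            raise ValueError(
                f"expected {self.model.n_features} features, got {X.shape[1]}"
            )
        _, Y = self.model._forward(self.weights, self._normalize(X))
        return Y

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard labels; exact score ties resolve to abnormal."""
        s = self.scores(X)
        return np.where(s[:, 1] >= s[:, 0], "abnormal", "normal")

    def accuracy(self, X: np.ndarray, y) -> float:
        y = np.asarray(y)
        if y.dtype.kind not in "USO":
            y = np.where(y.astype(int) == 1, "abnormal", "normal")
        if len(y) == 0:
            return np.nan
        return float(np.mean(self.predict(X) == y))

    def _partition_accuracy(self, partition: str) -> float:
        idx = self.split.indices(partition)
        if len(idx) == 0:
            return np.nan
        return self.accuracy(self.model.X[idx], self.model.y[idx])

    def validation_accuracy(self) -> float:
        acc = self._partition_accuracy("validation")
        # with no validation partition fall back to train accuracy
        return acc if np.isfinite(acc) else self._partition_accuracy("train")

    def summary(self) -> str:
        lines = [
            "Two-layer sigmoid MLP (scaled conjugate gradient)",
            "=" * 49,
            f"features:        {self.model.n_features}",
            f"hidden units:    {self.model.n_hidden}",
            f"seed:            {self.config.seed}",
            f"epochs run:      {self.epochs_run}",
            f"stop reason:     {self.stop_reason}",
            f"final train MSE: {self.final_mse:.6f}",
        ]
        for part in PARTITIONS:
            acc = self._partition_accuracy(part)
            if np.isfinite(acc):
                lines.append(f"{part + ' accuracy:':<17}{100 * acc:.1f}%")
        return "\n".join(lines)

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        W1, b1, W2, b2 = self.model._unpack(self.weights)
        lo, hi = self.normalization
        payload = {
            "feature_names": self.model.feature_names,
            "n_hidden": self.model.n_hidden,
            "W1": W1.tolist(), "b1": b1.tolist(),
            "W2": W2.tolist(), "b2": b2.tolist(),
            "norm_min": lo.tolist(), "norm_max": hi.tolist(),
            "seed": self.config.seed,
            "epochs_run": self.epochs_run,
            "stop_reason": self.stop_reason,
            "final_mse": self.final_mse,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def from_json(path: str | Path) -> "MLPResults":
        payload = json.loads(Path(path).read_text())
        names = payload["feature_names"]
        n_f = len(names)
        model = TextureMLP(np.zeros((2, n_f)), np.array([0, 1]),
                           feature_names=names, n_hidden=payload["n_hidden"])
        w = np.concatenate([
            np.asarray(payload["W1"], dtype=float).ravel(),
            np.asarray(payload["b1"], dtype=float),
            np.asarray(payload["W2"], dtype=float).ravel(),
            np.asarray(payload["b2"], dtype=float),
        ])
        labels = np.array(["train", "train"], dtype=object)
        split = SplitAssignment(labels=labels, proportions=(1.0, 0.0, 0.0),
                                seed=payload["seed"])
        cfg = TrainConfig(n_hidden=payload["n_hidden"], seed=payload["seed"])
        trace = pd.DataFrame([{"epoch": payload["epochs_run"],
                               "train_mse": payload["final_mse"],
                               "validation_mse": np.nan, "test_mse": np.nan}])
        return MLPResults(
            model=model, weights=w,
            normalization=(np.asarray(payload["norm_min"], dtype=float),
                           np.asarray(payload["norm_max"], dtype=float)),
            split=split, config=cfg, trace=trace,
            stop_reason=payload["stop_reason"], epochs_run=payload["epochs_run"],
        )


# -- functional wrappers matching the pipeline-stage vocabulary --------------

def forward(results: MLPResults, x: np.ndarray) -> tuple[float, float]:
    """(score_normal, score_abnormal) for one feature vector."""
    s = results.scores(np.atleast_2d(x))[0]
    return float(s[0]), float(s[1])


def scg_train(table: pd.DataFrame, split: SplitAssignment,
              config: TrainConfig | None = None) -> MLPResults:
    config = config or TrainConfig()
    model = TextureMLP.from_dataframe(table, n_hidden=config.n_hidden)
    return model.fit(split=split, config=config)


def predict(results: MLPResults, table: pd.DataFrame) -> pd.DataFrame:
    """Per-case scores and hard labels for a feature table."""
    if len(table) == 0:
        return pd.DataFrame(columns=["case_id", "score_normal",
                                     "score_abnormal", "predicted"])
    cols = results.model.feature_names
    X = table[cols].to_numpy(dtype=float)
    s = results.scores(X)
    return pd.DataFrame({
        "case_id": table["case_id"] if "case_id" in table else np.arange(len(table)),
        "score_normal": s[:, 0],
        "score_abnormal": s[:, 1],
        "predicted": results.predict(X),
    })


def retrain_until(table: pd.DataFrame, split: SplitAssignment,
                  config: TrainConfig | None = None,
                  min_accuracy: float = 0.9, max_restarts: int = 5) -> MLPResults:
    config = config or TrainConfig()
    model = TextureMLP.from_dataframe(table, n_hidden=config.n_hidden)
    return model.fit_until(split=split, config=config,
                           min_accuracy=min_accuracy, max_restarts=max_restarts)
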