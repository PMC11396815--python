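"""Regression learners, evaluation metrics, and the input-fusion matrix.

Three learners predict plot-level soil moisture from screened features:

* ``XGBoost`` — gradient-boosted trees at the published working point
  (100 estimators, learning rate 0.03, max depth 5), backed by
  scikit-learn's :class:`~sklearn.ensemble.GradientBoostingRegressor`;
* ``RF`` — random forest with 100 trees;
* ``GA-BP`` — a feedforward backpropagation network (one hidden layer of 5
  sigmoid units, linear output) whose initial weights are picked by a small
  genetic algorithm, implemented here from scratch.

Models are compared on a held-out third of the plots via R^2, RMSE and mean
relative error, across ten single- and fused-input combinations of the four
feature families (VIs, TF, TIs, TVIs).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor

from .errors import ConfigurationError, DomainError
from .screening import FAMILIES, ScreeningRecord

__all__ = [
    "COMBINATIONS",
    "MODEL_KINDS",
    "SplitSpec",
    "GABPConfig",
    "LearnerConfig",
    "split_data",
    "GABPRegressor",
    "train_gabp",
    "train_model",
    "metrics",
    "evaluate_combinations",
]

MODEL_KINDS = ("XGBoost", "RF", "GA-BP")

#: The ten single- and fused-input rows of the evaluation matrix.
COMBINATIONS = (
    "VIs", "TF", "TIs", "TVIs",
    "VIs+TIs", "TVIs+VIs", "TVIs+TIs",
    "VIs+TIs+TVIs", "VIs+TIs+TF", "VIs+TIs+TF+TVIs",
)


@dataclass(frozen=True)
class SplitSpec:
    """Seeded 2:1 train/validation split."""

    n_total: int
    train_fraction: float = 2.0 / 3.0
    seed: int = 0


@dataclass(frozen=True)
class GABPConfig:
    """GA-BP hyperparameters (published working point as defaults)."""

    population_size: int = 5
    generations: int = 50
    crossover_rate: float = 0.4
    mutation_rate: float = 0.05
    hidden_nodes: int = 5
    max_epochs: int = 1000
    training_goal: float = 1e-6
    learning_rate: float = 0.5
    refine_epochs: int = 20  # short BP refinement inside the GA fitness
    seed: int = 0

    def validate(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("population_size", "generations", "hidden_nodes",
                     "max_epochs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass(frozen=True)
class LearnerConfig:
    """Hyperparameters for the three learners."""

    xgboost: dict = field(default_factory=lambda: {
        "n_estimators": 100, "learning_rate": 0.03, "max_depth": 5})
    random_forest: dict = field(default_factory=lambda: {"n_trees": 100})
    gabp: GABPConfig = field(default_factory=GABPConfig)


def split_data(ids: Sequence, spec: SplitSpec) -> tuple[list, list]:
    """Seeded uniform random split of plot ids into train/validation."""
    ids = list(ids)
    n = len(ids)
    if n != spec.n_total:
        raise DomainError(f"ids length {n} != spec.n_total {spec.n_total}")
    if n < 6:
        raise DomainError(f"need at least 6 samples to split, got {n}")
    n_train = int(round(spec.train_fraction * n))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in perm[:n_train]]
    val = [ids[i] for i in perm[n_train:]]
    return train, val


# ---------------------------------------------------------------------------
# GA-BP


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class GABPRegressor:
    """Backpropagation network with GA-chosen initial weights.

    Internals operate on min-max-scaled inputs and targets (fitted on the
    training data and stored with the model); the training goal applies to
    the scaled mean-squared error. Backpropagation is full-batch gradient
    descent with an adaptive step (grow 1.05 on improvement, shrink 0.7 and
    reject the step otherwise), which is deterministic and robust across
    input dimensions.
    """

    def __init__(self, cfg: GABPConfig):
        cfg.validate()
        self.cfg = cfg
        self._w: np.ndarray | None = None
        self._n_features: int | None = None
        self._x_lo = self._x_span = None
        self._y_lo = self._y_span = None
        self._constant: float | None = None

    # -- genome layout -----------------------------------------------------
    def _shapes(self, d: int):
        h = self.cfg.hidden_nodes
        return (d, h)

    def _unpack(self, w: np.ndarray, d: int):
        h = self.cfg.hidden_nodes
        k = 0
        W1 = w[k:k + d * h].reshape(d, h); k += d * h
        b1 = w[k:k + h]; k += h
        W2 = w[k:k + h]; k += h
        b2 = w[k]
        return W1, b1, W2, b2

    def _forward(self, w: np.ndarray, X: np.ndarray) -> np.ndarray:
        W1, b1, W2, b2 = self._unpack(w, X.shape[1])
        return _sigmoid(X @ W1 + b1) @ W2 + b2

    def _mse(self, w: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean((self._forward(w, X) - y) ** 2))

    def _grad(self, w: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        W1, b1, W2, b2 = self._unpack(w, X.shape[1])
        H = _sigmoid(X @ W1 + b1)
        yhat = H @ W2 + b2
        n = len(y)
        e = 2.0 * (yhat - y) / n
        gW2 = H.T @ e
        gb2 = e.sum()
        dH = np.outer(e, W2) * H * (1.0 - H)
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        return np.concatenate([gW1.ravel(), gb1, gW2, [gb2]])

    def _backprop(self, w: np.ndarray, X: np.ndarray, y: np.ndarray,
                  epochs: int) -> tuple[np.ndarray, float]:
        lr = self.cfg.learning_rate
        w = w.copy()
        mse = self._mse(w, X, y)
        for _ in range(epochs):
            if mse <= self.cfg.training_goal:
                break
            cand = w - lr * self._grad(w, X, y)
            cand_mse = self._mse(cand, X, y)
            if cand_mse < mse:
                w, mse = cand, cand_mse
                lr *= 1.05
            else:
                lr *= 0.7
                if lr < 1e-12:
                    break
        return w, mse

    # -- fitting -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "GABPRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise DomainError("X must be 2-D with one row per target value")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise DomainError("GA-BP inputs must be finite")
        if len(y) < self.cfg.population_size:
            raise DomainError("fewer samples than GA population size")
        self._n_features = X.shape[1]

        self._x_lo = X.min(axis=0)
        self._x_span = np.where(np.ptp(X, axis=0) > 0, np.ptp(X, axis=0), 1.0)
        Xs = (X - self._x_lo) / self._x_span
        self._y_lo = float(y.min())
        yspan = float(np.ptp(y))
        if yspan == 0:
            warnings.warn("constant training target: GA-BP degenerates to a "
                          "constant predictor", stacklevel=2)
            self._constant = float(y[0])
            return self
        self._y_span = yspan
        ys = (y - self._y_lo) / yspan

        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        d = X.shape[1]
        n_w = d * cfg.hidden_nodes + cfg.hidden_nodes + cfg.hidden_nodes + 1
        pop = rng.uniform(-1.0, 1.0, size=(cfg.population_size, n_w))

        def fitness(genome: np.ndarray) -> float:
            _, mse = self._backprop(genome, Xs, ys, cfg.refine_epochs)
            return mse

        mses = np.array([fitness(g) for g in pop])
        for _ in range(cfg.generations):
            elite = pop[mses.argmin()].copy()
            # fitness-proportional selection on inverse MSE
            inv = 1.0 / (mses + 1e-12)
            probs = inv / inv.sum()
            idx = rng.choice(cfg.population_size, size=cfg.population_size,
                             p=probs)
            new = pop[idx].copy()
            # arithmetic crossover between consecutive parents
            for i in range(0, cfg.population_size - 1, 2):
                if rng.random() < cfg.crossover_rate:
                    alpha = rng.random()
                    a, b = new[i].copy(), new[i + 1].copy()
                    new[i] = alpha * a + (1 - alpha) * b
                    new[i + 1] = alpha * b + (1 - alpha) * a
            # Gaussian mutation, gene-wise
            mmask = rng.random(new.shape) < cfg.mutation_rate
            new = new + mmask * rng.normal(0.0, 0.5, size=new.shape)
            new[0] = elite  # elitism of 1
            pop = new
            mses = np.array([fitness(g) for g in pop])

        best = pop[mses.argmin()]
        self._w, _ = self._backprop(best, Xs, ys, cfg.max_epochs)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._constant is not None:
            return np.full(len(X), self._constant)
        if self._w is None:
            raise DomainError("model is not fitted")
        Xs = (X - self._x_lo) / self._x_span
        ys = self._forward(self._w, Xs)
        return ys * self._y_span + self._y_lo


def train_gabp(X, y, cfg: GABPConfig | None = None) -> GABPRegressor:
    """Fit a GA-BP network; deterministic given ``cfg.seed``."""
    return GABPRegressor(cfg or GABPConfig()).fit(X, y)


def train_model(kind: str, X, y, cfg: LearnerConfig | None = None,
                seed: int = 0):
    """Fit one of the three learners; the result exposes ``predict(X)``."""
    cfg = cfg or LearnerConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 6:
        raise DomainError("need at least 6 training rows")
    if kind == "XGBoost":
        xp = cfg.xgboost
        model = GradientBoostingRegressor(
            n_estimators=xp["n_estimators"],
            learning_rate=xp["learning_rate"],
            max_depth=xp["max_depth"],
            random_state=seed % 2**31,
        )
        return model.fit(X, y)
    if kind == "RF":
        model = RandomForestRegressor(
            n_estimators=cfg.random_forest["n_trees"],
            random_state=seed % 2**31,
        )
        return model.fit(X, y)
    if kind == "GA-BP":
        gcfg = GABPConfig(**{**vars(cfg.gabp), "seed": seed % 2**31})
        return train_gabp(X, y, gcfg)
    raise ConfigurationError(f"unknown model kind {kind!r}")


def metrics(y, yhat, printed_variant: bool = False) -> tuple[float, float, float]:
    """(R^2, RMSE, MRE%) of predictions against observations.

    Default: standard definitions — R^2 = 1 - SSE/SST, RMSE on prediction
    errors, MRE = mean |error|/y x 100. ``printed_variant=True`` switches to
    the published compatibility forms (R^2 as explained-variance ratio
    sum(yhat-ybar)^2 / sum(y-ybar)^2 and RMSE on deviations from the mean),
    kept only for comparison against sources using them.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise DomainError("metrics need two equal-length vectors, n >= 2")
    ybar = y.mean()
    sst = ((y - ybar) ** 2).sum()
    if sst == 0:
        raise DomainError("R^2 undefined: zero target variance")
    if np.any(y == 0):
        raise DomainError("MRE undefined: target contains zero")
    n = y.size
    if printed_variant:
        r2 = float(((yhat - ybar) ** 2).sum() / sst)
        rmse = float(np.sqrt(sst / n))
    else:
        sse = ((yhat - y) ** 2).sum()
        r2 = float(1.0 - sse / sst)
        rmse = float(np.sqrt(sse / n))
    mre = float(np.mean(np.abs(yhat - y) / np.abs(y)) * 100.0)
    return r2, rmse, mre


def _selected_by_family(
    records: Sequence[ScreeningRecord], layer: str
) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {fam: [] for fam in FAMILIES}
    for rec in records:
        if rec.layer == layer and rec.selected and rec.family in out:
            out[rec.family].append(rec.feature_name)
    return out


def evaluate_combinations(
    features: pd.DataFrame,
    records: Sequence[ScreeningRecord],
    smc_by_layer: dict[str, np.ndarray],
    split: SplitSpec,
    cfg: LearnerConfig | None = None,
    combinations: Sequence[str] = COMBINATIONS,
    models: Sequence[str] = MODEL_KINDS,
    smc_scale: float = 100.0,
) -> pd.DataFrame:
    """Validation metrics for every (layer, input combination, model) cell.

    ``features`` is plots x features (row order matches the smc vectors);
    only screened-in features enter each cell. SMC is scaled by
    ``smc_scale`` (fraction -> percent by default) before computing metrics,
    so RMSE is in % SMC. Cells whose combination has an empty selected
    family are emitted with NaN metrics and a reason.
    """
    cfg = cfg or LearnerConfig()
    n = len(features)
    idx = np.arange(n)
    train_ids, val_ids = split_data(list(idx), split)
    rows = []
    for layer, smc in smc_by_layer.items():
        y = np.asarray(smc, dtype=float) * smc_scale
        by_fam = _selected_by_family(records, layer)
        for combo in combinations:
            fams = combo.split("+")
            missing = [f for f in fams if not by_fam.get(f)]
            cols: list[str] = []
            for f in fams:
                cols.extend(by_fam.get(f, []))
            for kind in models:
                if missing:
                    rows.append({
                        "layer": layer, "combination": combo, "model": kind,
                        "r2": np.nan, "rmse_pct": np.nan, "mre_pct": np.nan,
                        "n_features": 0,
                        "note": f"no selected features in {'+'.join(missing)}",
                    })
                    continue
                X = features[cols].to_numpy(dtype=float)
                tag = zlib.crc32(f"{layer}|{combo}|{kind}".encode())
                seed = (split.seed * 1000003 + tag) % 2**31
                model = train_model(kind, X[train_ids], y[train_ids], cfg,
                                    seed=seed)
                yhat = model.predict(X[val_ids])
                r2, rmse, mre = metrics(y[val_ids], yhat)
                rows.append({
                    "layer": layer, "combination": combo, "model": kind,
                    "r2": r2, "rmse_pct": rmse, "mre_pct": mre,
                    "n_features": len(cols), "note": "",
                })
    return pd.DataFrame(rows)
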