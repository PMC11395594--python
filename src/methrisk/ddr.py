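"""Early/late disease-stage classification from the marker CpG panel.

The classifier is a multilayer perceptron over the panel's beta values with
a single sigmoid output (probability of late stage, label 1).  Model
selection follows a nested cross-validation protocol: stratified outer folds
estimate generalization; within each outer training set, a grid search over
architecture and optimization hyperparameters is scored by stratified
3-fold inner cross-validation on mean AUC; the winning configuration is
refit on the full outer training set and scored once on the outer test
fold.  The grid spans hidden-layer count {2, 5, 8}, width {16, 32, 48},
dropout {0, 0.1}, batch normalization, L1/L2/Elastic-Net regularization,
ReLU/SeLU activations and learning rates {0.0002, 0.0005, 0.001}; fixed
across the grid are the Adam optimizer, batch size 128, 200 training epochs,
binary cross-entropy loss, and a learning-rate decay by 0.2 whenever the
best training loss stalls for 30 consecutive epochs.  The reported
reference architecture is three hidden layers of 64 neurons, batch
normalization, no dropout, SeLU and Elastic Net at learning rate 0.001.

Six classical baselines (KNN, logistic regression, naive Bayes, random
forest, SVM, gradient-boosted trees) run on the identical folds with their
own small inner-search grids, yielding one comparison table.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import _nn
from .data_io import BetaMatrix, CohortTable, MetricsReport


# ---------------------------------------------------------------------------
# configuration


@dataclass
class DdrConfig:
    """One point in the hyperparameter grid (defaults: the reference
    architecture reported for this model family)."""

    hidden_layers: int = 3
    neurons: int = 64
    dropout: float = 0.0
    batch_norm: bool = True
    regularization: str = "elasticnet"   # l1 | l2 | elasticnet
    activation: str = "selu"             # relu | selu
    learning_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.regularization not in ("l1", "l2", "elasticnet"):
            raise ValueError(f"unknown regularization {self.regularization!r}")
        if self.activation not in _nn.ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class DdrGrid:
    """The hyperparameter search space (defaults: the full published grid)."""

    hidden_layers: tuple[int, ...] = (2, 5, 8)
    neurons: tuple[int, ...] = (16, 32, 48)
    dropout: tuple[float, ...] = (0.0, 0.1)
    batch_norm: tuple[bool, ...] = (True,)
    regularization: tuple[str, ...] = ("l1", "l2", "elasticnet")
    activation: tuple[str, ...] = ("relu", "selu")
    learning_rate: tuple[float, ...] = (0.0002, 0.0005, 0.001)

    def __post_init__(self) -> None:
        for f_ in dataclasses.fields(self):
            if not getattr(self, f_.name):
                raise ValueError(f"grid option list {f_.name} is empty")

    def combos(self) -> list[DdrConfig]:
        out = []
        for vals in itertools.product(self.hidden_layers, self.neurons,
                                      self.dropout, self.batch_norm,
                                      self.regularization, self.activation,
                                      self.learning_rate):
            out.append(DdrConfig(*vals))
        return out

    @classmethod
    def small(cls) -> "DdrGrid":
        """Desk-scale sub-grid for tests and worked examples."""
        return cls(hidden_layers=(2, 3), neurons=(32, 64), dropout=(0.0,),
                   regularization=("l2", "elasticnet"), activation=("selu",),
                   learning_rate=(0.001,))


@dataclass
class DdrTrainFixed:
    """Training schedule held fixed across the grid."""

    batch_size: int = 128
    epochs: int = 200
    plateau_patience: int = 30
    decay_factor: float = 0.2
    plateau_rel_tol: float = 1e-4
    l1_strength: float = 1e-5
    l2_strength: float = 1e-4
    seed: int = 0


@dataclass
class DdrModel:
    config: DdrConfig
    fixed: DdrTrainFixed
    params: dict[str, np.ndarray]
    run_stats: dict[str, np.ndarray]
    feature_cpg_order: list[str]
    history: list[float] = field(default_factory=list)
    lr_schedule: list[float] = field(default_factory=list)


@dataclass
class CvPlan:
    """Stratified nested cross-validation fold assignment by sample id."""

    outer_folds: list[list[str]]
    inner_folds: list[list[list[str]]]   # per outer fold: k_inner id lists partitioning outer-train
    seed: int
    stratified_by: str = "stage"

    def outer_train_ids(self, f: int) -> list[str]:
        test = set(self.outer_folds[f])
        return [s for fold in self.outer_folds for s in fold if s not in test]


def make_cv_plan(cohort: CohortTable, k_outer: int = 5, k_inner: int = 3,
                 seed: int = 0) -> CvPlan:
    """Stratified outer folds; stratified inner folds inside each outer
    training set.  Deterministic under ``seed``."""
    ids = np.asarray(cohort.sample_ids)
    y = cohort.stages().astype(int)
    counts = np.bincount(y, minlength=2)
    if (counts < k_outer).any():
        raise ValueError(
            f"each class needs >= {k_outer} samples; counts are {counts.tolist()}")
    outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    outer_folds, inner_folds = [], []
    for f, (tr, te) in enumerate(outer.split(ids, y)):
        outer_folds.append(ids[te].tolist())
        inner = StratifiedKFold(n_splits=k_inner, shuffle=True,
                                random_state=seed + 1 + f)
        inner_folds.append([ids[tr][iv].tolist()
                            for _, iv in inner.split(ids[tr], y[tr])])
    return CvPlan(outer_folds=outer_folds, inner_folds=inner_folds, seed=seed)


# ---------------------------------------------------------------------------
# the MLP


def _init_mlp(config: DdrConfig, n_features: int, seed: int
              ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    rng = np.random.default_rng([int(seed), 3])
    params: dict[str, np.ndarray] = {}
    run_stats: dict[str, np.ndarray] = {}
    fan_in = n_features
    for i in range(config.hidden_layers):
        params[f"W{i}"] = _nn.glorot(rng, fan_in, config.neurons)
        params[f"b{i}"] = np.zeros(config.neurons)
        if config.batch_norm:
            params[f"g{i}"] = np.ones(config.neurons)
            params[f"be{i}"] = np.zeros(config.neurons)
            run_stats[f"mean{i}"] = np.zeros(config.neurons)
            run_stats[f"var{i}"] = np.ones(config.neurons)
        fan_in = config.neurons
    params["Wo"] = _nn.glorot(rng, fan_in, 1)
    params["bo"] = np.zeros(1)
    return params, run_stats


_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _mlp_forward(params, run_stats, x, config: DdrConfig, train: bool,
                 rng: np.random.Generator | None = None):
    act, _ = _nn.ACTIVATIONS[config.activation]
    cache = {"inputs": [], "z": [], "bn": [], "drop": [], "act_in": []}
    h = x
    for i in range(config.hidden_layers):
        cache["inputs"].append(h)
        z = h @ params[f"W{i}"] + params[f"b{i}"]
        cache["z"].append(z)
        if config.batch_norm:
            if train:
                mu, var = z.mean(axis=0), z.var(axis=0)
                run_stats[f"mean{i}"] *= (1 - _BN_MOMENTUM)
                run_stats[f"mean{i}"] += _BN_MOMENTUM * mu
                run_stats[f"var{i}"] *= (1 - _BN_MOMENTUM)
                run_stats[f"var{i}"] += _BN_MOMENTUM * var
            else:
                mu, var = run_stats[f"mean{i}"], run_stats[f"var{i}"]
            inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z - mu) * inv_sd
            cache["bn"].append((xhat, inv_sd))
            a_in = params[f"g{i}"] * xhat + params[f"be{i}"]
        else:
            cache["bn"].append(None)
            a_in = z
        cache["act_in"].append(a_in)
        h = act(a_in)
        if train and config.dropout > 0:
            mask = (rng.random(h.shape) >= config.dropout) / (1 - config.dropout)
            h = h * mask
            cache["drop"].append(mask)
        else:
            cache["drop"].append(None)
    cache["h_last"] = h
    logits = (h @ params["Wo"] + params["bo"])[:, 0]
    p = _nn.sigmoid(logits)
    return p, cache


def _mlp_backward(params, cache, dlogits, config: DdrConfig):
    _, act_grad = _nn.ACTIVATIONS[config.activation]
    grads: dict[str, np.ndarray] = {}
    h = cache["h_last"]
    grads["Wo"] = h.T @ dlogits[:, None]
    grads["bo"] = np.array([dlogits.sum()])
    dh = dlogits[:, None] @ params["Wo"].T
    for i in reversed(range(config.hidden_layers)):
        if cache["drop"][i] is not None:
            dh = dh * cache["drop"][i]
        da_in = dh * act_grad(cache["act_in"][i])
        if config.batch_norm:
            xhat, inv_sd = cache["bn"][i]
            grads[f"g{i}"] = (da_in * xhat).sum(axis=0)
            grads[f"be{i}"] = da_in.sum(axis=0)
            dxhat = da_in * params[f"g{i}"]
            dz = inv_sd * (dxhat - dxhat.mean(axis=0)
                           - xhat * (dxhat * xhat).mean(axis=0))
        else:
            dz = da_in
        grads[f"W{i}"] = cache["inputs"][i].T @ dz
        grads[f"b{i}"] = dz.sum(axis=0)
        dh = dz @ params[f"W{i}"].T
    return grads


def _reg_penalty_and_grads(params, config: DdrConfig, fixed: DdrTrainFixed):
    l1 = fixed.l1_strength if config.regularization in ("l1", "elasticnet") else 0.0
    l2 = fixed.l2_strength if config.regularization in ("l2", "elasticnet") else 0.0
    penalty = 0.0
    grads: dict[str, np.ndarray] = {}
    for name, w in params.items():
        if not name.startswith("W"):
            continue
        g = np.zeros_like(w)
        if l1:
            penalty += l1 * np.abs(w).sum()
            g += l1 * np.sign(w)
        if l2:
            penalty += l2 * (w ** 2).sum()
            g += 2.0 * l2 * w
        grads[name] = g
    return penalty, grads


def train_mlp(config: DdrConfig, beta_panel: BetaMatrix,
              stages: Sequence[int], fixed: DdrTrainFixed) -> DdrModel:
    """Train the stage MLP on panel features; deterministic under the seed.

    ``stages`` aligns with ``beta_panel.sample_ids``; both classes must be
    present.  History records the per-epoch mean training loss (binary
    cross-entropy plus the regularization penalty, the quantity the plateau
    scheduler watches); ``lr_schedule`` records the learning rate per epoch.
    """
    y = np.asarray(stages, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    if np.isnan(beta_panel.values).any():
        raise ValueError("beta matrix has missing values; impute first")
    x = np.ascontiguousarray(beta_panel.values.T)
    n = x.shape[0]

    params, run_stats = _init_mlp(config, x.shape[1], fixed.seed)
    rng = np.random.default_rng([int(fixed.seed), 4])
    opt = _nn.Adam(lr=config.learning_rate)
    sched = _nn.PlateauScheduler(opt, patience=fixed.plateau_patience,
                                 factor=fixed.decay_factor,
                                 rel_tol=fixed.plateau_rel_tol)
    bs = min(fixed.batch_size, n)
    history, lr_schedule = [], []
    for _epoch in range(fixed.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = x[idx], y[idx]
            p, cache = _mlp_forward(params, run_stats, xb, config, True, rng)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            bce = -(yb * np.log(p) + (1 - yb) * np.log(1 - p)).mean()
            dlogits = (p - yb) / len(idx)
            grads = _mlp_backward(params, cache, dlogits, config)
            penalty, reg_grads = _reg_penalty_and_grads(params, config, fixed)
            for name, g in reg_grads.items():
                grads[name] = grads[name] + g
            opt.step(params, grads)
            losses.append(bce + penalty)
        history.append(float(np.mean(losses)))
        lr_schedule.append(opt.lr)
        sched.update(history[-1])
    return DdrModel(config=config, fixed=fixed, params=params,
                    run_stats=run_stats,
                    feature_cpg_order=list(beta_panel.cpg_ids),
                    history=history, lr_schedule=lr_schedule)


def predict_stage_proba(model: DdrModel, beta_panel: BetaMatrix) -> np.ndarray:
    """P(late stage) per sample; inference mode (running batch-norm stats,
    no dropout), so identical inputs give identical probabilities."""
    sub = beta_panel.subset_cpgs(model.feature_cpg_order)
    p, _ = _mlp_forward(model.params, model.run_stats,
                        np.ascontiguousarray(sub.values.T),
                        model.config, train=False)
    return p


# ---------------------------------------------------------------------------
# metrics


def evaluate(scores: Sequence[float], labels: Sequence[int]) -> dict[str, float]:
    """AUC (Mann-Whitney rank statistic, ties count 1/2), plus accuracy,
    precision and recall at threshold 0.5 with positive class = 1 (late)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores/labels length mismatch")
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    pred = (s >= 0.5).astype(int)
    acc = float((pred == y).mean())
    tp = int(((pred == 1) & (y == 1)).sum())
    precision = tp / max(int((pred == 1).sum()), 1) if (pred == 1).any() else 0.0
    recall = tp / n_pos if n_pos else 0.0
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"AUC undefined with a single class (ACC would be {acc:.3f})")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return {"auc": float(auc), "acc": acc,
            "precision": float(precision), "recall": float(recall)}


# ---------------------------------------------------------------------------
# nested cross-validation


def _single_disease(cohort: CohortTable) -> str:
    diseases = cohort.table["disease"].unique().tolist()
    if len(diseases) != 1:
        raise ValueError(f"expected a single-disease cohort, got {diseases}")
    return diseases[0]


def run_cv(beta_panel: BetaMatrix, cohort: CohortTable, grid: DdrGrid,
           fixed: DdrTrainFixed, plan: CvPlan) -> tuple[MetricsReport, dict]:
    """Nested CV for the MLP: inner grid search by mean AUC, refit, outer
    score.  Returns the mean-metric report row plus per-fold detail
    (winning configs, per-fold metrics, fold id lists for leakage audit)."""
    disease = _single_disease(cohort)
    combos = grid.combos()
    stage_of = dict(zip(cohort.sample_ids, cohort.stages().astype(int)))

    fold_metrics, winners = [], []
    for f, test_ids in enumerate(plan.outer_folds):
        train_ids = plan.outer_train_ids(f)
        inner = plan.inner_folds[f]
        best_cfg, best_auc = None, -np.inf
        for cfg in combos:
            aucs = []
            for v in range(len(inner)):
                val_ids = inner[v]
                fit_ids = [s for s in train_ids if s not in set(val_ids)]
                model = train_mlp(cfg, beta_panel.subset_samples(fit_ids),
                                  [stage_of[s] for s in fit_ids], fixed)
                proba = predict_stage_proba(model, beta_panel.subset_samples(val_ids))
                aucs.append(evaluate(proba, [stage_of[s] for s in val_ids])["auc"])
            mean_auc = float(np.mean(aucs))
            if mean_auc > best_auc:
                best_auc, best_cfg = mean_auc, cfg
        model = train_mlp(best_cfg, beta_panel.subset_samples(train_ids),
                          [stage_of[s] for s in train_ids], fixed)
        proba = predict_stage_proba(model, beta_panel.subset_samples(test_ids))
        fold_metrics.append(evaluate(proba, [stage_of[s] for s in test_ids]))
        winners.append({"fold": f, "config": dataclasses.asdict(best_cfg),
                        "inner_mean_auc": best_auc})

    mean = {k: float(np.mean([m[k] for m in fold_metrics]))
            for k in ("auc", "acc", "precision", "recall")}
    report = MetricsReport(pd.DataFrame([{"disease": disease, "model": "mlp",
                                          **mean}]))
    details = {"per_fold": fold_metrics, "winners": winners,
               "outer_folds": plan.outer_folds}
    return report, details


# ---------------------------------------------------------------------------
# baselines


BASELINE_GRIDS: dict[str, tuple] = {
    "knn": (KNeighborsClassifier, [{"n_neighbors": k} for k in (3, 5, 7)]),
    "logistic_regression": (LogisticRegression,
                            [{"C": c, "max_iter": 2000} for c in (0.1, 1.0, 10.0)]),
    "naive_bayes": (GaussianNB, [{"var_smoothing": v} for v in (1e-9, 1e-8)]),
    "random_forest": (RandomForestClassifier,
                      [{"n_estimators": n} for n in (100, 300)]),
    "svm": (SVC, [{"C": c, "probability": True} for c in (0.1, 1.0, 10.0)]),
    "gradient_boosting": (GradientBoostingClassifier,
                          [{"n_estimators": n} for n in (100, 300)]),
}

_SEEDED = {"random_forest", "svm", "gradient_boosting"}


def run_baselines(beta_panel: BetaMatrix, cohort: CohortTable, plan: CvPlan,
                  model_list: Sequence[str] = tuple(BASELINE_GRIDS),
                  seed: int = 0) -> tuple[MetricsReport, dict]:
    """Classical classifiers on the same outer folds as the MLP, each tuned
    by inner grid search on mean AUC over its small default grid."""
    disease = _single_disease(cohort)
    unknown = [m for m in model_list if m not in BASELINE_GRIDS]
    if unknown:
        raise ValueError(f"unknown baseline model(s): {unknown}; "
                         f"choose from {sorted(BASELINE_GRIDS)}")
    x_all = beta_panel.values.T
    idx_of = {s: i for i, s in enumerate(beta_panel.sample_ids)}
    stage_of = dict(zip(cohort.sample_ids, cohort.stages().astype(int)))

    def xy(ids):
        rows = [idx_of[s] for s in ids]
        return x_all[rows], np.array([stage_of[s] for s in ids])

    rows, details = [], {"per_model": {}, "outer_folds": plan.outer_folds}
    for name in model_list:
        cls, param_grid = BASELINE_GRIDS[name]
        fold_metrics = []
        for f, test_ids in enumerate(plan.outer_folds):
            train_ids = plan.outer_train_ids(f)
            best_params, best_auc = None, -np.inf
            for pset in param_grid:
                aucs = []
                for val_ids in plan.inner_folds[f]:
                    fit_ids = [s for s in train_ids if s not in set(val_ids)]
                    kw = dict(pset)
                    if name in _SEEDED:
                        kw["random_state"] = seed
                    est = cls(**kw)
                    xf, yf = xy(fit_ids)
                    est.fit(xf, yf)
                    xv, yv = xy(val_ids)
                    aucs.append(evaluate(est.predict_proba(xv)[:, 1], yv)["auc"])
                mean_auc = float(np.mean(aucs))
                if mean_auc > best_auc:
                    best_auc, best_params = mean_auc, pset
            kw = dict(best_params)
            if name in _SEEDED:
                kw["random_state"] = seed
            est = cls(**kw)
            xt, yt = xy(train_ids)
            est.fit(xt, yt)
            xe, ye = xy(test_ids)
            fold_metrics.append(evaluate(est.predict_proba(xe)[:, 1], ye))
        mean = {k: float(np.mean([m[k] for m in fold_metrics]))
                for k in ("auc", "acc", "precision", "recall")}
        rows.append({"disease": disease, "model": name, **mean})
        details["per_model"][name] = fold_metrics
    return MetricsReport(pd.DataFrame(rows)), details
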