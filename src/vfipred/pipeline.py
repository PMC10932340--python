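"""Training protocol: model zoo, greedy feature selection, random grid
search, repeated stratified cross-validation, ensembling and error maps.

The protocol mirrors common practice for small tabular clinical datasets:

* candidate algorithms are drawn from a registered zoo (linear, kernel,
  tree-ensemble, neighbour and Bayesian families);
* for each algorithm, features are chosen by forward greedy search scored
  with stratified 5-fold AUC-ROC, stopping after a patience of
  non-improving additions;
* hyperparameters come from a seeded random grid search over shipped
  per-algorithm spaces;
* performance is estimated by 5-fold cross-validation repeated 25 times
  under reshuffled splits, reporting mean and standard deviation of
  AUC-ROC, balanced accuracy, sensitivity and specificity;
* fitted models are combined by soft voting (probability averaging), hard
  voting, or stacking, with members picked by greedy ensemble selection on
  shared out-of-fold predictions.

Labels are binary with the pathogenic class coded 1; sensitivity is always
the true-positive rate of class 1.  Held-out ``test`` rows are guarded by
:class:`SplitDataset`, which refuses metric computation on them until an
explicit ``finalize()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import loguniform
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

METRIC_NAMES = ("auc_roc", "balanced_accuracy", "sensitivity", "specificity")


class TestSetGuardError(RuntimeError):
    """Raised when selection code touches held-out test rows before finalize()."""


# ---------------------------------------------------------------------------
# Model zoo
# ---------------------------------------------------------------------------


def _make_lightgbm(seed):
    from lightgbm import LGBMClassifier

    return LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1)


def _make_xgboost(seed):
    from xgboost import XGBClassifier

    return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss")


def _scaled(estimator):
    return Pipeline([("scale", StandardScaler()), ("clf", estimator)])


_ZOO = {
    "logistic_regression": lambda s: _scaled(LogisticRegression(max_iter=2000, random_state=s)),
    "svm": lambda s: _scaled(SVC(probability=True, random_state=s)),
    "random_forest": lambda s: RandomForestClassifier(random_state=s, n_jobs=1),
    "gradient_boosting": lambda s: GradientBoostingClassifier(random_state=s),
    "lightgbm": _make_lightgbm,
    "xgboost": _make_xgboost,
    "knn": lambda s: _scaled(KNeighborsClassifier()),
    "lda": lambda s: LinearDiscriminantAnalysis(),
    "naive_bayes": lambda s: GaussianNB(),
    "gaussian_process": lambda s: GaussianProcessClassifier(random_state=s),
}

# Shipped hyperparameter search spaces.  A space maps a parameter name to
# either a list of choices or a frozen scipy distribution.
DEFAULT_SEARCH_SPACES = {
    "logistic_regression": {"clf__C": loguniform(1e-3, 1e3)},
    "svm": {"clf__C": loguniform(1e-2, 1e3), "clf__gamma": loguniform(1e-4, 1e1)},
    "random_forest": {
        "n_estimators": [100, 200, 400],
        "max_depth": [None, 4, 8, 16],
        "max_features": ["sqrt", 0.5],
    },
    "gradient_boosting": {
        "n_estimators": [100, 200, 400],
        "learning_rate": loguniform(1e-2, 3e-1),
        "max_depth": [2, 3, 4],
    },
    "lightgbm": {
        "n_estimators": [100, 200, 400],
        "learning_rate": loguniform(1e-2, 3e-1),
        "num_leaves": [7, 15, 31],
    },
    "xgboost": {
        "n_estimators": [100, 200, 400],
        "learning_rate": loguniform(1e-2, 3e-1),
        "max_depth": [2, 4, 6],
    },
    "knn": {"clf__n_neighbors": [3, 5, 9, 15], "clf__weights": ["uniform", "distance"]},
    "lda": {},
    "naive_bayes": {},
    "gaussian_process": {},
}


@dataclass(frozen=True)
class ModelConfig:
    """An algorithm from the zoo plus its hyperparameters and feature subset."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    selected_features: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in _ZOO:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; registered: {sorted(_ZOO)}"
            )
        object.__setattr__(self, "selected_features", tuple(self.selected_features))

    def build(self):
        estimator = _ZOO[self.algorithm](self.seed)
        if self.hyperparameters:
            estimator.set_params(**dict(self.hyperparameters))
        return estimator


# Cheaper stand-ins used only while *scoring candidate feature sets /
# hyperparameter draws*: selection needs a ranking signal, not calibrated
# probabilities, so SVMs skip Platt calibration and tree ensembles use
# fewer trees.  Final models are always built from the full configuration.
SELECTION_OVERRIDES = {
    "svm": {"clf__probability": False},
    "random_forest": {"n_estimators": 30},
    "gradient_boosting": {"n_estimators": 50},
    "lightgbm": {"n_estimators": 50},
    "xgboost": {"n_estimators": 50},
}


def registered_algorithms() -> list[str]:
    return sorted(_ZOO)


# ---------------------------------------------------------------------------
# Split-aware dataset
# ---------------------------------------------------------------------------


@dataclass
class SplitDataset:
    """Features + labels with train/test discipline.

    Selection and cross-validation only ever see ``train`` rows.  Test rows
    are inaccessible until :meth:`finalize` is called once, at final
    evaluation time.
    """

    X: pd.DataFrame
    y: pd.Series
    split: pd.Series
    _finalized: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.split)):
            raise ValueError("X, y and split must have equal length")
        self.y = pd.Series(np.asarray(self.y, dtype=int), index=self.X.index)
        self.split = pd.Series(np.asarray(self.split, dtype=object), index=self.X.index)
        if self.X.isna().any().any():
            missing = self.X.columns[self.X.isna().any()].tolist()
            raise ValueError(f"missing feature values in columns {missing}; no imputation is performed")

    @property
    def train_X(self) -> pd.DataFrame:
        return self.X[self.split == "train"]

    @property
    def train_y(self) -> pd.Series:
        return self.y[self.split == "train"]

    @property
    def test_X(self) -> pd.DataFrame:
        if not self._finalized:
            raise TestSetGuardError(
                "held-out test rows are sealed; call finalize() for final evaluation"
            )
        return self.X[self.split == "test"]

    @property
    def test_y(self) -> pd.Series:
        if not self._finalized:
            raise TestSetGuardError(
                "held-out test rows are sealed; call finalize() for final evaluation"
            )
        return self.y[self.split == "test"]

    def finalize(self) -> "SplitDataset":
        self._finalized = True
        return self

    def restrict(self, features) -> "SplitDataset":
        ds = SplitDataset(self.X[list(features)], self.y, self.split)
        ds._finalized = self._finalized
        return ds


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_metrics(truth, scores, threshold: float = 0.5) -> dict:
    """AUC-ROC, balanced accuracy, sensitivity and specificity at a threshold.

    Sensitivity is TP/(TP+FN) for the positive class (1); AUC is the rank
    statistic with ties averaged.  Requires both classes in ``truth``.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if set(np.unique(truth)) != {0, 1}:
        raise ValueError("truth must contain both classes")
    pred = (scores >= threshold).astype(int)
    tp = int(((truth == 1) & (pred == 1)).sum())
    fn = int(((truth == 1) & (pred == 0)).sum())
    tn = int(((truth == 0) & (pred == 0)).sum())
    fp = int(((truth == 0) & (pred == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "auc_roc": float(roc_auc_score(truth, scores)),
        "balanced_accuracy": (sens + spec) / 2.0,
        "sensitivity": sens,
        "specificity": spec,
    }


# ---------------------------------------------------------------------------
# Repeated stratified cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per-split metrics plus per-sample held-out predictions across repeats."""

    per_split: pd.DataFrame  # columns: repeat, fold, auc_roc, ...
    predictions: pd.DataFrame  # index = sample index, columns = repeat number
    folds: int
    repeats: int
    labels: pd.Series

    @property
    def mean(self) -> pd.Series:
        return self.per_split[list(METRIC_NAMES)].mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_split[list(METRIC_NAMES)].std(ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n deterministic child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _fit_predict(estimator, X_tr, y_tr, X_te) -> np.ndarray:
    model = clone(estimator)
    model.fit(X_tr, y_tr)
    proba = model.predict_proba(X_te)
    pos = list(model.classes_).index(1)
    return proba[:, pos]


def _fit_score(estimator, X_tr, y_tr, X_te) -> np.ndarray:
    """Held-out ranking scores: decision_function when available (cheaper,
    AUC-equivalent), probabilities otherwise."""
    model = clone(estimator)
    model.fit(X_tr, y_tr)
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X_te), dtype=float)
    pos = list(model.classes_).index(1)
    return model.predict_proba(X_te)[:, pos]


def repeated_stratified_cv(
    dataset: SplitDataset,
    config: ModelConfig,
    folds: int = 5,
    repeats: int = 25,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV repeated under reshuffled splits.

    Every sample is held out exactly once per repeat, i.e. ``repeats`` times
    overall; metrics are aggregated as mean and standard deviation over all
    ``folds x repeats`` splits.
    """
    X = dataset.train_X[list(config.selected_features)] if config.selected_features else dataset.train_X
    y = dataset.train_y
    counts = y.value_counts()
    if (counts < folds).any():
        raise ValueError(
            f"each class needs at least {folds} members; got {counts.to_dict()}"
        )
    estimator = config.build()
    rows = []
    preds = pd.DataFrame(index=X.index, columns=range(repeats), dtype=float)
    for r, rseed in enumerate(_spawn_seeds(seed, repeats)):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rseed)
        for k, (tr, te) in enumerate(skf.split(X, y)):
            scores = _fit_predict(estimator, X.iloc[tr], y.iloc[tr], X.iloc[te])
            preds.iloc[te, r] = scores
            rows.append({"repeat": r, "fold": k, **compute_metrics(y.iloc[te], scores)})
    return CVReport(
        per_split=pd.DataFrame(rows),
        predictions=preds,
        folds=folds,
        repeats=repeats,
        labels=y,
    )


def _cv_auc(estimator, X, y, folds: int, seed: int) -> float:
    """Mean stratified k-fold AUC-ROC (the selection-time score)."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        scores = _fit_score(estimator, X.iloc[tr], y.iloc[tr], X.iloc[te])
        aucs.append(roc_auc_score(y.iloc[te], scores))
    return float(np.mean(aucs))


def _selection_estimator(config: "ModelConfig"):
    """The config's estimator with the selection-time overrides applied."""
    estimator = config.build()
    overrides = SELECTION_OVERRIDES.get(config.algorithm)
    if overrides:
        estimator.set_params(**{k: v for k, v in overrides.items()
                                if k not in config.hyperparameters})
    return estimator


# ---------------------------------------------------------------------------
# Greedy feature selection
# ---------------------------------------------------------------------------


def greedy_feature_selection(
    dataset: SplitDataset,
    config: ModelConfig,
    patience: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> tuple[list[str], list[float]]:
    """Forward greedy feature search scored by stratified k-fold AUC-ROC.

    At each step the candidate feature with the best score is added (ties
    broken by feature-name order); the search stops after ``patience``
    consecutive non-improving additions, and the prefix achieving the
    maximum score is returned together with the full score trace.
    """
    X, y = dataset.train_X, dataset.train_y
    candidates = list(X.columns)
    if len(candidates) < 1:
        raise ValueError("no candidate features")
    estimator = _selection_estimator(config)
    selected: list[str] = []
    trace: list[float] = []
    best_score = -np.inf
    best_len = 0
    since_improvement = 0
    fold_seed = _spawn_seeds(seed, 1)[0]
    while candidates and since_improvement < patience:
        step_score, step_feature = -np.inf, None
        for name in sorted(candidates):  # ties resolve to the first name in sorted order
            try:
                score = _cv_auc(estimator, X[selected + [name]], y, folds, fold_seed)
            except Exception:
                # degenerate candidate set for this estimator (e.g. a
                # constant column crashing an SVD) -> never selected
                continue
            if score > step_score:
                step_score, step_feature = score, name
        if step_feature is None:
            break
        selected.append(step_feature)
        candidates.remove(step_feature)
        trace.append(step_score)
        if step_score > best_score:
            best_score = step_score
            best_len = len(selected)
            since_improvement = 0
        else:
            since_improvement += 1
    return selected[:best_len], trace


# ---------------------------------------------------------------------------
# Random grid search
# ---------------------------------------------------------------------------


def _draw(space: dict, rng: np.random.Generator) -> dict:
    params = {}
    for name, choices in space.items():
        if hasattr(choices, "rvs"):
            params[name] = choices.rvs(random_state=rng)
        else:
            params[name] = choices[rng.integers(len(choices))]
    return params


def random_grid_search(
    dataset: SplitDataset,
    config: ModelConfig,
    space: dict | None = None,
    n_draws: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict, float]:
    """Seeded random search over a hyperparameter space.

    Returns the evaluated combination with the highest mean k-fold AUC-ROC,
    ties broken by draw order.  An empty space evaluates the algorithm's
    defaults once.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if space is None:
        space = DEFAULT_SEARCH_SPACES[config.algorithm]
    X = dataset.train_X[list(config.selected_features)] if config.selected_features else dataset.train_X
    y = dataset.train_y
    rng = np.random.default_rng(seed)
    fold_seed = _spawn_seeds(seed, 1)[0]
    best_params, best_score = {}, -np.inf
    n_eval = n_draws if space else 1
    for _ in range(n_eval):
        params = _draw(space, rng) if space else {}
        estimator = _selection_estimator(replace(config, hyperparameters=params))
        try:
            score = _cv_auc(estimator, X, y, folds, fold_seed)
        except Exception:
            continue  # unevaluable draw
        if score > best_score:
            best_params, best_score = params, score
    return best_params, best_score


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSpec:
    """Ordered member configurations plus the combination rule."""

    members: list[ModelConfig]
    strategy: str = "soft_vote"
    meta_learner: ModelConfig | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.strategy not in ("soft_vote", "hard_vote", "stacked"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


class FittedEnsemble:
    """Fitted members + combiner.  Probability output for the positive class."""

    def __init__(self, spec: EnsembleSpec, fitted_members, meta_model=None):
        self.spec = spec
        self.fitted_members = fitted_members
        self.meta_model = meta_model

    def _member_probas(self, X: pd.DataFrame) -> np.ndarray:
        cols = []
        for cfg, model in zip(self.spec.members, self.fitted_members):
            Xm = X[list(cfg.selected_features)] if cfg.selected_features else X
            pos = list(model.classes_).index(1)
            cols.append(model.predict_proba(Xm)[:, pos])
        return np.column_stack(cols)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        probas = self._member_probas(X)
        if self.spec.strategy == "soft_vote":
            return probas.mean(axis=1)
        if self.spec.strategy == "hard_vote":
            votes = (probas >= 0.5).sum(axis=1)
            # majority label; exact ties go to the positive class
            return (votes >= probas.shape[1] / 2.0).astype(float)
        pos = list(self.meta_model.classes_).index(1)
        return self.meta_model.predict_proba(probas)[:, pos]

    def predict(self, X: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def _oof_probas(
    dataset: SplitDataset, config: ModelConfig, folds: int, seed: int
) -> np.ndarray:
    """Out-of-fold positive-class probabilities on shared stratified folds."""
    X = dataset.train_X[list(config.selected_features)] if config.selected_features else dataset.train_X
    y = dataset.train_y
    estimator = config.build()
    out = np.empty(len(y))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        out[te] = _fit_predict(estimator, X.iloc[tr], y.iloc[tr], X.iloc[te])
    return out


def build_ensemble(
    dataset: SplitDataset,
    spec: EnsembleSpec,
    folds: int = 5,
    seed: int = 0,
) -> FittedEnsemble:
    """Fit all members on the full training split; for a stacked ensemble the
    meta-learner is trained on out-of-fold member probabilities to avoid
    leaking the members' training fit into the stacking stage."""
    y = dataset.train_y
    fitted = []
    for cfg in spec.members:
        X = dataset.train_X[list(cfg.selected_features)] if cfg.selected_features else dataset.train_X
        model = cfg.build()
        model.fit(X, y)
        fitted.append(model)
    meta_model = None
    if spec.strategy == "stacked":
        fold_seed = _spawn_seeds(seed, 1)[0]
        oof = np.column_stack(
            [_oof_probas(dataset, cfg, folds, fold_seed) for cfg in spec.members]
        )
        meta_cfg = spec.meta_learner or ModelConfig("logistic_regression", seed=seed)
        meta_model = meta_cfg.build()
        meta_model.fit(pd.DataFrame(oof), y)
    return FittedEnsemble(spec, fitted, meta_model)


def soft_vote(probabilities) -> float:
    """Arithmetic mean of member probabilities for one sample."""
    return float(np.mean(probabilities))


def hard_vote(labels) -> int:
    """Majority label; exact ties resolve to the positive class."""
    labels = np.asarray(labels, dtype=int)
    return int(labels.sum() >= len(labels) / 2.0)


def greedy_ensemble_selection(
    candidates: list[ModelConfig],
    dataset: SplitDataset,
    folds: int = 5,
    seed: int = 0,
    strategy: str = "soft_vote",
) -> tuple[EnsembleSpec, float]:
    """Greedy soft-vote member selection on shared out-of-fold predictions.

    All candidates are scored on the same stratified folds; members are
    added one at a time, each step picking the candidate whose inclusion
    maximizes the cross-validated AUC-ROC of the averaged probabilities.
    The best-scoring subset along the path is returned — its size emerges
    from the search.
    """
    if not candidates:
        raise ValueError("no candidate models")
    fold_seed = _spawn_seeds(seed, 1)[0]
    y = dataset.train_y.to_numpy()
    oof = {
        i: _oof_probas(dataset, cfg, folds, fold_seed) for i, cfg in enumerate(candidates)
    }
    remaining = list(range(len(candidates)))
    chosen: list[int] = []
    best_subset: list[int] = []
    best_score = -np.inf
    while remaining:
        step = [
            (roc_auc_score(y, np.mean([oof[j] for j in chosen + [i]], axis=0)), -i)
            for i in remaining
        ]
        score, neg_i = max(step)
        i = -neg_i
        chosen.append(i)
        remaining.remove(i)
        if score > best_score:
            best_score = score
            best_subset = list(chosen)
    spec = EnsembleSpec(members=[candidates[i] for i in best_subset], strategy=strategy)
    return spec, float(best_score)


def repeated_stratified_cv_ensemble(
    dataset: SplitDataset,
    spec: EnsembleSpec,
    folds: int = 5,
    repeats: int = 25,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified CV of a soft-vote ensemble: on every split each
    member is refit on the split's training folds and the held-out
    probabilities are averaged."""
    if spec.strategy != "soft_vote":
        raise ValueError("repeated CV is implemented for soft-vote ensembles")
    X_full = dataset.train_X
    y = dataset.train_y
    counts = y.value_counts()
    if (counts < folds).any():
        raise ValueError(f"each class needs at least {folds} members; got {counts.to_dict()}")
    rows = []
    preds = pd.DataFrame(index=X_full.index, columns=range(repeats), dtype=float)
    for r, rseed in enumerate(_spawn_seeds(seed, repeats)):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rseed)
        for k, (tr, te) in enumerate(skf.split(X_full, y)):
            member_scores = []
            for cfg in spec.members:
                X = X_full[list(cfg.selected_features)] if cfg.selected_features else X_full
                member_scores.append(
                    _fit_predict(cfg.build(), X.iloc[tr], y.iloc[tr], X.iloc[te])
                )
            scores = np.mean(member_scores, axis=0)
            preds.iloc[te, r] = scores
            rows.append({"repeat": r, "fold": k, **compute_metrics(y.iloc[te], scores)})
    return CVReport(
        per_split=pd.DataFrame(rows),
        predictions=preds,
        folds=folds,
        repeats=repeats,
        labels=y,
    )


# ---------------------------------------------------------------------------
# Error-rate map
# ---------------------------------------------------------------------------


def error_rate_map(report: CVReport, threshold: float = 0.5) -> pd.DataFrame:
    """Per-sample held-out misclassification ratio over all repeats.

    A sample is flagged when it is misclassified in more than half of its
    ``repeats`` held-out appearances — the chronic failure cases.
    """
    preds = report.predictions
    labels = report.labels
    hard = (preds >= threshold).astype(int)
    errors = hard.ne(labels, axis=0).sum(axis=1)
    ratio = errors / report.repeats
    return pd.DataFrame(
        {
            "label": labels,
            "errors": errors,
            "error_rate": ratio,
            "flagged": ratio > 0.5,
        }
    )
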