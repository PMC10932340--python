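"""Model-level API: build a classifier from data, ``fit()``, read a Results
object.

``PathogenicityModel`` runs the full protocol — per-algorithm greedy feature
selection, seeded random hyperparameter search, 5x25 repeated stratified
cross-validation and greedy soft-vote ensemble selection — and returns a
:class:`PathogenicityResults` carrying per-model CV reports, the selected
ensemble, its repeated-CV estimate and the fitted predictor.
``SeverityModel`` layers the severity adjustments on top: three-state label
merging, the endpoint-feature exclusion guard, and training-set threshold
optimization.

Typical use::

    gene = simulate.make_gene(simulate.GenePreset(master_seed=7))
    data = simulate.make_labels(gene, "pathogenicity")
    model = PathogenicityModel.from_gene(gene, data)
    results = model.fit(seed=1)
    print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import build_feature_matrix
from .pipeline import (
    CVReport,
    EnsembleSpec,
    FittedEnsemble,
    ModelConfig,
    SplitDataset,
    build_ensemble,
    compute_metrics,
    error_rate_map,
    greedy_ensemble_selection,
    greedy_feature_selection,
    random_grid_search,
    repeated_stratified_cv,
    repeated_stratified_cv_ensemble,
)
from .severity import (
    ThresholdedModel,
    check_no_endpoint_features,
    merge_severity_labels,
    optimize_threshold,
)

DEFAULT_CANDIDATES = ("logistic_regression", "svm", "random_forest", "lightgbm")


class PathogenicityModel:
    """Tolerated-vs-pathogenic classifier built from a feature matrix.

    Parameters
    ----------
    features : DataFrame, variants x named features
    labels : binary series (tolerated=0, pathogenic=1)
    split : series of {"train", "test", "unassigned"}
    candidates : algorithm names to consider (zoo keys)
    """

    task = "pathogenicity"
    positive_label = "pathogenic"
    negative_label = "tolerated"

    def __init__(self, features: pd.DataFrame, labels, split, candidates=DEFAULT_CANDIDATES):
        self.dataset = SplitDataset(
            features.reset_index(drop=True),
            pd.Series(list(labels)).reset_index(drop=True),
            pd.Series(list(split)).reset_index(drop=True),
        )
        self.candidates = tuple(candidates)

    @classmethod
    def from_gene(cls, gene, data: pd.DataFrame, sigma: float | None = None, **kwargs):
        """Build from a synthetic gene bundle plus a labeled dataset frame
        (columns: variant, label, split; label already binary for this task)."""
        profiles = gene.profiles(sigma=sigma)
        X = build_feature_matrix(
            list(data["variant"]),
            profiles,
            gene.domain_map,
            include_endpoint_aa=cls.task == "pathogenicity",
        )
        labels = data["label"]
        if labels.dtype == object:
            labels = labels.map({"tolerated": 0, "pathogenic": 1})
        return cls(X, labels, data["split"], **kwargs)

    def fit(
        self,
        folds: int = 5,
        repeats: int = 25,
        n_draws: int = 20,
        patience: int = 10,
        seed: int = 0,
    ) -> "PathogenicityResults":
        """Run selection, tuning, repeated CV and ensembling; return Results."""
        tuned: list[ModelConfig] = []
        model_rows = {}
        reports = {}
        for i, algorithm in enumerate(self.candidates):
            algo_seed = seed + 1000 * (i + 1)
            base = ModelConfig(algorithm, seed=algo_seed)
            selected, trace = greedy_feature_selection(
                self.dataset, base, patience=patience, folds=folds, seed=algo_seed
            )
            cfg = ModelConfig(algorithm, selected_features=selected, seed=algo_seed)
            params, _ = random_grid_search(
                self.dataset, cfg, n_draws=n_draws, folds=folds, seed=algo_seed
            )
            cfg = ModelConfig(
                algorithm, hyperparameters=params, selected_features=selected, seed=algo_seed
            )
            report = repeated_stratified_cv(
                self.dataset, cfg, folds=folds, repeats=repeats, seed=seed
            )
            tuned.append(cfg)
            reports[algorithm] = report
            model_rows[algorithm] = report.summary()
        spec, ensemble_sel_score = greedy_ensemble_selection(
            tuned, self.dataset, folds=folds, seed=seed
        )
        ensemble_report = repeated_stratified_cv_ensemble(
            self.dataset, spec, folds=folds, repeats=repeats, seed=seed
        )
        fitted = build_ensemble(self.dataset, spec, folds=folds, seed=seed)
        return PathogenicityResults(
            model=self,
            member_configs=tuned,
            member_reports=reports,
            ensemble_spec=spec,
            ensemble_report=ensemble_report,
            fitted_ensemble=fitted,
            seed=seed,
        )


@dataclass
class PathogenicityResults:
    """Everything the protocol estimated, plus the fitted ensemble."""

    model: PathogenicityModel
    member_configs: list[ModelConfig]
    member_reports: dict
    ensemble_spec: EnsembleSpec
    ensemble_report: CVReport
    fitted_ensemble: FittedEnsemble
    seed: int

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.fitted_ensemble.predict_proba(X)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.fitted_ensemble.predict(X)

    def error_map(self) -> pd.DataFrame:
        return error_rate_map(self.ensemble_report)

    def evaluate_test(self) -> dict:
        """Finalize the split guard and score the held-out test rows."""
        ds = self.model.dataset.finalize()
        return compute_metrics(ds.test_y, self.predict_proba(ds.test_X))

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} results "
            f"({self.ensemble_report.folds}-fold CV x {self.ensemble_report.repeats} repeats, seed {self.seed})",
            "",
            f"{'model':<24}{'AUC-ROC':>16}{'Bal. acc.':>16}{'Sensitivity':>16}{'Specificity':>16}",
        ]

        def _row(name, report):
            m, s = report.mean, report.sd
            cells = "".join(
                f"{m[k]:>9.3f} ({s[k]:.3f})"
                for k in ("auc_roc", "balanced_accuracy", "sensitivity", "specificity")
            )
            return f"{name:<24}{cells}"

        for cfg in self.member_configs:
            report = self.member_reports[cfg.algorithm]
            lines.append(_row(cfg.algorithm, report))
        lines.append(_row("ensemble (soft vote)", self.ensemble_report))
        lines.append("")
        members = ", ".join(c.algorithm for c in self.ensemble_spec.members)
        lines.append(f"ensemble members: {members}")
        for cfg in self.member_configs:
            feats = ", ".join(cfg.selected_features)
            lines.append(f"  {cfg.algorithm}: features [{feats}]")
        return "\n".join(lines)


class SeverityModel(PathogenicityModel):
    """Benign-vs-severe classifier over pathogenic variants.

    Requires a feature matrix without endpoint residue one-hots; ``fit()``
    additionally optimizes the decision threshold for balanced accuracy on
    training predictions and returns :class:`SeverityResults`.
    """

    task = "severity"
    positive_label = "severe"
    negative_label = "benign"

    def __init__(self, features, labels, split, candidates=DEFAULT_CANDIDATES):
        check_no_endpoint_features(features)
        super().__init__(features, labels, split, candidates)

    @classmethod
    def from_gene(cls, gene, data: pd.DataFrame, sigma: float | None = None, **kwargs):
        merged = merge_severity_labels(data)
        profiles = gene.profiles(sigma=sigma)
        X = build_feature_matrix(
            list(merged["variant"]),
            profiles,
            gene.domain_map,
            include_endpoint_aa=False,
        )
        return cls(X, merged["label"], merged["split"], **kwargs)

    def fit(self, **kwargs) -> "SeverityResults":
        base = super().fit(**kwargs)
        train_scores = base.fitted_ensemble.predict_proba(self.dataset.train_X)
        threshold, train_ba = optimize_threshold(train_scores, self.dataset.train_y)
        thresholded = ThresholdedModel(base.fitted_ensemble, threshold, train_ba)
        return SeverityResults(
            **{f.name: getattr(base, f.name) for f in base.__dataclass_fields__.values()},
            thresholded=thresholded,
        )


@dataclass
class SeverityResults(PathogenicityResults):
    """Severity protocol results with the training-optimized threshold attached."""

    thresholded: ThresholdedModel = None

    @property
    def threshold(self) -> float:
        return self.thresholded.threshold

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.thresholded.predict(X)

    def evaluate_test(self) -> dict:
        ds = self.model.dataset.finalize()
        return self.thresholded.evaluate(ds.test_X, ds.test_y)

    def summary(self) -> str:
        base = super().summary()
        return (
            base
            + f"\ndecision threshold (train-optimized): {self.threshold:.4f}"
            + f" (training balanced accuracy {self.thresholded.training_balanced_accuracy:.3f})"
        )
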