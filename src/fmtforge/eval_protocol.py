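"""Recipient-grouped cross-validation, LODO, metrics and model comparison.

All evaluation is leakage-guarded: every sample of a recipient subject stays
in a single fold, and preprocessing/covariate statistics are learned on the
training rows of each fold only (enforced by the per-fold `fit` calls).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import predictor as pred_mod
from .predictor import PredictionTask, TrainedPredictor, build_design
from .prep import PrepRecipe
from .tables_io import CohortBundle


@dataclasses.dataclass
class FoldPlan:
    """Assignment of recipient subjects to folds."""

    k: int
    subject_fold: dict[str, int]
    seed: int

    def fold_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.subject_fold.items() if f == fold}


@dataclasses.dataclass
class EvalMetrics:
    """Per-fold held-out metrics with mean +/- standard error."""

    per_fold_r2: list[float]
    per_fold_scc: list[float]
    per_fold_auc: list[float]
    skipped_folds: list[int]
    predictions: dict[str, float]  # held-out prediction per recipient sample
    truths: dict[str, float]
    days: dict[str, float]

    def _summ(self, vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            return float("nan"), float("nan")
        se = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
        return float(arr.mean()), float(se)

    @property
    def r2(self) -> float:
        return self._summ(self.per_fold_r2)[0]

    @property
    def scc(self) -> float:
        return self._summ(self.per_fold_scc)[0]

    @property
    def auc(self) -> float:
        return self._summ(self.per_fold_auc)[0]

    def summary(self) -> dict:
        out = {}
        for name, vals in (
            ("r2", self.per_fold_r2), ("scc", self.per_fold_scc), ("auc", self.per_fold_auc)
        ):
            mean, se = self._summ(vals)
            out[name] = {"mean": mean, "se": se, "per_fold": list(vals)}
        out["skipped_folds"] = list(self.skipped_folds)
        return out


def grouped_kfold(bundle: CohortBundle, k: int = 10, seed: int = 0) -> FoldPlan:
    """Partition recipient subjects into k near-equal folds (deterministic).

    A recipient's samples never span folds, preventing leakage of the
    recipient's own trajectory between train and test.
    """
    subjects = sorted({
        bundle.metadata[rid].subject_id for rid in bundle.pairing
    })
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} recipients < {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignment = {subjects[i]: int(f % k) for f, i in enumerate(order)}
    return FoldPlan(k=k, subject_fold=assignment, seed=seed)


def _score_fold(task: PredictionTask, y_true: np.ndarray, y_pred: np.ndarray):
    r2 = scc = auc = None
    if task.task_type == "binary":
        auc = auc_score(y_true, y_pred)
    else:
        ss_res = float(np.sum((y_true - y_pred) ** 2))
        ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
        if np.ptp(y_pred) == 0:
            scc = 0.0  # constant predictions carry no monotone association
        else:
            scc = float(stats.spearmanr(y_true, y_pred).statistic)
    return r2, scc, auc


def auc_score(y_true: np.ndarray, y_score: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y_true, y_score))


def cross_validate(
    task: PredictionTask,
    bundle: CohortBundle,
    model_kind: str,
    plan: FoldPlan,
    hyperparams: dict | None = None,
    seed: int = 0,
    recipe: PrepRecipe | None = None,
    labels: Mapping[str, float] | None = None,
) -> EvalMetrics:
    """k-fold CV with metrics computed on held-out folds only.

    `labels` optionally overrides the task labels per recipient sample
    (used e.g. for permutation nulls).
    """
    recipe = recipe or PrepRecipe()
    sample_subject = {rid: bundle.metadata[rid].subject_id for rid in bundle.pairing}
    post = [rid for rid, (_, day, _) in sorted(bundle.pairing.items()) if day > 0]
    metrics = EvalMetrics([], [], [], [], {}, {}, {})
    for fold in range(plan.k):
        test_subjects = plan.fold_subjects(fold)
        train_ids = [r for r in post if sample_subject[r] not in test_subjects]
        test_ids = [r for r in post if sample_subject[r] in test_subjects]
        if not test_ids:
            continue
        y_train_override = None
        if labels is not None:
            y_train_override = labels
        try:
            model = _fit_fold(
                task, bundle, model_kind, train_ids, hyperparams, seed, recipe,
                y_train_override,
            )
        except ValueError as err:
            warnings.warn(f"fold {fold} skipped: {err}")
            metrics.skipped_folds.append(fold)
            continue
        y_pred, y_true, days = _predict_samples(model, task, bundle, test_ids, recipe, labels)
        if np.ptp(y_true) == 0:
            warnings.warn(f"fold {fold} has constant held-out labels; skipped")
            metrics.skipped_folds.append(fold)
            continue
        r2, scc, auc = _score_fold(task, y_true, y_pred)
        if r2 is not None:
            metrics.per_fold_r2.append(r2)
        if scc is not None:
            metrics.per_fold_scc.append(scc)
        if auc is not None:
            metrics.per_fold_auc.append(auc)
        for rid, yp, yt, d in zip(test_ids, y_pred, y_true, days):
            metrics.predictions[rid] = float(yp)
            metrics.truths[rid] = float(yt)
            metrics.days[rid] = float(d)
    return metrics


def _fit_fold(task, bundle, model_kind, train_ids, hyperparams, seed, recipe, labels):
    if labels is None:
        return pred_mod.fit(
            task, bundle, model_kind, hyperparams, seed=seed, recipe=recipe,
            include_samples=train_ids, min_pairs=5,
        )
    # label override: rebuild the design with substituted y
    design = build_design(task, bundle, recipe, include_samples=train_ids)
    y = np.array([labels[r] for r in design.recipient_samples])
    if np.ptp(y) == 0:
        raise ValueError("constant labels; nothing to learn")
    if model_kind == "imic_cnn":
        from ._cnn import CNNConfig, ConvImageNet

        encoder = pred_mod.ImageEncoder(design.taxa, design.X.mean(axis=0))
        cfg = CNNConfig(**(hyperparams or {}))
        model = ConvImageNet(task.task_type, cfg, seed=seed)
        model.fit(encoder.encode(design.X), design.covariates, y, design.groups)
    else:
        encoder = None
        model = pred_mod._make_sklearn_model(model_kind, task.task_type, hyperparams or {}, seed)
        model.fit(np.hstack([design.X, design.covariates]), y)
    return TrainedPredictor(
        task=task, recipe=recipe, model_kind=model_kind, taxa=design.taxa,
        covariate_fields=design.covariate_fields, covariate_stats=design.covariate_stats,
        model=model, encoder=encoder, seed=seed, zscore_stats=design.zscore_stats,
        label_range=(float(y.min()), float(y.max())),
    )


def _predict_samples(model, task, bundle, sample_ids, recipe, labels=None):
    design = build_design(
        task, bundle, recipe, include_samples=sample_ids,
        covariate_fields=model.covariate_fields, covariate_stats=model.covariate_stats,
        zscore_stats=model.zscore_stats,
    )
    y_pred = model.predict_matrix(design.X, design.covariates)
    y_true = design.y
    if labels is not None:
        y_true = np.array([labels[r] for r in design.recipient_samples])
    return y_pred, y_true, design.days


def lodo(
    task: PredictionTask,
    bundle: CohortBundle,
    holdout_cohort: str,
    model_kind: str = "imic_cnn",
    hyperparams: dict | None = None,
    seed: int = 0,
    recipe: PrepRecipe | None = None,
) -> EvalMetrics:
    """Leave-one-dataset-out: train on every cohort except the holdout."""
    recipe = recipe or PrepRecipe()
    cohorts = bundle.cohort_ids
    if holdout_cohort not in cohorts:
        raise ValueError(f"unknown cohort {holdout_cohort!r}; have {cohorts}")
    if len(cohorts) < 2:
        raise ValueError("LODO needs at least two cohorts")
    post = [rid for rid, (_, day, _) in sorted(bundle.pairing.items()) if day > 0]
    train_ids = [r for r in post if bundle.pairing[r][2] != holdout_cohort]
    test_ids = [r for r in post if bundle.pairing[r][2] == holdout_cohort]
    if not test_ids:
        raise ValueError(f"holdout cohort {holdout_cohort!r} has no post-FMT samples")
    model = pred_mod.fit(
        task, bundle, model_kind, hyperparams, seed=seed, recipe=recipe,
        include_samples=train_ids,
    )
    y_pred, y_true, days = _predict_samples(model, task, bundle, test_ids, recipe)
    r2, scc, auc = _score_fold(task, y_true, y_pred)
    return EvalMetrics(
        per_fold_r2=[r2] if r2 is not None else [],
        per_fold_scc=[scc] if scc is not None else [],
        per_fold_auc=[auc] if auc is not None else [],
        skipped_folds=[],
        predictions={r: float(p) for r, p in zip(test_ids, y_pred)},
        truths={r: float(t) for r, t in zip(test_ids, y_true)},
        days={r: float(d) for r, d in zip(test_ids, days)},
    )


def compare_models(
    metrics_by_model: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA on per-fold metrics; if significant, paired one-sided
    t-tests of every model against the best-on-average model."""
    names = sorted(metrics_by_model)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    vectors = [np.asarray(metrics_by_model[n], dtype=float) for n in names]
    sizes = {len(v) for v in vectors}
    if len(sizes) > 1:
        raise ValueError(f"unequal fold counts: { {n: len(v) for n, v in zip(names, vectors)} }")
    if all(np.array_equal(v, vectors[0]) for v in vectors[1:]):
        return {"anova_F": 0.0, "anova_p": 1.0, "best_model": names[0], "pairwise": {}}
    f_stat, p = stats.f_oneway(*vectors)
    best = names[int(np.argmax([v.mean() for v in vectors]))]
    report = {"anova_F": float(f_stat), "anova_p": float(p), "best_model": best, "pairwise": {}}
    if p < alpha:
        best_v = np.asarray(metrics_by_model[best], dtype=float)
        for n, v in zip(names, vectors):
            if n == best:
                continue
            t, pp = stats.ttest_rel(best_v, v, alternative="greater")
            report["pairwise"][n] = {"t": float(t), "p": float(pp)}
    return report


def scc_by_time(
    task: PredictionTask,
    bundle: CohortBundle,
    model_kind: str,
    bins: Sequence[tuple[float, float]],
    k: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
    recipe: PrepRecipe | None = None,
) -> dict:
    """Held-out Spearman correlation per days-post-FMT bin.

    Runs one grouped k-fold CV, pools the held-out predictions, then scores
    each half-open bin [lo, hi). Empty bins are reported as missing.
    """
    plan = grouped_kfold(bundle, k=k, seed=seed)
    metrics = cross_validate(task, bundle, model_kind, plan, hyperparams, seed, recipe)
    out: dict[str, dict] = {}
    for lo, hi in bins:
        ids = [r for r, d in metrics.days.items() if lo <= d < hi]
        key = f"[{lo},{hi})"
        if len(ids) < 3:
            out[key] = {"scc": None, "n": len(ids)}
            continue
        yt = np.array([metrics.truths[r] for r in ids])
        yp = np.array([metrics.predictions[r] for r in ids])
        out[key] = {"scc": float(stats.spearmanr(yt, yp).statistic), "n": len(ids)}
    return out
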