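"""Donor-only outcome predictors: taxonomy-image CNN plus a baseline bank.

The central representation is the microbiome image: a (ranks x leaves)
matrix in which row r holds, for every leaf column, the value of the leaf's
ancestor at rank r (the mean abundance over the leaves of that ancestor's
subtree). Contiguous leaf blocks under one ancestor therefore form constant
segments that a small convolutional network can exploit. Baseline models
(ridge, kNN, SVR, random forest, gradient boosting, dense net) consume the
identical flattened design matrix, so model comparisons are confounder-free.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from ._cnn import CNNConfig, ConvImageNet
from .prep import (
    CovariateVector,
    PrepRecipe,
    assemble_covariates,
    close_to_relative,
    covariate_matrix,
    merge_to_level,
    normalize,
    shannon,
    standardize_covariates,
)
from .tables_io import RANK_NAMES, CohortBundle, FeatureTable, TaxonomyString

MODEL_KINDS = ("imic_cnn", "ridge", "knn", "svr", "rf", "gboost", "dense_nn")


@dataclasses.dataclass(frozen=True)
class PredictionTask:
    """One prediction target: what to predict in the recipient, and when.

    target: "shannon", "taxon_abundance", "taxon_presence" or
    "clinical_outcome"; taxon/level select the taxon for per-taxon tasks.
    One model is fitted per task.
    """

    target: str
    taxon: str | None = None
    level: str = "order"
    horizon: int = 7

    def __post_init__(self) -> None:
        if self.target not in ("shannon", "taxon_abundance", "taxon_presence", "clinical_outcome"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.target.startswith("taxon_") and self.taxon is None:
            raise ValueError("per-taxon task needs a taxon")

    @property
    def task_type(self) -> str:
        return "binary" if self.target in ("taxon_presence", "clinical_outcome") else "regression"


# ---------------------------------------------------------------------------
# taxonomy tree and image


class TaxonomyTree:
    """Rooted tree over full root-to-leaf taxonomy paths.

    The per-sample value of an internal node is the mean abundance over the
    leaves of its subtree, so row r of the derived image coincides with a
    mean-merge of the leaf vector at rank r.
    """

    def __init__(self, taxa: Sequence[TaxonomyString]):
        if not taxa:
            raise ValueError("empty taxa list")
        self.leaves = [t.filled() for t in taxa]
        self.n_ranks = len(RANK_NAMES)
        # children map: path tuple -> sorted set of child labels
        self.children: dict[tuple[str, ...], set[str]] = {(): set()}
        for leaf in self.leaves:
            path: tuple[str, ...] = ()
            for lab in leaf.labels:
                self.children.setdefault(path, set()).add(lab)
                path = path + (lab,)
                self.children.setdefault(path, set())

    def node_values(self, x: np.ndarray) -> dict[tuple[str, ...], float]:
        """Value of every node for one leaf vector x (subtree leaf mean)."""
        x = np.asarray(x, dtype=float)
        sums: dict[tuple[str, ...], float] = {}
        counts: dict[tuple[str, ...], int] = {}
        for j, leaf in enumerate(self.leaves):
            for k in range(self.n_ranks + 1):
                p = tuple(leaf.labels[:k])
                sums[p] = sums.get(p, 0.0) + x[j]
                counts[p] = counts.get(p, 0) + 1
        return {p: sums[p] / counts[p] for p in sums}


def build_tree(taxa: Sequence[TaxonomyString], values: np.ndarray | None = None) -> TaxonomyTree:
    """Build the taxonomy tree; `values` is kept only for API symmetry."""
    return TaxonomyTree(taxa)


class ImageEncoder:
    """Turns leaf abundance vectors into (ranks x leaves) microbiome images.

    Leaf order is a depth-first traversal with the children of every node
    sorted by descending mean reference abundance of their subtree (ties
    lexicographic); the reference is the training-set mean, so the column
    order is fixed at fit time.
    """

    def __init__(self, taxa: Sequence[TaxonomyString], reference: np.ndarray | None = None):
        self.tree = TaxonomyTree(taxa)
        leaves = self.tree.leaves
        n = len(leaves)
        ref = np.asarray(reference, dtype=float) if reference is not None else np.zeros(n)
        # subtree reference means for ordering
        ref_vals = self.tree.node_values(ref)
        leaf_index = {leaf.labels: j for j, leaf in enumerate(leaves)}

        order: list[int] = []

        def dfs(path: tuple[str, ...]) -> None:
            kids = self.tree.children.get(path, set())
            if not kids:
                order.append(leaf_index[path])
                return
            for lab in sorted(kids, key=lambda l: (-ref_vals[path + (l,)], l)):
                dfs(path + (lab,))

        dfs(())
        self.leaf_order = np.array(order)
        # per-rank group averaging operators under the fixed leaf order
        ordered = [leaves[j] for j in self.leaf_order]
        self._group_ids: list[np.ndarray] = []
        self._group_mats: list[np.ndarray] = []
        for r in range(self.tree.n_ranks):
            keys = [t.labels[: r + 1] for t in ordered]
            uniq: dict[tuple[str, ...], int] = {}
            gid = np.array([uniq.setdefault(k, len(uniq)) for k in keys])
            mat = np.zeros((len(uniq), n))
            for c, g in enumerate(gid):
                mat[g, c] = 1.0
            mat /= mat.sum(axis=1, keepdims=True)
            self._group_ids.append(gid)
            self._group_mats.append(mat)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    @property
    def n_ranks(self) -> int:
        return self.tree.n_ranks

    def encode(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_leaves) -> (n_samples, n_ranks, n_leaves) images."""
        X = np.atleast_2d(np.asarray(X, dtype=float))[:, self.leaf_order]
        images = np.empty((X.shape[0], self.n_ranks, self.n_leaves))
        for r, (gid, mat) in enumerate(zip(self._group_ids, self._group_mats)):
            group_means = X @ mat.T  # (n_samples, n_groups)
            images[:, r, :] = group_means[:, gid]
        return images


def to_image(
    tree_or_taxa: TaxonomyTree | Sequence[TaxonomyString],
    x: np.ndarray,
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-shot image build for a single leaf vector.

    Returns (image, leaf_order). The ordering reference defaults to the
    vector itself.
    """
    taxa = tree_or_taxa.leaves if isinstance(tree_or_taxa, TaxonomyTree) else list(tree_or_taxa)
    x = np.asarray(x, dtype=float)
    enc = ImageEncoder(taxa, reference if reference is not None else x)
    return enc.encode(x[None, :])[0], enc.leaf_order


# ---------------------------------------------------------------------------
# training-set assembly


@dataclasses.dataclass
class DesignMatrix:
    """Model-ready design: one row per post-FMT recipient sample."""

    recipient_samples: list[str]
    donor_samples: list[str]
    X: np.ndarray  # preprocessed donor vectors, log space
    covariates: np.ndarray  # standardized numeric covariates
    y: np.ndarray
    groups: np.ndarray  # recipient subject ids
    cohorts: np.ndarray
    days: np.ndarray
    taxa: list[TaxonomyString]
    covariate_fields: list[str]
    covariate_stats: tuple[np.ndarray, np.ndarray] | None = None
    zscore_stats: tuple[np.ndarray, np.ndarray] | None = None


def _label_for(task: PredictionTask, bundle: CohortBundle, recipient_sample: str) -> float | None:
    md = bundle.metadata[recipient_sample]
    if task.target == "clinical_outcome":
        return None if md.outcome is None else float(md.outcome)
    idx = bundle.recipients.sample_ids.index(recipient_sample)
    comp = bundle.recipients.values[idx]
    if comp.sum() == 0:
        return None
    if task.target == "shannon":
        return shannon(comp)
    level_table = merge_to_level(
        FeatureTable([recipient_sample], list(bundle.recipients.taxa), comp[None, :],
                     bundle.recipients.space_tag),
        task.level, "sum",
    )
    names = [str(t) for t in level_table.taxa]
    if task.taxon not in names:
        value = 0.0
    else:
        value = float(level_table.values[0, names.index(task.taxon)])
    total = level_table.values[0].sum()
    rel = value / total if total > 0 else 0.0
    if task.target == "taxon_presence":
        return float(rel > 0)
    return rel


def build_design(
    task: PredictionTask,
    bundle: CohortBundle,
    recipe: PrepRecipe,
    include_samples: Sequence[str] | None = None,
    covariate_fields: Sequence[str] = ("days_post_fmt",),
    covariate_stats: tuple[np.ndarray, np.ndarray] | None = None,
    zscore_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> DesignMatrix:
    """Assemble (donor features, covariates, label) rows for recipient samples.

    Only post-FMT samples (days_post_fmt > 0) yield rows. Standardization
    statistics (z-score per taxon, covariate mean/sd) are taken from
    `covariate_stats` / `zscore_stats` when given (i.e. frozen from the
    training split); otherwise they are learned from the rows built here,
    which are exactly the training rows during a fit.
    """
    wanted = set(include_samples) if include_samples is not None else None
    rows = []
    for rid, (did, day, cohort) in sorted(bundle.pairing.items()):
        if day <= 0:
            continue
        if wanted is not None and rid not in wanted:
            continue
        y = _label_for(task, bundle, rid)
        if y is None:
            continue
        rows.append((rid, did, day, cohort, y))
    if not rows:
        raise ValueError(f"no labelled post-FMT samples for task {task.target!r}")
    rids = [r[0] for r in rows]
    dids = [r[1] for r in rows]
    used_donors = sorted(set(dids))
    merged = merge_to_level(
        bundle.donors.select_samples(used_donors), recipe.merge_level, recipe.merge_method
    )
    if recipe.zscore and zscore_stats is None:
        from .prep import zscore_stats as _zs

        zscore_stats = _zs(merged, recipe)
    donors_prep = normalize(merged, recipe, zscore_stats)
    donor_pos = {s: i for i, s in enumerate(donors_prep.sample_ids)}
    extra = [f for f in covariate_fields if f != "days_post_fmt"]
    if extra:
        donor_meta_ids = dids
        covs = assemble_covariates(bundle.metadata, donor_meta_ids, fields=tuple(extra))
    else:
        covs = [CovariateVector(sample_id=d, days_post_fmt=None, age=None, sex=None, weight=None)
                for d in dids]
    for cv, (_, _, day, _, _) in zip(covs, rows):
        cv.days_post_fmt = float(day)
    if covariate_stats is None:
        covariate_stats = standardize_covariates(covs, covariate_fields)
    cov_mat = covariate_matrix(covs, covariate_fields, covariate_stats)
    return DesignMatrix(
        recipient_samples=rids,
        donor_samples=dids,
        X=donors_prep.values[[donor_pos[d] for d in dids]],
        covariates=cov_mat,
        y=np.array([r[4] for r in rows]),
        groups=np.array([bundle.metadata[r].subject_id for r in rids], dtype=object),
        cohorts=np.array([r[3] for r in rows], dtype=object),
        days=np.array([r[2] for r in rows], dtype=float),
        taxa=list(donors_prep.taxa),
        covariate_fields=list(covariate_fields),
        covariate_stats=covariate_stats,
        zscore_stats=zscore_stats,
    )


# ---------------------------------------------------------------------------
# model bank


def _make_sklearn_model(model_kind: str, task_type: str, hyperparams: dict, seed: int):
    hp = dict(hyperparams)
    if model_kind == "ridge":
        if task_type == "regression":
            from sklearn.linear_model import Ridge
            return Ridge(alpha=hp.pop("alpha", 1.0))
        from sklearn.linear_model import LogisticRegression
        return LogisticRegression(C=hp.pop("C", 1.0), max_iter=2000)
    if model_kind == "knn":
        if task_type == "regression":
            from sklearn.neighbors import KNeighborsRegressor
            return KNeighborsRegressor(n_neighbors=hp.pop("n_neighbors", 5))
        from sklearn.neighbors import KNeighborsClassifier
        return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5))
    if model_kind == "svr":
        if task_type == "regression":
            from sklearn.svm import SVR
            return SVR(C=hp.pop("C", 1.0))
        from sklearn.svm import SVC
        return SVC(C=hp.pop("C", 1.0), probability=True, random_state=seed)
    if model_kind == "rf":
        if task_type == "regression":
            from sklearn.ensemble import RandomForestRegressor
            return RandomForestRegressor(
                n_estimators=hp.pop("n_estimators", 200), random_state=seed, n_jobs=1
            )
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 200), random_state=seed, n_jobs=1
        )
    if model_kind == "gboost":
        import xgboost as xgb
        common = dict(
            n_estimators=hp.pop("n_estimators", 150),
            max_depth=hp.pop("max_depth", 4),
            learning_rate=hp.pop("learning_rate", 0.1),
            random_state=seed, n_jobs=1, verbosity=0,
        )
        if task_type == "regression":
            return xgb.XGBRegressor(**common)
        return xgb.XGBClassifier(**common)
    if model_kind == "dense_nn":
        if task_type == "regression":
            from sklearn.neural_network import MLPRegressor
            return MLPRegressor(
                hidden_layer_sizes=hp.pop("hidden_layer_sizes", (64, 32)),
                max_iter=hp.pop("max_iter", 500), random_state=seed,
            )
        from sklearn.neural_network import MLPClassifier
        return MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (64, 32)),
            max_iter=hp.pop("max_iter", 500), random_state=seed,
        )
    raise ValueError(f"unknown model kind {model_kind!r}")


@dataclasses.dataclass
class TrainedPredictor:
    """A fitted model for one task: recipe + schema + state, replayable."""

    task: PredictionTask
    recipe: PrepRecipe
    model_kind: str
    taxa: list[TaxonomyString]
    covariate_fields: list[str]
    covariate_stats: tuple[np.ndarray, np.ndarray]
    model: object
    encoder: ImageEncoder | None
    seed: int
    zscore_stats: tuple[np.ndarray, np.ndarray] | None = None
    label_range: tuple[float, float] | None = None

    def predict_matrix(self, X: np.ndarray, cov: np.ndarray) -> np.ndarray:
        """Predict from preprocessed donor vectors + standardized covariates.

        Regression outputs are bounded to the training label range: the
        model has no evidence for values outside it, and an optimizer run
        against the predictor must not be rewarded for extrapolation.
        """
        if self.model_kind == "imic_cnn":
            out = self.model.predict(self.encoder.encode(X), cov)
        else:
            design = np.hstack([X, cov])
            if self.task.task_type == "binary":
                return self.model.predict_proba(design)[:, 1]
            out = self.model.predict(design)
        if self.task.task_type == "regression" and self.label_range is not None:
            out = np.clip(out, *self.label_range)
        return out


def fit(
    task: PredictionTask,
    bundle: CohortBundle,
    model_kind: str = "imic_cnn",
    hyperparams: dict | None = None,
    seed: int = 0,
    recipe: PrepRecipe | None = None,
    include_samples: Sequence[str] | None = None,
    covariate_fields: Sequence[str] = ("days_post_fmt",),
    min_pairs: int = 20,
) -> TrainedPredictor:
    """Train one predictor for `task` on the bundle's donor/recipient pairs."""
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    hyperparams = dict(hyperparams or {})
    recipe = recipe or PrepRecipe()
    design = build_design(
        task, bundle, recipe, include_samples=include_samples,
        covariate_fields=covariate_fields,
    )
    if len(design.y) < min_pairs:
        raise ValueError(f"only {len(design.y)} training pairs; need >= {min_pairs}")
    if np.ptp(design.y) == 0:
        raise ValueError("constant labels; nothing to learn")
    # covariate standardization statistics frozen from the training rows
    cov_stats = design.covariate_stats

    encoder = None
    if model_kind == "imic_cnn":
        reference = design.X.mean(axis=0)
        encoder = ImageEncoder(design.taxa, reference)
        cnn_cfg = CNNConfig(**hyperparams) if hyperparams else CNNConfig()
        model = ConvImageNet(task.task_type, cnn_cfg, seed=seed)
        model.fit(encoder.encode(design.X), design.covariates, design.y, design.groups)
    else:
        model = _make_sklearn_model(model_kind, task.task_type, hyperparams, seed)
        model.fit(np.hstack([design.X, design.covariates]), design.y)
    return TrainedPredictor(
        task=task, recipe=recipe, model_kind=model_kind, taxa=design.taxa,
        covariate_fields=list(design.covariate_fields), covariate_stats=cov_stats,
        model=model, encoder=encoder, seed=seed, zscore_stats=design.zscore_stats,
        label_range=(float(design.y.min()), float(design.y.max())),
    )


def predict(
    model: TrainedPredictor,
    donors: FeatureTable,
    covariates: Mapping[str, Sequence[float]] | None = None,
) -> np.ndarray:
    """Predict the recipient outcome for each donor row.

    `donors` may be raw (counts/relative on the leaf axis, preprocessed
    here via the stored recipe) or already merged to the training taxon
    axis. Covariates default to days_post_fmt = the task horizon.
    """
    train_names = [str(t) for t in model.taxa]
    if [str(t) for t in donors.taxa] == train_names:
        table = donors
        if table.space_tag != "log_normalized":
            table = normalize(table, model.recipe, model.zscore_stats)
    else:
        merged = merge_to_level(donors, model.recipe.merge_level, model.recipe.merge_method)
        names = [str(t) for t in merged.taxa]
        if set(names) - set(train_names):
            missing = sorted(set(names) - set(train_names))[:5]
            raise ValueError(f"donor taxa not seen in training (e.g. {missing})")
        values = np.zeros((merged.n_samples, len(train_names)))
        pos = {n: j for j, n in enumerate(train_names)}
        for j, n in enumerate(names):
            values[:, pos[n]] = merged.values[:, j]
        table = normalize(
            FeatureTable(list(merged.sample_ids), list(model.taxa), values, merged.space_tag),
            model.recipe, model.zscore_stats,
        )
    n = table.n_samples
    cov = np.zeros((n, len(model.covariate_fields)))
    defaults = {"days_post_fmt": float(model.task.horizon)}
    for j, field in enumerate(model.covariate_fields):
        if covariates is not None and field in covariates:
            cov[:, j] = np.asarray(covariates[field], dtype=float)
        else:
            cov[:, j] = defaults.get(field, 0.0)
    mu, sd = model.covariate_stats
    cov = np.nan_to_num((cov - mu) / sd, nan=0.0)
    return model.predict_matrix(table.values, cov)


def raw_donor_recipient_scc(bundle: CohortBundle, property: str = "shannon") -> float:
    """Spearman correlation between a donor property and the paired recipient
    property post-FMT — the univariate baseline the multivariate models are
    measured against."""
    donor_pos = {s: i for i, s in enumerate(bundle.donors.sample_ids)}
    recip_pos = {s: i for i, s in enumerate(bundle.recipients.sample_ids)}

    def prop(table: FeatureTable, idx: int) -> float:
        comp = table.values[idx]
        if property == "shannon":
            return shannon(comp)
        names = [str(t) for t in table.taxa]
        return float(comp[names.index(property)] / comp.sum())

    xs, ys = [], []
    for rid, (did, day, _) in bundle.pairing.items():
        if day <= 0:
            continue
        xs.append(prop(bundle.donors, donor_pos[did]))
        ys.append(prop(bundle.recipients, recip_pos[rid]))
    if len(xs) < 3:
        raise ValueError("need at least 3 donor/recipient pairs")
    return float(spearmanr(xs, ys).statistic)
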