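"""MIPMLP-style preprocessing: taxonomic merge, normalization, covariates.

The preprocessing pipeline mirrors the MIPMLP protocol used for 16S feature
tables: merge leaf taxa to a chosen taxonomic level ("mean" or "sum"), close
each sample to relative abundance, then log-transform (log10(x + eps)) with
an optional per-taxon z-score learned on the training split only.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .tables_io import (
    RANK_INDEX,
    FeatureTable,
    SampleMetadata,
    TaxonomyString,
)


@dataclasses.dataclass
class PrepRecipe:
    """Replayable preprocessing recipe.

    merge_level/merge_method control the taxonomic merge; normalization is
    either plain closure ("relative_only") or closure followed by
    log10(x + log_epsilon) ("relative_then_log"); zscore standardizes each
    taxon across samples using statistics frozen from the training split.
    """

    merge_level: str = "species"
    merge_method: str = "mean"
    normalization: str = "relative_then_log"
    log_epsilon: float = 1e-4
    zscore: bool = False

    def __post_init__(self) -> None:
        if self.log_epsilon <= 0:
            raise ValueError("log_epsilon must be positive")
        if self.merge_method not in ("mean", "sum"):
            raise ValueError(f"unknown merge method {self.merge_method!r}")
        if self.normalization not in ("relative_then_log", "relative_only"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.merge_level not in RANK_INDEX:
            raise ValueError(f"unknown rank {self.merge_level!r}")


def merge_to_level(table: FeatureTable, level: str, method: str = "mean") -> FeatureTable:
    """Merge leaf taxa by their lineage truncated at `level`.

    method="sum" adds member leaves per sample (conserves row totals);
    method="mean" averages them. Output taxa are the truncated paths in
    lexicographic order.
    """
    if method not in ("mean", "sum"):
        raise ValueError(f"unknown merge method {method!r}")
    k = RANK_INDEX[level] + 1
    if all(t.depth < k for t in table.taxa):
        raise ValueError(f"no taxon resolved to {level} level")
    groups: dict[TaxonomyString, list[int]] = {}
    for j, t in enumerate(table.taxa):
        trunc = t.filled().at_rank(level)
        groups.setdefault(trunc, []).append(j)
    keys = sorted(groups)
    values = np.empty((table.n_samples, len(keys)))
    for out_j, key in enumerate(keys):
        cols = table.values[:, groups[key]]
        values[:, out_j] = cols.sum(axis=1) if method == "sum" else cols.mean(axis=1)
    tag = table.space_tag
    if method == "mean" and tag == "relative":
        tag = "counts"  # means of relative parts no longer close to 1
    return FeatureTable(list(table.sample_ids), keys, values, tag)


def close_to_relative(table: FeatureTable) -> FeatureTable:
    """Close each row onto the simplex."""
    sums = table.values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"all-zero sample row: {table.sample_ids[zero[0]]!r}")
    return FeatureTable(
        list(table.sample_ids), list(table.taxa), table.values / sums[:, None], "relative"
    )


def normalize(
    table: FeatureTable,
    recipe: PrepRecipe,
    zscore_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureTable:
    """Close to relative abundance, then optionally log10(x + eps) and z-score.

    `zscore_stats` (mean, sd per taxon) must come from the training split
    when given; when absent they are computed from `table` itself. Re-running
    on an already log-normalized table is an error (no double transform).
    """
    if table.space_tag == "log_normalized":
        raise ValueError("table is already log-normalized")
    rel = close_to_relative(table)
    if recipe.normalization == "relative_only":
        return rel
    values = np.log10(rel.values + recipe.log_epsilon)
    if recipe.zscore:
        if zscore_stats is None:
            mu = values.mean(axis=0)
            sd = values.std(axis=0)
        else:
            mu, sd = zscore_stats
        sd = np.where(sd > 0, sd, 1.0)
        values = (values - mu) / sd
    return FeatureTable(list(table.sample_ids), list(table.taxa), values, "log_normalized")


def zscore_stats(table: FeatureTable, recipe: PrepRecipe) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon mean/sd of the log-transformed training table (for freezing)."""
    rel = close_to_relative(table)
    values = np.log10(rel.values + recipe.log_epsilon)
    return values.mean(axis=0), values.std(axis=0)


def preprocess(
    table: FeatureTable,
    recipe: PrepRecipe,
    zscore_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> FeatureTable:
    """Full pipeline: merge to recipe.merge_level then normalize."""
    merged = merge_to_level(table, recipe.merge_level, recipe.merge_method)
    return normalize(merged, recipe, zscore_stats)


def shannon(p: Sequence[float] | np.ndarray, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i of a composition (nats).

    The vector is closed onto the simplex first, so the statistic is
    scale-invariant; `base` switches the logarithm (default natural log).
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative entries in abundance vector")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = p / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


@dataclasses.dataclass
class CovariateVector:
    """Numeric donor covariates with imputation flags."""

    sample_id: str
    days_post_fmt: float | None
    age: float | None
    sex: float | None  # encoded 0/1
    weight: float | None
    imputed: dict[str, bool] = dataclasses.field(default_factory=dict)

    def as_array(self, fields: Sequence[str]) -> np.ndarray:
        vals = [getattr(self, f) for f in fields]
        return np.array([v if v is not None else np.nan for v in vals], dtype=float)


_SEX_CODES = {"f": 0.0, "female": 0.0, "m": 1.0, "male": 1.0, "0": 0.0, "1": 1.0}


def assemble_covariates(
    metadata: Mapping[str, SampleMetadata],
    sample_ids: Sequence[str],
    impute_policy: str = "cohort_median",
    fields: Sequence[str] = ("age", "sex", "weight"),
) -> list[CovariateVector]:
    """Build per-sample covariate vectors, imputing missing values.

    impute_policy: "cohort_median" fills from the sample's cohort median,
    "global_median" from the whole-set median, "drop" requires complete data
    and errors when a requested covariate is entirely missing.
    """
    if impute_policy not in ("cohort_median", "global_median", "drop"):
        raise ValueError(f"unknown impute policy {impute_policy!r}")

    def raw(md: SampleMetadata, field: str) -> float | None:
        v = getattr(md, field)
        if v is None:
            return None
        if field == "sex":
            return _SEX_CODES.get(str(v).strip().lower())
        return float(v)

    cohort_of = {s: metadata[s].cohort_id for s in sample_ids}
    # per-field medians for imputation
    medians: dict[str, dict[str | None, float]] = {}
    for field in fields:
        vals_by_cohort: dict[str | None, list[float]] = {}
        for s in sample_ids:
            v = raw(metadata[s], field)
            if v is not None:
                vals_by_cohort.setdefault(cohort_of[s], []).append(v)
                vals_by_cohort.setdefault(None, []).append(v)  # global pool
        medians[field] = {
            c: float(np.median(v)) for c, v in vals_by_cohort.items()
        }

    out: list[CovariateVector] = []
    for s in sample_ids:
        md = metadata[s]
        kwargs: dict[str, float | None] = {"days_post_fmt": None, "age": None, "sex": None, "weight": None}
        if md.days_post_fmt is not None:
            kwargs["days_post_fmt"] = float(md.days_post_fmt)
        flags: dict[str, bool] = {}
        for field in fields:
            v = raw(md, field)
            if v is None:
                if impute_policy == "drop":
                    if None not in medians[field]:
                        raise ValueError(f"covariate {field!r} entirely missing")
                    raise ValueError(
                        f"missing {field!r} for sample {s!r} with policy=drop"
                    )
                key = cohort_of[s] if impute_policy == "cohort_median" else None
                pool = medians[field]
                if key not in pool:
                    key = None  # cohort entirely missing -> fall back to global
                if key not in pool and None not in pool:
                    raise ValueError(f"covariate {field!r} entirely missing")
                v = pool.get(key, pool.get(None))
                flags[field] = True
            else:
                flags[field] = False
            kwargs[field] = v
        out.append(CovariateVector(sample_id=s, imputed=flags, **kwargs))
    return out


def standardize_covariates(
    train: Sequence[CovariateVector],
    fields: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean/sd per covariate learned on the training split (leakage control)."""
    mat = np.vstack([c.as_array(fields) for c in train])
    mu = np.nanmean(mat, axis=0)
    sd = np.nanstd(mat, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def covariate_matrix(
    covs: Sequence[CovariateVector],
    fields: Sequence[str],
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    mat = np.vstack([c.as_array(fields) for c in covs]) if covs else np.empty((0, len(fields)))
    if stats is not None:
        mu, sd = stats
        mat = (mat - mu) / sd
    return np.nan_to_num(mat, nan=0.0)
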