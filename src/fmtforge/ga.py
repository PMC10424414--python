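"""Generative genetic algorithm for designing sparse synthetic transplants.

A population of candidate donor profiles (compositions on the simplex) is
scored by a pre-trained predictor: the fitness of candidate i is

    fitness_max(s_i, b_i) = s_i - sum(b_i) * gamma

where s_i is the predicted recipient outcome at the 7-day horizon, b_i the
binary support mask (b_ij = 1 iff abundance a_ij > 0) and gamma >= 0 weighs
the cocktail-size penalty. Minimization negates s_i inside the same form.
Each generation the top `n_select` candidates pass unchanged (elitism) and
the population is refilled by uniform crossover and toggling mutations on
the elites, so the best fitness is non-decreasing.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from .predictor import TrainedPredictor
from .prep import merge_to_level, shannon
from .tables_io import FeatureTable


@dataclasses.dataclass
class GAConfig:
    population_size: int = 100
    n_select: int = 30
    p_mutation: float = 0.3
    p_recombination: float = 0.3
    gamma: float = 0.0
    mode: str = "maximize"
    horizon_days: int = 7
    max_generations: int = 25
    plateau_patience: int | None = None
    mutation_rate_lambda: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_mutation <= 1 and 0 <= self.p_recombination <= 1):
            raise ValueError("operator probabilities must lie in [0, 1]")
        if self.n_select >= self.population_size:
            raise ValueError("n_select must be smaller than population_size")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.mode not in ("maximize", "minimize"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclasses.dataclass
class CandidateDonor:
    """One candidate profile: abundances a on the simplex, mask b = (a > 0)."""

    a: np.ndarray
    lineage: int
    fitness: float = np.nan
    prediction: float = np.nan

    @property
    def b(self) -> np.ndarray:
        return (self.a > 0).astype(int)

    @property
    def nnz(self) -> int:
        return int((self.a > 0).sum())


@dataclasses.dataclass
class GAResult:
    best_fitness: list[float]  # per generation
    mean_elite_nnz: list[float]
    elite_profiles: np.ndarray  # final elites, rows on the simplex
    elite_fitness: np.ndarray
    elite_predictions: np.ndarray
    taxa: list
    generations_run: int
    triviality_scc: float | None = None
    dominant_order_table: dict | None = None


def fitness(s_i: float, b_i: np.ndarray, gamma: float, mode: str = "maximize") -> float:
    """Sparsity-penalized fitness of one candidate."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if not np.isfinite(s_i):
        raise ValueError("predicted outcome must be finite")
    nnz = float(np.sum(np.asarray(b_i) != 0))
    base = s_i if mode == "maximize" else -s_i
    return float(base - nnz * gamma)


def _close(a: np.ndarray) -> np.ndarray:
    a = np.clip(a, 0.0, None)
    total = a.sum()
    if total == 0:
        raise ValueError("candidate lost all taxa")
    return a / total


def expand_pool(
    real_donors: FeatureTable, n_total: int, seed: int = 0, jitter_sd: float = 0.3
) -> FeatureTable:
    """Grow a donor pool to `n_total` profiles by mixing real donors.

    Each synthetic profile takes the support of one randomly drawn parent
    and, on that support, a convex mixture (weight ~ U(0,1)) of the parent
    and a second random donor, multiplied by lognormal jitter and re-closed.
    Keeping the first parent's support preserves per-taxon prevalence.
    """
    n_real = real_donors.n_samples
    if n_real < 2:
        raise ValueError("need at least 2 real donors")
    if n_total < n_real:
        raise ValueError(f"n_total={n_total} smaller than the real pool ({n_real})")
    rng = np.random.default_rng(seed)
    base = real_donors.values / real_donors.values.sum(axis=1, keepdims=True)
    rows = [base[i] for i in range(n_real)]
    ids = list(real_donors.sample_ids)
    for k in range(n_total - n_real):
        i, j = rng.choice(n_real, size=2, replace=False)
        w = rng.random()
        mix = w * base[i] + (1 - w) * base[j]
        support = base[i] > 0
        prof = np.where(support, mix, 0.0)
        if jitter_sd > 0:
            prof = prof * np.exp(rng.normal(0.0, jitter_sd, size=prof.shape))
        rows.append(_close(prof))
        ids.append(f"synthetic_donor_{k}")
    return FeatureTable(ids, list(real_donors.taxa), np.vstack(rows), "relative")


def init_population(donor_pool: FeatureTable, config: GAConfig, rng: np.random.Generator) -> list[CandidateDonor]:
    """Sample the initial population without replacement from the pool."""
    if donor_pool.n_samples < config.population_size:
        raise ValueError(
            f"pool of {donor_pool.n_samples} smaller than population "
            f"{config.population_size}; expand the pool first"
        )
    idx = rng.choice(donor_pool.n_samples, size=config.population_size, replace=False)
    values = donor_pool.values / donor_pool.values.sum(axis=1, keepdims=True)
    return [CandidateDonor(a=values[i].copy(), lineage=k) for k, i in enumerate(idx)]


def mutate(
    candidate: CandidateDonor,
    rng: np.random.Generator,
    pool_values: np.ndarray,
    p_mutation: float,
    rate_lambda: float = 3.0,
    lineage: int | None = None,
) -> CandidateDonor:
    """With probability p_mutation toggle k ~ Poisson(lambda)+1 random taxa.

    A taxon switched on draws its abundance from the pool's empirical
    nonzero distribution for that taxon (global nonzero values as fallback);
    a taxon switched off is zeroed. The vector is re-closed and the mask
    re-derived from the abundances.
    """
    new_lineage = candidate.lineage if lineage is None else lineage
    if rng.random() >= p_mutation:
        return CandidateDonor(a=candidate.a.copy(), lineage=new_lineage)
    a = candidate.a.copy()
    k = int(rng.poisson(rate_lambda)) + 1
    targets = rng.choice(len(a), size=min(k, len(a)), replace=False)
    global_nonzero = pool_values[pool_values > 0]
    for j in targets:
        if a[j] > 0:
            if candidate.nnz > 1:  # never delete the last taxon
                a[j] = 0.0
        else:
            col = pool_values[:, j]
            nz = col[col > 0]
            source = nz if nz.size else global_nonzero
            a[j] = float(rng.choice(source))
    return CandidateDonor(a=_close(a), lineage=new_lineage)


def recombine(
    parent_a: CandidateDonor,
    parent_b: CandidateDonor,
    rng: np.random.Generator,
    p_recombination: float,
    lineage: int,
) -> CandidateDonor:
    """Uniform crossover with probability p_recombination, else a clone.

    Each taxon's abundance comes from either parent with equal probability;
    the offspring support is therefore a subset of the parents' union.
    """
    if parent_a.a.shape != parent_b.a.shape:
        raise ValueError("parents on different taxon axes")
    if rng.random() >= p_recombination:
        src = parent_a if rng.random() < 0.5 else parent_b
        return CandidateDonor(a=src.a.copy(), lineage=lineage)
    pick = rng.random(parent_a.a.shape) < 0.5
    child = np.where(pick, parent_a.a, parent_b.a)
    if child.sum() == 0:  # degenerate crossover of disjoint supports
        child = parent_a.a.copy()
    return CandidateDonor(a=_close(child), lineage=lineage)


def select(population: Sequence[CandidateDonor], config: GAConfig) -> list[CandidateDonor]:
    """Top n_select by fitness; ties by fewer nonzero taxa, then lineage."""
    if len(population) < config.n_select:
        raise ValueError("population smaller than n_select")
    ranked = sorted(population, key=lambda c: (-c.fitness, c.nnz, c.lineage))
    return ranked[: config.n_select]


def _evaluate(
    population: Sequence[CandidateDonor],
    model: TrainedPredictor,
    taxa,
    config: GAConfig,
) -> None:
    todo = [c for c in population if not np.isfinite(c.fitness)]
    if not todo:
        return
    X = np.vstack([c.a for c in todo])
    table = FeatureTable(
        [f"cand{k}" for k in range(len(todo))], list(taxa), X, "relative"
    )
    from .predictor import predict as _predict

    s = _predict(model, table, {"days_post_fmt": [config.horizon_days] * len(todo)})
    for c, s_i in zip(todo, s):
        c.prediction = float(s_i)
        c.fitness = fitness(s_i, c.b, config.gamma, config.mode)


def run(
    config: GAConfig,
    model: TrainedPredictor,
    donor_pool: FeatureTable,
) -> GAResult:
    """Run the full GA loop and summarize the final elite community."""
    rng = np.random.default_rng(config.seed)
    pool_values = donor_pool.values / donor_pool.values.sum(axis=1, keepdims=True)
    population = init_population(donor_pool, config, rng)
    lineage_counter = len(population)
    best_traj: list[float] = []
    nnz_traj: list[float] = []
    elites: list[CandidateDonor] = []
    stall = 0
    generations = 0
    for gen in range(config.max_generations):
        _evaluate(population, model, donor_pool.taxa, config)
        elites = select(population, config)
        best_traj.append(elites[0].fitness)
        nnz_traj.append(float(np.mean([c.nnz for c in elites])))
        generations = gen + 1
        if config.plateau_patience is not None and gen > 0:
            if best_traj[-1] - best_traj[-2] <= 1e-6:
                stall += 1
                if stall >= config.plateau_patience:
                    break
            else:
                stall = 0
        if gen == config.max_generations - 1:
            break
        # refill: elites pass unchanged, offspring bred from elites only
        population = list(elites)
        while len(population) < config.population_size:
            pa, pb = rng.choice(len(elites), size=2, replace=False)
            child = recombine(elites[pa], elites[pb], rng, config.p_recombination, lineage_counter)
            child = mutate(child, rng, pool_values, config.p_mutation,
                           config.mutation_rate_lambda, lineage=lineage_counter)
            lineage_counter += 1
            population.append(child)

    result = GAResult(
        best_fitness=best_traj,
        mean_elite_nnz=nnz_traj,
        elite_profiles=np.vstack([c.a for c in elites]),
        elite_fitness=np.array([c.fitness for c in elites]),
        elite_predictions=np.array([c.prediction for c in elites]),
        taxa=list(donor_pool.taxa),
        generations_run=generations,
    )
    result.triviality_scc = _triviality_scc(result, model)
    result.dominant_order_table = dominant_orders(result, top_k=10)
    return result


def _triviality_scc(result: GAResult, model: TrainedPredictor) -> float | None:
    """Spearman between each elite donor's own target property and its
    predicted recipient property; a low value means the GA did not simply
    breed donors that already exhibit the target."""
    target = model.task.target
    own: list[float] = []
    if target == "shannon":
        own = [shannon(row) for row in result.elite_profiles]
    elif target == "taxon_abundance":
        table = FeatureTable(
            [f"e{k}" for k in range(len(result.elite_profiles))],
            list(result.taxa), result.elite_profiles, "relative",
        )
        merged = merge_to_level(table, model.task.level, "sum")
        names = [str(t) for t in merged.taxa]
        if model.task.taxon not in names:
            return None
        own = list(merged.values[:, names.index(model.task.taxon)])
    else:
        return None
    if np.ptp(own) == 0 or np.ptp(result.elite_predictions) == 0:
        return None
    return float(spearmanr(own, result.elite_predictions).statistic)


def dominant_orders(result: GAResult, top_k: int = 10) -> dict:
    """Mean relative contribution of each order across the final elites."""
    table = FeatureTable(
        [f"e{k}" for k in range(len(result.elite_profiles))],
        list(result.taxa), result.elite_profiles, "relative",
    )
    merged = merge_to_level(table, "order", "sum")
    means = merged.values.mean(axis=0)
    order = np.argsort(-means)[:top_k]
    return {str(merged.taxa[j]): float(means[j]) for j in order}


def convergence_generation(best_fitness: Sequence[float], rel_tol: float = 0.01) -> int:
    """First generation index (1-based) after which the best fitness never
    improves by more than `rel_tol` (relative) for the rest of the run."""
    traj = np.asarray(best_fitness, dtype=float)
    if traj.size == 0:
        raise ValueError("empty trajectory")
    for g in range(traj.size):
        ref = traj[g]
        scale = max(abs(ref), 1e-12)
        if np.all(traj[g:] - ref <= rel_tol * scale):
            return g + 1
    return traj.size
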