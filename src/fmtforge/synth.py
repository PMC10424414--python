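"""Synthetic FMT cohorts with a known donor-to-recipient transfer model.

Donor compositions are sparse lognormal communities. A recipient sampled t
days post-FMT is a closed mixture of three simplex components:

    r(t) = close( delta * exp(-tau*t) * close(engraftability ⊙ donor)
                  + rho * host_background
                  + (1 - delta*exp(-tau*t) - rho) * noise )

delta is the donor-effect strength, rho the recipient-background strength
(0 approximates a germ-free recipient, high values an untreated human), tau
a time-decay rate, and engraftability a fixed per-taxon colonization factor.
Pre-FMT baseline samples (day 0) are drawn from the host background alone,
so they are donor-independent by construction. Clinical outcomes are
Bernoulli draws from a sigmoid of the realized recipient Shannon diversity.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .prep import shannon
from .tables_io import CohortBundle, FeatureTable, SampleMetadata, TaxonomyString


@dataclasses.dataclass
class SynthConfig:
    n_taxa: int = 80
    n_orders: int = 8
    n_donors: int = 100
    recipients_per_donor: int = 4
    timepoints: tuple[int, ...] = (7,)
    donor_effect: float = 0.7  # delta
    recipient_background: float = 0.1  # rho
    time_decay: float = 0.0  # tau, per day
    engraftability: np.ndarray | None = None  # per-taxon in [0,1]
    outcome_alpha: float = 3.0
    outcome_beta: float = 0.0
    outcome_mode: str = "recipient_shannon"  # or "donor_deterministic"
    noise_sd: float = 0.8  # lognormal sd of community draws
    include_pre_fmt: bool = True
    cohort_id: str = "synth0"
    seed: int = 0
    world_seed: int | None = None  # shared taxonomy/population across cohorts

    def __post_init__(self) -> None:
        if self.donor_effect + self.recipient_background > 1 + 1e-12:
            raise ValueError("donor_effect + recipient_background must be <= 1")
        if not (0 <= self.donor_effect <= 1 and 0 <= self.recipient_background <= 1):
            raise ValueError("effect strengths must lie in [0, 1]")
        if self.time_decay < 0:
            raise ValueError("time_decay must be >= 0")


def generate_taxonomy(n_taxa: int, n_orders: int, seed: int = 0) -> list[TaxonomyString]:
    """Full 7-rank lineages for n_taxa species spread over n_orders orders.

    Order sizes follow a Zipf-like (1/rank) distribution, mimicking the
    skewed order occupancy of real gut communities; orders are nested under
    a handful of phyla.
    """
    if not (n_taxa >= n_orders >= 1):
        raise ValueError("need n_taxa >= n_orders >= 1")
    rng = np.random.default_rng(seed)
    weights = 1.0 / np.arange(1, n_orders + 1)
    weights /= weights.sum()
    counts = np.ones(n_orders, dtype=int)  # each order keeps >= 1 species
    extra = rng.multinomial(n_taxa - n_orders, weights)
    counts += extra
    n_phyla = max(1, (n_orders + 2) // 3)
    taxa: list[TaxonomyString] = []
    species = 0
    for o in range(n_orders):
        ph = o % n_phyla
        for _ in range(counts[o]):
            taxa.append(TaxonomyString((
                "Bacteria", f"P{ph:02d}", f"C{ph:02d}", f"O{o:02d}",
                f"F{species:04d}", f"G{species:04d}", f"S{species:04d}",
            )))
            species += 1
    return taxa


def _community(rng: np.random.Generator, log_mean: np.ndarray, prevalence: np.ndarray,
               sd: float) -> np.ndarray:
    """One sparse lognormal composition on the simplex."""
    raw = np.exp(log_mean + rng.normal(0.0, sd, size=log_mean.shape))
    mask = rng.random(log_mean.shape) < prevalence
    if not mask.any():
        mask[rng.integers(len(mask))] = True
    raw = raw * mask
    return raw / raw.sum()


def generate_cohort(config: SynthConfig) -> CohortBundle:
    """Generate a paired donor/recipient cohort under the transfer model.

    The returned bundle's `provenance` records every generator parameter
    plus the hidden ground truth (engraftability, host backgrounds).
    """
    rng = np.random.default_rng(config.seed)
    world_seed = config.seed if config.world_seed is None else config.world_seed
    world_rng = np.random.default_rng(world_seed)
    taxa = generate_taxonomy(config.n_taxa, config.n_orders, seed=world_seed)
    n = config.n_taxa
    # population-level structure: shared by cohorts with the same world_seed
    log_mean = world_rng.normal(0.0, 1.2, size=n)
    prevalence = world_rng.uniform(0.3, 1.0, size=n)
    if config.engraftability is not None:
        engraft = np.asarray(config.engraftability, dtype=float)
        if engraft.shape != (n,):
            raise ValueError("engraftability must have one entry per taxon")
    else:
        engraft = world_rng.uniform(0.2, 1.0, size=n)

    donor_rows, donor_ids = [], []
    recip_rows, recip_ids = [], []
    metadata: dict[str, SampleMetadata] = {}
    pairing: dict[str, tuple[str, int, str]] = {}
    shannon_first: dict[str, float] = {}  # recipient subject -> H at first timepoint
    donor_shannon: dict[str, float] = {}

    for d in range(config.n_donors):
        did = f"D{d:04d}"
        donor = _community(rng, log_mean, prevalence, config.noise_sd)
        donor_rows.append(donor)
        donor_ids.append(did)
        donor_shannon[did] = shannon(donor)
        metadata[did] = SampleMetadata(
            sample_id=did, subject_id=f"donor_{d:04d}", role="donor",
            cohort_id=config.cohort_id,
            age=float(np.round(rng.uniform(20, 60), 1)),
            sex="F" if rng.random() < 0.5 else "M",
            weight=float(np.round(rng.normal(70, 10), 1)),
        )
        engrafted = donor * engraft
        engrafted = engrafted / engrafted.sum()
        for r in range(config.recipients_per_donor):
            subject = f"R{d:04d}_{r}"
            host = _community(rng, log_mean, prevalence, config.noise_sd)
            if config.include_pre_fmt:
                sid = f"{subject}_t0"
                pre = 0.9 * host + 0.1 * _community(rng, log_mean, prevalence, config.noise_sd)
                recip_rows.append(pre / pre.sum())
                recip_ids.append(sid)
                metadata[sid] = SampleMetadata(
                    sample_id=sid, subject_id=subject, role="recipient",
                    donor_id=did, cohort_id=config.cohort_id, days_post_fmt=0,
                )
                pairing[sid] = (did, 0, config.cohort_id)
            for t in config.timepoints:
                sid = f"{subject}_t{t}"
                w_d = config.donor_effect * np.exp(-config.time_decay * t)
                w_h = config.recipient_background
                w_n = max(0.0, 1.0 - w_d - w_h)
                noise = _community(rng, log_mean, prevalence, config.noise_sd)
                comp = w_d * engrafted + w_h * host + w_n * noise
                comp = comp / comp.sum()
                recip_rows.append(comp)
                recip_ids.append(sid)
                metadata[sid] = SampleMetadata(
                    sample_id=sid, subject_id=subject, role="recipient",
                    donor_id=did, cohort_id=config.cohort_id, days_post_fmt=int(t),
                )
                pairing[sid] = (did, int(t), config.cohort_id)
                if subject not in shannon_first:
                    shannon_first[subject] = shannon(comp)

    # clinical outcomes
    if config.outcome_mode == "donor_deterministic":
        med = float(np.median(list(donor_shannon.values())))
        outcome_of = {
            subj: int(donor_shannon[pairing[f"{subj}_t{config.timepoints[0]}"][0]] > med)
            for subj in shannon_first
        }
    else:
        h = np.array([shannon_first[s] for s in sorted(shannon_first)])
        center = float(np.median(h))
        outcome_of = {}
        for subj in sorted(shannon_first):
            logit = config.outcome_alpha * (shannon_first[subj] - center) + config.outcome_beta
            p = 1.0 / (1.0 + np.exp(-logit))
            outcome_of[subj] = int(rng.random() < p)
    for sid, md in metadata.items():
        if md.role == "recipient":
            md.outcome = outcome_of[md.subject_id]

    donors = FeatureTable(donor_ids, list(taxa), np.vstack(donor_rows), "relative")
    recipients = FeatureTable(recip_ids, list(taxa), np.vstack(recip_rows), "relative")
    bundle = CohortBundle(donors=donors, recipients=recipients, metadata=metadata,
                          pairing=pairing)
    bundle.provenance = {
        "config": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "engraftability": engraft.tolist(),
    }
    return bundle


def regime_presets() -> dict[str, dict]:
    """The four recipient-background regimes, ordered by increasing rho.

    germ_free: no resident microbiome; abx_mouse / abx_human: antibiotic
    pre-treatment leaves a small / moderate background; untreated_human: the
    background is intact. delta shrinks as rho grows because the donor
    competes with the resident community.
    """
    return {
        "germ_free": {"recipient_background": 0.0, "donor_effect": 0.85},
        "abx_mouse": {"recipient_background": 0.1, "donor_effect": 0.7},
        "abx_human": {"recipient_background": 0.25, "donor_effect": 0.5},
        "untreated_human": {"recipient_background": 0.45, "donor_effect": 0.3},
    }
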