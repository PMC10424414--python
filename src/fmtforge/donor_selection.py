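"""Donor ranking and the clinical analyses built on the trained predictor.

Candidate donors are ranked by their predicted recipient outcome and split
into predicted-high / predicted-low groups (optionally with a covariate-
matched low group, mirroring an adult/child control); clinical operations
summarize per-donor success fractions and compare predicted richness
between clinically successful and failed transplants.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .predictor import TrainedPredictor, predict
from .tables_io import CohortBundle, FeatureTable


@dataclasses.dataclass
class DonorRanking:
    """Descending ranking of candidate donors by predicted outcome."""

    donor_ids: list[str]  # in rank order (rank 1 first)
    predictions: dict[str, float]
    groups: dict[str, str]  # donor id -> predicted_high | predicted_low | excluded
    strata: dict[str, object] | None = None

    def rank_of(self, donor_id: str) -> int:
        return self.donor_ids.index(donor_id) + 1


def rank_donors(
    model: TrainedPredictor,
    candidate_donors: FeatureTable,
    covariates: Mapping[str, Sequence[float]] | None = None,
) -> DonorRanking:
    """Rank donors by predicted recipient outcome, best first.

    Ties are broken by donor id (lexicographic) so the ranking is
    deterministic.
    """
    preds = predict(model, candidate_donors, covariates)
    ids = list(candidate_donors.sample_ids)
    order = sorted(range(len(ids)), key=lambda i: (-preds[i], ids[i]))
    ranked = [ids[i] for i in order]
    return DonorRanking(
        donor_ids=ranked,
        predictions={ids[i]: float(preds[i]) for i in range(len(ids))},
        groups={d: "excluded" for d in ranked},
    )


def split_groups(
    ranking: DonorRanking,
    n_high: int,
    n_low: int,
    stratify_by: Mapping[str, object] | None = None,
) -> DonorRanking:
    """Assign the top n_high donors to predicted_high and the bottom n_low
    to predicted_low.

    With `stratify_by` (donor id -> stratum), the low group is instead drawn
    from the lowest-ranked donors within the high group's majority stratum,
    so the comparison is covariate-matched.
    """
    n = len(ranking.donor_ids)
    if n_high + n_low > n:
        raise ValueError(f"requested {n_high}+{n_low} donors from a pool of {n}")
    groups = {d: "excluded" for d in ranking.donor_ids}
    high = ranking.donor_ids[:n_high]
    for d in high:
        groups[d] = "predicted_high"
    if stratify_by is not None:
        strata_high = [stratify_by[d] for d in high]
        values, counts = np.unique(np.array(strata_high, dtype=object), return_counts=True)
        target = values[int(np.argmax(counts))]
        eligible = [
            d for d in reversed(ranking.donor_ids)
            if groups[d] == "excluded" and stratify_by[d] == target
        ]
        low = eligible[:n_low]
        if len(low) < n_low:
            raise ValueError(
                f"only {len(low)} donors available in stratum {target!r} for the low group"
            )
    else:
        low = [d for d in ranking.donor_ids[::-1] if groups[d] == "excluded"][:n_low]
    for d in low:
        groups[d] = "predicted_low"
    return DonorRanking(
        donor_ids=list(ranking.donor_ids),
        predictions=dict(ranking.predictions),
        groups=groups,
        strata=dict(stratify_by) if stratify_by is not None else None,
    )


def success_fraction_per_donor(bundle: CohortBundle) -> dict:
    """Fraction of clinically successful transplants per donor.

    Donors with a single recipient are reported separately (their fraction
    is always 0 or 1 by construction and would distort the histogram).
    """
    outcomes: dict[str, list[int]] = {}
    for rid, (did, day, _) in bundle.pairing.items():
        md = bundle.metadata[rid]
        if md.outcome is None:
            continue
        donor_subject = bundle.metadata[did].subject_id if did in bundle.metadata else did
        outcomes.setdefault(donor_subject, [])
        # one outcome per recipient subject, not per longitudinal sample
        outcomes[donor_subject].append((md.subject_id, int(md.outcome)))
    if not outcomes:
        raise ValueError("no outcome labels in bundle")
    fractions: dict[str, float] = {}
    singletons: dict[str, float] = {}
    for donor, pairs in outcomes.items():
        per_subject = {s: o for s, o in pairs}
        vals = list(per_subject.values())
        frac = float(np.mean(vals))
        if len(vals) >= 2:
            fractions[donor] = frac
        else:
            singletons[donor] = frac
    return {"fractions": fractions, "single_recipient_donors": singletons}


def success_vs_failure_richness(model: TrainedPredictor, bundle: CohortBundle) -> dict:
    """Two-sided t-test of predicted post-FMT Shannon between clinical
    successes and failures.

    For each labelled recipient, the donor's predicted recipient Shannon is
    computed from the trained model; the test asks whether successes received
    donors predicted to induce richer microbiomes.
    """
    donor_of: dict[str, str] = {}
    outcome_of: dict[str, int] = {}
    for rid, (did, day, _) in bundle.pairing.items():
        md = bundle.metadata[rid]
        if md.outcome is None:
            continue
        donor_of[md.subject_id] = did
        outcome_of[md.subject_id] = int(md.outcome)
    if not outcome_of:
        raise ValueError("no outcome labels in bundle")
    donors_needed = sorted(set(donor_of.values()))
    table = bundle.donors.select_samples(donors_needed)
    preds = predict(model, table)
    pred_of = dict(zip(donors_needed, preds))
    success = [pred_of[donor_of[s]] for s, o in outcome_of.items() if o == 1]
    failure = [pred_of[donor_of[s]] for s, o in outcome_of.items() if o == 0]
    if len(success) < 2 or len(failure) < 2:
        raise ValueError("each outcome class needs at least 2 recipients")
    if np.ptp(success + failure) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(success, failure)
    return {
        "mean_success": float(np.mean(success)),
        "mean_failure": float(np.mean(failure)),
        "n_success": len(success),
        "n_failure": len(failure),
        "t": float(t),
        "p": float(p),
    }
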