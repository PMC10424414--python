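"""Distance-hierarchy analysis of donor versus recipient-background effects.

Recipient samples are compared pairwise in three groups: SDSR (same donor,
same recipient, across timepoints), SDDR (same donor, different recipients,
matched timepoint) and DDDR (different donors, different recipients, matched
timepoint). If the donor shapes the post-FMT microbiome more than the
recipient background does, distances stack SDSR < SDDR < DDDR; pre-FMT the
SDDR/DDDR gap should vanish because backgrounds are donor-independent.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import stats

from .prep import close_to_relative, merge_to_level, shannon
from .tables_io import CohortBundle

GROUPS = ("SDSR", "SDDR", "DDDR")
METRICS = ("euclidean_order_vectors", "abs_shannon_difference")


@dataclasses.dataclass
class DistanceGroupResult:
    group: str
    distances: np.ndarray
    metric: str
    phase: str

    @property
    def n(self) -> int:
        return len(self.distances)


def _recipient_vectors(bundle: CohortBundle, metric: str) -> dict[str, float | np.ndarray]:
    """Per-recipient-sample comparison value: order-level relative vector or
    Shannon diversity of the sample composition."""
    table = bundle.recipients
    if table.space_tag == "counts":
        table = close_to_relative(table)
    if metric == "euclidean_order_vectors":
        order = merge_to_level(table, "order", "sum")
        return {s: order.values[i] for i, s in enumerate(order.sample_ids)}
    return {s: shannon(table.values[i]) for i, s in enumerate(table.sample_ids)}


def pairwise_distances(
    bundle: CohortBundle,
    metric: str = "euclidean_order_vectors",
    phase: str = "post_fmt",
    time_tolerance: int = 0,
) -> dict[str, DistanceGroupResult]:
    """Compute the SDSR/SDDR/DDDR distance distributions for one phase.

    Timepoint matching for SDDR/DDDR is exact by default; `time_tolerance`
    (days) allows ragged sampling schedules. SDSR is only defined post-FMT.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if phase not in ("pre_fmt", "post_fmt"):
        raise ValueError(f"unknown phase {phase!r}")
    values = _recipient_vectors(bundle, metric)

    def dist(a, b) -> float:
        if metric == "euclidean_order_vectors":
            return float(np.linalg.norm(a - b))
        return abs(a - b)

    samples = []
    for rid, (did, day, _) in bundle.pairing.items():
        in_phase = day > 0 if phase == "post_fmt" else day <= 0
        if in_phase and rid in values:
            samples.append((rid, did, day, bundle.metadata[rid].subject_id))

    out = {g: [] for g in GROUPS}
    for (r1, d1, t1, s1), (r2, d2, t2, s2) in itertools.combinations(samples, 2):
        if s1 == s2:
            if phase == "post_fmt" and t1 != t2:
                out["SDSR"].append(dist(values[r1], values[r2]))
            continue
        if abs(t1 - t2) > time_tolerance:
            continue
        key = "SDDR" if d1 == d2 else "DDDR"
        out[key].append(dist(values[r1], values[r2]))

    return {
        g: DistanceGroupResult(g, np.asarray(v, dtype=float), metric, phase)
        for g, v in out.items()
    }


def hierarchy_test(results: dict[str, DistanceGroupResult]) -> dict:
    """One-sided t-tests of the expected ordering SDSR < SDDR < DDDR.

    Each comparison reports t, p and a star code (* p<0.05, ** p<0.01,
    *** p<0.001); groups with fewer than 2 distances are skipped with a note.
    """
    comparisons = [("SDSR", "SDDR"), ("SDDR", "DDDR"), ("SDSR", "DDDR")]
    report: dict[str, dict] = {}
    nonempty = 0
    for g, res in results.items():
        if res.n >= 2:
            nonempty += 1
    if nonempty < 2:
        raise ValueError("need at least two non-empty distance groups")
    for lo, hi in comparisons:
        a, b = results.get(lo), results.get(hi)
        key = f"{lo}<{hi}"
        if a is None or b is None or a.n < 2 or b.n < 2:
            report[key] = {"skipped": True, "note": "group with < 2 pairs"}
            continue
        t, p = stats.ttest_ind(a.distances, b.distances, alternative="less")
        report[key] = {
            "t": float(t), "p": float(p), "stars": _stars(float(p)),
            "mean_low": float(a.distances.mean()), "mean_high": float(b.distances.mean()),
            "n_low": a.n, "n_high": b.n,
        }
    return report


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
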