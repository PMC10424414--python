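import numpy as np
import pytest
from scipy.stats import spearmanr

from fmtforge import eval_protocol, synth
from fmtforge.eval_protocol import (
    auc_score,
    compare_models,
    cross_validate,
    grouped_kfold,
    lodo,
    scc_by_time,
)
from fmtforge.predictor import PredictionTask
from fmtforge.tables_io import CohortBundle


@pytest.fixture(scope="module")
def bundle():
    cfg = synth.SynthConfig(n_donors=40, recipients_per_donor=2, seed=6)
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="module")
def two_cohorts():
    # one recipient per donor: pooled CV and LODO then both measure
    # cross-donor generalization on the same underlying population
    a = synth.generate_cohort(synth.SynthConfig(
        n_donors=80, recipients_per_donor=1, seed=13, world_seed=13, cohort_id="A"))
    b = synth.generate_cohort(synth.SynthConfig(
        n_donors=80, recipients_per_donor=1, seed=14, world_seed=13, cohort_id="B"))
    # merge the two generated cohorts into one bundle
    from fmtforge.tables_io import FeatureTable, align_union

    def prefix(table, tag):
        return FeatureTable([f"{tag}{s}" for s in table.sample_ids],
                            list(table.taxa), table.values, table.space_tag)

    donors_a, donors_b = align_union([prefix(a.donors, "A"), prefix(b.donors, "B")])
    rec_a, rec_b = align_union([prefix(a.recipients, "A"), prefix(b.recipients, "B")])
    donors = FeatureTable(donors_a.sample_ids + donors_b.sample_ids,
                          list(donors_a.taxa),
                          np.vstack([donors_a.values, donors_b.values]), "relative")
    recips = FeatureTable(rec_a.sample_ids + rec_b.sample_ids,
                          list(rec_a.taxa),
                          np.vstack([rec_a.values, rec_b.values]), "relative")
    metadata = {}
    pairing = {}
    for tag, src in (("A", a), ("B", b)):
        for sid, md in src.metadata.items():
            import dataclasses

            new = dataclasses.replace(
                md, sample_id=f"{tag}{sid}",
                subject_id=f"{tag}{md.subject_id}",
                donor_id=f"{tag}{md.donor_id}" if md.donor_id else None,
            )
            metadata[new.sample_id] = new
        for rid, (did, day, _) in src.pairing.items():
            pairing[f"{tag}{rid}"] = (f"{tag}{did}", day, tag)
    return CohortBundle(donors=donors, recipients=recips, metadata=metadata,
                        pairing=pairing)


class TestGroupedKFold:
    def test_near_equal_partition(self, bundle):
        plan = grouped_kfold(bundle, k=10, seed=1)
        sizes = [len(plan.fold_subjects(f)) for f in range(10)]
        assert sum(sizes) == 80
        assert max(sizes) - min(sizes) <= 1

    def test_disjoint_and_exhaustive(self, bundle):
        plan = grouped_kfold(bundle, k=10, seed=1)
        all_subjects = set()
        for f in range(10):
            s = plan.fold_subjects(f)
            assert not (s & all_subjects)
            all_subjects |= s
        assert all_subjects == {bundle.metadata[r].subject_id for r in bundle.pairing}

    def test_recipient_samples_share_fold(self):
        cfg = synth.SynthConfig(n_donors=12, recipients_per_donor=2,
                                timepoints=(7, 14, 21), seed=8)
        b = synth.generate_cohort(cfg)
        plan = grouped_kfold(b, k=10, seed=0)
        fold_of = {}
        for rid in b.pairing:
            subj = b.metadata[rid].subject_id
            f = plan.subject_fold[subj]
            fold_of.setdefault(subj, f)
            assert fold_of[subj] == f

    def test_deterministic_per_seed(self, bundle):
        assert grouped_kfold(bundle, seed=3).subject_fold == grouped_kfold(bundle, seed=3).subject_fold
        assert grouped_kfold(bundle, seed=3).subject_fold != grouped_kfold(bundle, seed=4).subject_fold

    def test_fewer_recipients_than_folds_rejected(self):
        cfg = synth.SynthConfig(n_donors=3, recipients_per_donor=1, seed=1)
        b = synth.generate_cohort(cfg)
        with pytest.raises(ValueError):
            grouped_kfold(b, k=10)


class TestCrossValidate:
    def test_linear_labels_recovered_by_ridge(self, bundle):
        # oracle: labels are an exact linear function of the donor features,
        # so a linear model must reach R2 ~ 1 and SCC ~ 1 out of fold
        from fmtforge.predictor import build_design
        from fmtforge.prep import PrepRecipe

        design = build_design(PredictionTask("shannon"), bundle, PrepRecipe())
        rng = np.random.default_rng(1)
        w = rng.normal(size=design.X.shape[1])
        lin = design.X @ w
        labels = dict(zip(design.recipient_samples, lin))
        plan = grouped_kfold(bundle, k=5, seed=2)
        metrics = cross_validate(PredictionTask("shannon"), bundle, "ridge", plan,
                                 hyperparams={"alpha": 1e-6}, labels=labels)
        assert np.mean(metrics.per_fold_r2) > 0.95
        assert np.mean(metrics.per_fold_scc) > 0.95

    def test_shuffled_labels_give_no_skill(self, bundle):
        from fmtforge.predictor import build_design
        from fmtforge.prep import PrepRecipe

        design = build_design(PredictionTask("shannon"), bundle, PrepRecipe())
        rng = np.random.default_rng(0)
        labels = dict(zip(design.recipient_samples, rng.permutation(design.y)))
        plan = grouped_kfold(bundle, k=5, seed=2)
        metrics = cross_validate(PredictionTask("shannon"), bundle, "ridge", plan, labels=labels)
        assert np.mean(metrics.per_fold_r2) <= 0.05

    def test_held_out_samples_only_are_scored(self, bundle):
        plan = grouped_kfold(bundle, k=5, seed=0)
        metrics = cross_validate(PredictionTask("shannon"), bundle, "ridge", plan)
        post = {r for r, (_, d, _) in bundle.pairing.items() if d > 0}
        assert set(metrics.predictions) == post  # every sample scored exactly once


class TestLodo:
    def test_same_distribution_cohorts_transfer(self, two_cohorts):
        task = PredictionTask("shannon")
        out = lodo(task, two_cohorts, "B", model_kind="rf", seed=0)
        plan = grouped_kfold(two_cohorts, k=5, seed=0)
        pooled = cross_validate(task, two_cohorts, "rf", plan, seed=0)
        assert abs(out.scc - pooled.scc) <= 0.15

    def test_training_excludes_holdout(self, two_cohorts):
        out = lodo(PredictionTask("shannon"), two_cohorts, "B", model_kind="ridge")
        assert all(two_cohorts.pairing[r][2] == "B" for r in out.predictions)

    def test_unknown_cohort_rejected(self, two_cohorts):
        with pytest.raises(ValueError, match="unknown cohort"):
            lodo(PredictionTask("shannon"), two_cohorts, "C")

    def test_single_cohort_rejected(self, bundle):
        with pytest.raises(ValueError):
            lodo(PredictionTask("shannon"), bundle, "synth0")


class TestCompareModels:
    def test_identical_vectors_no_pairwise(self):
        report = compare_models({"a": [0.5, 0.6], "b": [0.5, 0.6]})
        assert report["anova_p"] == 1.0
        assert report["pairwise"] == {}

    def test_dominating_model_detected(self, rng):
        good = 0.8 + 0.01 * rng.standard_normal(10)
        bad = 0.3 + 0.01 * rng.standard_normal(10)
        report = compare_models({"good": good, "bad": bad})
        assert report["anova_p"] < 0.05
        assert report["best_model"] == "good"
        assert report["pairwise"]["bad"]["p"] < 0.05

    def test_fold_order_invariance(self, rng):
        a = rng.random(8)
        b = rng.random(8)
        r1 = compare_models({"a": a, "b": b})
        r2 = compare_models({"b": b, "a": a})
        assert r1["anova_F"] == pytest.approx(r2["anova_F"])

    def test_unequal_fold_counts_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            compare_models({"a": [1, 2, 3], "b": [1, 2]})


class TestTimeStratified:
    def test_decay_reduces_late_accuracy(self):
        cfg = synth.SynthConfig(n_donors=50, recipients_per_donor=2,
                                timepoints=(7, 56), time_decay=0.05, seed=10)
        b = synth.generate_cohort(cfg)
        out = scc_by_time(PredictionTask("shannon"), b, "rf",
                          bins=[(1, 30), (30, 100)], k=5, seed=0)
        early, late = out["[1,30)"]["scc"], out["[30,100)"]["scc"]
        assert early > late

    def test_no_decay_keeps_bins_comparable(self):
        cfg = synth.SynthConfig(n_donors=50, recipients_per_donor=2,
                                timepoints=(7, 56), time_decay=0.0, seed=10)
        b = synth.generate_cohort(cfg)
        out = scc_by_time(PredictionTask("shannon"), b, "rf",
                          bins=[(1, 30), (30, 100)], k=5, seed=0)
        assert abs(out["[1,30)"]["scc"] - out["[30,100)"]["scc"]) < 0.25

    def test_empty_bin_reported_missing(self, bundle):
        out = scc_by_time(PredictionTask("shannon"), bundle, "ridge",
                          bins=[(1, 30), (100, 200)], k=5, seed=0)
        assert out["[100,200)"]["scc"] is None


class TestMetricIdentities:
    def test_auc_label_flip_identity(self, rng):
        y = rng.integers(0, 2, size=50)
        while y.min() == y.max():
            y = rng.integers(0, 2, size=50)
        score = rng.random(50)
        assert auc_score(y, score) == pytest.approx(1.0 - auc_score(1 - y, score))

    def test_scc_monotone_transform_invariance(self, rng):
        y = rng.random(30)
        pred = rng.random(30)
        base = spearmanr(y, pred).statistic
        assert spearmanr(y, np.exp(3 * pred)).statistic == pytest.approx(base)
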