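"""Kaplan-Meier, log-rank, quartile stratification and signature scoring."""

import numpy as np
import pandas as pd
import pytest

from hormonesig import simulate
from hormonesig.diffexpr import GeneSignature
from hormonesig.errors import ConfigError, DataError
from hormonesig.matrix import FeatureMatrix
from hormonesig.survival import (
    SurvivalCohort,
    km_estimate,
    log_rank,
    quartile_stratify,
    run_survival,
    signature_score,
)


def cohort(times, events, prefix="p"):
    ids = [f"{prefix}{i}" for i in range(len(times))]
    return SurvivalCohort(ids, np.array(times, float), np.array(events, int))


# Six-patient toy cohort with its by-hand O/E/V log-rank table frozen below.
TOY_HIGH = ([1.0, 3.0, 5.0], [1, 1, 0])
TOY_LOW = ([2.0, 4.0, 6.0], [1, 1, 1])
# event time: (n_high, n_low, d_high, d_total)
TOY_TABLE = [
    (1.0, 3, 3, 1, 1),
    (2.0, 2, 3, 0, 1),
    (3.0, 2, 2, 1, 1),
    (4.0, 1, 2, 0, 1),
    (6.0, 0, 1, 0, 1),
]


def toy_oracle_chi2():
    O = E = V = 0.0
    for _, n1, n2, d1, d in TOY_TABLE:
        n = n1 + n2
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        curve = km_estimate(cohort([1, 2, 3], [0, 0, 0]))
        assert curve.times.size == 0
        assert curve.at(100.0) == 1.0

    def test_hand_product_limit(self):
        curve = km_estimate(cohort([1, 2, 3], [1, 1, 1]))
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(curve.n_risk, [3, 2, 1])

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(5.0, size=60)
        curve = km_estimate(cohort(times, np.ones(60)))
        for t in rng.uniform(0, 15, size=10):
            assert curve.at(t) == pytest.approx(np.mean(times > t))

    def test_censored_at_event_time_counts_at_risk(self):
        # one death and one censoring at t=2: n_risk there must include both
        curve = km_estimate(cohort([2, 2, 5], [1, 0, 1]))
        assert curve.n_risk[0] == 3
        assert curve.survival[0] == pytest.approx(2 / 3)

    def test_ordering_invariance_and_late_censoring(self, rng):
        times = [3, 1, 4, 1, 5, 6]
        events = [1, 1, 0, 1, 1, 0]
        perm = rng.permutation(6)
        c1 = km_estimate(cohort(times, events))
        c2 = km_estimate(cohort([times[i] for i in perm], [events[i] for i in perm]))
        assert np.allclose(c1.survival, c2.survival)
        # pushing a censoring that already follows the last event further out
        # cannot change the curve
        c3 = km_estimate(cohort(times[:-1] + [99], events))
        assert np.allclose(c1.survival, c3.survival)

    def test_non_increasing_from_one(self, rng):
        times = rng.exponential(3.0, size=80)
        events = rng.integers(0, 2, size=80)
        if events.sum() == 0:
            events[0] = 1
        curve = km_estimate(cohort(times, events))
        values = np.concatenate([[1.0], curve.survival])
        assert (np.diff(values) <= 1e-12).all()

    def test_negative_time_rejected(self):
        with pytest.raises(DataError):
            cohort([-1.0], [1])

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = rng.exponential(5.0, size=100)
        events = rng.integers(0, 2, size=100)
        events[0] = 1
        curve = km_estimate(cohort(times, events))
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )


class TestLogRank:
    def test_identical_groups_give_zero(self):
        g = cohort([1, 2, 3, 4], [1, 1, 0, 1])
        res = log_rank(g, cohort([1, 2, 3, 4], [1, 1, 0, 1], prefix="q"))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_cohort_matches_hand_table(self):
        res = log_rank(cohort(*TOY_HIGH), cohort(*TOY_LOW, prefix="q"))
        assert res.statistic == pytest.approx(toy_oracle_chi2(), rel=1e-12)

    def test_matches_lifelines(self, rng):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        t1 = rng.exponential(5.0, 70)
        t2 = rng.exponential(3.0, 60)
        e1 = rng.integers(0, 2, 70)
        e2 = rng.integers(0, 2, 60)
        e1[0] = e2[0] = 1
        res = log_rank(cohort(t1, e1), cohort(t2, e2, prefix="q"))
        ref = lifelines_stats.logrank_test(t1, t2, e1, e2)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_symmetric_in_group_labels(self, rng):
        t1, t2 = rng.exponential(4, 30), rng.exponential(2, 30)
        a, b = cohort(t1, np.ones(30)), cohort(t2, np.ones(30), prefix="q")
        assert log_rank(a, b).statistic == pytest.approx(log_rank(b, a).statistic)

    def test_no_events_undefined(self):
        with pytest.raises(DataError):
            log_rank(cohort([1, 2], [0, 0]), cohort([3], [0], prefix="q"))


class TestStratify:
    def test_scores_one_to_eight(self):
        scores = pd.Series(
            np.arange(1.0, 9.0), index=[f"p{i}" for i in range(1, 9)]
        )
        groups = quartile_stratify(scores)
        assert groups.high == ["p7", "p8"]
        assert groups.low == ["p1", "p2"]
        assert len(groups.middle) == 4

    def test_identical_scores_impossible(self):
        scores = pd.Series(1.0, index=[f"p{i}" for i in range(10)])
        with pytest.raises(DataError):
            quartile_stratify(scores)

    def test_too_few_patients(self):
        with pytest.raises(ConfigError):
            quartile_stratify(pd.Series(np.arange(7.0)))

    def test_order_invariance(self, rng):
        scores = pd.Series(rng.normal(size=40), index=[f"p{i}" for i in range(40)])
        shuffled = scores.sample(frac=1.0, random_state=3)
        g1, g2 = quartile_stratify(scores), quartile_stratify(shuffled)
        assert g1.high == g2.high and g1.low == g2.low


class TestSignatureScore:
    def _matrix(self, values, genes, patients):
        data = pd.DataFrame(values, index=genes, columns=patients)
        return FeatureMatrix(data, pd.Series(1000.0, index=genes), "counts")

    def test_single_gene_reduces_to_zscore(self):
        genes, patients = ["g1"], [f"p{i}" for i in range(5)]
        values = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        fm = self._matrix(values, genes, patients)
        sig = GeneSignature(genes, {"g1": 1})
        scores, absent = signature_score(fm, sig)
        z = (values[0] - values[0].mean()) / values[0].std()
        assert np.allclose(scores.to_numpy(), z)
        assert absent == []

    def test_direction_signs_flip_contributions(self):
        genes, patients = ["g1"], [f"p{i}" for i in range(4)]
        values = np.array([[1.0, 2.0, 3.0, 4.0]])
        fm = self._matrix(values, genes, patients)
        up, _ = signature_score(fm, GeneSignature(genes, {"g1": 1}))
        down, _ = signature_score(fm, GeneSignature(genes, {"g1": -1}))
        assert np.allclose(up.to_numpy(), -down.to_numpy())

    def test_zero_variance_gene_excluded_with_warning(self):
        genes, patients = ["g1", "flat"], [f"p{i}" for i in range(4)]
        values = np.array([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        fm = self._matrix(values, genes, patients)
        with pytest.warns(UserWarning, match="zero-variance"):
            scores, excluded = signature_score(
                fm, GeneSignature(genes, {"g1": 1, "flat": 1})
            )
        assert "flat" in excluded

    def test_planted_score_recovered(self):
        cohort_, expr, truth = simulate.generate_cohort(seed=2, beta=0.5)
        genes = truth.data["signature_genes"]
        scores, _ = signature_score(expr, GeneSignature(genes, {g: 1 for g in genes}))
        planted = pd.Series(truth.data["scores"]).loc[scores.index]
        assert np.corrcoef(scores, planted)[0, 1] >= 0.9


class TestRunSurvival:
    def test_protective_signature_orders_curves(self):
        cohort_, expr, truth = simulate.generate_cohort(
            seed=9, n_patients=200, beta=-1.0, censor_rate=0.02
        )
        genes = truth.data["signature_genes"]
        sig = GeneSignature(genes, {g: 1 for g in genes})
        report = run_survival(cohort_, expr, sig)
        t_med = float(np.median(cohort_.time))
        assert report.curve_high.at(t_med) > report.curve_low.at(t_med)

    def test_deterministic_end_to_end(self):
        outputs = []
        for _ in range(2):
            cohort_, expr, truth = simulate.generate_cohort(seed=4, beta=0.9)
            genes = truth.data["signature_genes"]
            report = run_survival(cohort_, expr, GeneSignature(genes, {g: 1 for g in genes}))
            outputs.append((report.test.statistic, tuple(report.groups.high)))
        assert outputs[0] == outputs[1]
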