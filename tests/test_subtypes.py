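"""Consensus clustering, subtype differentials, clinical and survival tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from m6ascape.subtypes import (
    clinical_association, consensus_cluster, km_logrank, subtype_differential,
)


def two_group_matrix(n_per_group=15, n_peaks=40, delta=5.0, sd=1.0, seed=0):
    """Peaks x samples matrix with two well-separated sample groups."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n_peaks, n_per_group))
    b = rng.normal(delta * sd, sd, size=(n_peaks, n_per_group))
    cols = [f"A{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)]
    m = pd.DataFrame(np.hstack([a, b]), columns=cols)
    truth = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=cols)
    return m, truth


class TestConsensusCluster:
    def test_separated_groups_recovered_perfectly(self):
        m, truth = two_group_matrix(seed=1)
        res = consensus_cluster(m, k=2, n_boot=200, subsample=0.8, seed=2)
        assert adjusted_rand_score(truth.values, res.labels.values) == 1.0
        cons = res.consensus[2].to_numpy()
        within = truth.values[:, None] == truth.values[None, :]
        off_diag = ~np.eye(len(truth), dtype=bool)
        assert cons[within & off_diag].min() >= 0.95
        assert cons[~within].max() <= 0.05

    def test_consensus_matrix_invariants(self):
        m, _ = two_group_matrix(n_per_group=8, n_peaks=20, delta=1.0, seed=3)
        res = consensus_cluster(m, k=2, n_boot=50, seed=4)
        cons = res.consensus[2].to_numpy()
        assert np.allclose(cons, cons.T)
        assert np.allclose(np.diag(cons), 1.0)
        assert cons.min() >= 0.0 and cons.max() <= 1.0

    def test_sample_permutation_equivariance(self):
        m, truth = two_group_matrix(n_per_group=10, seed=5)
        res = consensus_cluster(m, k=2, n_boot=100, seed=6)
        rng = np.random.default_rng(7)
        perm = rng.permutation(m.columns)
        res_p = consensus_cluster(m[perm], k=2, n_boot=100, seed=6)
        # grouping identical up to renaming: ARI of the two label vectors is 1
        joined = pd.concat([res.labels, res_p.labels], axis=1, keys=["a", "b"])
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_small_run_matches_bruteforce_tally_of_recorded_resamples(self):
        m, _ = two_group_matrix(n_per_group=3, n_peaks=10, delta=2.0, seed=8)
        res = consensus_cluster(m, k=2, n_boot=3, seed=9, record_resamples=True)
        n = m.shape[1]
        co_cluster = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        assert len(res.resamples) == 3
        for idx, labels in res.resamples:
            for i, j in itertools.product(range(len(idx)), repeat=2):
                co_sampled[idx[i], idx[j]] += 1
                if labels[i] == labels[j]:
                    co_cluster[idx[i], idx[j]] += 1
        expected = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
        assert np.allclose(res.consensus[2].to_numpy(), expected)

    def test_parameter_validation(self):
        m, _ = two_group_matrix(n_per_group=3, n_peaks=5)
        with pytest.raises(ValueError):
            consensus_cluster(m, k=10, n_boot=5)
        with pytest.raises(ValueError):
            consensus_cluster(m, k=2, subsample=1.5)

    def test_s_labels_ordered_by_methylation_level(self):
        m, truth = two_group_matrix(seed=10)  # group B is the high one
        res = consensus_cluster(m, k=2, n_boot=100, seed=11)
        high = res.labels[truth == "B"].unique()
        assert list(high) == ["S2"]


def exact_rank_sum_oracle(a, b):
    """Enumerate all group assignments of the pooled ranks (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n_a)]
    mean = np.mean(sums)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in sums)
    return extreme / len(sums)


class TestSubtypeDifferential:
    def make(self, vals_a, vals_b, n_peaks=1):
        cols_a = [f"A{i}" for i in range(len(vals_a))]
        cols_b = [f"B{i}" for i in range(len(vals_b))]
        m = pd.DataFrame([list(vals_a) + list(vals_b)] * n_peaks,
                         columns=cols_a + cols_b,
                         index=[f"p{i}" for i in range(n_peaks)])
        labels = pd.Series(["S1"] * len(vals_a) + ["S2"] * len(vals_b),
                           index=m.columns)
        return m, labels

    def test_identical_groups_are_ns(self):
        m, labels = self.make([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        res = subtype_differential(m, labels)
        assert (res.direction == "ns").all()

    def test_exact_p_matches_enumeration_oracle(self):
        a, b = [1, 2, 3, 4, 5], [6, 7, 8, 9, 10]
        m, labels = self.make(a, b)
        res = subtype_differential(m, labels)
        assert res.loc["p0", "p"] == pytest.approx(exact_rank_sum_oracle(b, a))
        assert res.loc["p0", "direction"] == "hyper"  # S2 is the high group

    def test_small_group_raises(self):
        m, labels = self.make([1, 2, 3], [4, 5, 6, 7, 8])
        with pytest.raises(ValueError, match="S1"):
            subtype_differential(m, labels)

    def test_planted_subtype_peaks_recovered(self, small_cohort):
        truth = small_cohort["truth"]
        m = small_cohort["m6a"][truth["subtype"].index]
        res = subtype_differential(m, truth["subtype"], fdr_cut=0.1)
        hyper = set(res.index[res.direction == "hyper"])
        planted = set(truth["hyper"])
        assert len(hyper & planted) / len(planted) >= 0.9


class TestClinicalAssociation:
    def test_diagonal_table_matches_hypergeometric_closed_form(self):
        labels = pd.Series(["S1"] * 10 + ["S2"] * 10,
                           index=[f"s{i}" for i in range(20)])
        feature = pd.DataFrame({"f": ["x"] * 10 + ["y"] * 10}, index=labels.index)
        res = clinical_association(labels, feature)
        from scipy.special import comb
        assert res.loc["f", "p"] == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert res.loc["f", "test"] == "fisher"

    def test_constant_feature_reports_p_one(self):
        labels = pd.Series(["S1", "S1", "S2", "S2"], index=list("abcd"))
        feature = pd.DataFrame({"f": ["x"] * 4}, index=labels.index)
        res = clinical_association(labels, feature)
        assert res.loc["f", "p"] == 1.0
        assert "constant" in res.loc["f", "note"]

    def test_independent_feature_p_is_uniform(self):
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(200):
            labels = pd.Series(rng.choice(["S1", "S2"], size=40),
                               index=[f"s{i}" for i in range(40)])
            feature = pd.DataFrame({"f": rng.choice(["x", "y"], size=40)},
                                   index=labels.index)
            res = clinical_association(labels, feature)
            pvals.append(res.loc["f", "p"])
        # Fisher p on discrete tables is conservative; check no excess of
        # small p rather than strict uniformity
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.07

    def test_multilevel_feature_uses_chi_square(self):
        rng = np.random.default_rng(13)
        labels = pd.Series(rng.choice(["S1", "S2"], size=60),
                           index=[f"s{i}" for i in range(60)])
        feature = pd.DataFrame({"f": rng.choice(["x", "y", "z"], size=60)},
                               index=labels.index)
        res = clinical_association(labels, feature)
        assert res.loc["f", "test"] == "chi-square"


def logrank_oracle(times_a, times_b):
    """Textbook observed-minus-expected log-rank statistic, no censoring."""
    events = sorted(set(times_a) | set(times_b))
    o_minus_e, var = 0.0, 0.0
    for t in events:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = times_a.count(t)
        d_b = times_b.count(t)
        n, d = n_a + n_b, d_a + d_b
        if n < 1:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKMLogrank:
    def surv(self, times, events=None):
        events = events if events is not None else [1] * len(times)
        idx = [f"s{i}" for i in range(len(times))]
        return pd.DataFrame({"time": times, "event": events}, index=idx)

    def test_product_limit_on_uncensored_times(self):
        times = list(range(1, 11)) + [100] * 10
        labels = pd.Series(["G1"] * 10 + ["G2"] * 10,
                           index=[f"s{i}" for i in range(20)])
        res = km_logrank(self.surv(times), labels)
        curve = res["curves"]["G1"]
        assert curve.loc[5.0] == pytest.approx(0.5)
        assert res["medians"]["G1"] == pytest.approx(5.0)
        # KM curve is non-increasing and starts at 1
        assert curve.iloc[0] == 1.0
        assert (np.diff(curve.values) <= 1e-12).all()

    def test_identical_groups_give_null_statistic(self):
        times = [1, 2, 3, 4, 5] * 2
        labels = pd.Series(["G1"] * 5 + ["G2"] * 5,
                           index=[f"s{i}" for i in range(10)])
        res = km_logrank(self.surv(times), labels)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] == pytest.approx(1.0, abs=1e-6)

    def test_statistic_matches_textbook_oracle(self):
        a, b = [1, 2, 3], [10, 20, 30]
        labels = pd.Series(["G1"] * 3 + ["G2"] * 3,
                           index=[f"s{i}" for i in range(6)])
        res = km_logrank(self.surv(a + b), labels)
        assert res["statistic"] == pytest.approx(logrank_oracle(a, b), rel=1e-6)

    def test_relabeling_invariance(self):
        times = [1, 3, 5, 7, 2, 4, 6, 8]
        labels = pd.Series(["G1"] * 4 + ["G2"] * 4,
                           index=[f"s{i}" for i in range(8)])
        flipped = labels.map({"G1": "G2", "G2": "G1"})
        assert km_logrank(self.surv(times), labels)["p"] == pytest.approx(
            km_logrank(self.surv(times), flipped)["p"])

    def test_error_cases(self):
        labels = pd.Series(["G1", "G1", "G2", "G2"], index=list("abcd"))
        surv = pd.DataFrame({"time": [1, 2, 3, 4], "event": [0, 0, 0, 0]},
                            index=list("abcd"))
        with pytest.raises(ValueError, match="events"):
            km_logrank(surv, labels)

    def test_median_none_when_never_reached(self):
        # G1: one early event then censoring only, so S(t) stays at 0.75
        times = [10, 20, 30, 40, 1, 2, 3, 4]
        events = [1, 0, 0, 0, 1, 1, 1, 1]
        labels = pd.Series(["G1"] * 4 + ["G2"] * 4,
                           index=[f"s{i}" for i in range(8)])
        res = km_logrank(self.surv(times, events), labels)
        assert res["medians"]["G1"] is None
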