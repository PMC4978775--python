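"""Ensemble selection criteria, clustering, and ensemble statistics."""

import numpy as np
import pytest

from lckphos.fit import FitResult
from lckphos.params import PARAM_NAMES, RateParameterSet
from lckphos.select import (
    SelectionConfig,
    cluster_parameter_sets,
    cluster_validation_medians,
    elbow_cutoff,
    ensemble_stats,
    select_ensemble,
)

from conftest import uniform_params


def _member(training):
    return FitResult(x=np.zeros(38), wssr_quant=training)


class TestSelection:
    def _run(self, training, validation, double, config=None):
        ensemble = [_member(t) for t in training]
        return select_ensemble(
            ensemble, None, config or SelectionConfig(),
            validation_wssr=np.asarray(validation, float),
            double_phospho=np.asarray(double, float),
        )

    def test_matches_brute_force_filter(self, rng):
        """100 synthetic sets with known scores against a direct filter."""
        n = 100
        training = rng.uniform(0, 20, n)
        validation = rng.uniform(0, 8, n)
        double = rng.uniform(0.5, 1.0, n)
        sel = self._run(training, validation, double)
        brute = [
            i for i in range(n)
            if training[i] < 7.1 and validation[i] < 3.3 and double[i] >= 0.90
        ]
        assert sel.survivor_indices == brute

    def test_removal_attribution_order(self):
        sel = self._run(
            training=[10.0, 5.0, 5.0, 5.0],
            validation=[0.1, 9.0, 1.0, 1.0],
            double=[1.0, 1.0, 0.5, 0.95],
        )
        assert sel.removed == {
            0: "training_wssr", 1: "validation_wssr", 2: "double_phospho"
        }
        assert sel.survivor_indices == [3]

    def test_paper_cutoff_example_retained(self):
        sel = self._run([6.0], [2.0], [0.95])
        assert sel.survivor_indices == [0]

    def test_all_fail_first_criterion(self):
        sel = self._run([8.0, 9.0], [0.0, 0.0], [1.0, 1.0])
        assert sel.survivors == []
        assert set(sel.removed.values()) == {"training_wssr"}

    def test_selection_is_idempotent(self, rng):
        n = 50
        training = rng.uniform(0, 20, n)
        validation = rng.uniform(0, 8, n)
        double = rng.uniform(0.5, 1.0, n)
        sel = self._run(training, validation, double)
        idx = sel.survivor_indices
        again = self._run(training[idx], validation[idx], double[idx])
        assert again.survivor_indices == list(range(len(idx)))

    def test_elbow_cutoff_finds_step(self):
        w = np.array([1.0, 1.1, 1.2, 1.3, 50.0, 51.0, 52.0])
        cut = elbow_cutoff(w)
        assert 1.3 <= cut <= 50.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(training_wssr_cutoff=-1)
        with pytest.raises(ValueError):
            SelectionConfig(double_phospho_threshold=1.5)


class TestClustering:
    def test_two_separated_blobs_recovered(self, rng):
        """Two 38-D lognormal blobs with separation >> spread give k=2 and
        a perfect labeling up to permutation."""
        base = np.log10(uniform_params(1e-3).to_vector())
        sets = []
        truth = []
        for i in range(24):
            center = base + (6.0 if i % 2 else -6.0)
            sets.append(RateParameterSet.from_vector(
                10 ** (center + rng.normal(0, 0.2, 38))
            ))
            truth.append(i % 2)
        res = cluster_parameter_sets(sets, seed=1)
        assert res.k == 2
        labels = res.labels
        agreement = max(
            np.mean(labels == truth), np.mean(labels == 1 - np.array(truth))
        )
        assert agreement == 1.0

    def test_identical_points_reported_as_single_cluster(self):
        sets = [uniform_params(1.0) for _ in range(8)]
        res = cluster_parameter_sets(sets)
        assert res.k == 1
        assert "silhouette undefined" in res.diagnostic

    def test_clustering_is_deterministic(self, rng):
        X = rng.normal(size=(20, 38))
        a = cluster_parameter_sets(X, seed=4)
        b = cluster_parameter_sets(X, seed=4)
        assert a.k == b.k
        assert np.array_equal(a.labels, b.labels)

    def test_cluster_validation_medians(self):
        from lckphos.select import ClusterResult

        res = ClusterResult(labels=np.array([0, 0, 1, 1]), k=2, silhouette_sum={})
        med = cluster_validation_medians(res, np.array([1.0, 3.0, 10.0, 20.0]))
        assert med == {0: 2.0, 1: 15.0}


class TestEnsembleStats:
    def test_identical_sets_have_zero_width_ci_and_no_significance(self):
        stats = ensemble_stats([uniform_params(0.5)] * 5)
        assert (stats.summary["ci_low"] == stats.summary["ci_high"]).all()
        assert (stats.summary["median"] == 0.5).all()
        assert (stats.anova["p"] == 1.0).all()

    def test_median_of_three(self):
        sets = [uniform_params(v) for v in (1.0, 2.0, 3.0)]
        stats = ensemble_stats(sets)
        assert (stats.summary["median"] == 2.0).all()

    def test_anova_detects_enzyme_effect(self, rng):
        """One substrate's catalytic rates drawn from shifted lognormals per
        enzyme: the enzyme-vs-enzyme ANOVA on that substrate is significant."""
        sets = []
        for _ in range(20):
            p = uniform_params(1.0)
            # Y394@UU rates: pairs 1 (UU), 4 (PU), 7 (UP), 13 (PP)
            p = p.replace(
                k_cat_1=10 ** rng.normal(0.0, 0.1),
                k_cat_4=10 ** rng.normal(3.0, 0.1),
                k_cat_7=10 ** rng.normal(-3.0, 0.1),
                k_cat_13=10 ** rng.normal(1.0, 0.1),
            )
            sets.append(p)
        stats = ensemble_stats(sets)
        row = stats.anova[
            (stats.anova["substrate"] == "Y394@UU") & (stats.anova["rate"] == "k_cat")
        ]
        assert float(row["p"].iloc[0]) < 0.01

    def test_requires_three_sets(self):
        with pytest.raises(ValueError):
            ensemble_stats([uniform_params(1.0)] * 2)
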