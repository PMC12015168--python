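import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from preemie_probiome.community import (
    DirichletMultinomialMixture,
    assign_type,
    probiotic_associated_types,
    pseudo_counts,
    type_proportions_by_group,
)


def _mixture_data(rng, k=3, n=150, n_taxa=10, concentration=60.0):
    means = rng.dirichlet(np.ones(n_taxa) * 0.3, size=k)
    labels = rng.integers(k, size=n)
    X = np.array([rng.dirichlet(means[l] * concentration + 0.1) for l in labels])
    return X, labels, means


class TestPseudoCounts:
    def test_rows_sum_exactly_to_depth(self, rng):
        p = rng.dirichlet(np.ones(7), size=20)
        counts = pseudo_counts(p, depth=1000)
        assert np.all(counts.sum(axis=1) == 1000)

    def test_per_taxon_error_bounded(self, rng):
        p = rng.dirichlet(np.ones(7), size=20)
        counts = pseudo_counts(p, depth=1000)
        assert np.max(np.abs(counts / 1000 - p)) <= 1 / 1000 + 1e-12

    def test_depth_floor_enforced(self):
        with pytest.raises(ValueError):
            pseudo_counts([[0.5, 0.5]], depth=10)


class TestDMMFit:
    def test_recovers_planted_components(self, rng):
        X, labels, _ = _mixture_data(rng)
        model = DirichletMultinomialMixture(
            n_components=3, depth=1000, n_init=3, random_state=0
        ).fit(X)
        assert adjusted_rand_score(labels, model.labels_) >= 0.9

    def test_loglik_monotone_nondecreasing(self, rng):
        X, _, _ = _mixture_data(rng)
        model = DirichletMultinomialMixture(
            n_components=3, depth=1000, n_init=1, random_state=1
        ).fit(X)
        h = np.array(model.ll_history_)
        assert np.all(np.diff(h) >= -1e-6 * np.abs(h[:-1]))

    def test_single_component_matches_pooled_mean(self, rng):
        mean = rng.dirichlet(np.ones(8))
        X = np.array([rng.dirichlet(mean * 50 + 0.05) for _ in range(100)])
        model = DirichletMultinomialMixture(
            n_components=1, depth=1000, n_init=1, random_state=0, max_iter=500
        ).fit(X)
        assert np.max(np.abs(model.component_means_[0] - X.mean(axis=0))) < 0.02

    def test_fixed_seed_deterministic(self, rng):
        X, _, _ = _mixture_data(rng)
        a = DirichletMultinomialMixture(n_components=3, depth=500, n_init=2, random_state=3).fit(X)
        b = DirichletMultinomialMixture(n_components=3, depth=500, n_init=2, random_state=3).fit(X)
        assert np.array_equal(a.alpha_, b.alpha_)
        assert a.log_likelihood_ == b.log_likelihood_

    def test_k_exceeding_n_rejected(self, rng):
        X = rng.dirichlet(np.ones(4), size=3)
        with pytest.raises(ValueError, match="exceeds"):
            DirichletMultinomialMixture(n_components=5).fit(X)

    def test_weights_sum_to_one_and_alpha_positive(self, rng):
        X, _, _ = _mixture_data(rng, k=2, n=60)
        model = DirichletMultinomialMixture(n_components=2, depth=500, random_state=0).fit(X)
        assert model.weights_.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(model.alpha_ > 0)


class TestAssignType:
    def _well_separated_model(self, rng):
        X, labels, means = _mixture_data(rng, k=3, n=120, concentration=200.0)
        model = DirichletMultinomialMixture(
            n_components=3, depth=2000, n_init=3, random_state=0
        ).fit(X)
        return model, means

    def test_component_mean_assigned_to_itself(self, rng):
        model, _ = self._well_separated_model(rng)
        for k, mean in enumerate(model.component_means_):
            tid, proba = assign_type(model, mean)
            assert tid == k
            assert proba[k] > 0.99

    def test_posteriors_sum_to_one(self, rng):
        model, _ = self._well_separated_model(rng)
        X = rng.dirichlet(np.ones(10), size=5)
        proba = model.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_symmetric_tie_breaks_to_lower_id(self):
        # two identical components: posterior is (0.5, 0.5), argmax -> type 0
        model = DirichletMultinomialMixture(n_components=2, depth=1000)
        model.alpha_ = np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        model.weights_ = np.array([0.5, 0.5])
        model.taxa_ = None
        tid, proba = assign_type(model, [0.2, 0.3, 0.5])
        assert tid == 0
        np.testing.assert_allclose(proba, [0.5, 0.5], atol=1e-12)

    def test_taxon_reordering_invariance(self, rng):
        model, _ = self._well_separated_model(rng)
        X = rng.dirichlet(np.ones(10), size=8)
        base = model.predict(X)
        perm = rng.permutation(10)
        permuted = DirichletMultinomialMixture(n_components=3, depth=2000)
        permuted.alpha_ = model.alpha_[:, perm]
        permuted.weights_ = model.weights_
        permuted.taxa_ = None
        assert np.array_equal(permuted.predict(X[:, perm]), base)


class TestProbioticTypes:
    def _model_with_means(self, means, taxa):
        model = DirichletMultinomialMixture(n_components=len(means))
        model.alpha_ = np.asarray(means, dtype=float) * 100
        model.weights_ = np.full(len(means), 1 / len(means))
        model.taxa_ = list(taxa)
        return model

    TAXA = ["Bifidobacterium_bifidum", "Lactobacillus_acidophilus", "Escherichia_coli", "Klebsiella_pneumoniae"]

    def test_bifidobacterium_dominant_component_found(self):
        model = self._model_with_means(
            [[0.6, 0.1, 0.2, 0.1], [0.05, 0.05, 0.6, 0.3]], self.TAXA
        )
        assert probiotic_associated_types(model) == {0}

    def test_no_probiotic_dominant_component(self, caplog):
        model = self._model_with_means(
            [[0.1, 0.1, 0.5, 0.3], [0.2, 0.1, 0.3, 0.4]], self.TAXA
        )
        with caplog.at_level("WARNING"):
            assert probiotic_associated_types(model) == set()
        assert "no probiotic-dominant" in caplog.text

    def test_two_probiotic_led_components(self):
        model = self._model_with_means(
            [[0.5, 0.2, 0.2, 0.1], [0.1, 0.6, 0.2, 0.1], [0.1, 0.1, 0.4, 0.4]],
            self.TAXA,
        )
        assert probiotic_associated_types(model) == {0, 1}


class TestTypeProportions:
    def test_single_type_proportion_one(self, small_cohort):
        infants, samples, _, _ = small_cohort
        use = [s for s in samples if s.during_probiotic_use]
        assignments = pd.Series(0, index=[s.sample_id for s in use])
        props = type_proportions_by_group(assignments, samples, infants, probiotic_types={0})
        np.testing.assert_allclose(props.proportions[0].to_numpy(), 1.0)
        np.testing.assert_allclose(props.probiotic_associated.to_numpy(), 1.0)

    def test_during_use_filter_excludes_none_arm(self, small_cohort):
        infants, samples, _, _ = small_cohort
        assignments = pd.Series(0, index=[s.sample_id for s in samples])
        props = type_proportions_by_group(
            assignments, samples, infants, during_probiotic_only=True
        )
        none_ids = {i.infant_id for i in infants if i.probiotic_product == "none"}
        used = {s.infant_id for s in samples if s.during_probiotic_use}
        assert not (none_ids & used)
        assert props.counts.to_numpy().sum() == sum(1 for s in samples if s.during_probiotic_use)

    def test_group_independent_assignment_balanced(self, rng):
        """Types assigned independently of group: proportions agree within 5 points."""
        from preemie_probiome.cohort_io import InfantRecord, SampleRecord

        infants, samples, assignment = [], [], {}
        for g, (ga, bw) in enumerate([(26.0, 800.0), (30.0, 1400.0)]):
            for i in range(320):
                iid = f"G{g}I{i}"
                infants.append(
                    InfantRecord(
                        infant_id=iid, gestational_age=ga, birthweight=bw, sex="male",
                        birth_mode="vaginal", season="spring", probiotic_product="labinic",
                        probiotic_start_day=5.0, probiotic_last_day=40.0,
                    )
                )
                sid = f"{iid}_S0"
                samples.append(
                    SampleRecord(sample_id=sid, infant_id=iid, day_of_life=20.0,
                                 during_probiotic_use=True)
                )
                assignment[sid] = int(rng.random() < 0.3)
        props = type_proportions_by_group(
            pd.Series(assignment), samples, infants, probiotic_types={1}
        )
        diff = abs(props.probiotic_associated.iloc[0] - props.probiotic_associated.iloc[1])
        assert diff < 0.05
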