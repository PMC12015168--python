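import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from preemie_probiome.cohort_io import covariate_table
from preemie_probiome.permanova import (
    RankDeficiencyError,
    fdr_bh,
    permanova,
    variance_grid,
)
from preemie_probiome.synthetic import generate_cohort
from tests.conftest import small_config


def _design(labels):
    return pd.DataFrame({"g": list(labels)})


def _two_level_oracle(d: np.ndarray, labels):
    """Independent between/within decomposition + exhaustive arrangement p.

    For a single 2-level factor, SS_within is the sum over groups of mean
    squared within-group distances; the pseudo-F null is enumerated over
    all distinct label arrangements.
    """
    labels = np.asarray(labels)
    n = len(labels)
    d2 = d**2

    def f_stat(lab):
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in np.unique(lab):
            idx = np.where(lab == g)[0]
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_between = ss_total - ss_within
        return (ss_between / 1) / (ss_within / (n - 2)), ss_between, ss_total

    f_obs, ss_b, ss_t = f_stat(labels)
    n1 = int((labels == labels[0]).sum())
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        lab = np.array(["B"] * n, dtype=object)
        lab[list(combo)] = "A"
        f, _, _ = f_stat(lab)
        total += 1
        count += f >= f_obs - 1e-12
    return f_obs, ss_b, ss_t, count / total


class TestPermanovaCore:
    def test_separated_clusters_dominant_r2_and_floor_p(self, rng):
        a = rng.dirichlet([40, 2, 2, 2], size=10)
        b = rng.dirichlet([2, 2, 2, 40], size=10)
        d = squareform(pdist(np.vstack([a, b]), "braycurtis"))
        res = permanova(d, _design(["a"] * 10 + ["b"] * 10), n_perm=999, seed=0)
        term = res.terms[0]
        assert term.r2 > 0.9
        assert term.p_value == pytest.approx(1 / 1000)

    def test_matches_between_within_oracle(self, rng):
        X = rng.dirichlet(np.ones(6), size=9)
        d = squareform(pdist(X, "braycurtis"))
        labels = ["a"] * 4 + ["b"] * 5
        f_obs, ss_b, ss_t, _ = _two_level_oracle(d, labels)
        res = permanova(d, _design(labels), n_perm=9, seed=0)
        assert res.terms[0].pseudo_f == pytest.approx(f_obs, abs=1e-9)
        assert res.terms[0].ss == pytest.approx(ss_b, abs=1e-9)
        assert res.total_ss == pytest.approx(ss_t, abs=1e-9)

    def test_exhaustive_p_equals_enumeration_oracle(self, rng):
        X = rng.dirichlet(np.ones(5), size=6)
        d = squareform(pdist(X, "braycurtis"))
        labels = ["a", "a", "a", "b", "b", "b"]
        _, _, _, p_oracle = _two_level_oracle(d, labels)
        res = permanova(d, _design(labels), n_perm=None)
        assert res.terms[0].p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_sampled_p_converges_to_exact(self, rng):
        X = rng.dirichlet(np.ones(4), size=7)
        d = squareform(pdist(X, "braycurtis"))
        labels = ["a", "a", "a", "b", "b", "b", "b"]
        _, _, _, p_exact = _two_level_oracle(d, labels)
        res = permanova(d, _design(labels), n_perm=20000, seed=1)
        assert res.terms[0].p_value == pytest.approx(p_exact, abs=0.02)

    def test_agrees_with_skbio(self, rng):
        X = rng.dirichlet(np.ones(8), size=18)
        d = squareform(pdist(X, "braycurtis"))
        labels = ["a"] * 9 + ["b"] * 9
        dm = DistanceMatrix(d, ids=[str(i) for i in range(18)])
        ours = permanova(dm, pd.DataFrame({"g": labels}, index=dm.ids), n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=labels, permutations=99)
        assert ours.terms[0].pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_r2_invariant_under_joint_reordering(self, rng):
        X = rng.dirichlet(np.ones(5), size=12)
        d = squareform(pdist(X, "braycurtis"))
        labels = np.array(["a", "b"] * 6)
        res = permanova(d, _design(labels), n_perm=9, seed=0)
        perm = rng.permutation(12)
        res2 = permanova(d[np.ix_(perm, perm)], _design(labels[perm]), n_perm=9, seed=0)
        assert res2.terms[0].r2 == pytest.approx(res.terms[0].r2, rel=1e-9)

    def test_r2_partition_sums_to_one(self, rng):
        X = rng.dirichlet(np.ones(6), size=16)
        d = squareform(pdist(X, "braycurtis"))
        design = pd.DataFrame(
            {"g": ["a", "b"] * 8, "h": ["x"] * 4 + ["y"] * 4 + ["x"] * 4 + ["y"] * 4}
        )
        res = permanova(d, design, n_perm=9, seed=0)
        total_r2 = sum(t.r2 for t in res.terms) + res.residual_r2
        assert total_r2 == pytest.approx(1.0, abs=1e-9)

    def test_identical_samples_rejected(self):
        d = np.zeros((5, 5))
        with pytest.raises(ValueError, match="zero"):
            permanova(d, _design(["a", "a", "b", "b", "b"]), n_perm=9)

    def test_confounded_term_names_offender(self, rng):
        X = rng.dirichlet(np.ones(4), size=8)
        d = squareform(pdist(X, "braycurtis"))
        design = pd.DataFrame({"g": ["a", "b"] * 4, "twin": ["a", "b"] * 4})
        with pytest.raises(RankDeficiencyError, match="twin"):
            permanova(d, design, n_perm=9)

    def test_type_i_error_within_binomial_bounds(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            X = rng.dirichlet(np.ones(10), size=30)
            d = squareform(pdist(X, "braycurtis"))
            labels = rng.permutation(["a"] * 15 + ["b"] * 15)
            res = permanova(d, _design(labels), n_perm=199, seed=int(rng.integers(2**31 - 1)))
            rejections += res.terms[0].p_value < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09


class TestFdrBH:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_monotone_after_adjustment(self, rng):
        p = np.sort(rng.uniform(size=20))
        q = fdr_bh(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestVarianceGrid:
    def test_single_window_single_covariate_reduces_to_permanova(self, small_cohort):
        infants, samples, profiles, _ = small_cohort
        grid = variance_grid(
            profiles, infants, samples, windows=[(10, 14)], covariates=("probiotic",),
            n_perm=99, seed=4, min_n=5,
        )
        assert len(grid) == 1
        from preemie_probiome.cohort_io import select_one_sample_per_infant
        from preemie_probiome.diversity import distance_matrix

        chosen = select_one_sample_per_infant(samples, "10-14")
        ids = [s.sample_id for s in chosen]
        cov = covariate_table(infants, samples).loc[ids, ["probiotic"]]
        direct = permanova(
            distance_matrix(profiles.subset(ids)), cov, n_perm=99,
            seed=np.random.default_rng(4).integers(2**31 - 1),
        )
        assert grid["R2"].iloc[0] == pytest.approx(direct.terms[0].r2, rel=1e-9)
        assert grid["p"].iloc[0] == direct.terms[0].p_value

    def test_probiotic_is_top_driver_with_planted_effect(self, small_cohort):
        infants, samples, profiles, _ = small_cohort
        grid = variance_grid(
            profiles, infants, samples, n_perm=49, seed=0, min_n=10,
        )
        mean_r2 = grid.groupby("covariate")["R2"].mean()
        assert mean_r2.idxmax() == "probiotic"

    def test_small_windows_skipped(self, small_cohort, caplog):
        infants, samples, profiles, _ = small_cohort
        with caplog.at_level("WARNING"):
            grid = variance_grid(
                profiles, infants, samples, windows=[(0, 9)], covariates=("probiotic",),
                n_perm=9, seed=0, min_n=10**6,
            )
        assert grid.empty
        assert "skipped" in caplog.text

    def test_q_values_bound_p_values(self, small_cohort):
        infants, samples, profiles, _ = small_cohort
        grid = variance_grid(
            profiles, infants, samples, windows=[(10, 14), (15, 19)],
            covariates=("probiotic", "sex"), n_perm=49, seed=2, min_n=5,
        )
        assert np.all(grid["q"].to_numpy() >= grid["p"].to_numpy() - 1e-12)
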