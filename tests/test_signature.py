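import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from m6ascape.io import ClinicalTable, ExpressionMatrix
from m6ascape.signature import (
    SignatureModel,
    filter_degs,
    m6a_score,
    median_split_series,
    moderated_t_de,
    partition_by_sign,
    prognostic_filter,
    rf_importance_select,
)
from m6ascape.stats import cox_fit
from m6ascape.synthetic import simulate_survival

from conftest import make_expression


def _labels(em, n1, a="A", b="B"):
    return pd.Series([a] * n1 + [b] * (len(em.sample_ids) - n1),
                     index=em.sample_ids)


class TestModeratedT:
    def test_zero_prior_equals_pooled_t(self, rng):
        X = rng.normal(size=(200, 30))
        em = make_expression(X)
        labels = _labels(em, 15)
        de = moderated_t_de(em, labels, d0_override=0)
        ref = sps.ttest_ind(X[:, 15:].T, X[:, :15].T, equal_var=True)
        np.testing.assert_allclose(de["t"].to_numpy(), ref.statistic, atol=1e-10)
        np.testing.assert_allclose(de["p"].to_numpy(), ref.pvalue, atol=1e-10)

    def test_null_type_I_calibration(self):
        rng = np.random.default_rng(99)
        X = rng.normal(size=(1000, 40))
        em = make_expression(X)
        labels = pd.Series(rng.permutation([0] * 20 + [1] * 20),
                           index=em.sample_ids)
        de = moderated_t_de(em, labels)
        rate = (de["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_power_on_planted_fold_changes(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(1000, 80))
        X[:50, 40:] += 1.0  # log2FC = 1 on the first 50 genes
        em = make_expression(X)
        de = moderated_t_de(em, _labels(em, 40)).set_index("gene")
        hits = sum(
            (de.loc[f"g{i}", "adj_p"] < 0.05) and abs(de.loc[f"g{i}", "log2FC"]) > 0.5
            for i in range(50))
        assert hits >= 45

    def test_shrinkage_moves_variances_toward_prior(self, rng):
        X = rng.normal(size=(500, 20))
        em = make_expression(X)
        de = moderated_t_de(em, _labels(em, 10))
        assert de.attrs["d0"] > 0

    def test_small_group_rejected(self, rng):
        em = make_expression(rng.normal(size=(20, 5)))
        with pytest.raises(ValueError):
            moderated_t_de(em, _labels(em, 1))


class TestFilterDegs:
    @pytest.mark.parametrize(
        "adj_p,lfc,expected",
        [(0.05, 0.6, False),   # adj_p at the boundary is excluded
         (0.01, 0.5, False),   # |log2FC| at the boundary is excluded
         (0.01, 0.6, True)])
    def test_strict_boundaries(self, adj_p, lfc, expected):
        de = pd.DataFrame({"gene": ["g"], "log2FC": [lfc], "t": [1.0],
                           "p": [adj_p], "adj_p": [adj_p]})
        assert (filter_degs(de) == ["g"]) is expected

    def test_direct_filter(self):
        de = pd.DataFrame({
            "gene": ["a", "b", "c", "d"],
            "log2FC": [1.0, 0.2, -1.0, 0.9],
            "t": [5, 1, -5, 4],
            "p": [0.001, 0.5, 0.001, 0.2],
            "adj_p": [0.004, 0.6, 0.2, 0.3]})
        assert filter_degs(de) == ["a"]


class TestRfImportance:
    def test_informative_genes_rank_high(self):
        rng = np.random.default_rng(17)
        n = 200
        X = rng.normal(size=(105, n))
        truth = np.repeat([0, 1], n // 2)
        X[:5, truth == 1] += 3.0
        em = make_expression(X)
        labels = pd.Series(truth, index=em.sample_ids)
        imp = rf_importance_select(em, labels, n_trees=150, seed=4)
        top10 = set(imp["gene"].head(10))
        assert {f"g{i}" for i in range(5)} <= top10

    def test_null_labels_importance_within_permutation_band(self):
        rng = np.random.default_rng(29)
        n, p = 100, 20
        X = rng.normal(size=(p, n))
        em = make_expression(X)
        y = np.repeat([0, 1], n // 2)
        null_max = []
        for s in range(20):
            shuffled = pd.Series(rng.permutation(y), index=em.sample_ids)
            imp = rf_importance_select(em, shuffled, n_trees=80, seed=s)
            null_max.append(imp["importance"].max())
        band = np.quantile(null_max, 0.95)
        imp0 = rf_importance_select(
            em, pd.Series(rng.permutation(y), index=em.sample_ids),
            n_trees=80, seed=100)
        assert (imp0["importance"] <= band).mean() >= 0.90

    def test_duplicated_informative_gene_keeps_both_copies(self):
        rng = np.random.default_rng(41)
        n = 150
        truth = np.repeat([0, 1], n // 2)
        signal = truth * 3.0 + rng.normal(size=n)
        X = np.vstack([signal, signal.copy(), rng.normal(size=(10, n))])
        em = make_expression(X)
        imp = rf_importance_select(em, pd.Series(truth, index=em.sample_ids),
                                   n_trees=150, seed=2).set_index("gene")
        assert imp.loc["g0", "importance"] > 0
        assert imp.loc["g1", "importance"] > 0

    def test_single_class_rejected(self, rng):
        em = make_expression(rng.normal(size=(5, 10)))
        with pytest.raises(ValueError):
            rf_importance_select(em, pd.Series(np.zeros(10), index=em.sample_ids),
                                 n_trees=60)

    def test_low_tree_count_warns(self, rng):
        em = make_expression(rng.normal(size=(3, 20)))
        labels = pd.Series(np.repeat([0, 1], 10), index=em.sample_ids)
        with pytest.warns(UserWarning, match="n_trees"):
            rf_importance_select(em, labels, n_trees=10)


def _clinical_from(time, event, ids):
    return ClinicalTable(pd.DataFrame(
        {"sample_id": ids, "os_time": time, "os_event": event}))


class TestPrognosticFilter:
    def test_planted_risk_gene_retained(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.normal(size=n)
        t, e = simulate_survival(0.8 * x, 0.01, 0.2, seed=6)
        em = make_expression(np.vstack([x]))
        clin = _clinical_from(t, e, em.sample_ids)
        model = prognostic_filter(em, clin, ["g0"])
        assert model.genes["hr"].iloc[0] > 1

    def test_noise_gene_type_I_rate(self):
        rng = np.random.default_rng(9)
        kept = 0
        reps = 500
        for _ in range(reps):
            n = 60
            x = rng.normal(size=n)
            t = rng.exponential(100, n)
            e = (rng.random(n) < 0.8).astype(int)
            em = make_expression(np.vstack([x]))
            clin = _clinical_from(t, e, em.sample_ids)
            try:
                prognostic_filter(em, clin, ["g0"])
                kept += 1
            except ValueError:
                pass
        assert 0.03 <= kept / reps <= 0.07

    def test_alpha_near_one_keeps_all(self, rng):
        n = 100
        X = rng.normal(size=(5, n))
        t = rng.exponential(100, n)
        e = np.ones(n, dtype=int)
        em = make_expression(X)
        clin = _clinical_from(t, e, em.sample_ids)
        model = prognostic_filter(em, clin, em.gene_ids, alpha_surv=1.0 - 1e-12)
        assert len(model.genes) == 5


class TestPartitionAndScore:
    def _model(self, genes, betas):
        return SignatureModel(genes=pd.DataFrame(
            {"gene": genes, "importance": 1.0, "beta": betas,
             "hr": np.exp(betas), "p": 0.01}))

    def test_sign_rule(self):
        m = self._model(["g1", "g2", "g3"], [0.2, -0.3, 0.1])
        X, Y = partition_by_sign(m)
        assert X == ["g1", "g3"] and Y == ["g2"]

    def test_all_positive_betas_allowed(self):
        m = self._model(["g1", "g2"], [0.2, 0.3])
        X, Y = partition_by_sign(m)
        assert Y == []

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            partition_by_sign(self._model(["g1"], [0.0]))

    def test_hr_sign_convention_matches_published_table(self):
        # HR > 1 <=> beta > 0 (risk, X side); HR < 1 <=> beta < 0 (Y side)
        betas = np.log([1.326562, 0.755901])
        m = self._model(["KIAA1429", "ALKBH5"], betas)
        X, Y = partition_by_sign(m)
        assert X == ["KIAA1429"] and Y == ["ALKBH5"]

    def test_hand_scaled_scores(self):
        em = ExpressionMatrix(pd.DataFrame(
            [[2.0, 1.0], [1.0, 2.0]], index=["g1", "g2"], columns=["s1", "s2"]))
        m = self._model(["g1", "g2"], [0.5, -0.5])
        partition_by_sign(m)
        sv = m6a_score(em, m)
        np.testing.assert_allclose(sv.scores, [1 / np.sqrt(2), -1 / np.sqrt(2)],
                                   atol=1e-12)

    def test_constant_raw_score_rejected(self):
        em = ExpressionMatrix(pd.DataFrame(
            [[1.0, 1.0, 1.0]], index=["g"], columns=["s1", "s2", "s3"]))
        m = self._model(["g"], [0.5])
        partition_by_sign(m)
        with pytest.raises(ValueError, match="scale"):
            m6a_score(em, m)

    def test_training_scores_standardized(self, rng):
        em = make_expression(rng.normal(size=(4, 50)))
        m = self._model(em.gene_ids, [0.5, 0.4, -0.2, -0.6])
        partition_by_sign(m)
        sv = m6a_score(em, m)
        assert abs(sv.scores.mean()) < 1e-10
        assert abs(sv.scores.std(ddof=1) - 1.0) < 1e-10

    def test_invariant_to_gene_and_sample_order(self, rng):
        X = rng.normal(size=(4, 20))
        em = make_expression(X)
        m1 = self._model(em.gene_ids, [0.5, 0.4, -0.2, -0.6])
        partition_by_sign(m1)
        s1 = m6a_score(em, m1).scores
        perm_g = [2, 0, 3, 1]
        perm_s = rng.permutation(20)
        em2 = ExpressionMatrix(em.values.iloc[perm_g, perm_s])
        m2 = self._model([em.gene_ids[i] for i in [0, 1, 2, 3]],
                         [0.5, 0.4, -0.2, -0.6])
        partition_by_sign(m2)
        s2 = m6a_score(em2, m2).scores
        np.testing.assert_allclose(s1.loc[s2.index], s2, atol=1e-12)

    def test_constant_gene_shift_leaves_scaled_scores_unchanged(self, rng):
        X = rng.normal(size=(3, 25))
        em = make_expression(X)
        m1 = self._model(em.gene_ids, [0.5, 0.2, -0.4])
        partition_by_sign(m1)
        s1 = m6a_score(em, m1).scores
        X2 = X.copy()
        X2[0] += 7.0  # uniform shift on an X gene
        m2 = self._model(em.gene_ids, [0.5, 0.2, -0.4])
        partition_by_sign(m2)
        s2 = m6a_score(make_expression(X2), m2).scores
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_application_mode_reuses_scale(self, rng):
        em = make_expression(rng.normal(size=(3, 30)))
        m = self._model(em.gene_ids, [0.5, 0.2, -0.4])
        partition_by_sign(m)
        m6a_score(em, m)
        mean0, sd0 = m.scale_mean, m.scale_sd
        em2 = make_expression(rng.normal(size=(3, 10)) + 5.0)
        sv2 = m6a_score(em2, m)
        assert (m.scale_mean, m.scale_sd) == (mean0, sd0)
        assert abs(sv2.scores.mean()) > 0.5  # shifted cohort is not re-centered

    def test_pca_mode_correlates_with_sum_mode(self, rng):
        em = make_expression(rng.normal(size=(6, 40)))
        betas = [0.5, 0.4, 0.3, -0.2, -0.3, -0.1]
        m_sum = self._model(em.gene_ids, betas)
        partition_by_sign(m_sum)
        s_sum = m6a_score(em, m_sum).scores
        m_pca = self._model(em.gene_ids, betas)
        partition_by_sign(m_pca)
        s_pca = m6a_score(em, m_pca, mode="pca").scores
        assert np.corrcoef(s_sum, s_pca)[0, 1] > 0


class TestMedianSplit:
    def test_strict_above_median(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups, med = median_split_series(s)
        assert med == 2.5
        assert set(s.index[groups == "high"]) == {"c", "d"}

    def test_ties_go_low(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        groups, med = median_split_series(s)
        assert med == 2.0
        assert list(groups) == ["low", "low", "low", "high"]

    def test_all_equal_warns_all_low(self):
        s = pd.Series([1.0, 1.0, 1.0])
        with pytest.warns(UserWarning):
            groups, _ = median_split_series(s)
        assert (groups == "low").all()
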