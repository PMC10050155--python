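import warnings

import numpy as np
import pandas as pd
import pytest

from dualsub.derive import (
    DeriveParams,
    assemble_option_c,
    build_option_a,
    cross_cohort_concordance,
    derive_option_b,
    lasso_group_genes,
    meta_signature_check,
    select_class_specific_sets,
    ttest_filter,
    zscore_class_means,
)
from dualsub.enrichment import ssgsea_score
from dualsub.ntp import NtpParams, ntp_classify
from dualsub.simulate import SimParams, simulate_cohort
from dualsub.types import (
    ExpressionMatrix,
    GeneSetCollection,
    OrthologMap,
    SubtypeTemplate,
)

CLASSES = ["CMS1", "CMS2", "CMS3", "CMS4"]


def class_labels(n_per: int) -> pd.Series:
    samples = [f"s{i}" for i in range(4 * n_per)]
    return pd.Series([CLASSES[i // n_per] for i in range(4 * n_per)], index=samples)


class TestZscore:
    def test_single_high_class(self):
        z = zscore_class_means(
            pd.DataFrame([[10.0, 0, 0, 0]], index=["S"], columns=CLASSES)
        )
        # mean 2.5, sample SD over the 4 class means = 5
        assert np.allclose(z.loc["S"], [1.5, -0.5, -0.5, -0.5])

    def test_two_high_classes(self):
        z = zscore_class_means(
            pd.DataFrame([[5.0, 5, 0, 0]], index=["S"], columns=CLASSES)
        )
        v = 2.5 / np.std([5, 5, 0, 0], ddof=1)
        assert np.allclose(z.loc["S"], [v, v, -v, -v])

    def test_degenerate_row_excluded(self):
        z = zscore_class_means(
            pd.DataFrame(
                [[1.0, 1, 1, 1], [2.0, 0, 0, 0]], index=["flat", "ok"],
                columns=CLASSES,
            )
        )
        assert list(z.index) == ["ok"]

    def test_rows_centered_with_unit_sd(self):
        rng = np.random.default_rng(0)
        z = zscore_class_means(
            pd.DataFrame(
                rng.normal(size=(30, 4)), columns=CLASSES,
                index=[f"S{i}" for i in range(30)],
            )
        )
        assert np.allclose(z.sum(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestSelection:
    def test_sign_rule(self):
        z = pd.DataFrame(
            [[1.5, -0.5, -0.5, -0.5],   # CMS1-specific
             [0.5, 0.5, -0.5, -0.5],    # two positives: discarded
             [-0.9, 1.2, -0.2, -0.1],   # CMS2-specific
             [-1.0, -0.2, 1.1, 0.1],    # zero not below 0? 0.1>0: discarded
             [-1.0, -0.2, 1.4, -0.2],   # CMS3-specific
             [-0.5, -0.5, -0.5, 1.5]],  # CMS4-specific
            index=[f"S{i}" for i in range(6)], columns=CLASSES,
        )
        tmpl = select_class_specific_sets(z)
        assert tmpl.features_by_class == {
            "CMS1": ["S0"], "CMS2": ["S2"], "CMS3": ["S4"], "CMS4": ["S5"]
        }

    def test_class_without_sets_is_error(self):
        z = pd.DataFrame([[1.5, -0.5, -0.5, -0.5]], index=["S"], columns=CLASSES)
        with pytest.raises(ValueError, match="CMS"):
            select_class_specific_sets(z)

    def test_planted_sets_recovered(self, default_cohort):
        m, labels, sets, _, truth = default_cohort
        lab = labels[labels != "unclassified"]
        sub = ExpressionMatrix(m.data[list(lab.index)])
        tmpl = derive_option_b(sub, lab, sets)
        correct = sum(
            1 for cls in CLASSES for s in tmpl.features_by_class[cls]
            if truth["set_truth"][s] == cls
        )
        assert correct / len(truth["set_truth"]) >= 0.9


class TestTtestFilter:
    def _scores(self, rng, planted=True):
        lab = class_labels(25)
        vals = rng.normal(0, 1, size=(8, 100))
        names = [f"S{i}" for i in range(8)]
        truth = {}
        if planted:
            for i, cls in enumerate(CLASSES):
                vals[i, lab.to_numpy() == cls] += 2.0
                truth[names[i]] = cls
        scores = ExpressionMatrix(
            pd.DataFrame(vals, index=names, columns=lab.index)
        )
        return scores, lab, truth

    def test_clear_separation_kept(self):
        lab = class_labels(4)
        vals = np.zeros((1, 16))
        vals[0, :4] = [2.0, 2.1, 1.9, 2.2]
        vals[0, 4:] = np.resize([0.0, 0.1, -0.1, 0.05], 12)
        scores = ExpressionMatrix(pd.DataFrame(vals, index=["S"], columns=lab.index))
        tmpl = ttest_filter(scores, lab, allow_empty=True)
        assert tmpl.features_by_class["CMS1"] == ["S"]

    def test_identical_distributions_discarded(self):
        lab = class_labels(4)
        vals = np.tile([1.0, 2.0, 3.0, 4.0], (1, 4))
        scores = ExpressionMatrix(pd.DataFrame(vals, index=["S"], columns=lab.index))
        tmpl = ttest_filter(scores, lab, allow_empty=True)
        assert all(not v for v in tmpl.features_by_class.values())

    def test_two_way_tie_discarded(self):
        # high in CMS1 and CMS2 equally: fails the CMS1-vs-CMS2 pairwise test
        lab = class_labels(5)
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.1, size=(1, 20))
        vals[0, :10] += 3.0
        scores = ExpressionMatrix(pd.DataFrame(vals, index=["S"], columns=lab.index))
        tmpl = ttest_filter(scores, lab, allow_empty=True)
        assert all(not v for v in tmpl.features_by_class.values())

    def test_small_class_rejected(self):
        lab = pd.Series(
            ["A", "A", "B", "B", "B"], index=[f"s{i}" for i in range(5)]
        )
        scores = ExpressionMatrix(
            pd.DataFrame(np.ones((1, 5)) + np.arange(5), index=["S"],
                         columns=lab.index)
        )
        with pytest.raises(ValueError, match="< 3"):
            ttest_filter(scores, lab)

    def test_planted_recovery_and_null_rejection(self):
        rng = np.random.default_rng(21)
        scores, lab, truth = self._scores(rng, planted=True)
        tmpl = ttest_filter(scores, lab, allow_empty=True)
        hits = sum(
            1 for cls in CLASSES for s in tmpl.features_by_class[cls]
            if truth.get(s) == cls
        )
        assert hits >= 0.9 * len(truth)
        noise, lab, _ = self._scores(rng, planted=False)
        tmpl0 = ttest_filter(noise, lab, allow_empty=True)
        assert sum(len(v) for v in tmpl0.features_by_class.values()) == 0


class TestLasso:
    def _planted(self, seed=7, n_genes=40, n_per=20, delta=3.0, sigma=0.5):
        rng = np.random.default_rng(seed)
        lab = class_labels(n_per)
        vals = rng.normal(0, sigma, size=(n_genes, 4 * n_per))
        truth = {}
        for ci, cls in enumerate(CLASSES):
            for g in range(ci * 3, ci * 3 + 3):
                vals[g, lab.to_numpy() == cls] += delta
                truth[f"g{g}"] = cls
        em = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                         columns=lab.index)
        )
        return em, lab, truth

    def test_planted_markers_assigned_to_their_class(self):
        em, lab, truth = self._planted()
        groups = lasso_group_genes(em, lab, DeriveParams(lasso_seed=0))
        hits = sum(1 for g, c in truth.items() if g in groups.get(c, []))
        assert hits >= 0.8 * len(truth)

    def test_noise_selection_is_sparse(self):
        """Monte-Carlo under the null: on average almost nothing survives
        the one-SE penalty choice."""
        lab = class_labels(20)
        fracs = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            em = ExpressionMatrix(
                pd.DataFrame(rng.normal(0, 0.5, size=(40, 80)),
                             index=[f"g{i}" for i in range(40)],
                             columns=lab.index)
            )
            groups = lasso_group_genes(em, lab, DeriveParams(lasso_seed=0))
            fracs.append(sum(len(v) for v in groups.values()) / 40)
        assert np.mean(fracs) <= 0.05

    def test_constant_gene_excluded_with_warning(self):
        em, lab, _ = self._planted(n_genes=20)
        df = em.data.copy()
        df.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            lasso_group_genes(ExpressionMatrix(df), lab, DeriveParams(lasso_seed=0))

    def test_fold_starved_class_rejected(self):
        em, lab, _ = self._planted(n_per=5)
        with pytest.raises(ValueError, match="folds"):
            lasso_group_genes(em, lab, DeriveParams(lasso_folds=10))


class TestOptionC:
    def _cohort(self, delta=2.0, seed=33):
        params = SimParams(
            n_classes=4, n_per_class=12, n_genes=900, sets_per_class=3,
            genes_per_set=15, delta=delta, sigma=1.0, frac_null=0.0, seed=seed,
        )
        return simulate_cohort(params)

    def test_planted_collections_recovered(self):
        m, labels, sets, _, truth = self._cohort()
        names = sets.set_names
        curated = GeneSetCollection({n: sets.sets[n] for n in names[:4]})
        hallm = GeneSetCollection({n: sets.sets[n] for n in names[4:8]})
        mcp = GeneSetCollection({n: sets.sets[n] for n in names[8:12]})
        # immune panel: markers of each class from the planted pool
        immune = [g for n in names for g in sets.sets[n][:2]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tmpl, report = assemble_option_c(
                curated, hallm, mcp, immune, m, labels,
                DeriveParams(lasso_seed=0),
            )
        # every retained named set must sit in its planted class
        for cls in CLASSES:
            for feat in tmpl.features_by_class[cls]:
                if feat.startswith("SET_"):
                    assert truth["set_truth"][feat] == cls
                else:
                    assert feat == f"IMMUNE_{cls}"
        assert sum(report["per_step_counts"].values()) == sum(
            tmpl.class_sizes().values()
        )
        # template classes disjoint by construction
        feats = tmpl.all_features
        assert len(feats) == len(set(feats))

    def test_all_noise_collections_error(self):
        m, labels, sets, _, _ = self._cohort(delta=0.0, seed=5)
        names = sets.set_names
        curated = GeneSetCollection({n: sets.sets[n] for n in names[:4]})
        hallm = GeneSetCollection({n: sets.sets[n] for n in names[4:8]})
        mcp = GeneSetCollection({n: sets.sets[n] for n in names[8:12]})
        immune = [g for n in names for g in sets.sets[n][:2]]
        with pytest.raises(ValueError, match="empty"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assemble_option_c(
                    curated, hallm, mcp, immune, m, labels,
                    DeriveParams(lasso_seed=0),
                )


class TestOptionA:
    def test_delegates_to_translation(self):
        tmpl = SubtypeTemplate({"c1": ["A", "B"], "c2": ["C"]})
        m = OrthologMap.from_pairs([("A", "a1"), ("A", "a2"), ("B", "b"), ("C", "c")])
        out, reports, _ = build_option_a(tmpl, m)
        assert out.class_sizes() == {"c1": 3, "c2": 1}
        assert reports["c1"].n_expanded == 1


class TestMetaSignature:
    def test_planted_genes_give_diagonal_dominance(self, default_cohort,
                                                   default_template):
        m, labels, sets, _, _ = default_cohort
        scores = ssgsea_score(m, sets)
        calls = ntp_classify(scores, default_template, NtpParams(seed=9))
        # planted shifts are 1.5 log2 units; use a matching fold threshold
        mat, flagged = meta_signature_check(
            m, calls, DeriveParams(fc_threshold=2.0)
        )
        assert not flagged
        for cls in mat.index:
            row = mat.loc[cls]
            assert row.idxmax() == cls

    def test_no_qualifying_genes_all_flagged(self):
        rng = np.random.default_rng(12)
        lab = class_labels(5)
        em = ExpressionMatrix(
            pd.DataFrame(rng.normal(6, 0.01, size=(30, 20)),
                         index=[f"g{i}" for i in range(30)], columns=lab.index)
        )
        mat, flagged = meta_signature_check(em, lab)
        assert set(flagged) == set(CLASSES)

    def test_top_n_larger_than_pool_is_fine(self):
        rng = np.random.default_rng(13)
        lab = class_labels(5)
        vals = rng.normal(0, 0.2, size=(8, 20))
        for ci, cls in enumerate(CLASSES):
            vals[ci, lab.to_numpy() == cls] += 3.0  # 8-fold on log2 scale
        em = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(8)],
                         columns=lab.index)
        )
        mat, flagged = meta_signature_check(
            em, lab, DeriveParams(meta_top_n=50)
        )
        assert not flagged
        assert np.all(np.asarray(mat.values.diagonal()) >= mat.to_numpy().max(axis=1) - 1e-12)


class TestCrossCohortConcordance:
    def _means(self, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(10, 4)), index=[f"S{i}" for i in range(10)],
            columns=CLASSES,
        )

    def test_identical_matrices_r_one(self):
        a = self._means()
        r = cross_cohort_concordance(a, a)
        assert np.allclose(r, 1.0)

    def test_negated_copy_r_minus_one(self):
        a = self._means()
        r = cross_cohort_concordance(a, -a)
        assert np.allclose(r, -1.0)

    def test_direct_pearson_arithmetic(self):
        a = pd.DataFrame({"CMS1": [1.0, 2, 3]}, index=list("abc"))
        b = pd.DataFrame({"CMS1": [1.0, 2, 4]}, index=list("abc"))
        r = cross_cohort_concordance(a, b)
        assert r["CMS1"] == pytest.approx(0.981980506, abs=1e-6)

    def test_too_few_shared_sets_rejected(self):
        a = self._means().iloc[:2]
        with pytest.raises(ValueError, match="3 shared"):
            cross_cohort_concordance(a, a)
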