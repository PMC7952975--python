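import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score
from sklearn.pipeline import Pipeline

import stagedfs as s
from stagedfs.errors import PipelineError
from tests.conftest import make_dataset


class TestFoldChange:
    def test_equal_means_give_unit_fc(self):
        v = np.log2(1 + np.full(6, 50.0))
        ds = make_dataset(v[None, :], [1, 1, 1, 0, 0, 0])
        fc, lfc = s.fold_change(ds, "g0")
        assert fc == pytest.approx(1.0)
        assert lfc == pytest.approx(0.0)

    def test_four_fold_change(self):
        # linear CPM means 800 vs 200; pseudocount of 1 is negligible here
        v = np.log2(1 + np.array([800.0] * 3 + [200.0] * 3))
        ds = make_dataset(v[None, :], [1, 1, 1, 0, 0, 0])
        fc, lfc = s.fold_change(ds, "g0")
        assert fc == pytest.approx(4.0, rel=0.01)
        assert lfc == pytest.approx(2.0, abs=0.01)

    def test_zero_means_resolved_by_pseudocount(self):
        v = np.zeros(6)
        ds = make_dataset(v[None, :], [1, 1, 1, 0, 0, 0])
        fc, lfc = s.fold_change(ds, "g0")
        assert fc == 1.0 and lfc == 0.0

    def test_unknown_gene_is_lookup_error(self, toy_dataset):
        with pytest.raises(KeyError):
            s.fold_change(toy_dataset, "nope")


class TestWelch:
    def test_constant_gene_has_p_one(self):
        ds = make_dataset(np.full((1, 8), 3.0), [1] * 5 + [0] * 3)
        assert s.differential_pvalues(ds).iloc[0] == 1.0

    def test_planted_effect_is_significant(self, toy_dataset):
        p = s.differential_pvalues(toy_dataset)
        assert p.iloc[0] < 1e-4   # separated gene
        assert p.iloc[1] > 0.01   # flat gene

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(5, 1, size=(2000, 60))
        ds = make_dataset(vals, [1] * 40 + [0] * 20)
        p = s.differential_pvalues(ds)
        frac = (p < 0.05).mean()
        assert 0.025 < frac < 0.08

    def test_single_sample_class_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(3, 3)), [1, 1, 0])
        with pytest.raises(PipelineError):
            s.differential_pvalues(ds)


class TestBH:
    def test_step_up_by_hand(self):
        q = s.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert s.bh_adjust([0.37]) == pytest.approx([0.37])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            s.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_bh_bounds_and_order(self, pvals):
        p = np.array(pvals)
        q = s.bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestMutualInformation:
    def test_perfect_binary_association_is_one_bit(self):
        g = np.array([0, 0, 0, 1, 1, 1], float)
        l = np.array([0, 0, 0, 1, 1, 1])
        assert s.mutual_information(g, l, bins=2) == pytest.approx(1.0)

    def test_constant_feature_has_zero_mi(self):
        assert s.mutual_information(np.ones(10), np.r_[np.zeros(5), np.ones(5)]) == 0.0

    def test_worked_two_by_two_table(self):
        # joint counts [[2,1],[1,2]] over 6 samples: MI = 2 - 1.9183 bits
        g = np.array([0, 0, 0, 1, 1, 1], float)
        l = np.array([0, 0, 1, 0, 1, 1])
        assert s.mutual_information(g, l, bins=2) == pytest.approx(0.0817, abs=2e-4)

    def test_symmetry_on_discrete_data(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 40).astype(float)
        b = rng.integers(0, 2, 40)
        assert s.mutual_information(a, b, bins=40) == pytest.approx(
            s.mutual_information(b.astype(float), a.astype(int), bins=40)
        )

    def test_matches_sklearn_on_discrete_data(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 4, 100)
        l = rng.integers(0, 2, 100)
        ours = s.mutual_information(g.astype(float), l, bins=100)
        theirs = mutual_info_score(g, l) / np.log(2)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            s.mutual_information(np.ones(3), np.ones(4))

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=50),
        st.data(),
    )
    def test_bounded_by_marginal_entropies(self, feat, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(feat), max_size=len(feat))
        )
        g, l = np.array(feat, float), np.array(labels)
        mi = s.mutual_information(g, l, bins=len(feat))
        from stagedfs.selection import _entropy_bits

        assert -1e-12 <= mi <= min(
            _entropy_bits(g.astype(int)), _entropy_bits(l)
        ) + 1e-12


class TestSelectDEGenes:
    def _table(self):
        return pd.DataFrame(
            {
                "qvalue": [0.04, 0.04, 0.2, 0.01],
                "log2fc": [0.5, -1.5, 3.0, 1.2],
            },
            index=["a", "b", "c", "d"],
        )

    def test_conjunction_of_thresholds(self):
        assert s.select_de_genes(self._table()) == ["b", "d"]

    def test_two_sided_log_fc(self):
        assert "b" in s.select_de_genes(self._table())

    def test_empty_survivors_is_pipeline_error(self):
        with pytest.raises(PipelineError, match="relax"):
            s.select_de_genes(self._table(), fdr_threshold=1e-9)

    def test_selection_shrinks_as_thresholds_tighten(self, dataset):
        table = s.differential_expression(dataset)
        loose = set(s.select_de_genes(table, 0.1, 0.5))
        tight = set(s.select_de_genes(table, 0.01, 1.0))
        assert tight <= loose


class TestRanking:
    def test_truncation_to_available_genes(self, toy_dataset):
        ranking = s.rank_by_mi(toy_dataset, M=50)
        assert len(ranking.entries) == 2
        assert ranking.genes()[0] == "g0"  # the separated gene ranks first

    def test_ranks_are_descending_in_mi(self, dataset):
        ranking = s.rank_by_mi(dataset, M=50)
        mi = [e[1] for e in ranking.entries]
        assert mi == sorted(mi, reverse=True)

    def test_deterministic_tie_break(self):
        vals = np.tile(np.r_[np.ones(4), np.zeros(4)], (3, 1))
        ds = make_dataset(vals, [1] * 4 + [0] * 4)
        a = s.rank_by_mi(ds, M=3)
        b = s.rank_by_mi(ds, M=3)
        assert a.genes() == b.genes() == sorted(a.genes())

    def test_drivers_dominate_ranking(self, dataset, sim_data):
        _, truth, _ = sim_data
        table = s.differential_expression(dataset)
        de = s.select_de_genes(table)
        ranking = s.rank_by_mi(dataset, genes=de, M=50, log2fc=table["log2fc"])
        got = set(ranking.genes()) & truth.driver_genes
        assert len(got) / min(len(ranking.entries), len(truth.driver_genes)) >= 0.8


class TestEstimators:
    def test_selectors_compose_in_sklearn_pipeline(self, dataset):
        pipe = Pipeline(
            [
                ("de", s.DifferentialExpressionSelector()),
                ("mi", s.MutualInfoSelector(top_m=5)),
            ]
        )
        Xt = pipe.fit_transform(dataset.X(), dataset.y())
        assert Xt.shape == (len(dataset.samples), 5)

    def test_de_selector_exposes_result_table(self, dataset):
        sel = s.DifferentialExpressionSelector().fit(dataset.X(), dataset.y())
        assert {"fc", "log2fc", "pvalue", "qvalue", "significant"} <= set(
            sel.results_.columns
        )
        assert (sel.results_["qvalue"] >= sel.results_["pvalue"] - 1e-15).all()

    def test_mi_selector_keeps_top_m(self, dataset):
        sel = s.MutualInfoSelector(top_m=7).fit(dataset.X(), dataset.y())
        assert sel._get_support_mask().sum() == 7
        kept = sel.mi_[sel._get_support_mask()]
        assert kept.min() >= np.sort(sel.mi_)[-7]
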