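import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg

from pvqnet import features as ft
from pvqnet import questionnaire_io as qio
from pvqnet import synthetic_data as sd


class TestScoreOQ:
    @pytest.mark.parametrize("items,mean,oq8", [
        ({3: 0, 13: 4, 24: 4, 31: 4, 8: 0}, 0.0, 0),   # best-case answers
        ({3: 4, 13: 0, 24: 0, 31: 0, 8: 4}, 4.0, 4),   # worst-case answers
        ({3: 2, 13: 1, 24: 3, 31: 4, 8: 1}, 1.5, 1),   # hand-applied reversal
    ])
    def test_examples(self, items, mean, oq8):
        assert ft.score_oq(items) == (mean, oq8)

    def test_reversal_set_matches_independent_item_table(self):
        # independent per-item scoring table: item -> map answer->score
        table = {3: {a: a for a in range(5)},
                 13: {a: 4 - a for a in range(5)},
                 24: {a: 4 - a for a in range(5)},
                 31: {a: 4 - a for a in range(5)}}
        rng = np.random.default_rng(0)
        for _ in range(50):
            items = {i: int(rng.integers(0, 5)) for i in qio.OQ_ITEMS}
            expected = np.mean([table[i][items[i]] for i in (3, 13, 24, 31)])
            assert ft.score_oq(items)[0] == pytest.approx(expected)

    def test_monotone_in_each_scored_item(self):
        base = {3: 2, 13: 2, 24: 2, 31: 2, 8: 2}
        m0 = ft.score_oq(base)[0]
        assert ft.score_oq({**base, 3: 3})[0] > m0      # as-keyed item
        assert ft.score_oq({**base, 13: 3})[0] < m0     # reverse-keyed item

    def test_missing_item_names_it(self):
        with pytest.raises(ft.ScoringError, match="8"):
            ft.score_oq({3: 1, 13: 1, 24: 1, 31: 1})


class TestScoreRFL:
    def test_extremes(self):
        assert ft.score_rfl({i: 6 for i in qio.RFL_ITEMS}) == (6.0, 6)
        assert ft.score_rfl({i: 1 for i in qio.RFL_ITEMS}) == (1.0, 1)

    def test_item25_is_kept_separate(self):
        values = dict(zip(qio.RFL_ITEMS, (2, 3, 4, 5, 6, 1, 2, 3, 4, 5, 5, 6, 1, 2)))
        assert values[25] == 5
        mean, r25 = ft.score_rfl(values)
        composite = [values[i] for i in qio.RFL_ITEMS if i != 25]
        assert mean == pytest.approx(sum(composite) / 13)  # = 44/13
        assert r25 == 5

    def test_item25_does_not_affect_composite(self):
        values = {i: 3 for i in qio.RFL_ITEMS}
        m1, _ = ft.score_rfl(values)
        m2, _ = ft.score_rfl({**values, 25: 6})
        assert m1 == m2


class TestDeqPCA:
    def test_matches_independent_eigendecomposition(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(20, 6)) @ rng.normal(size=(6, 6)) + rng.normal(size=(20, 6))
        model = ft.fit_deq_pca(X)
        # oracle: symmetric eigendecomposition of the correlation matrix
        corr = np.corrcoef(X, rowvar=False)
        w, v = linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for c in range(2):
            assert model.variance_proportions[c] == pytest.approx(w[c] / 6, abs=1e-8)
            col = v[:, c] * np.sign(v[qio.DEQ_ITEMS.index(19), c] or 1.0)
            assert np.abs(model.loadings[:, c] - col).max() < 1e-8

    def test_isotropic_data_spreads_variance_evenly(self):
        rng = np.random.default_rng(1)
        model = ft.fit_deq_pca(rng.normal(size=(100_000, 6)))
        assert np.all(np.abs(model.variance_proportions - 1 / 6) < 0.01)

    def test_two_perfect_blocks_explain_everything(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(200, 1)), rng.normal(size=(200, 1))
        X = np.hstack([a, a, a, b, b, b])
        model = ft.fit_deq_pca(X)
        assert model.variance_proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_rejected(self):
        X = np.ones((30, 6))
        with pytest.raises(ft.DegenerateInputError):
            ft.fit_deq_pca(X)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ft.DegenerateInputError):
            ft.fit_deq_pca(np.random.default_rng(0).normal(size=(5, 6)))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariants_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 6)) + rng.normal(size=(1, 6))
        model = ft.fit_deq_pca(X)
        for c in range(2):
            assert np.linalg.norm(model.loadings[:, c]) == pytest.approx(1.0, abs=1e-9)
        assert abs(model.loadings[:, 0] @ model.loadings[:, 1]) < 1e-10
        vp = model.variance_proportions
        assert vp[0] >= vp[1] - 1e-12 and 0 < vp[1] and vp[0] <= 1
        assert model.loadings[qio.DEQ_ITEMS.index(19), 0] >= 0
        assert model.loadings[qio.DEQ_ITEMS.index(19), 1] >= 0


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(500, 6)) @ rng.normal(size=(6, 6))
    return ft.fit_deq_pca(X), X


class TestProjection:

    def test_training_mean_projects_to_origin(self, model):
        m, X = model
        items = dict(zip(m.item_order, m.means))
        # bypass range check by projecting manually through the linear map
        z = (np.array([items[i] for i in m.item_order]) - m.means) / m.sds
        assert np.allclose(z @ m.loadings, 0)

    def test_score_variance_equals_eigenvalue(self, model):
        m, X = model
        Z = (X - m.means) / m.sds
        scores = Z @ m.loadings
        for c in range(2):
            ev = m.variance_proportions[c] * 6
            assert scores[:, c].var(ddof=1) == pytest.approx(ev, abs=1e-8)

    def test_shift_in_item19_moves_both_scores_up(self, model):
        m, _ = model
        base = {i: 4 for i in m.item_order}
        s = ft.project_deq(m, base)
        idx = m.item_order.index(19)
        shifted = dict(base)
        shifted[19] = 5
        s2 = ft.project_deq(m, shifted)
        expected = m.loadings[idx] / m.sds[idx]
        assert s2[0] - s[0] == pytest.approx(expected[0])
        assert s2[1] - s[1] == pytest.approx(expected[1])
        assert s2[0] >= s[0] and s2[1] >= s[1]  # sign convention


class TestQuadrant:
    @pytest.mark.parametrize("s1,s2,code", [
        (-0.5, 1.2, "01"), (0.0, 0.0, "11"), (1.0, -1.0, "10"), (-2.0, -0.1, "00"),
    ])
    def test_assignment(self, s1, s2, code):
        assert ft.assign_quadrant(s1, s2) == code

    def test_partition_of_the_plane(self):
        rng = np.random.default_rng(4)
        for s1, s2 in rng.normal(size=(200, 2)):
            codes = [ft.assign_quadrant(s1, s2)]
            assert len(codes) == 1 and codes[0] in ft.QUADRANTS

    def test_symmetric_scores_fill_quadrants_evenly(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=(100_000, 2))
        codes = np.array([f"{int(a >= 0)}{int(b >= 0)}" for a, b in s])
        for q in ft.QUADRANTS:
            assert abs((codes == q).mean() - 0.25) < 0.01

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            ft.assign_quadrant(np.nan, 0.0)


class TestDiscretizer:
    def test_uniform_values_split_evenly(self):
        values = np.arange(1, 101, dtype=float)
        edges = ft.fit_discretizer(values, 4)
        levels = ft.apply_discretizer(edges, values)
        assert np.bincount(levels)[1:].tolist() == [25, 25, 25, 25]

    def test_clamping_below_and_above(self):
        edges = ft.fit_discretizer(np.arange(10.0), 3)
        assert ft.apply_discretizer(edges, -100.0) == 1
        assert ft.apply_discretizer(edges, 100.0) == 3

    def test_counts_near_equal_up_to_ties(self):
        rng = np.random.default_rng(6)
        values = np.round(rng.normal(size=300), 1)   # induces ties
        edges = ft.fit_discretizer(values, 3)
        levels = ft.apply_discretizer(edges, values)
        # oracle: rank-based thirds
        ranks = np.argsort(np.argsort(values, kind="stable"), kind="stable")
        for lvl in (1, 2, 3):
            ties = np.sum(np.isin(values, edges))
            assert abs((levels == lvl).sum() - 100) <= ties

    def test_monotone(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=100)
        edges = ft.fit_discretizer(values, 4)
        a, b = np.sort(rng.normal(size=2))
        assert ft.apply_discretizer(edges, a) <= ft.apply_discretizer(edges, b)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ft.DegenerateInputError):
            ft.fit_discretizer([1.0, 1.0, 2.0], 3)


class TestFeatureTable:
    def test_single_record_quadrant_consistent(self, small_cohort):
        transforms = ft.fit_transforms(small_cohort.records)
        table = ft.build_feature_table(small_cohort.records[:1], transforms)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.deq_quadrant == ft.assign_quadrant(row.pc1_score, row.pc2_score)

    def test_deterministic(self, small_cohort):
        transforms = ft.fit_transforms(small_cohort.records)
        t1 = ft.build_feature_table(small_cohort.records, transforms)
        t2 = ft.build_feature_table(small_cohort.records, transforms)
        assert t1.equals(t2)

    def test_quadrant_shares_near_uniform_on_default_cohort(self):
        cohort = sd.generate_cohort(sd.GeneratorConfig(n=650, seed=11))
        transforms = ft.fit_transforms(cohort.records)
        table = ft.build_feature_table(cohort.records, transforms)
        shares = table.deq_quadrant.value_counts(normalize=True)
        for q in ft.QUADRANTS:
            assert 0.22 <= shares[q] <= 0.28

    def test_transforms_serialize_round_trip(self, small_cohort, tmp_path):
        transforms = ft.fit_transforms(small_cohort.records)
        path = tmp_path / "transforms.json"
        transforms.to_json(path)
        back = ft.FeatureTransforms.from_json(path)
        t1 = ft.build_feature_table(small_cohort.records, transforms)
        t2 = ft.build_feature_table(small_cohort.records, back)
        assert t1.equals(t2)
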