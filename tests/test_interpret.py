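"""Interpretation: permutation importance, clustering ARS, mutation scans."""

import itertools

import numpy as np
import pytest

import rnagrid as rg
from rnagrid.model import cross_entropy

from conftest import random_rna

TINY = dict(block1_filters=2, block2_filters=4)


def _train_on_images(xd, xg, y, epochs=25, lr=3e-3, seed=0, **kw):
    cfg = rg.ModelConfig(seed=seed, epochs=epochs, learning_rate=lr,
                         batch_size=16, **kw)
    model = rg.DualPathModel(cfg, xd.shape[1:], xg.shape[1:])
    model.train(xd, xg, y)
    return model


class TestPermutationImportance:
    def test_structurally_zero_cell_has_exactly_zero_is(self, templates,
                                                        rendered, rng):
        tpl_d, tpl_g = templates
        xd, xg, y = rendered
        model = _train_on_images(xd, xg, y, epochs=2, **TINY)
        # pick features whose cells are constant across the corpus and a few
        # that are not
        constant, varying = [], []
        for name, (r, c) in tpl_d.placement.items():
            ch = tpl_d.subgroups.index(tpl_d.subgroup_of[name])
            col = xd[:, r, c, ch]
            (constant if np.all(col == col[0]) else varying).append(name)
        assert constant, "expected at least one constant cell"
        subset = constant[:3] + varying[:3]
        report = rg.permutation_importance(
            model, xd, xg, y, tpl_d, tpl_g, n_permutations=3, seed=0,
            features=subset)
        tab = report.table.set_index("name")
        for name in constant[:3]:
            assert tab.loc[name, "is"] == 0.0
        assert report.ocel == pytest.approx(
            cross_entropy(model.predict_proba(xd, xg), y))

    def test_deterministic_given_seed(self, templates, rendered):
        tpl_d, tpl_g = templates
        xd, xg, y = rendered
        model = _train_on_images(xd, xg, y, epochs=2, **TINY)
        subset = list(tpl_d.placement)[:10]
        a = rg.permutation_importance(model, xd, xg, y, tpl_d, tpl_g,
                                      n_permutations=2, seed=3,
                                      features=subset)
        b = rg.permutation_importance(model, xd, xg, y, tpl_d, tpl_g,
                                      n_permutations=2, seed=3,
                                      features=subset)
        np.testing.assert_array_equal(a.table["is"], b.table["is"])

    def test_unknown_feature_rejected(self, templates, rendered):
        tpl_d, tpl_g = templates
        xd, xg, y = rendered
        model = _train_on_images(xd, xg, y, epochs=1, **TINY)
        with pytest.raises(KeyError, match="bogus"):
            rg.permutation_importance(model, xd, xg, y, tpl_d, tpl_g,
                                      features=["bogus"])

    def test_ranking_is_permutation_of_features(self, templates, rendered):
        tpl_d, tpl_g = templates
        xd, xg, y = rendered
        model = _train_on_images(xd, xg, y, epochs=1, **TINY)
        subset = list(tpl_d.placement)[:8] + list(tpl_g.placement)[:8]
        rep = rg.permutation_importance(model, xd, xg, y, tpl_d, tpl_g,
                                        n_permutations=1, seed=0,
                                        features=subset)
        assert sorted(rep.ranking) == sorted(subset)

    def test_null_model_has_near_zero_mean_is(self, templates, rendered, rng):
        """After training on shuffled labels, importance is noise around 0."""
        tpl_d, tpl_g = templates
        xd, xg, y = rendered
        y_shuf = rng.permutation(y)
        while len(np.unique(y_shuf)) < 2:  # pragma: no cover
            y_shuf = rng.permutation(y)
        model = _train_on_images(xd, xg, y_shuf, epochs=2, **TINY)
        subset = list(tpl_d.placement)[:40] + list(tpl_g.placement)[:40]
        rep = rg.permutation_importance(model, xd, xg, y_shuf, tpl_d, tpl_g,
                                        n_permutations=3, seed=1,
                                        features=subset)
        assert abs(rep.table["is"].mean()) < 0.05


class TestTopNArs:
    def test_label_identical_clustering_scores_one(self):
        y = np.array([0] * 10 + [1] * 10)
        feats = np.column_stack([y * 10.0, np.zeros(20)])
        names = ["sig", "null"]
        ars = rg.top_n_ars(feats, y, ["sig"], names, 1)
        assert ars == 1.0

    def test_random_features_score_near_zero(self, rng):
        y = np.array([0, 1] * 30)
        feats = rng.normal(size=(60, 5))
        names = [f"f{i}" for i in range(5)]
        ars = rg.top_n_ars(feats, y, names, names, 5)
        assert abs(ars) < 0.25

    def test_matches_contingency_closed_form(self):
        """6-point, 2-cluster instance checked against the ARI formula."""
        y = np.array([0, 0, 0, 1, 1, 1])
        # two tight clusters; ward recovers them but point 3 is mislabelled
        feats = np.array([[0.0], [0.1], [0.2], [0.15], [5.0], [5.1]])
        ars = rg.top_n_ars(feats, y, ["f"], ["f"], 1)
        # clustering = [A,A,A,A,B,B]; closed-form ARI from the contingency
        # table [[3,0],[1,2]] computed by hand:
        n = 6
        sum_comb_cells = 3 + 0 + 0 + 1          # C(3,2)+C(1,2)+C(2,2)
        a = [4, 2]                               # cluster sizes
        b = [3, 3]                               # class sizes
        comb = lambda m: m * (m - 1) // 2
        sum_a = sum(comb(v) for v in a)
        sum_b = sum(comb(v) for v in b)
        expected_index = sum_a * sum_b / comb(n)
        max_index = (sum_a + sum_b) / 2
        ari = (sum_comb_cells - expected_index) / (max_index - expected_index)
        assert ars == pytest.approx(ari, abs=1e-12)

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            rg.top_n_ars(np.zeros((4, 2)), np.array([0, 0, 1, 1]),
                         ["a", "b"], ["a", "b"], 3)


class TestMutationScan:
    @staticmethod
    def constant_scorer(value=0.7):
        return lambda seqs: np.full(len(seqs), value)

    @staticmethod
    def hash_scorer(seqs):
        """Deterministic pseudo-random score per sequence string."""
        import zlib
        return np.array([(zlib.crc32(s.residues.encode()) % 1000) / 1000
                         for s in seqs])

    def test_nine_mutants_per_pair(self, rng):
        seq = random_rna(rng, 60)
        res = rg.scan_pair(seq, self.hash_scorer, 5, 20)
        assert len(res.mutant_scores) == 9
        muts = rg.interpret._mutants(seq, 5, 20)
        assert len({m.residues for m in muts}) == 9
        for m in muts:
            assert m.residues[4] != seq.residues[4]
            assert m.residues[19] != seq.residues[19]

    def test_constant_model_gives_zero_contribution(self, rng):
        seq = random_rna(rng, 80)
        pairs = rg.enumerate_window_pairs(seq.length, 1, 6)
        results = rg.pairwise_mutation_scan(seq, self.constant_scorer(), pairs)
        assert all(r.c_pair == 0.0 for r in results)

    def test_mean_within_mutant_bounds(self, rng):
        seq = random_rna(rng, 50)
        for i, j in [(1, 2), (3, 40), (10, 50)]:
            r = rg.scan_pair(seq, self.hash_scorer, i, j)
            assert r.mutant_scores.min() <= r.p_mutated <= r.mutant_scores.max()
            assert r.c_pair == pytest.approx(r.p_original - r.p_mutated)

    def test_scan_symmetry(self, rng):
        seq = random_rna(rng, 40)
        a = rg.scan_pair(seq, self.hash_scorer, 7, 21)
        b = rg.scan_pair(seq, self.hash_scorer, 21, 7)
        assert a.p_mutated == pytest.approx(b.p_mutated, abs=1e-15)
        assert a.c_pair == pytest.approx(b.c_pair, abs=1e-15)

    def test_gap_feature_pair_semantics(self):
        # 37-GC: positions (2, 40) have 40 - 2 - 1 = 37 intervening bases
        residues = list("A" * 60)
        residues[1] = "G"    # position 2, 1-based
        residues[39] = "C"   # position 40
        seq = rg.RnaSequence("s", "".join(residues))
        assert rg.enumerate_gfeature_pairs(seq, "37-GC") == [(2, 40)]

    def test_window_and_position_validation(self, rng):
        seq = random_rna(rng, 30)
        with pytest.raises(ValueError):
            rg.enumerate_window_pairs(seq.length, 5, 5)
        with pytest.raises(ValueError):
            rg.enumerate_window_pairs(seq.length, 0, 10)
        with pytest.raises(ValueError):
            rg.scan_pair(seq, self.hash_scorer, 1, 31)

    def test_contribution_matrix_symmetry(self, rng):
        seq = random_rna(rng, 20)
        pairs = list(itertools.combinations(range(1, 6), 2))
        results = rg.pairwise_mutation_scan(seq, self.hash_scorer, pairs)
        mat = rg.contribution_matrix(results, seq.length)
        filled = ~np.isnan(mat)
        np.testing.assert_array_equal(filled, filled.T)
        np.testing.assert_allclose(mat[filled], mat.T[filled])

    def test_end_to_end_scorer_cps(self, templates, rendered, small_corpus):
        tpl_d, tpl_g = templates
        xd, xg, y = rendered
        model = _train_on_images(xd, xg, y, epochs=2, **TINY)
        scorer = rg.SequenceScorer(model, tpl_d, tpl_g, positive_class=0)
        seq = small_corpus.sequences[0]
        cps = scorer([seq])
        proba = model.predict_proba(xd[:1], xg[:1])
        assert cps[0] == pytest.approx(proba[0, 0], abs=1e-6)
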