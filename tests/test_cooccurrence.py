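"""Dice/Spearman co-occurrence, random-group nulls, pathway similarity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from microtensor import LongitudinalTensor, call_modules
from microtensor.cooccurrence import (
    dice_index,
    functional_similarity,
    intramodule_score,
    pairwise_cooccurrence,
    random_group_null,
    read_pathway_contributions,
    top_pathways,
)


class TestDice:
    def test_identical_disjoint_and_partial_supports(self):
        assert dice_index([1, 2, 3, 0], [4, 5, 6, 0]) == 1.0
        assert dice_index([1, 0, 0], [0, 2, 3]) == 0.0
        # supports {0,1,2} vs {1,2,3}: 2*2/(3+3)
        assert dice_index([1, 1, 1, 0], [0, 1, 1, 1]) == pytest.approx(2 / 3)

    def test_both_empty_defined_as_zero(self):
        assert dice_index([0, 0], [0, 0]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_index([1], [1, 2])


def _toy_tensor():
    rng = np.random.default_rng(7)
    data = np.abs(rng.standard_normal((2, 4, 3)))
    data[data < 0.4] = 0.0
    return LongitudinalTensor(data)


class TestPairwise:
    def test_matrix_matches_double_loop_oracle(self):
        t = _toy_tensor()
        pm = pairwise_cooccurrence(t, "dice", "per_subject_mean")
        L = t.n_taxa
        for i in range(L):
            for j in range(L):
                vals = [
                    dice_index(t.data[n, i, :], t.data[n, j, :])
                    for n in range(t.n_subjects)
                ]
                assert pm.values[i, j] == pytest.approx(np.mean(vals))

    def test_across_samples_matches_flattened_oracle(self):
        t = _toy_tensor()
        pm = pairwise_cooccurrence(t, "abs_spearman", "across_samples")
        flat = t.data.transpose(1, 0, 2).reshape(t.n_taxa, -1)
        for i in range(t.n_taxa):
            for j in range(i + 1, t.n_taxa):
                if np.ptp(flat[i]) == 0 or np.ptp(flat[j]) == 0:
                    assert np.isnan(pm.values[i, j])
                else:
                    rho = abs(spearmanr(flat[i], flat[j]).statistic)
                    assert pm.values[i, j] == pytest.approx(rho)

    def test_self_pairs_are_unity(self):
        t = _toy_tensor()
        dm = pairwise_cooccurrence(t, "dice", "across_samples")
        sm = pairwise_cooccurrence(t, "abs_spearman", "across_samples")
        np.testing.assert_allclose(np.diag(dm.values), 1.0)
        nonconst = np.ptp(t.data.transpose(1, 0, 2).reshape(t.n_taxa, -1), axis=1) > 0
        np.testing.assert_allclose(np.diag(sm.values)[nonconst], 1.0)

    def test_identical_subjects_collapse_to_single_subject_statistic(self):
        one = np.abs(np.random.default_rng(3).standard_normal((1, 5, 4)))
        rep = LongitudinalTensor(np.repeat(one, 3, axis=0))
        single = pairwise_cooccurrence(LongitudinalTensor(one), "dice", "per_subject_mean")
        mean = pairwise_cooccurrence(rep, "dice", "per_subject_mean")
        np.testing.assert_allclose(mean.values, single.values)

    def test_across_samples_invariant_to_subject_order(self):
        t = _toy_tensor()
        perm = LongitudinalTensor(t.data[::-1].copy())
        a = pairwise_cooccurrence(t, "dice", "across_samples").values
        b = pairwise_cooccurrence(perm, "dice", "across_samples").values
        np.testing.assert_allclose(a, b)

    def test_symmetry_and_range(self):
        t = _toy_tensor()
        for stat in ("dice", "abs_spearman"):
            v = pairwise_cooccurrence(t, stat, "across_samples").values
            np.testing.assert_allclose(v, v.T, equal_nan=True)
            ok = np.isfinite(v)
            assert (v[ok] >= 0).all() and (v[ok] <= 1).all()


class _Group:
    def __init__(self, index, members):
        self.index = index
        self.member_indices = np.asarray(members)


class TestIntramodule:
    def test_pair_mean_matches_hand_average(self):
        pm = pairwise_cooccurrence(_toy_tensor(), "dice", "across_samples")
        mod = _Group(0, [0, 1, 2])
        out = intramodule_score([mod], pm)
        hand = np.mean([pm.values[0, 1], pm.values[0, 2], pm.values[1, 2]])
        assert out.loc[0, "score"] == pytest.approx(hand)

    def test_two_member_module_is_single_pair(self):
        pm = pairwise_cooccurrence(_toy_tensor(), "dice", "across_samples")
        out = intramodule_score([_Group(0, [1, 3])], pm)
        assert out.loc[0, "score"] == pytest.approx(pm.values[1, 3])

    def test_singletons_skipped(self):
        pm = pairwise_cooccurrence(_toy_tensor(), "dice", "across_samples")
        assert intramodule_score([_Group(0, [2])], pm).empty

    def test_mutually_exclusive_taxa_score_zero(self):
        data = np.zeros((1, 3, 4))
        data[0, 0, :2] = 1.0
        data[0, 1, 2:] = 1.0
        data[0, 2, :] = 0.0
        pm = pairwise_cooccurrence(LongitudinalTensor(data), "dice", "across_samples")
        out = intramodule_score([_Group(0, [0, 1])], pm)
        assert out.loc[0, "score"] == 0.0


class TestRandomGroupNull:
    def test_cohesive_modules_beat_structureless_null(self, planted, planted_fit):
        tensor, _ = planted
        mods = call_modules(planted_fit)
        pm = pairwise_cooccurrence(tensor, "abs_spearman", "per_subject_mean")
        mod_scores, null_scores, p = random_group_null(mods, pm, n_groups=60, seed=0)
        assert p <= 0.01
        assert np.nanmean(mod_scores) > np.nanmean(null_scores)

    def test_null_mean_consistent_with_eligible_pairs(self, planted, planted_fit):
        tensor, _ = planted
        mods = call_modules(planted_fit)
        pm = pairwise_cooccurrence(tensor, "dice", "across_samples")
        _, null_scores, _ = random_group_null(mods, pm, n_groups=150, seed=1)
        # population mean over pairs not co-occurring in any module
        L = pm.values.shape[0]
        eligible = np.ones((L, L), bool)
        np.fill_diagonal(eligible, False)
        for m in mods:
            idx = m.member_indices
            eligible[np.ix_(idx, idx)] = False
        pop = pm.values[np.triu(eligible)]
        pop_mean = np.nanmean(pop)
        se = np.nanstd(null_scores) / np.sqrt(len(null_scores))
        assert abs(np.mean(null_scores) - pop_mean) <= max(4 * se, 0.05)

    def test_empty_module_set_rejected(self):
        pm = pairwise_cooccurrence(_toy_tensor(), "dice", "across_samples")
        with pytest.raises(ValueError, match="no modules"):
            random_group_null([], pm, n_groups=5, seed=0)


PATHWAY_TSV = """# Pathway\tS1\tS2
PWY1: one|taxonA\t4.0\t0.0
PWY1: one|taxonB\t2.0\t0.0
PWY2: two|taxonA\t0.0\t3.0
PWY2: two|taxonB\t0.0\t1.5
PWY2: two|taxonC\t5.0\t5.0
PWY1: one\t6.0\t0.0
"""


class TestFunctionalSimilarity:
    @pytest.fixture()
    def contrib(self, tmp_path):
        p = tmp_path / "pathways.tsv"
        p.write_text(PATHWAY_TSV)
        return read_pathway_contributions(p)

    def test_stratified_rows_parsed(self, contrib):
        assert set(contrib.index.get_level_values("taxon")) == {"taxonA", "taxonB", "taxonC"}
        # community-total (unstratified) row dropped
        assert len(contrib) == 5

    def test_proportional_profiles_are_identical(self, contrib):
        out = functional_similarity(contrib, [_NamedModule(0, ["taxonA", "taxonB"])])
        # A and B contribute to the same pathway in each sample -> cosine 1
        assert out.loc[0, "similarity"] == pytest.approx(1.0)

    def test_orthogonal_profiles_score_zero(self, tmp_path):
        p = tmp_path / "ortho.tsv"
        p.write_text(
            "# Pathway\tS1\nPWY1: x|taxonA\t2.0\nPWY2: y|taxonB\t3.0\n"
        )
        contrib = read_pathway_contributions(p)
        out = functional_similarity(contrib, [_NamedModule(0, ["taxonA", "taxonB"])])
        assert out.loc[0, "similarity"] == pytest.approx(0.0)

    def test_hand_cosine_average(self, contrib):
        out = functional_similarity(contrib, [_NamedModule(0, ["taxonA", "taxonC"])])
        # S1: A=(4,0), C=(0,5) -> 0 ; S2: A=(0,3), C=(0,5) -> 1
        assert out.loc[0, "similarity"] == pytest.approx(0.5)

    def test_absent_taxon_excluded_with_warning(self, contrib):
        with pytest.warns(UserWarning, match="absent"):
            out = functional_similarity(
                contrib, [_NamedModule(0, ["taxonA", "taxonB", "ghost"])]
            )
        assert out.loc[0, "n_members"] == 2

    def test_top_pathways_ranked_by_member_contribution(self, contrib):
        ranked = top_pathways(contrib, _NamedModule(0, ["taxonA", "taxonB"]), top_n=20)
        # PWY1 total from A+B = 6.0; PWY2 total = 4.5
        assert list(ranked.index) == ["PWY1: one", "PWY2: two"]
        assert ranked.iloc[0] == pytest.approx(6.0)
        # top_n larger than pathway count returns everything
        assert len(top_pathways(contrib, _NamedModule(0, ["taxonC"]), top_n=99)) == 1


class _NamedModule:
    def __init__(self, index, members):
        self.index = index
        self.members = members
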