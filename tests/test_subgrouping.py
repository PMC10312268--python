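import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from usemkit import model_search as ms
from usemkit import subgrouping as sg
from usemkit import synthetic_data as syn


def block_similarity(n=20, weight=5.0, n_blocks=2):
    W = np.zeros((n, n))
    size = n // n_blocks
    for b in range(n_blocks):
        sl = slice(b * size, (b + 1) * size)
        W[sl, sl] = weight
    np.fill_diagonal(W, 0.0)
    return sg.SimilarityMatrix(W, [f"s{i:02d}" for i in range(n)])


def random_similarity(n=20, seed=0, high=6):
    rng = np.random.default_rng(seed)
    W = np.triu(rng.integers(0, high, size=(n, n)).astype(float), 1)
    return sg.SimilarityMatrix(W + W.T, [f"s{i:02d}" for i in range(n)])


class TestBuildSimilarity:
    def test_identical_subjects_share_everything(self):
        """Two copies of the same data must agree on every significant MI
        and every group-path sign, so s_ij equals the count recomputed
        directly from one subject's MI table and estimates."""
        scen = syn.make_scenario(dict(n_subjects=1, n_endogenous=4,
                                      n_exogenous=0, n_timepoints=300,
                                      n_group_paths=2, n_individual_pool=0,
                                      beta_range=(0.5, 0.7), seed=41))
        cohort, _ = syn.simulate_cohort(scen)
        twin = syn.simulate_subject(scen, 0)
        twin.subject_id = "twin"
        both = [cohort[0], twin]
        group, models, datas, _ = ms.group_search(both, gamma=0.0)
        sim = sg.build_similarity(models, datas, group)
        from usemkit.usem_core import MI_CRITICAL_95, modification_indices
        sid = sorted(models)[0]
        mi = modification_indices(models[sid], datas[sid])
        k = int((mi.mi >= MI_CRITICAL_95).sum())
        zs = models[sid].z
        g = sum(1 for p in group
                if np.isfinite(zs.get(p, np.nan)) and abs(zs[p]) >= 1.96)
        assert sim.values[0, 1] == k + g

    def test_planted_subgroups_are_more_similar_within(self):
        scen = syn.make_scenario(dict(
            n_subjects=16, n_endogenous=5, n_exogenous=0, n_timepoints=250,
            n_group_paths=2, subgroup_defs=[(0.5, 2), (0.5, 2)],
            n_individual_pool=0, beta_range=(0.5, 0.7), seed=42))
        cohort, ledger = syn.simulate_cohort(scen)
        group, models, datas, _ = ms.group_search(cohort)
        sim = sg.build_similarity(models, datas, group)
        labels = ledger.membership.loc[sim.subject_ids].to_numpy()
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        within = sim.values[same].mean()
        between = sim.values[~same & ~np.eye(len(labels), dtype=bool)].mean()
        assert within > between


class TestWalktrap:
    def test_disconnected_blocks_recovered_exactly(self):
        sim = block_similarity(n=20, n_blocks=2)
        memb = sg.walktrap(sim)
        assert memb.nunique() == 2
        assert memb.iloc[:10].nunique() == 1
        assert memb.iloc[10:].nunique() == 1

    def test_subject_order_permutation_invariance(self):
        sim = block_similarity(n=18, n_blocks=3)
        rng = np.random.default_rng(3)
        perm = rng.permutation(18)
        permuted = sg.SimilarityMatrix(
            sim.values[np.ix_(perm, perm)],
            [sim.subject_ids[i] for i in perm])
        m1 = sg.walktrap(sim)
        m2 = sg.walktrap(permuted)
        aligned = m2.loc[m1.index]
        assert sg.ari(m1.to_numpy(), aligned.to_numpy()) == 1.0

    def test_all_zero_matrix_single_community_with_warning(self):
        sim = sg.SimilarityMatrix(np.zeros((5, 5)), list("abcde"))
        with pytest.warns(UserWarning, match="one community"):
            memb = sg.walktrap(sim)
        assert memb.nunique() == 1


class TestModularity:
    def test_two_equal_cliques_give_half(self):
        sim = block_similarity(n=16, n_blocks=2)
        labels = np.repeat([1, 2], 8)
        assert sg.modularity(sim, labels) == pytest.approx(0.5)

    def test_single_community_zero(self):
        sim = random_similarity(seed=1)
        assert sg.modularity(sim, np.ones(sim.n)) == pytest.approx(0.0)

    def test_matches_brute_force_double_sum(self):
        sim = random_similarity(n=20, seed=2)
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 3, sim.n)
        W = sim.values
        two_m = W.sum()
        k = W.sum(axis=1)
        q = 0.0
        for i in range(sim.n):
            for j in range(sim.n):
                if labels[i] == labels[j]:
                    q += W[i, j] - k[i] * k[j] / two_m
        q /= two_m
        assert sg.modularity(sim, labels) == pytest.approx(q, abs=1e-12)


class TestPerturbEdges:
    def test_fraction_zero_is_identity(self):
        sim = random_similarity(seed=5)
        out = sg.perturb_edges(sim, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, sim.values)

    @pytest.mark.parametrize("fraction", [0.2, 0.5, 1.0])
    def test_weight_multiset_conserved(self, fraction):
        sim = random_similarity(seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = sg.perturb_edges(sim, fraction, seed=2)
        iu = np.triu_indices(sim.n, 1)
        before = np.sort(sim.values[iu])
        after = np.sort(out.values[iu])
        np.testing.assert_array_equal(before, after)

    def test_full_rewire_changes_support(self):
        # sparse matrix with plenty of vacant pairs
        W = np.zeros((30, 30))
        rng = np.random.default_rng(7)
        idx = rng.choice(30 * 29 // 2, 40, replace=False)
        iu = np.triu_indices(30, 1)
        W[iu[0][idx], iu[1][idx]] = rng.integers(1, 5, 40)
        sim = sg.SimilarityMatrix(W + W.T, [f"s{i}" for i in range(30)])
        out = sg.perturb_edges(sim, 1.0, seed=3)
        assert (out.values != sim.values).any()


class TestPartitionMetrics:
    def test_identical_partitions(self):
        p = [1, 1, 2, 2, 3]
        assert sg.vi(p, p) == 0.0
        assert sg.ari(p, p) == 1.0

    def test_fully_crossed_partitions(self):
        p1, p2 = [1, 1, 2, 2], [1, 2, 1, 2]
        assert sg.vi(p1, p2) == pytest.approx(2 * np.log(2))
        assert sg.ari(p1, p2) <= 0.0

    def test_vi_matches_contingency_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            p1 = rng.integers(0, 4, 50)
            p2 = rng.integers(0, 3, 50)
            # direct plug-in computation from the contingency table
            C = np.zeros((4, 3))
            for a, b in zip(p1, p2):
                C[a, b] += 1
            P = C / 50
            pi, pj = P.sum(1), P.sum(0)
            h1 = -sum(x * np.log(x) for x in pi if x > 0)
            h2 = -sum(x * np.log(x) for x in pj if x > 0)
            i_ab = sum(P[a, b] * np.log(P[a, b] / (pi[a] * pj[b]))
                       for a in range(4) for b in range(3) if P[a, b] > 0)
            assert sg.vi(p1, p2) == pytest.approx(h1 + h2 - 2 * i_ab)

    def test_ari_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(9)
        p1 = rng.integers(0, 3, 40)
        p2 = rng.integers(0, 4, 40)
        # brute-force over all pairs
        from math import comb
        n = len(p1)
        a = b = c = d = 0
        for i in range(n):
            for j in range(i + 1, n):
                s1 = p1[i] == p1[j]
                s2 = p2[i] == p2[j]
                a += s1 and s2
                b += s1 and not s2
                c += (not s1) and s2
                d += not s1 and not s2
        total = comb(n, 2)
        expected_index = (a + b) * (a + c) / total
        max_index = ((a + b) + (a + c)) / 2
        ari_oracle = (a - expected_index) / (max_index - expected_index)
        assert sg.ari(p1, p2) == pytest.approx(ari_oracle, abs=1e-12)

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_ari_label_invariance(self, labels):
        relabeled = [(x + 1) % 4 for x in labels]
        assert sg.ari(labels, relabeled) == pytest.approx(1.0)
        assert sg.vi(labels, relabeled) == pytest.approx(0.0, abs=1e-12)


class TestNullModularity:
    def test_deterministic_under_seed(self):
        sim = random_similarity(seed=10)
        q1 = sg.random_null_modularity(sim, n_draws=25, seed=5)
        q2 = sg.random_null_modularity(sim, n_draws=25, seed=5)
        np.testing.assert_array_equal(q1, q2)

    def test_modular_matrix_beats_null(self):
        sim = block_similarity(n=30, n_blocks=3)
        memb = sg.walktrap(sim)
        q_obs = sg.modularity(sim, memb.to_numpy())
        nulls = sg.random_null_modularity(sim, n_draws=50, seed=6)
        assert q_obs > np.percentile(nulls, 95)


class TestRobustnessReport:
    def test_block_matrix_is_stable_and_modular(self):
        sim = block_similarity(n=24, n_blocks=2)
        memb = sg.walktrap(sim)
        sol = sg.robustness_report(sim, memb, reps=10, seed=7, n_null=30)
        assert sol.stability_pass
        assert sol.modularity_pass
        assert sol.modularity_q == pytest.approx(0.5)

    def test_uniform_random_matrix_fails_modularity(self):
        sim = random_similarity(n=30, seed=11)
        memb = sg.walktrap(sim)
        sol = sg.robustness_report(sim, memb, reps=10, seed=8, n_null=30)
        assert not sol.modularity_pass

    def test_vi_curve_roughly_monotone(self):
        sim = block_similarity(n=24, n_blocks=2)
        memb = sg.walktrap(sim)
        sol = sg.robustness_report(sim, memb, reps=10, seed=9, n_null=30)
        curve = sol.vi_curve.to_numpy()
        # rising on average: heavy perturbation disturbs the solution more
        # (the far tail can dip when the rewired graph collapses to one
        # community, so compare halves rather than successive steps)
        half = len(curve) // 2
        assert curve[half:].mean() >= curve[:half].mean()
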