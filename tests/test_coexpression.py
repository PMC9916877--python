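"""Soft threshold, TOM, module detection, eigengenes, hubs, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import rand_score

from circheterosis import coexpression, synthetic
from circheterosis.design import default_design


def _brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Element-by-element evaluation of the TOM formula (independent oracle)."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    n = a.shape[0]
    tom = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTom:
    def test_matches_brute_force_to_1e10(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(20, 12)),
                            index=[f"f{i}" for i in range(20)])
        tom = coexpression.build_tom(expr, beta=6)
        adj = coexpression.adjacency_matrix(expr, 6).to_numpy()
        expected = _brute_force_tom(adj)
        assert np.abs(tom.to_numpy() - expected).max() < 1e-10
        assert np.allclose(tom, tom.T)
        assert tom.to_numpy().min() >= 0 and tom.to_numpy().max() <= 1

    def test_identical_profiles_tom_one(self):
        v = np.arange(10, dtype=float)
        expr = pd.DataFrame([v, v], index=["a", "b"])
        tom = coexpression.build_tom(expr, beta=6)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_orthogonal_profiles_tom_zero(self):
        expr = pd.DataFrame(
            [[1, -1, 1, -1, 1, -1, 1, -1], [1, 1, -1, -1, 1, 1, -1, -1]],
            index=["a", "b"], dtype=float,
        )
        tom = coexpression.build_tom(expr, beta=6)
        assert tom.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_feature_dropped(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [2, 4, 6, 8], [5, 5, 5, 5]], index=["a", "b", "const"]
        )
        with pytest.warns(UserWarning):
            tom = coexpression.build_tom(expr, beta=2)
        assert "const" not in tom.index


class TestPickBeta:
    def test_r2_target_zero_returns_smallest_power(self):
        mat, _ = synthetic.generate_module_matrix(seed=3)
        assert coexpression.pick_beta(mat, r2_target=0.0) == 1

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            coexpression.pick_beta(expr)

    def test_module_partition_stable_across_reasonable_betas(self):
        """On a strongly block-structured matrix the partition is the same for
        the picked beta and the default 6."""
        mat, labels = synthetic.generate_module_matrix(seed=13, noise_sd=0.1)
        beta = coexpression.pick_beta(mat)
        part_picked = coexpression.detect_modules(coexpression.build_tom(mat, beta))
        part_default = coexpression.detect_modules(coexpression.build_tom(mat, 6))
        assert rand_score(part_picked.values, part_default.values) == pytest.approx(1.0)


class TestDetectModules:
    def test_planted_three_block_partition_recovered(self):
        mat, labels = synthetic.generate_module_matrix(n_blocks=3, block_size=30,
                                                       noise_sd=0.1, seed=2)
        tom = coexpression.build_tom(mat, 6)
        assignments = coexpression.detect_modules(tom, min_module_size=5)
        assert rand_score(labels.values, assignments.values) >= 0.95

    def test_min_module_size_larger_than_n_gives_all_grey(self):
        mat, _ = synthetic.generate_module_matrix(n_blocks=1, block_size=10, seed=4)
        tom = coexpression.build_tom(mat, 6)
        with pytest.warns(UserWarning):
            assignments = coexpression.detect_modules(tom, min_module_size=11)
        assert (assignments == coexpression.GREY).all()

    def test_permutation_invariance_up_to_labels(self):
        mat, _ = synthetic.generate_module_matrix(seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(mat))
        a1 = coexpression.detect_modules(coexpression.build_tom(mat, 6))
        a2 = coexpression.detect_modules(coexpression.build_tom(mat.iloc[perm], 6))
        assert rand_score(a1.reindex(a2.index).values, a2.values) == pytest.approx(1.0)


class TestEigengenesAndTraits:
    def test_eigengene_unit_norm_and_orientation(self):
        mat, _ = synthetic.generate_module_matrix(seed=8)
        asg = coexpression.detect_modules(coexpression.build_tom(mat, 6))
        eig = coexpression.module_eigengenes(mat, asg)
        for module in eig.index:
            e = eig.loc[module].to_numpy()
            assert np.linalg.norm(e) == pytest.approx(1.0)
            feats = asg.index[asg == module]
            cors = [np.corrcoef(mat.loc[f], e)[0, 1] for f in feats]
            assert np.mean(cors) > 0

    def test_eigengene_explains_most_variance(self):
        mat, _ = synthetic.generate_module_matrix(n_blocks=1, block_size=20, seed=9)
        asg = pd.Series("turquoise", index=mat.index)
        eig = coexpression.module_eigengenes(mat, asg).loc["turquoise"].to_numpy()
        z = ((mat.T - mat.mean(axis=1)) / mat.std(axis=1)).T.to_numpy()
        explained = np.sum((z @ eig) ** 2)
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.normal(size=len(eig))
            d /= np.linalg.norm(d)
            assert explained >= np.sum((z @ d) ** 2) - 1e-9

    def test_planted_trait_coupled_module_has_top_correlation(self):
        """A module high only in F1_high samples correlates most with that group."""
        design = default_design(seed=1)
        high = [s for gt in design.genotypes_of_role("F1_high") for s in design.samples_of(gt)]
        rng = np.random.default_rng(12)
        rows = []
        for _ in range(20):
            v = rng.normal(0, 0.1, len(design.sample_ids))
            v[[design.sample_ids.index(s) for s in high]] += 3.0
            rows.append(v)
        for _ in range(20):
            rows.append(rng.normal(0, 1.0, len(design.sample_ids)))
        mat = pd.DataFrame(rows, columns=design.sample_ids,
                           index=[f"f{i}" for i in range(40)])
        asg = pd.Series(["pink"] * 20 + [coexpression.GREY] * 20, index=mat.index)
        eig = coexpression.module_eigengenes(mat, asg)
        r, p = coexpression.module_trait(eig, design, encoding="role")
        assert r.loc["pink"].idxmax() == "F1_high"
        assert r.loc["pink", "F1_high"] > 0.9


class TestSelectHubs:
    def test_most_connected_feature_ranks_first(self):
        rng = np.random.default_rng(21)
        latent = rng.normal(size=12)
        rows = [latent]  # hub: nearly identical to the shared signal
        for _ in range(29):
            rows.append(latent + rng.normal(0, 0.8, 12))
        mat = pd.DataFrame(rows, index=[f"f{i}" for i in range(30)])
        asg = pd.Series("blue", index=mat.index)
        hubs = coexpression.select_hubs(mat, asg, "blue", k=5)
        assert hubs["feature"].iloc[0] == "f0"

    def test_k_zero_empty_and_small_module_warns(self):
        mat, _ = synthetic.generate_module_matrix(n_blocks=1, block_size=10, seed=14)
        asg = pd.Series("red", index=mat.index)
        assert coexpression.select_hubs(mat, asg, "red", k=0).empty
        with pytest.warns(UserWarning):
            hubs = coexpression.select_hubs(mat, asg, "red", k=25)
        assert len(hubs) == 10

    def test_hub_set_stable_under_outside_noise(self):
        mat, _ = synthetic.generate_module_matrix(n_blocks=1, block_size=15, seed=15)
        asg = pd.Series("green", index=mat.index)
        hubs_before = coexpression.select_hubs(mat, asg, "green", k=5)["feature"].tolist()
        rng = np.random.default_rng(16)
        noise = pd.DataFrame(rng.normal(size=(20, mat.shape[1])), columns=mat.columns,
                             index=[f"noise{i}" for i in range(20)])
        big = pd.concat([mat, noise])
        asg_big = pd.concat([asg, pd.Series(coexpression.GREY, index=noise.index)])
        hubs_after = coexpression.select_hubs(big, asg_big, "green", k=5)["feature"].tolist()
        assert hubs_before == hubs_after


class TestEnrichment:
    def test_matches_closed_form_hypergeometric_sum(self):
        universe = {f"f{i}" for i in range(40)}
        term = {f"f{i}" for i in range(8)}
        feature_set = {f"f{i}" for i in range(10)}
        out = coexpression.enrich_hypergeometric(feature_set, {"T": term}, universe)
        x = len(term & feature_set)
        M, K, N = 40, 8, 10
        p_closed = sum(
            math.comb(K, i) * math.comb(M - K, N - i) / math.comb(M, N)
            for i in range(x, min(K, N) + 1)
        )
        assert out["p"].iloc[0] == pytest.approx(p_closed, abs=1e-12)

    def test_disjoint_set_p_one(self):
        universe = {f"f{i}" for i in range(20)}
        out = coexpression.enrich_hypergeometric(
            {"f0", "f1"}, {"T": {"f10", "f11"}}, universe
        )
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_universe_equals_set_saturates(self):
        universe = {f"f{i}" for i in range(10)}
        out = coexpression.enrich_hypergeometric(
            universe, {"T": {"f0", "f1", "f2"}}, universe
        )
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_term_absent_from_universe_skipped(self):
        out = coexpression.enrich_hypergeometric(
            {"f0"}, {"T": {"zzz"}}, {"f0", "f1"}
        )
        assert out.empty

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            coexpression.enrich_hypergeometric({"x"}, {}, {"f0"})


def test_module_size_summary_bookkeeping():
    asg = pd.Series(["blue"] * 10 + ["pink"] * 6 + [coexpression.GREY] * 3)
    out = coexpression.module_size_summary(asg)
    assert out == {"n_modules": 2, "n_assigned": 16, "mean_per_module": 8.0}
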