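"""Network construction, TOM, dynamic module detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from strisk import synthetic
from strisk.coexpression import (
    NetworkConfig,
    compute_eigengenes,
    detect_modules,
    filter_and_qc,
    pick_soft_power,
    signed_adjacency,
    tom_dissimilarity,
)

from conftest import make_tensor


def brute_force_tom_diss(A: np.ndarray) -> np.ndarray:
    """Per-entry formula evaluation with explicit loops (oracle)."""
    n = A.shape[0]
    k = A.sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            tom = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
            out[i, j] = 1 - tom
    return out


def random_adjacency(rng, n):
    A = rng.uniform(0, 1, size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


class TestFilterQc:
    def test_row_sum_boundary(self):
        t = make_tensor(np.array([[9.9 / 3] * 3, [10.0 / 3] * 3]))
        out = filter_and_qc(t, NetworkConfig(min_total_expression=10.0))
        assert list(out.values.index) == ["G1"]

    def test_zero_threshold_is_identity_on_nonnegative_data(self, rng):
        t = make_tensor(rng.uniform(0, 5, size=(10, 4)))
        out = filter_and_qc(t, NetworkConfig(min_total_expression=0.0))
        assert out.n_genes == 10

    def test_all_filtered_is_error(self):
        t = make_tensor(np.ones((3, 3)))
        with pytest.raises(ValueError):
            filter_and_qc(t, NetworkConfig(min_total_expression=1e6))

    def test_scaled_outlier_sample_is_cut(self, rng):
        X = np.tile(rng.uniform(1, 2, size=(20, 1)), (1, 6))
        X += rng.normal(0, 0.01, X.shape)
        X[:, 5] *= 1000  # one wildly scaled sample
        t = make_tensor(np.abs(X))
        out = filter_and_qc(t, NetworkConfig(min_total_expression=0.0,
                                             sample_cut_height=100.0))
        assert out.n_samples == 5
        assert "S5" not in out.values.columns


class TestAdjacencyAndPower:
    def test_power_one_is_half_shifted_correlation(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 1.0, 4.0, 3.0],
                      [4.0, 3.0, 2.0, 1.0]])
        t = make_tensor(X)
        A = signed_adjacency(t, power=1).to_numpy()
        C = np.corrcoef(X)
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else (1 + C[i, j]) / 2
                assert A[i, j] == pytest.approx(expected)

    def test_entries_bounded(self, rng):
        t = make_tensor(rng.normal(size=(30, 12)))
        A = signed_adjacency(t, power=7).to_numpy()
        assert A.min() >= 0 and A.max() <= 1

    def test_equal_r2_tie_prefers_smaller_power(self, monkeypatch, rng):
        import strisk.coexpression as cx
        monkeypatch.setattr(cx, "_scale_free_r2", lambda k: 0.5)
        t = make_tensor(rng.normal(size=(40, 15)))
        fit = pick_soft_power(t, candidates=[4, 8], target_r2=0.85)
        assert fit.chosen == 4

    def test_hub_structured_network_reaches_scale_free_target(self):
        """Heavy-tailed factor loadings (few hubs, many peripheral genes)
        admit a power with scale-free fit above the 0.85 target."""
        rng = np.random.default_rng(0)
        n, m = 400, 60
        w = rng.uniform(0, 1, n) ** 2.5
        f = rng.standard_normal(m)
        X = (w[:, None] * f[None, :]
             + np.sqrt(1 - w[:, None] ** 2) * rng.standard_normal((n, m)))
        fit = pick_soft_power(make_tensor(X), candidates=[1, 2, 4, 5, 6, 7, 8, 10, 12])
        assert max(fit.r_squared) > 0.85
        assert fit.chosen == min(
            p for p, r2 in zip(fit.candidates, fit.r_squared) if r2 > 0.85)


class TestTom:
    def test_identical_fully_connected_rows_have_zero_dissimilarity(self):
        """Directly linked genes sharing every (full-weight) neighbor
        overlap perfectly, so their dissimilarity is 0."""
        A = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        d = tom_dissimilarity(A)
        assert d[0, 1] == pytest.approx(0.0)

    def test_isolated_pair_has_unit_dissimilarity(self):
        A = np.zeros((4, 4))
        A[2, 3] = A[3, 2] = 0.9  # i=0, j=1 unconnected with no shared neighbors
        d = tom_dissimilarity(A)
        assert d[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_formula(self, rng):
        for n in (4, 5, 7, 10):
            A = random_adjacency(rng, n)
            d = tom_dissimilarity(A)
            assert d == pytest.approx(brute_force_tom_diss(A), abs=1e-12)
            assert d.min() >= 0 and d.max() <= 1
            assert np.allclose(np.diag(d), 0)

    def test_asymmetric_input_rejected(self):
        A = np.array([[0, 0.1], [0.9, 0]])
        with pytest.raises(ValueError):
            tom_dissimilarity(A)


class TestModuleDetection:
    def _block_tensor(self, rng, sizes, rho=0.8, n_samples=50):
        rows = []
        for size in sizes:
            f = rng.standard_normal(n_samples)
            rows.append(np.sqrt(rho) * f + np.sqrt(1 - rho)
                        * rng.standard_normal((size, n_samples)))
        return make_tensor(np.vstack(rows))

    def test_two_planted_blocks_recovered_exactly(self, rng):
        t = self._block_tensor(rng, [50, 50])
        cfg = NetworkConfig(min_module_size=20)
        mods = detect_modules(tom_dissimilarity(signed_adjacency(t, 7)), cfg)
        truth = np.repeat([0, 1], 50)
        assert len(mods.sizes) == 2
        assert adjusted_rand_score(truth, mods.assignment.to_numpy()) == 1.0

    def test_three_blocks_high_ari_across_seeds(self):
        scores = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = self._block_tensor(rng, [40, 40, 40], rho=0.6)
            cfg = NetworkConfig(min_module_size=20)
            mods = detect_modules(tom_dissimilarity(signed_adjacency(t, 7)), cfg)
            truth = np.repeat([0, 1, 2], 40)
            scores.append(adjusted_rand_score(truth, mods.assignment.to_numpy()))
        assert np.mean(scores) >= 0.9

    def test_min_size_above_n_genes_leaves_all_unassigned(self, rng):
        t = self._block_tensor(rng, [10, 10])
        cfg = NetworkConfig(min_module_size=50)
        mods = detect_modules(tom_dissimilarity(signed_adjacency(t, 7)), cfg)
        assert (mods.assignment == "unassigned").all()

    def test_pure_noise_yields_no_modules(self, rng):
        t = make_tensor(rng.standard_normal((200, 40)))
        cfg = NetworkConfig(min_module_size=30)
        mods = detect_modules(tom_dissimilarity(signed_adjacency(t, 7)), cfg)
        assert len(mods.sizes) == 0

    def test_detection_is_deterministic(self, rng):
        t = self._block_tensor(rng, [40, 40])
        cfg = NetworkConfig(min_module_size=20)
        d = tom_dissimilarity(signed_adjacency(t, 7))
        a = detect_modules(d, cfg).assignment
        b = detect_modules(d, cfg).assignment
        assert (a == b).all()

    def test_labels_ordered_by_descending_size(self, rng):
        t = self._block_tensor(rng, [60, 30])
        cfg = NetworkConfig(min_module_size=20)
        mods = detect_modules(tom_dissimilarity(signed_adjacency(t, 7)), cfg)
        sizes = mods.sizes
        assert sizes["M1"] >= sizes["M2"]


class TestEigengenes:
    def test_identical_rows_give_that_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        t = make_tensor(np.tile(profile, (4, 1)))
        assignment = pd.Series("M1", index=t.values.index)
        eig = compute_eigengenes(t, assignment).loc["M1"].to_numpy()
        std = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(eig, std)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(eig, profile)[0, 1] > 0  # sign orientation

    def test_anticorrelated_pair_resolves_sign_to_mean(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t = make_tensor(np.vstack([a, 5 - a + 0.1 * np.array([0, 1, 0, 1])]))
        assignment = pd.Series("M1", index=t.values.index)
        eig = compute_eigengenes(t, assignment).loc["M1"].to_numpy()
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_planted_factor_recovered(self):
        t, truth = synthetic.make_modules(synthetic.modules_preset(seed=2))
        cfg = NetworkConfig(min_module_size=40)
        mods = detect_modules(tom_dissimilarity(signed_adjacency(t, 7)), cfg)
        eig = compute_eigengenes(t, mods.assignment)
        for name in truth.module_members:
            f = truth.module_factors.loc[name].to_numpy()
            best = max(abs(np.corrcoef(eig.loc[m], f)[0, 1]) for m in eig.index)
            assert best >= 0.95

    def test_pc1_beats_any_single_member_alignment(self, rng):
        """Eigengene variance explained >= any standardized member gene's."""
        X = rng.standard_normal((6, 20))
        t = make_tensor(X)
        assignment = pd.Series("M1", index=t.values.index)
        eig = compute_eigengenes(t, assignment).loc["M1"].to_numpy()
        Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        var_eig = np.sum((Xs @ eig) ** 2)
        for g in range(6):
            u = Xs[g] / np.linalg.norm(Xs[g])
            assert var_eig >= np.sum((Xs @ u) ** 2) - 1e-9

    def test_unit_norm_rows(self, rng):
        t = make_tensor(rng.standard_normal((10, 8)))
        assignment = pd.Series(["M1"] * 5 + ["M2"] * 5, index=t.values.index)
        eig = compute_eigengenes(t, assignment)
        assert np.linalg.norm(eig, axis=1) == pytest.approx(np.ones(2))
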