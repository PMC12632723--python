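"""Rank-biserial enrichment: oracles, invariances, trajectories, hot-spots."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strisk import enrichment, synthetic
from strisk.enrichment import (
    enrich_matrix,
    moving_average,
    rank_biserial,
    stage_trajectory,
    top_hotspots,
)
from strisk.genesets import GeneSet, GeneSetCollection

from conftest import make_tensor, pair_count_rank_biserial


class TestRankBiserial:
    def test_complete_separation(self):
        """Risk genes occupying the top ranks give U = n1*n2 and r = 1."""
        cell = rank_biserial(np.array([1.0, 2.0, 10.0, 20.0]),
                             np.array([False, False, True, True]))
        assert cell.U == 4 and cell.r == 1.0

    def test_symmetric_interleaving_gives_zero(self):
        """Risk at ranks {1, 4} vs non-risk {2, 3}: U = 2, r = 0."""
        cell = rank_biserial(np.array([1.0, 2.0, 3.0, 4.0]),
                             np.array([True, False, False, True]))
        assert cell.U == 2 and cell.r == 0.0

    def test_worked_example(self):
        """values [5,3,8,1,9,2], risk {8,9,2}: 7 wins of 9 pairs -> U=7, r=5/9."""
        values = np.array([5.0, 3.0, 8.0, 1.0, 9.0, 2.0])
        risk = np.array([False, False, True, False, True, True])
        cell = rank_biserial(values, risk)
        assert cell.U == 7
        assert cell.r == pytest.approx(5 / 9)

    def test_identity_r_from_U(self, rng):
        """r = 2U/(n1 n2) - 1 holds exactly on random instances."""
        for _ in range(20):
            values = rng.integers(0, 20, size=30).astype(float)
            risk = np.zeros(30, bool)
            risk[rng.choice(30, 8, replace=False)] = True
            cell = rank_biserial(values, risk)
            assert cell.r == pytest.approx(2 * cell.U / (cell.n1 * cell.n2) - 1, abs=1e-12)

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_matches_pair_counting_oracle(self, rng, with_ties):
        """U and r equal exhaustive pair enumeration (ties count 1/2)."""
        for _ in range(60):
            n = int(rng.integers(5, 60))
            values = (rng.integers(0, max(2, n // 3), size=n).astype(float)
                      if with_ties else rng.normal(size=n))
            n1 = int(rng.integers(1, n))
            risk = np.zeros(n, bool)
            risk[rng.choice(n, n1, replace=False)] = True
            U_oracle, r_oracle = pair_count_rank_biserial(values, risk)
            cell = rank_biserial(values, risk)
            assert cell.U == pytest.approx(U_oracle, abs=1e-9)
            assert cell.r == pytest.approx(r_oracle, abs=1e-12)

    def test_matches_scipy_mannwhitneyu(self, rng):
        """U and one-sided p agree with the reference Mann-Whitney test."""
        for _ in range(25):
            n = int(rng.integers(20, 80))
            values = rng.integers(0, 15, size=n).astype(float)
            risk = np.zeros(n, bool)
            risk[rng.choice(n, int(rng.integers(3, n - 3)), replace=False)] = True
            cell = rank_biserial(values, risk)
            ref = stats.mannwhitneyu(values[risk], values[~risk],
                                     alternative="greater", method="asymptotic")
            assert cell.U == pytest.approx(ref.statistic)
            assert cell.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_antisymmetry(self, rng):
        """Swapping the risk mask negates r."""
        values = rng.normal(size=40)
        risk = np.zeros(40, bool)
        risk[:15] = True
        assert rank_biserial(values, risk).r == pytest.approx(
            -rank_biserial(values, ~risk).r)

    def test_monotone_transform_invariance(self, rng):
        """r depends on ranks only: strictly monotone transforms preserve it."""
        values = rng.normal(size=50)
        risk = np.zeros(50, bool)
        risk[rng.choice(50, 12, replace=False)] = True
        base = rank_biserial(values, risk).r
        for f in (np.exp, lambda x: x**3, lambda x: 5 * x - 2):
            assert rank_biserial(f(values), risk).r == pytest.approx(base)

    def test_boosting_risk_genes_never_decreases_r(self, rng):
        """Adding a constant to risk-gene values can only raise their ranks."""
        values = rng.normal(size=50)
        risk = np.zeros(50, bool)
        risk[rng.choice(50, 10, replace=False)] = True
        base = rank_biserial(values, risk).r
        boosted = values.copy()
        boosted[risk] += 1.0
        assert rank_biserial(boosted, risk).r >= base

    def test_degenerate_constant_sample(self):
        """All-identical values: r = 0, p = 0.5."""
        cell = rank_biserial(np.full(20, 3.0), np.arange(20) < 5)
        assert cell.r == 0.0 and cell.p == 0.5

    def test_empty_risk_group_is_missing(self):
        assert rank_biserial(np.arange(5.0), np.zeros(5, bool)) is None


class TestEnrichMatrix:
    def _coll(self, sets):
        return GeneSetCollection(sets=[
            GeneSet.from_symbols(name, genes) for name, genes in sets.items()])

    def test_constant_matrix_degenerates_to_zero(self):
        t = make_tensor(np.full((6, 4), 2.0), regions=["A"] * 4, stages=["s"] * 4)
        em = enrich_matrix(t, self._coll({"X": ["G0", "G1"]}))
        assert (em.r.to_numpy() == 0).all()
        assert (em.z.to_numpy() == 0).all()

    def test_z_is_sample_sd_normalized(self):
        """Per-set z equals (r - mean) / sample SD across the three samples."""
        t = make_tensor(np.array([
            [5.0, 5.0, 6.0],
            [2.6, 3.5, 5.0],
            [3.0, 3.0, 3.0],
            [2.0, 2.0, 2.0],
            [1.0, 1.0, 1.0],
        ]), regions=["A"] * 3, stages=["s"] * 3)
        em = enrich_matrix(t, self._coll({"X": ["G0", "G1"]}))
        z = em.z.loc["X"].to_numpy()
        r = em.r.loc["X"].to_numpy()
        expected = (r - r.mean()) / r.std(ddof=1)
        assert z == pytest.approx(expected)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1)

    def test_bh_correction_matches_hand_stepup(self, rng):
        """Per-set BH q-values equal a hand-computed step-up on each row."""
        t = make_tensor(rng.normal(size=(30, 4)), regions=list("AABB"),
                        stages=["s1", "s1", "s2", "s2"])
        coll = self._coll({"X": [f"G{i}" for i in range(5)],
                           "Y": [f"G{i}" for i in range(10, 18)]})
        em = enrich_matrix(t, coll)
        for name, grp in em.table.groupby("set"):
            p = grp["p"].to_numpy()
            m = len(p)
            order = np.argsort(p)
            q_sorted = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            q_hand = np.empty(m)
            q_hand[order] = np.minimum(q_sorted, 1.0)
            assert grp["q"].to_numpy() == pytest.approx(q_hand)

    def test_unmeasured_set_gives_missing_row(self, rng):
        t = make_tensor(rng.normal(size=(10, 3)), regions=["A"] * 3, stages=["s"] * 3)
        em = enrich_matrix(t, self._coll({"X": ["G1"], "ZZ": ["ABSENT1", "ABSENT2"]}))
        assert em.r.loc["ZZ"].isna().all()
        assert em.r.loc["X"].notna().all()


class TestTrajectory:
    def test_linear_stage_means_smooth_to_shifted_line(self):
        """Stage means 1..11 -> smoothed 2..10, i.e. 9 values from 11 stages."""
        assert moving_average(np.arange(1.0, 12.0)) == pytest.approx(
            np.arange(2.0, 11.0))

    def test_constant_series_is_fixed_point(self):
        assert moving_average(np.full(7, 3.3)) == pytest.approx(np.full(5, 3.3))

    def test_eleven_stage_tensor_yields_nine_smoothed_points(self, rng):
        stages = [f"st{i:02d}" for i in range(11)]
        t = make_tensor(rng.normal(size=(20, 11)), regions=["A"] * 11,
                        stages=stages, stage_order=stages)
        em = enrich_matrix(t, GeneSetCollection(
            sets=[GeneSet.from_symbols("X", ["G0", "G1", "G2"])]))
        traj = stage_trajectory(em, "X")
        assert len(traj.stage_means) == 11
        assert len(traj.smoothed) == 9
        assert not np.isnan(traj.smoothed).any()

    def test_missing_stage_propagates_to_windows(self, rng):
        stages = [f"st{i}" for i in range(5)]
        t = make_tensor(rng.normal(size=(20, 4)), regions=["A"] * 4,
                        stages=["st0", "st1", "st3", "st4"], stage_order=stages)
        traj = stage_trajectory(
            enrich_matrix(t, GeneSetCollection(
                sets=[GeneSet.from_symbols("X", ["G0", "G1"])])), "X")
        assert np.isnan(traj.stage_means[2])
        assert np.isnan(traj.smoothed).all()  # every window contains stage 2


class TestHotspots:
    def test_planted_cell_is_rank_one(self):
        cfg = synthetic.enrichment_preset(seed=11)
        tensor, coll, truth = synthetic.make_bulk(cfg)
        em = enrich_matrix(tensor, coll)
        for name, cells in truth.set_cells.items():
            top = top_hotspots(em, name, k=3)[0]
            assert (top.region, top.stage) == cells[0]

    def test_exactly_top_k_reported_and_sorted(self, rng):
        cfg = synthetic.enrichment_preset(seed=5)
        tensor, coll, _ = synthetic.make_bulk(cfg)
        em = enrich_matrix(tensor, coll)
        hs = top_hotspots(em, "RiskA", k=3)
        assert len(hs) == 3
        assert [h.rank for h in hs] == [1, 2, 3]
        assert all(hs[i].mean_r >= hs[i + 1].mean_r for i in range(2))

    def test_full_ranking_non_increasing(self):
        cfg = synthetic.enrichment_preset(seed=5)
        tensor, coll, _ = synthetic.make_bulk(cfg)
        em = enrich_matrix(tensor, coll)
        n_cells = len(set(zip(tensor.samples["region"], tensor.samples["stage"])))
        hs = top_hotspots(em, "RiskA", k=n_cells)
        means = [h.mean_r for h in hs]
        assert means == sorted(means, reverse=True)

    def test_uniform_tensor_tie_break_is_deterministic(self):
        t = make_tensor(np.tile(np.arange(8.0)[:, None], (1, 4)),
                        regions=list("BBAA"), stages=["s1", "s2", "s1", "s2"],
                        stage_order=["s1", "s2"])
        em = enrich_matrix(t, GeneSetCollection(
            sets=[GeneSet.from_symbols("X", ["G6", "G7"])]))
        hs = top_hotspots(em, "X", k=4)
        # all cells tie on mean_r and count: lexicographic region, stage order
        assert [(h.region, h.stage) for h in hs] == [
            ("A", "s1"), ("A", "s2"), ("B", "s1"), ("B", "s2")]
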