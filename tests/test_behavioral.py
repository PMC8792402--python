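"""Visual-field grids, behavioral scores, and score-centrality correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ecmap.behavioral import (
    VFMap,
    abs_diff_md,
    behavioral_scores,
    bivf,
    correlate_scores_with_ec,
    read_vf_csv,
    worse_md,
    write_vf_csv,
)
from ecmap.centrality import HubSet
from ecmap.vfgrids import blind_spot, expected_point_count, grid_locations


class TestGrids:
    @pytest.mark.parametrize("grid,n", [("24-2", 52), ("30-2", 74)])
    def test_point_counts(self, grid, n):
        for eye in ("left", "right"):
            assert grid_locations(grid, eye).shape == (n, 2)
        assert expected_point_count(grid) == n

    @pytest.mark.parametrize("grid", ["24-2", "30-2"])
    def test_blind_spot_excluded(self, grid):
        for eye in ("left", "right"):
            pts = {tuple(p) for p in grid_locations(grid, eye).tolist()}
            for b in blind_spot(eye).tolist():
                assert tuple(b) not in pts

    def test_left_right_mirror(self):
        right = {tuple(p) for p in grid_locations("24-2", "right").tolist()}
        left = {(-x, y) for x, y in grid_locations("24-2", "left").tolist()}
        assert right == left

    def test_bad_grid(self):
        with pytest.raises(ValueError, match="grid"):
            grid_locations("10-2", "right")


class TestScalarScores:
    @pytest.mark.parametrize("l,r,expected", [
        (-7.0, -9.0, -9.0),
        (0.1, 0.1, 0.1),
        (-2.0, 3.0, -2.0),
    ])
    def test_worse_md(self, l, r, expected):
        assert worse_md(l, r) == expected
        assert worse_md(r, l) == expected  # symmetric

    @pytest.mark.parametrize("l,r,expected", [
        (-7.0, -9.0, 2.0),
        (-3.3, -3.3, 0.0),
        (-12.11, 0.0, 12.11),
    ])
    def test_abs_diff_md(self, l, r, expected):
        assert abs_diff_md(l, r) == pytest.approx(expected)
        assert abs_diff_md(r, l) == pytest.approx(expected)

    def test_missing_eye_gives_nan(self):
        assert np.isnan(worse_md(float("nan"), -2.0))
        assert np.isnan(abs_diff_md(None, -2.0))


def _map(eye, td, locs, pid="p"):
    td = np.asarray(td, float)
    return VFMap(eye=eye, grid="24-2", td=td, locations=np.asarray(locs, float),
                 md=float(td.mean()), participant_id=pid)


class TestBIVF:
    LOCS = [(3.0, 3.0), (9.0, 3.0), (3.0, -3.0)]

    def test_pointwise_max_rule(self):
        left = _map("left", [-5, -2, -30], self.LOCS)
        right = _map("right", [-1, -6, -30], self.LOCS)
        assert bivf(left, right) == pytest.approx(-11.0)

    def test_identical_eyes_reduce_to_mean(self):
        td = [-4.0, -1.0, -7.0]
        assert bivf(_map("left", td, self.LOCS), _map("right", td, self.LOCS)) \
            == pytest.approx(np.mean(td))

    def test_blind_eye_fully_compensated(self):
        left = _map("left", [-30, -30, -30], self.LOCS)
        right = _map("right", [0, 0, 0], self.LOCS)
        assert bivf(left, right) == 0.0

    def test_symmetric_in_eyes(self, rng):
        left = _map("left", rng.uniform(-30, 0, 3), self.LOCS)
        right = _map("right", rng.uniform(-30, 0, 3), self.LOCS)
        assert bivf(left, right) == bivf(right, left)

    def test_same_eye_rejected(self):
        with pytest.raises(ValueError, match="per eye"):
            bivf(_map("left", [0, 0, 0], self.LOCS), _map("left", [0, 0, 0], self.LOCS))

    def test_empty_overlap_rejected(self):
        left = _map("left", [0.0], [(-27.0, 3.0)])
        right = _map("right", [0.0], [(27.0, 3.0)])
        with pytest.raises(ValueError, match="overlap"):
            bivf(left, right)

    def test_mixed_grid_overlap_is_common_subset(self, rng):
        left = VFMap(eye="left", grid="30-2", td=rng.uniform(-10, 0, 74),
                     locations=grid_locations("30-2", "left"), md=0.0)
        right = VFMap(eye="right", grid="24-2", td=rng.uniform(-10, 0, 52),
                      locations=grid_locations("24-2", "right"), md=0.0)
        # must evaluate without error on the common locations
        val = bivf(left, right)
        assert -10 <= val <= 0

    @given(st.integers(min_value=0, max_value=5000))
    def test_max_dominance_over_single_eye(self, seed):
        rng = np.random.default_rng(seed)
        tdl = rng.uniform(-32, 2, 3)
        tdr = rng.uniform(-32, 2, 3)
        left, right = _map("left", tdl, self.LOCS), _map("right", tdr, self.LOCS)
        assert bivf(left, right) >= np.mean(tdl) - 1e-12
        assert bivf(left, right) >= np.mean(tdr) - 1e-12

    def test_full_grid_maps(self, rng):
        left = VFMap.on_standard_grid("left", "24-2", rng.uniform(-20, 0, 52), None, "p")
        right = VFMap.on_standard_grid("right", "24-2", rng.uniform(-20, 0, 52), None, "p")
        scores = behavioral_scores(left, right, "p")
        assert scores.abs_diff_md >= 0
        assert scores.worse_md == min(left.md, right.md)


class TestCorrelation:
    def _inputs(self, rng, n=12):
        ec = pd.DataFrame({5: np.arange(n, dtype=float)},
                          index=[f"s{i}" for i in range(n)])
        base = pd.DataFrame({
            "worse_md": rng.normal(size=n),
            "bivf": np.arange(n, dtype=float),  # perfectly monotone with EC
            "abs_diff_md": rng.normal(size=n),
        }, index=ec.index)
        return base, ec, HubSet(roi_ids=[5], threshold=0.0)

    def test_monotone_scores_give_rho_one(self, rng):
        scores, ec, hubs = self._inputs(rng)
        out = correlate_scores_with_ec(scores, ec, hubs)
        row = out[(out.hub == 5) & (out.score == "bivf")].iloc[0]
        assert row.rho == pytest.approx(1.0)
        assert row.p < 1e-6
        assert row.n == 12

    def test_hand_ranked_example_matches_rank_formula(self):
        """5-point example checked against the d^2 rank formula."""
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        d = stats.rankdata(x) - stats.rankdata(y)
        rho_formula = 1 - 6 * np.sum(d**2) / (5 * 24)
        scores = pd.DataFrame({"worse_md": y, "bivf": y, "abs_diff_md": y},
                              index=[f"s{i}" for i in range(5)])
        ec = pd.DataFrame({1: x}, index=scores.index)
        out = correlate_scores_with_ec(scores, ec, HubSet(roi_ids=[1], threshold=0))
        assert out.iloc[0].rho == pytest.approx(rho_formula)

    def test_exact_small_n_p_matches_enumeration(self):
        # n = 5 without ties: exact two-sided p for rho = 0.9 is known (2*.0417? -> via enumeration)
        x = np.arange(5.0)
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        scores = pd.DataFrame({"worse_md": y, "bivf": y, "abs_diff_md": y},
                              index=[f"s{i}" for i in range(5)])
        ec = pd.DataFrame({1: x}, index=scores.index)
        out = correlate_scores_with_ec(scores, ec, HubSet(roi_ids=[1], threshold=0))
        # brute force over all 120 permutations
        import itertools

        rho_obs = stats.spearmanr(x, y).statistic
        cnt = tot = 0
        for perm in itertools.permutations(y):
            cnt += abs(stats.spearmanr(x, np.array(perm)).statistic) >= abs(rho_obs) - 1e-12
            tot += 1
        assert out.iloc[0].p == pytest.approx(cnt / tot)

    def test_missing_scores_dropped_pairwise(self, rng):
        scores, ec, hubs = self._inputs(rng)
        scores.loc["s0", "bivf"] = np.nan
        out = correlate_scores_with_ec(scores, ec, hubs)
        assert out[(out.score == "bivf")].iloc[0].n == 11
        assert out[(out.score == "worse_md")].iloc[0].n == 12

    def test_too_few_pairs_marked_not_computable(self, rng):
        scores, ec, hubs = self._inputs(rng, n=3)
        out = correlate_scores_with_ec(scores, ec, hubs)
        assert out.rho.isna().all()
        assert (out.n == 3).all()

    def test_null_rejection_rate_calibrated(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            hits += stats.spearmanr(x, y).pvalue <= 0.05
        assert 0.02 <= hits / reps <= 0.09


def test_vf_csv_roundtrip(tmp_path, rng):
    vf = VFMap.on_standard_grid("right", "24-2", rng.uniform(-15, 0, 52),
                                md=-4.5, participant_id="px")
    write_vf_csv(vf, tmp_path / "px_right.csv")
    back = read_vf_csv(tmp_path / "px_right.csv")
    assert back.eye == "right" and back.grid == "24-2"
    assert back.md == pytest.approx(-4.5)
    assert back.participant_id == "px"
    assert np.allclose(back.td, vf.td)
    assert np.allclose(back.locations, vf.locations)
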