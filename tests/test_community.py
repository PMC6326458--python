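import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

import reefcs as rc
from reefcs.community import DissimilarityMatrix, _bc_condensed


def _fish(rows):
    return pd.DataFrame(rows, columns=["site", "habitat", "transect", "year", "species", "count"])


class TestAnnualMeanMatrix:
    def test_mean_over_sampled_transects(self):
        rows = [("A", "crest", f"t{i}", 2002, "sp", 2) for i in range(3)]
        rows += [("A", "crest", "t0", 2003, "sp", 6),
                 ("A", "crest", "t1", 2003, "other", 3)]
        m = rc.annual_mean_matrix(_fish(rows))
        df = m.to_frame()
        assert df.loc[2002, "sp"] == 2.0           # 3 transects, count 2 each
        assert df.loc[2003, "sp"] == 3.0           # 6 over 2 sampled transects
        assert df.loc[2002, "other"] == 0.0        # absent species -> 0

    def test_unbalanced_years_use_per_year_denominators(self):
        rows = [("A", "crest", f"t{i}", 2002, "sp", 1) for i in range(4)]
        rows += [("A", "crest", "t0", 2003, "sp", 1)]
        df = rc.annual_mean_matrix(_fish(rows)).to_frame()
        assert df.loc[2002, "sp"] == 0.25 * 4 / 1  # 4/4
        assert df.loc[2003, "sp"] == 1.0           # 1/1

    def test_single_year_errors(self):
        with pytest.raises(ValueError, match="2 years"):
            rc.annual_mean_matrix(_fish([("A", "crest", "t1", 2002, "sp", 1)]))


class TestBrayCurtis:
    def test_hand_computed_value(self):
        m = rc.CommunityMatrix(labels=[1, 2], species=["a", "b", "c"],
                               values=np.array([[1, 2, 0], [0, 2, 4]]))
        d = rc.bray_curtis(m)
        assert d.values[0, 1] == pytest.approx(5 / 9)

    def test_identical_rows_zero_and_disjoint_rows_one(self):
        m = rc.CommunityMatrix(labels=[1, 2, 3], species=list("ab"),
                               values=np.array([[3, 1], [3, 1], [0, 0]]))
        d = rc.bray_curtis(m)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0       # disjoint support
        # both-zero rows are 0 by convention
        m2 = rc.CommunityMatrix(labels=[1, 2], species=list("ab"),
                                values=np.zeros((2, 2)))
        assert rc.bray_curtis(m2).values[0, 1] == 0.0

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(1.0, 2.0, size=(7, 12))
        m = rc.CommunityMatrix(labels=list(range(7)), species=[f"s{i}" for i in range(12)],
                               values=x)
        for transform, tx in [("none", x), ("sqrt", np.sqrt(x)), ("fourth_root", x ** 0.25)]:
            mine = rc.bray_curtis(m, transform).condensed()
            ref = pdist(tx, metric="braycurtis")
            assert np.allclose(mine, ref)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_output_is_valid_dissimilarity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(0.5, 3.0, size=(5, 8)) * rng.integers(0, 2, size=(5, 8))
        m = rc.CommunityMatrix(labels=list(range(5)), species=[f"s{i}" for i in range(8)],
                               values=x)
        d = rc.bray_curtis(m)
        v = d.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0)
        assert (v >= 0).all() and (v <= 1).all()


class TestNMDS:
    def test_equilateral_three_points_reach_zero_stress(self):
        d = DissimilarityMatrix(labels=[0, 1, 2],
                                values=np.array([[0, .5, .5], [.5, 0, .5], [.5, .5, 0.]]))
        res = rc.nmds(d, restarts=5, seed=0)
        assert res.stress <= 1e-9

    def test_exactly_embeddable_distances_reach_zero_stress(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(9, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        res = rc.nmds(DissimilarityMatrix(labels=list(range(9)), values=D),
                      restarts=8, seed=0)
        assert res.stress <= 1e-6

    def test_duplicate_samples_coincide(self):
        D = np.array([[0, 0, .6, .7], [0, 0, .6, .7],
                      [.6, .6, 0, .5], [.7, .7, .5, 0.]])
        res = rc.nmds(DissimilarityMatrix(labels=list("abcd"), values=D),
                      restarts=8, seed=0)
        assert np.linalg.norm(res.coords[0] - res.coords[1]) < 1e-6

    def test_stress_trace_non_increasing(self, clean_fish):
        clean, _ = clean_fish
        d = rc.bray_curtis(rc.annual_mean_matrix(clean))
        res = rc.nmds(d, restarts=10, seed=3)
        for trace in res.stress_traces:
            assert (np.diff(trace) <= 1e-12).all()

    def test_configuration_centred_unit_rms(self, clean_fish):
        clean, _ = clean_fish
        d = rc.bray_curtis(rc.annual_mean_matrix(clean))
        res = rc.nmds(d, restarts=5, seed=0)
        assert np.allclose(res.coords.mean(axis=0), 0, atol=1e-9)
        assert math.sqrt((res.coords ** 2).sum() / d.n) == pytest.approx(1.0)

    def test_too_few_samples_error(self):
        d = DissimilarityMatrix(labels=[0, 1], values=np.array([[0, .5], [.5, 0.]]))
        with pytest.raises(ValueError):
            rc.nmds(d)


def brute_force_seriation_p(values, n):
    """Independent enumeration oracle for the seriation permutation test."""
    iu = np.triu_indices(n, k=1)
    model = rankdata(np.abs(iu[0] - iu[1]).astype(float))

    def rho(cond):
        r = rankdata(cond)
        rc_, mc = r - r.mean(), model - model.mean()
        return float((rc_ * mc).sum() / math.sqrt((rc_ ** 2).sum() * (mc ** 2).sum()))

    obs = rho(values[iu])
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        if rho(values[np.ix_(p, p)][iu]) >= obs - 1e-12:
            hits += 1
        total += 1
    return obs, hits / total


class TestSeriation:
    def test_perfectly_seriated_matrix_gives_rho_one(self):
        n = 6
        vals = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float) / n
        res = rc.relate_seriation(DissimilarityMatrix(labels=list(range(n)), values=vals))
        assert res.rho == pytest.approx(1.0)
        assert res.exact  # 6! = 720 <= enumeration cutoff

    def test_constant_matrix_is_degenerate(self):
        vals = np.full((4, 4), 0.5)
        np.fill_diagonal(vals, 0.0)
        res = rc.relate_seriation(DissimilarityMatrix(labels=list(range(4)), values=vals))
        assert res.degenerate and res.rho == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("n,seed", [(4, 0), (4, 7), (5, 1), (5, 9)])
    def test_exact_p_matches_enumeration_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(1.0, 1.0, size=(n, 6))
        m = rc.CommunityMatrix(labels=list(range(n)), species=[f"s{i}" for i in range(6)], values=x)
        d = rc.bray_curtis(m)
        res = rc.relate_seriation(d, method="exact")
        rho_oracle, p_oracle = brute_force_seriation_p(d.values, n)
        assert res.rho == pytest.approx(rho_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_sampled_p_has_add_one_correction(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(1.0, 1.0, size=(9, 6))
        d = rc.bray_curtis(rc.CommunityMatrix(
            labels=list(range(9)), species=[f"s{i}" for i in range(6)], values=x))
        res = rc.relate_seriation(d, n_perm=99, seed=5, method="sampled")
        assert res.p >= 1 / 100
        assert not res.exact


class TestSimprof:
    def test_identical_rows_single_group(self):
        m = rc.CommunityMatrix(labels=list(range(5)), species=list("abc"),
                               values=np.tile([2.0, 1.0, 0.0], (5, 1)))
        res = rc.simprof(m, seed=0, n_perm_profile=99, n_perm_test=99)
        assert res.groups == [[0, 1, 2, 3, 4]]

    def test_two_disjoint_blocks_give_two_groups(self):
        a = np.array([4.0, 2.0, 1.0, 0, 0, 0])
        b = np.array([0, 0, 0, 3.0, 5.0, 1.0])
        vals = np.vstack([np.tile(a, (4, 1)), np.tile(b, (4, 1))])
        m = rc.CommunityMatrix(labels=list(range(8)), species=[f"s{i}" for i in range(6)],
                               values=vals)
        res = rc.simprof(m, alpha=0.05, seed=1)
        assert sorted(res.groups) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_warns_when_permutations_cannot_reach_alpha(self):
        m = rc.CommunityMatrix(labels=list(range(4)), species=list("ab"),
                               values=np.arange(8.0).reshape(4, 2))
        with pytest.warns(UserWarning, match="cannot attain"):
            rc.simprof(m, alpha=0.05, n_perm_profile=9, n_perm_test=9, seed=0)

    def test_groups_partition_labels(self, clean_fish):
        clean, _ = clean_fish
        m = rc.annual_mean_matrix(clean)
        res = rc.simprof(m, seed=2, n_perm_profile=199, n_perm_test=199)
        flat = sorted(y for g in res.groups for y in g)
        assert flat == sorted(m.labels)
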