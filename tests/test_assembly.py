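import itertools

import numpy as np
import pandas as pd
import pytest

from ecoassembly.assembly import (
    AssemblyModel,
    bmntd,
    bnti,
    classify_process,
    rc_bray,
    summarize_processes,
)
from ecoassembly.containers import OtuTable
from ecoassembly.phylo import patristic_matrix
from ecoassembly.synthetic import simulate_tree


def _bmntd_brute_force(table, dist, pair, weighted=True):
    """Exhaustive double-loop betaMNTD, independent of the array path."""
    j, k = pair
    total = 0.0
    for a, b in ((j, k), (k, j)):
        row_a = table.counts.loc[a]
        row_b = table.counts.loc[b]
        present_a = [t for t in table.taxon_ids if row_a[t] > 0]
        present_b = [t for t in table.taxon_ids if row_b[t] > 0]
        for t in present_a:
            nearest = min(dist.loc[t, u] for u in present_b)
            f = (
                row_a[t] / row_a.sum()
                if weighted
                else 1.0 / len(present_a)
            )
            total += f * nearest
    return total / 2.0


class TestBmntd:
    def test_identical_composition_is_zero(self, small_tree):
        table = OtuTable(
            pd.DataFrame(
                [[1, 2, 3], [1, 2, 3]], index=["x", "y"], columns=list("ABC")
            )
        )
        dist = patristic_matrix(small_tree)
        assert bmntd(table, dist, ("x", "y")) == pytest.approx(0.0)

    def test_singleton_samples(self, small_tree):
        table = OtuTable(
            pd.DataFrame(
                [[4, 0, 0], [0, 9, 0]], index=["x", "y"], columns=list("ABC")
            )
        )
        dist = patristic_matrix(small_tree)
        # {A} vs {B}: d(A,B) = 2 both ways -> (2+2)/2 = 2
        assert bmntd(table, dist, ("x", "y")) == pytest.approx(2.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force(self, weighted):
        tree = simulate_tree(5, seed=17)
        dist = patristic_matrix(tree)
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 6, size=(4, 5))
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = OtuTable(
            pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(4)],
                columns=[t.name for t in tree.tips()],
            )
        )
        for pair in itertools.combinations(table.sample_ids, 2):
            assert bmntd(table, dist, pair, weighted) == pytest.approx(
                _bmntd_brute_force(table, dist, pair, weighted), abs=1e-10
            )

    def test_empty_sample_errors(self, small_tree):
        table = OtuTable(
            pd.DataFrame(
                [[0, 0, 0], [1, 1, 1]], index=["x", "y"], columns=list("ABC")
            )
        )
        with pytest.raises(ValueError, match="empty"):
            bmntd(table, patristic_matrix(small_tree), ("x", "y"))


class TestBnti:
    def test_degenerate_equidistant_matrix_is_nan(self):
        # star phylogeny: all off-diagonal distances equal -> null has no
        # spread -> NaN with warning
        ids = list("ABCD")
        d = pd.DataFrame(2.0, index=ids, columns=ids)
        np.fill_diagonal(d.to_numpy(), 0)
        d = pd.DataFrame(
            np.where(np.eye(4, dtype=bool), 0.0, 2.0), index=ids, columns=ids
        )
        table = OtuTable(
            pd.DataFrame(
                [[1, 2, 0, 0], [0, 0, 3, 1]], index=["x", "y"], columns=ids
            )
        )
        with pytest.warns(UserWarning, match="degenerate"):
            z = bnti(table, d, ("x", "y"), reps=99, seed=0)
        assert np.isnan(z)

    def test_invariant_under_branch_length_scaling(self):
        tree = simulate_tree(20, seed=4)
        dist = patristic_matrix(tree)
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 10, size=(2, 20))
        counts[:, 0] += 1
        table = OtuTable(
            pd.DataFrame(
                counts, index=["x", "y"], columns=list(dist.index)
            )
        )
        z1 = bnti(table, dist, ("x", "y"), reps=199, seed=7)
        z2 = bnti(table, dist * 13.7, ("x", "y"), reps=199, seed=7)
        assert z1 == pytest.approx(z2, abs=1e-9)


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------

def _rc_oracle_enumerate(table, pair, pool):
    """Fully independent RC oracle: enumerate ordered taxon-draw sequences
    and read-by-read allocation sequences with their probabilities."""
    counts = table.counts[pool.taxon_ids]
    occupancy = (pool.counts.to_numpy() > 0).sum(axis=0).astype(float)
    occ_p = occupancy / occupancy.sum()
    meta = pool.counts.to_numpy().sum(axis=0).astype(float)
    meta_p = meta / meta.sum()
    n_taxa = len(occ_p)

    def sample_distribution(richness, reads):
        # ordered draws without replacement
        out = {}
        for order in itertools.permutations(
            [t for t in range(n_taxa) if occ_p[t] > 0], richness
        ):
            prob = 1.0
            remaining = 1.0
            for t in order:
                prob *= occ_p[t] / remaining
                remaining -= occ_p[t]
            chosen = list(order)
            q = meta_p[chosen] / meta_p[chosen].sum()
            # read-by-read allocation sequences
            for seq in itertools.product(range(richness), repeat=reads):
                p_seq = prob
                vec = np.zeros(n_taxa)
                for slot in seq:
                    p_seq *= q[slot]
                    vec[chosen[slot]] += 1
                key = tuple(vec)
                out[key] = out.get(key, 0.0) + p_seq
        return out

    def bray(u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        return 1.0 - np.minimum(u / u.sum(), v / v.sum()).sum()

    j, k = pair
    row_j = counts.loc[j].to_numpy(dtype=float)
    row_k = counts.loc[k].to_numpy(dtype=float)
    obs = bray(row_j, row_k)
    dist_j = sample_distribution(int((row_j > 0).sum()), int(row_j.sum()))
    dist_k = sample_distribution(int((row_k > 0).sum()), int(row_k.sum()))
    less = 0.0
    for u, pu in dist_j.items():
        for v, pv in dist_k.items():
            if sum(u) == 0 or sum(v) == 0:
                continue
            bc = bray(u, v)
            if bc < obs - 1e-12:
                less += pu * pv
            elif abs(bc - obs) <= 1e-12:
                less += 0.5 * pu * pv
    return (less - 0.5) * 2.0


class TestRcBray:
    @pytest.fixture
    def tiny_pool(self):
        """2-taxon pool: 3 samples with few reads (enumerable null)."""
        return OtuTable(
            pd.DataFrame(
                [[2, 1], [3, 0], [1, 2]],
                index=["x", "y", "z"],
                columns=["a", "b"],
            )
        )

    def test_exact_matches_independent_enumeration(self, tiny_pool):
        for pair in itertools.combinations(tiny_pool.sample_ids, 2):
            exact = rc_bray(tiny_pool, pair, exact=True)
            oracle = _rc_oracle_enumerate(tiny_pool, pair, tiny_pool)
            assert exact == pytest.approx(oracle, abs=1e-10)

    def test_monte_carlo_converges_to_exact(self, tiny_pool):
        exact = rc_bray(tiny_pool, ("x", "y"), exact=True)
        mc = rc_bray(tiny_pool, ("x", "y"), reps=20_000, seed=1)
        assert mc == pytest.approx(exact, abs=0.03)

    def test_symmetric_in_pair(self, tiny_pool):
        a = rc_bray(tiny_pool, ("x", "z"), exact=True)
        b = rc_bray(tiny_pool, ("z", "x"), exact=True)
        assert a == pytest.approx(b, abs=1e-12)

    def test_identical_pair_hits_lower_boundary(self):
        """BC_obs = 0 below every sampled null -> RC = -1 exactly."""
        counts = pd.DataFrame(
            [[125, 125, 125, 125], [125, 125, 125, 125], [300, 100, 50, 50]],
            index=["x", "y", "z"],
            columns=list("abcd"),
        )
        table = OtuTable(counts)
        rc = rc_bray(table, ("x", "y"), reps=999, seed=3)
        assert rc == -1.0

    def test_extreme_pair_hits_upper_boundary(self):
        """BC_obs above every sampled null -> RC = +1 exactly."""
        counts = pd.DataFrame(
            [[97, 1, 1, 1], [1, 1, 1, 97], [25, 25, 25, 25]],
            index=["x", "y", "z"],
            columns=list("abcd"),
        )
        table = OtuTable(counts)
        rc = rc_bray(table, ("x", "y"), reps=999, seed=3)
        assert rc == 1.0

    def test_bounds_always_hold(self, random_table):
        rng = np.random.default_rng(0)
        for _ in range(5):
            j, k = rng.choice(random_table.sample_ids, 2, replace=False)
            rc = rc_bray(random_table, (j, k), reps=99, seed=int(rng.integers(1e6)))
            assert -1.0 <= rc <= 1.0

    def test_richness_above_pool_errors(self):
        table = OtuTable(
            pd.DataFrame(
                [[1, 1], [1, 1]], index=["x", "y"], columns=["a", "b"]
            )
        )
        pool = OtuTable(
            pd.DataFrame([[1, 0]], index=["z"], columns=["a", "b"])
        )
        with pytest.raises(ValueError, match="richness"):
            rc_bray(table, ("x", "y"), pool=pool)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassifyProcess:
    @pytest.mark.parametrize(
        "bnti_v, rc_v, expected",
        [
            (2.5, 0.1, "variable_selection"),
            (-2.5, 0.99, "homogeneous_selection"),
            (-2.5, -0.99, "homogeneous_selection"),
            (-1.0, 0.99, "dispersal_limitation"),
            (-1.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            # boundary conventions: betaNTI exactly +/-2 is not selection;
            # |RC| exactly 0.95 goes to the dispersal classes
            (2.0, 0.0, "undominated"),
            (-2.0, 0.0, "undominated"),
            (2.0, 0.95, "dispersal_limitation"),
            (0.0, -0.95, "homogenizing_dispersal"),
            (1.99, 0.949, "undominated"),
        ],
    )
    def test_threshold_rules(self, bnti_v, rc_v, expected):
        assert classify_process(bnti_v, rc_v) == expected

    def test_nan_propagates(self):
        assert classify_process(float("nan"), 0.5) is None

    def test_total_on_random_grid(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            label = classify_process(
                rng.normal(0, 3), rng.uniform(-1, 1)
            )
            assert label in {
                "variable_selection",
                "homogeneous_selection",
                "dispersal_limitation",
                "homogenizing_dispersal",
                "undominated",
            }


class TestSummarizeProcesses:
    def test_single_class_is_100_percent(self):
        pairs = pd.DataFrame(
            {"group": ["g"] * 4, "process": ["undominated"] * 4}
        )
        out = summarize_processes(pairs)
        assert out.loc[0, "undominated"] == 100.0
        assert out.loc[0, "n_pairs"] == 4

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        procs = rng.choice(
            ["undominated", "variable_selection", "dispersal_limitation"], 60
        )
        pairs = pd.DataFrame(
            {"group": rng.choice(["a", "b"], 60), "process": procs}
        )
        out = summarize_processes(pairs)
        sums = out[
            [
                "variable_selection",
                "homogeneous_selection",
                "dispersal_limitation",
                "homogenizing_dispersal",
                "undominated",
            ]
        ].sum(axis=1)
        assert sums.to_numpy() == pytest.approx([100.0] * len(out), abs=0.01)

    def test_nan_pairs_excluded(self):
        pairs = pd.DataFrame(
            {
                "group": ["g"] * 3,
                "process": ["undominated", None, "undominated"],
            }
        )
        out = summarize_processes(pairs)
        assert out.loc[0, "n_pairs"] == 2


class TestAssemblyModel:
    def test_within_group_pairs_only(self, small_tree):
        counts = pd.DataFrame(
            np.ones((4, 3), dtype=int),
            index=["a1", "a2", "b1", "b2"],
            columns=list("ABC"),
        )
        groups = pd.Series(
            ["g1", "g1", "g2", "g2"], index=["a1", "a2", "b1", "b2"]
        )
        table = OtuTable(counts, groups=groups)
        dist = patristic_matrix(small_tree)
        res = AssemblyModel(table, dist).fit(reps=49, seed=0)
        assert len(res.pairs) == 2  # one pair per group
        assert set(res.pairs["group"]) == {"g1", "g2"}

    def test_results_reproducible_and_consistent(self):
        tree = simulate_tree(30, seed=41)
        dist = patristic_matrix(tree)
        rng = np.random.default_rng(5)
        counts = rng.multinomial(500, rng.dirichlet(np.ones(30)), size=6)
        table = OtuTable(
            pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(6)],
                columns=list(dist.index),
            )
        )
        r1 = AssemblyModel(table, dist).fit(reps=99, seed=11)
        r2 = AssemblyModel(table, dist).fit(reps=99, seed=11)
        pd.testing.assert_frame_equal(r1.pairs, r2.pairs)
        # labels consistent with the rule applied to the stored values
        for _, row in r1.pairs.iterrows():
            assert row["process"] == classify_process(
                row["bnti"], row["rc_bray"]
            )
        assert "betaNTI" in r1.summary() or "pairs" in r1.summary()
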