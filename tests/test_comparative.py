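"""Comparative screens against independently coded brute-force oracles."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from sagkit import comparative as cp
from sagkit import io as sio
from sagkit import synthetic as sy


# ---------------------------------------------------------------------------
# oracles


def brute_deficiency(matrix, core_frac, min_absent):
    """Double-loop reference implementation of the deficiency screen."""
    fl = matrix.free_living
    tg = matrix.targets
    thr = math.ceil(core_frac * len(fl))
    out = {}
    for fn in matrix.data.index:
        present_fl = sum(int(matrix.data.loc[fn, s]) for s in fl)
        absent_tg = sum(1 for s in tg if matrix.data.loc[fn, s] == 0)
        core = present_fl >= thr
        out[fn] = (core, core and absent_tg >= min_absent)
    return out


def brute_select(counts, panel, max_missing, min_taxa):
    sel = []
    for cid in counts.index:
        row = counts.loc[cid]
        present = [s for s in counts.columns if row[s] > 0]
        if any(row[s] > 1 for s in present):
            continue
        if panel - len(present) > max_missing:
            continue
        if len(present) < min_taxa:
            continue
        sel.append(cid)
    return sel


def brute_fitch(tree, leaf_state):
    """Exhaustive minimisation over all internal 0/1 labelings."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for combo in itertools.product((0, 1), repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), combo))
        for lf in tree.leaf_node_iter():
            assign[id(lf)] = leaf_state[lf.taxon.label]
        changes = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                changes += assign[id(node)] != assign[id(node.parent_node)]
        best = changes if best is None else min(best, changes)
    return best


def brute_bipartitions(tree):
    """Nontrivial bipartitions of an unrooted tree as frozensets of label pairs."""
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = labels - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return splits


def brute_rf(t1, t2):
    return len(brute_bipartitions(t1) ^ brute_bipartitions(t2))


def random_tree(labels, rng):
    """Random bifurcating topology by iteratively joining subtrees."""
    subtrees = [lbl for lbl in labels]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b})")
    import sagkit.io as _sio

    return _sio.read_newick(subtrees[0] + ";", rooted=True)


# ---------------------------------------------------------------------------
# deficiency screen


class TestDeficiencyScreen:
    def test_fixture_universal_enzyme_not_flagged(self):
        m = sy.core_metabolism_fixture()
        rep = cp.deficiency_screen(m)
        assert not rep.loc["EC 2.3.3.1", "deficient"]
        assert rep.loc["EC 2.3.3.1", "target_absent"] == 0

    def test_fixture_thiamine_enzyme_flagged(self):
        m = sy.core_metabolism_fixture()
        rep = cp.deficiency_screen(m)
        assert rep.loc["EC 2.5.1.3", "deficient"]
        assert rep.loc["EC 2.5.1.3", "target_absent"] == 7

    def test_toy_rules(self):
        # 4 free-living (core needs >=3), 3 targets, min_absent 2
        data = pd.DataFrame(
            {
                "flagged": [1, 1, 1, 0, 0, 0, 1],
                "notcore": [1, 1, 0, 0, 1, 0, 0],
            },
            index=["FL1", "FL2", "FL3", "FL4", "T1", "T2", "T3"],
        ).T
        roles = pd.Series(
            ["free_living"] * 4 + ["target"] * 3, index=data.columns
        )
        m = cp.PresenceAbsenceMatrix(data=data, roles=roles)
        rep = cp.deficiency_screen(m, core_frac=0.75, min_absent_targets=2)
        assert rep.loc["flagged", "deficient"]
        assert not rep.loc["notcore", "core"]
        assert not rep.loc["notcore", "deficient"]

    def test_matches_double_loop_oracle_on_random_matrices(self, rng):
        for i in range(100):
            n_fl = int(rng.integers(3, 10))
            n_tg = int(rng.integers(3, 10))
            n_fn = int(rng.integers(1, 12))
            species = [f"F{j}" for j in range(n_fl)] + [f"T{j}" for j in range(n_tg)]
            data = pd.DataFrame(
                rng.integers(0, 2, size=(n_fn, len(species))),
                index=[f"fn{j}" for j in range(n_fn)],
                columns=species,
            )
            roles = pd.Series(["free_living"] * n_fl + ["target"] * n_tg, index=species)
            m = cp.PresenceAbsenceMatrix(data=data, roles=roles)
            min_absent = int(rng.integers(1, n_tg + 1))
            rep = cp.deficiency_screen(m, 0.75, min_absent)
            oracle = brute_deficiency(m, 0.75, min_absent)
            for fn, (core, deficient) in oracle.items():
                assert rep.loc[fn, "core"] == core
                assert rep.loc[fn, "deficient"] == deficient

    def test_core_threshold_ceiling_semantics(self):
        assert cp.core_threshold(24, 0.75) == 18

    def test_empty_role_rejected(self):
        data = pd.DataFrame({"A": [1]}, index=["fn"])
        m = cp.PresenceAbsenceMatrix(data=data, roles=pd.Series({"A": "target"}))
        with pytest.raises(ValueError):
            cp.deficiency_screen(m)


class TestRatioRegression:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(rows, columns=["cazyme_total", "protease_total", "lifestyle"])

    def test_perfect_linear_fit(self):
        df = self.frame([(20, 10, "s"), (40, 20, "s"), (60, 30, "s")])
        rep = cp.ratio_regression(df)
        assert rep.loc["s", "slope"] == pytest.approx(2.0)
        assert rep.loc["s", "intercept"] == pytest.approx(0.0)
        assert rep.loc["s", "r_squared"] == pytest.approx(1.0)
        assert rep.loc["s", "included"]

    def test_small_group_excluded(self):
        df = self.frame([(20, 10, "m"), (40, 30, "m")])
        rep = cp.ratio_regression(df)
        assert not rep.loc["m", "included"]

    def test_low_r2_excluded(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 100, 20)
        y = rng.uniform(10, 100, 20)  # no relationship
        df = self.frame(list(zip(y, x, ["sap"] * 20)))
        rep = cp.ratio_regression(df, min_r2=0.3)
        assert not rep.loc["sap", "included"]

    def test_matches_normal_equations(self, rng):
        # OLS identity against closed-form normal-equation solution
        for _ in range(20):
            n = int(rng.integers(3, 30))
            x = rng.uniform(0, 100, n)
            y = 3.0 * x + 100 + rng.normal(0, 10, n)
            df = self.frame(list(zip(y, x, ["L"] * n)))
            rep = cp.ratio_regression(df)
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
            assert abs(rep.loc["L", "intercept"] - beta[0]) < 1e-9
            assert abs(rep.loc["L", "slope"] - beta[1]) < 1e-9
            assert abs(rep.loc["L", "r_squared"] - r2) < 1e-9

    def test_zero_variance_predictor_rejected(self):
        df = self.frame([(1, 5, "L"), (2, 5, "L"), (3, 5, "L")])
        with pytest.raises(ValueError):
            cp.ratio_regression(df)


class TestClusterSelection:
    def test_rule_enumeration(self):
        counts = pd.DataFrame(
            {"A": [1, 2], "B": [1, 1], "C": [1, 1], "D": [0, 1]},
            index=["c1", "c2"],
        )
        cs = cp.OrthoClusterSet(counts=counts)
        sel = cp.select_single_copy_clusters(cs, panel_size=4, max_missing=1, min_taxa=3)
        assert sel == ["c1"]  # c2 rejected: two copies in A

    def test_complete_single_copy_selected_at_zero_missing(self):
        counts = pd.DataFrame({"A": [1], "B": [1], "C": [1], "D": [1]}, index=["c"])
        cs = cp.OrthoClusterSet(counts=counts)
        assert cp.select_single_copy_clusters(cs, max_missing=0, min_taxa=3) == ["c"]

    def test_missing_threshold_edge(self):
        cs = sy.make_ortho_clusters(8, 40, missing_model=sy.fixed_missing_model(3), seed=4)
        assert cp.select_single_copy_clusters(cs, max_missing=2) == []
        assert len(cp.select_single_copy_clusters(cs, max_missing=3)) == 40

    def test_matches_brute_force_on_random_instances(self):
        cs = sy.make_ortho_clusters(
            12, 1000,
            copy_model=sy.poisson_copy_model(0.3),
            missing_model=sy.uniform_missing_model(11),
            seed=77,
        )
        got = cp.select_single_copy_clusters(cs, max_missing=8, min_taxa=3)
        expected = brute_select(cs.counts, 12, 8, 3)
        assert got == expected

    def test_max_missing_must_be_below_panel(self):
        cs = sy.make_ortho_clusters(4, 5, seed=1)
        with pytest.raises(ValueError):
            cp.select_single_copy_clusters(cs, max_missing=4)


class TestSupermatrixStats:
    def test_arithmetic(self):
        counts = pd.DataFrame({"X": [1, 0], "Y": [1, 1]}, index=["c1", "c2"])
        lengths = pd.Series([100, 50], index=["c1", "c2"])
        cs = cp.OrthoClusterSet(counts=counts, lengths=lengths)
        missing, _ = cp.supermatrix_stats(cs)
        assert missing["X"] == pytest.approx(50 / 150)
        assert missing["Y"] == 0.0

    def test_absent_everywhere(self):
        counts = pd.DataFrame({"X": [0, 0], "Y": [1, 1]}, index=["c1", "c2"])
        cs = cp.OrthoClusterSet(counts=counts, lengths=pd.Series([10, 20], index=["c1", "c2"]))
        missing, _ = cp.supermatrix_stats(cs)
        assert missing["X"] == 1.0

    def test_group_medians(self):
        counts = pd.DataFrame(
            {"X": [0, 1], "Y": [1, 1], "Z": [1, 0]}, index=["c1", "c2"]
        )
        cs = cp.OrthoClusterSet(
            counts=counts, lengths=pd.Series([60, 40], index=["c1", "c2"])
        )
        groups = pd.Series({"X": "target", "Y": "other", "Z": "target"})
        missing, medians = cp.supermatrix_stats(cs, groups=groups)
        assert medians["other"] == 0.0
        assert medians["target"] == pytest.approx(np.median([0.6, 0.4]))

    def test_requires_lengths(self):
        cs = cp.OrthoClusterSet(counts=pd.DataFrame({"X": [1]}, index=["c"]))
        with pytest.raises(ValueError):
            cp.supermatrix_stats(cs)


class TestFitchAncestral:
    def test_constant_character_no_changes(self):
        tree = sio.read_newick("((A,B),(C,D));", rooted=True)
        states = pd.DataFrame({"f": {"A": 1, "B": 1, "C": 1, "D": 1}})
        rep = cp.fitch_ancestral(tree, states)
        assert rep.change_counts["f"] == 0
        assert all(s == frozenset({1}) for s in rep.node_states["f"].values())

    def test_single_derived_leaf(self):
        tree = sio.read_newick("((A,B),(C,D));", rooted=True)
        states = pd.DataFrame({"f": {"A": 1, "B": 0, "C": 0, "D": 0}})
        rep = cp.fitch_ancestral(tree, states)
        assert rep.change_counts["f"] == 1
        assert brute_fitch(tree, {"A": 1, "B": 0, "C": 0, "D": 0}) == 1

    def test_sister_pair_gain_on_stem(self):
        tree = sio.read_newick("((((A,B)ab,C)abc,D)abcd,E)root;", rooted=True)
        states = pd.DataFrame({"f": {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0}})
        rep = cp.fitch_ancestral(tree, states)
        assert rep.change_counts["f"] == 1
        gains = rep.branch_events.query("event == 'gain'")
        assert list(gains["child"]) == ["ab"]

    def test_ambiguity_surfaced_not_resolved(self):
        # balanced quartet with one derived pair: the root is genuinely
        # ambiguous (gain on one stem vs loss on the other)
        tree = sio.read_newick("((A,B),(C,D));", rooted=True)
        states = pd.DataFrame({"f": {"A": 1, "B": 1, "C": 0, "D": 0}})
        rep = cp.fitch_ancestral(tree, states)
        assert rep.change_counts["f"] == 1
        root_label = [
            lbl for lbl, s in rep.node_states["f"].items() if len(s) == 2
        ]
        assert root_label  # at least one ambiguous node reported
        assert (rep.branch_events["event"] == "ambiguous").any()

    def test_matches_exhaustive_minimisation_on_random_trees(self, rng):
        for i in range(15):
            n = int(rng.integers(4, 9))
            labels = [f"L{j}" for j in range(n)]
            tree = random_tree(labels, np.random.default_rng(100 + i))
            states = {lbl: int(rng.integers(0, 2)) for lbl in labels}
            rep = cp.fitch_ancestral(tree, pd.DataFrame({"f": states}))
            assert rep.change_counts["f"] == brute_fitch(tree, states)

    def test_lineage_summary_relative_to_ancestor(self):
        tree = sio.read_newick("(((A,B)ab,C)abc,D)root;", rooted=True)
        states = pd.DataFrame({"f": {"A": 1, "B": 1, "C": 0, "D": 0}})
        rep = cp.fitch_ancestral(tree, states, ancestor="root")
        row = rep.lineage_summary.query("leaf == 'A'").iloc[0]
        assert row["gains"] == 1 and row["losses"] == 0

    def test_unrooted_tree_rejected(self):
        tree = sio.read_newick("((A,B),(C,D));", rooted=False)
        with pytest.raises(ValueError):
            cp.fitch_ancestral(tree, pd.DataFrame({"f": {"A": 1, "B": 0, "C": 0, "D": 0}}))

    def test_missing_leaf_state_rejected(self):
        tree = sio.read_newick("((A,B),(C,D));", rooted=True)
        with pytest.raises(ValueError):
            cp.fitch_ancestral(tree, pd.DataFrame({"f": {"A": 1, "B": 0, "C": 0}}))


class TestRFCongruence:
    def test_identical_topologies(self):
        t1 = sio.read_newick("((A,B),(C,(D,E)));")
        t2 = sio.read_newick("((A,B),(C,(D,E)));")
        rf, congruent = cp.rf_congruence(t1, t2, "A")
        assert rf == 0 and congruent

    def test_known_rf_two(self):
        # {A,B} vs {A,C} each unmatched; {D,E} shared
        t1 = sio.read_newick("((A,B),C,(D,E));")
        t2 = sio.read_newick("((A,C),B,(D,E));")
        assert cp.rf_distance(t1, t2) == 2
        assert brute_rf(t1, t2) == 2

    def test_congruent_despite_distant_rearrangement(self):
        # focal taxon A keeps sister B; rearrangement among C/D/E/F only
        t1 = sio.read_newick("((A,B),((C,D),(E,F)));")
        t2 = sio.read_newick("((A,B),((C,E),(D,F)));")
        rf, congruent = cp.rf_congruence(t1, t2, "A")
        assert congruent and rf > 0

    def test_incongruent_focal_placement(self):
        t1 = sio.read_newick("((A,B),(C,(D,E)));")
        t2 = sio.read_newick("((A,C),(B,(D,E)));")
        _rf, congruent = cp.rf_congruence(t1, t2, "A")
        assert not congruent

    def test_pruned_to_shared_leaves(self):
        # extra taxon X in tree1 must not affect congruence
        t1 = sio.read_newick("(((A,X),B),(C,(D,E)));")
        t2 = sio.read_newick("((A,B),(C,(D,E)));")
        rf, congruent = cp.rf_congruence(t1, t2, "A")
        assert rf == 0 and congruent

    def test_metric_properties_against_brute_force(self, rng):
        labels = [f"L{j}" for j in range(7)]
        for i in range(10):
            t1 = random_tree(labels, np.random.default_rng(i))
            t2 = random_tree(labels, np.random.default_rng(1000 + i))
            d12 = cp.rf_distance(t1, t2)
            assert d12 == brute_rf(t1, t2)
            assert cp.rf_distance(t2, t1) == d12
            assert cp.rf_distance(t1, t1) == 0

    def test_too_few_shared_leaves_rejected(self):
        t1 = sio.read_newick("((A,B),C);")
        t2 = sio.read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            cp.rf_congruence(t1, t2, "A")

    def test_missing_focal_rejected(self):
        t1 = sio.read_newick("((A,B),(C,D));")
        t2 = sio.read_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            cp.rf_congruence(t1, t2, "Z")
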