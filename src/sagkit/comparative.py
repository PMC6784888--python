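"""Comparative-genomics screens for single-cell fungal genome sets.

Covers the downstream analyses run once genomes are annotated: the
core-metabolism deficiency filter (enzymes conserved in free-living fungi
but absent from several unculturable targets), CAZyme-to-protease ratio
regressions by lifestyle, single-copy orthogroup selection for supermatrix
phylogenomics, exact binary-character parsimony for ancestral gains/losses,
and Robinson–Foulds congruence of per-library trees against a reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PresenceAbsenceMatrix:
    """Binary functions × species matrix with a lifestyle role per species.

    `data` rows are functions (e.g. EC numbers), columns are species;
    `roles` labels every species either "free_living" or "target".
    """

    data: pd.DataFrame
    roles: pd.Series

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("presence/absence matrix must be strictly binary")
        missing = set(self.data.columns) - set(self.roles.index)
        if missing:
            raise ValueError(f"species without a role: {sorted(missing)}")
        bad = set(self.roles.unique()) - {"free_living", "target"}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    @property
    def free_living(self) -> list[str]:
        return [s for s in self.data.columns if self.roles[s] == "free_living"]

    @property
    def targets(self) -> list[str]:
        return [s for s in self.data.columns if self.roles[s] == "target"]


def deficiency_screen(
    matrix: PresenceAbsenceMatrix,
    core_frac: float = 0.75,
    min_absent_targets: int = 5,
) -> pd.DataFrame:
    """Flag core enzymes that several target genomes lack.

    An enzyme is *core* when it is present in at least ceil(core_frac × n)
    of the n free-living species; it is *deficient* when it is core and
    absent from at least `min_absent_targets` target genomes.  Returns a
    per-function report with columns free_living_presence, target_absent,
    core, deficient.
    """
    fl = matrix.free_living
    tg = matrix.targets
    if not fl or not tg:
        raise ValueError("both free-living and target species are required")
    core_threshold = math.ceil(core_frac * len(fl))
    fl_presence = matrix.data[fl].sum(axis=1)
    tg_absent = len(tg) - matrix.data[tg].sum(axis=1)
    core = fl_presence >= core_threshold
    deficient = core & (tg_absent >= min_absent_targets)
    return pd.DataFrame(
        {
            "free_living_presence": fl_presence,
            "target_absent": tg_absent,
            "core": core,
            "deficient": deficient,
        }
    )


def core_threshold(n_free_living: int, core_frac: float = 0.75) -> int:
    """Presence count needed for core status: ceil(core_frac × n)."""
    return math.ceil(core_frac * n_free_living)


def ratio_regression(
    counts: pd.DataFrame,
    min_n: int = 3,
    min_r2: float = 0.3,
) -> pd.DataFrame:
    """Per-lifestyle OLS of CAZyme totals on protease totals.

    `counts` needs columns cazyme_total, protease_total, lifestyle (one row
    per species).  A lifestyle's trend line is excluded (included = False)
    when it has fewer than `min_n` species or its fit has r² < `min_r2`;
    slope/intercept/r² are still reported whenever a fit is possible.
    """
    required = {"cazyme_total", "protease_total", "lifestyle"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts must have columns {sorted(required)}")
    if (counts[["cazyme_total", "protease_total"]].to_numpy() < 0).any():
        raise ValueError("totals must be non-negative")
    rows = []
    for lifestyle, grp in counts.groupby("lifestyle", sort=True):
        n = len(grp)
        slope = intercept = r2 = float("nan")
        if n >= 2:
            x = grp["protease_total"].to_numpy(float)
            y = grp["cazyme_total"].to_numpy(float)
            if np.ptp(x) == 0:
                raise ValueError(
                    f"zero-variance protease totals within lifestyle {lifestyle!r}"
                )
            fit = stats.linregress(x, y)
            slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
        included = n >= min_n and np.isfinite(r2) and r2 >= min_r2
        rows.append(
            {
                "lifestyle": lifestyle,
                "n": n,
                "slope": slope,
                "intercept": intercept,
                "r_squared": r2,
                "included": included,
            }
        )
    return pd.DataFrame(rows).set_index("lifestyle")


# ---------------------------------------------------------------------------
# Orthogroup selection and supermatrix statistics


@dataclass
class OrthoClusterSet:
    """Cluster → per-species gene copy counts, with optional alignment lengths.

    `truth` carries generator-side ground truth (n_missing, max_copies) when
    the set was simulated; it is never consulted by the selection logic.
    """

    counts: pd.DataFrame  # clusters × species, integer copy counts
    lengths: pd.Series | None = None
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("copy counts must be non-negative")

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)


def select_single_copy_clusters(
    clusters: OrthoClusterSet,
    panel_size: int | None = None,
    max_missing: int = 8,
    min_taxa: int = 3,
) -> list[str]:
    """Select clusters usable in a single-copy supermatrix.

    A cluster qualifies when every present species has exactly one copy,
    at most `max_missing` of the `panel_size` species are absent, and at
    least `min_taxa` species are present.
    """
    counts = clusters.counts
    panel = panel_size if panel_size is not None else counts.shape[1]
    if max_missing >= panel:
        raise ValueError("max_missing must be smaller than the panel size")
    arr = counts.to_numpy()
    single = (arr <= 1).all(axis=1)
    n_present = (arr > 0).sum(axis=1)
    ok = single & (panel - n_present <= max_missing) & (n_present >= min_taxa)
    return list(counts.index[ok])


def supermatrix_stats(
    clusters: OrthoClusterSet,
    selected: list[str] | None = None,
    groups: pd.Series | None = None,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-taxon missing-data fractions of the concatenated supermatrix.

    For each taxon: (sum of alignment lengths of selected clusters lacking
    it) / (total selected alignment length).  When `groups` maps species to
    group labels, per-group medians are returned alongside.
    """
    if clusters.lengths is None:
        raise ValueError("cluster alignment lengths are required")
    ids = selected if selected is not None else list(clusters.counts.index)
    if not ids:
        raise ValueError("no selected clusters")
    counts = clusters.counts.loc[ids]
    lengths = clusters.lengths.loc[ids].astype(float)
    if (lengths <= 0).any():
        raise ValueError("alignment lengths must be positive")
    total = lengths.sum()
    absent = (counts == 0).astype(float)
    missing_frac = absent.mul(lengths, axis=0).sum(axis=0) / total
    missing_frac.name = "missing_fraction"
    medians: dict[str, float] = {}
    if groups is not None:
        for g, members in groups.groupby(groups):
            medians[str(g)] = float(missing_frac[members.index].median())
    return missing_frac, medians


# ---------------------------------------------------------------------------
# Ancestral state reconstruction (binary small parsimony)


@dataclass
class AncestralReport:
    """Exact parsimony reconstruction of binary characters on a rooted tree.

    change_counts: parsimony minimum per function.
    node_states: function → {node label → MPR state set} (frozenset of 0/1;
        two-element sets mark genuinely ambiguous nodes).
    branch_events: rows (function, child, event) with event in
        {"gain", "loss", "ambiguous"}; a branch is ambiguous when either
        endpoint has more than one most-parsimonious state.
    lineage_summary: per-leaf definite gains/losses (and ambiguous branches)
        on the path from the named ancestor, when one was given.
    """

    change_counts: pd.Series
    node_states: dict[str, dict[str, frozenset]]
    branch_events: pd.DataFrame
    lineage_summary: pd.DataFrame | None = None


def _node_label(node: dendropy.Node, idx: int) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return f"__node{idx}"


def fitch_ancestral(
    tree: dendropy.Tree,
    states: pd.DataFrame,
    ancestor: str | None = None,
) -> AncestralReport:
    """Minimum-change ancestral reconstruction for 0/1 characters.

    `states` is a leaves × functions frame of 0/1 values; every leaf of the
    (rooted) tree must appear in its index.  Change counts are the exact
    parsimony minima (Sankoff dynamic programming with unit costs, valid for
    polytomies); per-node state sets are the full most-parsimonious-
    reconstruction sets, so ambiguity is surfaced rather than resolved.
    When `ancestor` names an internal node, gains and losses in each leaf
    lineage are totted up relative to that node.
    """
    if not tree.is_rooted:
        raise ValueError("ancestral reconstruction requires a rooted tree")
    leaves = [lf for lf in tree.leaf_node_iter()]
    leaf_labels = [lf.taxon.label for lf in leaves]
    if any(lbl is None for lbl in leaf_labels):
        raise ValueError("every leaf must be labelled")
    missing = set(leaf_labels) - set(states.index)
    if missing:
        raise ValueError(f"leaves without states: {sorted(missing)}")

    nodes = list(tree.preorder_node_iter())
    labels = {id(n): _node_label(n, i) for i, n in enumerate(nodes)}
    postorder = list(tree.postorder_node_iter())
    INF = float("inf")

    change_counts: dict[str, int] = {}
    node_states: dict[str, dict[str, frozenset]] = {}
    events_rows: list[dict] = []
    lineage_rows: list[dict] = []

    ancestor_node = None
    if ancestor is not None:
        for n in nodes:
            if labels[id(n)] == ancestor:
                ancestor_node = n
                break
        if ancestor_node is None:
            raise ValueError(f"no node labelled {ancestor!r}")

    for fn in states.columns:
        leaf_state = {lbl: int(states.loc[lbl, fn]) for lbl in leaf_labels}
        if any(v not in (0, 1) for v in leaf_state.values()):
            raise ValueError(f"character {fn!r} is not binary")
        # down-pass: c[v][s] = min changes in v's subtree with v in state s
        c: dict[int, list[float]] = {}
        for v in postorder:
            if v.is_leaf():
                s = leaf_state[v.taxon.label]
                c[id(v)] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
            else:
                cost = [0.0, 0.0]
                for ch in v.child_nodes():
                    cc = c[id(ch)]
                    for s in (0, 1):
                        cost[s] += min(cc[s], cc[1 - s] + 1)
                c[id(v)] = cost
        root = tree.seed_node
        best = min(c[id(root)])
        change_counts[fn] = int(best)
        # up-pass: r[v][s] = best cost of everything outside v's subtree,
        # given v in state s (includes the v--parent branch)
        r: dict[int, list[float]] = {id(root): [0.0, 0.0]}
        for v in nodes:
            if v is root:
                continue
            p = v.parent_node
            cv = c[id(v)]
            rp = r[id(p)]
            cp_minus = [
                c[id(p)][s] - min(cv[s], cv[1 - s] + 1) for s in (0, 1)
            ]
            r[id(v)] = [
                min(rp[sp] + cp_minus[sp] + (0 if s == sp else 1) for sp in (0, 1))
                for s in (0, 1)
            ]
        mpr: dict[int, frozenset] = {}
        for v in nodes:
            tot = [c[id(v)][s] + r[id(v)][s] for s in (0, 1)]
            mpr[id(v)] = frozenset(s for s in (0, 1) if tot[s] == best)
        node_states[fn] = {labels[id(v)]: mpr[id(v)] for v in nodes}
        # branch events (definite only when both endpoints unambiguous)
        for v in nodes:
            if v is root:
                continue
            sp, sv = mpr[id(v.parent_node)], mpr[id(v)]
            if len(sp) == 1 and len(sv) == 1:
                a, b = next(iter(sp)), next(iter(sv))
                if a == b:
                    continue
                event = "gain" if b == 1 else "loss"
            else:
                event = "ambiguous"
            events_rows.append({"function": fn, "child": labels[id(v)], "event": event})
        if ancestor_node is not None:
            for lf in leaves:
                gains = losses = ambig = 0
                v = lf
                on_path = False
                while v is not None:
                    if v is ancestor_node:
                        on_path = True
                        break
                    p = v.parent_node
                    if p is None:
                        break
                    sp, sv = mpr[id(p)], mpr[id(v)]
                    if len(sp) == 1 and len(sv) == 1:
                        a, b = next(iter(sp)), next(iter(sv))
                        if a != b:
                            if b == 1:
                                gains += 1
                            else:
                                losses += 1
                    else:
                        ambig += 1
                    v = p
                if on_path:
                    lineage_rows.append(
                        {
                            "function": fn,
                            "leaf": lf.taxon.label,
                            "gains": gains,
                            "losses": losses,
                            "ambiguous_branches": ambig,
                        }
                    )

    events = pd.DataFrame(events_rows, columns=["function", "child", "event"])
    lineage = (
        pd.DataFrame(
            lineage_rows,
            columns=["function", "leaf", "gains", "losses", "ambiguous_branches"],
        )
        if ancestor is not None
        else None
    )
    return AncestralReport(
        change_counts=pd.Series(change_counts, name="changes"),
        node_states=node_states,
        branch_events=events,
        lineage_summary=lineage,
    )


# ---------------------------------------------------------------------------
# Tree congruence


def _pruned_copy(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.retain_taxa_with_labels(sorted(keep))
    return t


def _sister_group(tree: dendropy.Tree, focal: str) -> frozenset:
    """Leaves of the minimal clade containing the focal leaf, minus itself."""
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == focal:
            leaf = lf
            break
    if leaf is None or leaf.parent_node is None:
        raise ValueError(f"focal taxon {focal!r} not found")
    parent = leaf.parent_node
    return frozenset(
        lf.taxon.label for lf in parent.leaf_iter() if lf.taxon.label != focal
    )


def rf_distance(tree1: dendropy.Tree, tree2: dendropy.Tree) -> int:
    """Unrooted Robinson–Foulds distance (symmetric bipartition difference)."""
    ns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(
        data=tree1.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    t2 = dendropy.Tree.get(
        data=tree2.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    t1.is_rooted = False
    t2.is_rooted = False
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))


def rf_congruence(
    tree1: dendropy.Tree, tree2: dendropy.Tree, focal_taxon: str
) -> tuple[int, bool]:
    """Compare a library tree against a reference for one focal taxon.

    Both trees are pruned to their shared leaves; the Robinson–Foulds
    distance is reported alongside a congruence flag that is True when the
    focal taxon's sister group (the other leaves of the minimal clade
    containing it) is identical in both pruned trees.
    """
    leaves1 = {lf.taxon.label for lf in tree1.leaf_node_iter()}
    leaves2 = {lf.taxon.label for lf in tree2.leaf_node_iter()}
    shared = leaves1 & leaves2
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared leaves, got {len(shared)}")
    if focal_taxon not in shared:
        raise ValueError(f"focal taxon {focal_taxon!r} must be in both trees")
    p1 = _pruned_copy(tree1, shared)
    p2 = _pruned_copy(tree2, shared)
    rf = rf_distance(p1, p2)
    congruent = _sister_group(p1, focal_taxon) == _sister_group(p2, focal_taxon)
    return rf, congruent


def pairwise_congruence_rate(
    library_trees: dict[str, dendropy.Tree],
    reference: dendropy.Tree,
    focal_taxa: dict[str, str],
) -> pd.DataFrame:
    """Run rf_congruence for each library tree against the reference."""
    rows = []
    for lib, tree in library_trees.items():
        rf, congruent = rf_congruence(tree, reference, focal_taxa[lib])
        rows.append({"library": lib, "rf": rf, "congruent": congruent})
    return pd.DataFrame(rows).set_index("library")
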