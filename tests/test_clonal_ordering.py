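"""Containment-rule ancestry: worked cases, exhaustive oracle, Newick export."""

import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonarch.clonal_ordering import (
    Dendrogram,
    DendroNode,
    MutationZoneMatrix,
    build_matrix,
    cohort_heterogeneity,
    heterogeneity_fraction,
    infer_ancestry,
    to_newick,
)
from clonarch.somatic_calling import SomaticCall


def matrix_from_sets(zone_sets, mutations=None, lesion="lesion"):
    zones = list(zone_sets)
    if mutations is None:
        mutations = sorted(set().union(*map(set, zone_sets.values())))
    presence = np.array(
        [[m in zone_sets[z] for m in mutations] for z in zones], dtype=bool
    ).reshape(len(zones), len(mutations))
    return MutationZoneMatrix(lesion=lesion, zones=zones, mutations=list(mutations), presence=presence)


def node_by_zone(dendro, zone):
    for node in dendro.nodes():
        if zone in node.zones:
            return node
    raise AssertionError(f"{zone} missing from dendrogram")


class TestBuildMatrix:
    def call(self, gene, pos, alt="A", zone_fa=10.0):
        return SomaticCall("ctg", pos, "G", alt, gene=gene, consequence="missense",
                           fractional_abundance=zone_fa)

    def test_single_zone_all_true(self):
        matrix = build_matrix({"Z1": [self.call("EGFR", 1), self.call("TP53", 2)]})
        assert matrix.presence.all() and matrix.presence.shape == (1, 2)

    def test_shared_call_single_column(self):
        shared = self.call("EGFR", 1)
        matrix = build_matrix({"Z1": [shared], "Z2": [shared, self.call("TP53", 2)]})
        assert len(matrix.mutations) == 2
        frame = matrix.to_frame()
        assert frame.loc["Z1"].sum() == 1 and frame.loc["Z2"].sum() == 2

    def test_rejected_calls_excluded(self):
        silent = SomaticCall("ctg", 3, "G", "A", gene="KRAS", consequence="silent",
                             status="rejected", reason="consequence")
        matrix = build_matrix({"Z1": [self.call("EGFR", 1), silent]})
        assert matrix.mutations == ["EGFR|ctg:1G>A"]


class TestInferAncestry:
    def test_forced_chain_by_containment(self):
        dendro = infer_ancestry(matrix_from_sets({"Z1": {"a"}, "Z2": {"a", "b"}, "Z3": {"a", "b", "c"}}))
        assert node_by_zone(dendro, "Z1") is dendro.root
        z2, z3 = node_by_zone(dendro, "Z2"), node_by_zone(dendro, "Z3")
        assert z2.gained == {"b"} and z3.gained == {"c"}
        assert dendro.ancestor_pairs() == {("Z1", "Z2"), ("Z1", "Z3"), ("Z2", "Z3")}

    def test_inferred_common_precursor(self):
        dendro = infer_ancestry(matrix_from_sets({"Z1": {"a", "b"}, "Z2": {"a", "c"}}))
        assert dendro.root.inferred and dendro.root.mutations == {"a"}
        assert node_by_zone(dendro, "Z1").gained == {"b"}
        assert node_by_zone(dendro, "Z2").gained == {"c"}

    def test_empty_zone_parallel_branch_at_root(self):
        dendro = infer_ancestry(matrix_from_sets({"Z1": set(), "Z2": {"a"}}, mutations=["a"]))
        z1, z2 = node_by_zone(dendro, "Z1"), node_by_zone(dendro, "Z2")
        assert dendro.root.mutations == frozenset()
        assert z1 in dendro.root.children or z1 is dendro.root
        assert z2.gained == {"a"}
        # Z1 is a parallel branch: no ancestry between Z1 and Z2 either way
        assert dendro.ancestor_pairs() == set()

    def test_empty_as_ancestor_switch(self):
        matrix = matrix_from_sets({"Z1": set(), "Z2": {"a"}}, mutations=["a"])
        dendro = infer_ancestry(matrix, empty_as_ancestor=True)
        assert ("Z1", "Z2") in dendro.ancestor_pairs()

    def test_equal_sets_merge_into_clade(self):
        dendro = infer_ancestry(matrix_from_sets({"Z1": {"a"}, "Z2": {"a"}, "Z3": {"a", "b"}}))
        clade = node_by_zone(dendro, "Z1")
        assert set(clade.zones) == {"Z1", "Z2"}
        assert node_by_zone(dendro, "Z3").gained == {"b"}

    def test_superset_monotonicity_validated(self):
        bad = Dendrogram(
            lesion="x",
            root=DendroNode(label="r", zones=("Z1",), mutations=frozenset({"a"}),
                            children=[DendroNode(label="c", zones=("Z2",), mutations=frozenset())]),
        )
        with pytest.raises(ValueError, match="superset"):
            bad.validate()


def brute_force_ancestry(zone_sets):
    """Naive, standalone re-application of the containment/precursor rule.

    Returns the same canonical nested form as Dendrogram.canonical():
    (sorted zones, sorted mutations, sorted children).  Kept deliberately
    separate from the production implementation (plain dicts, no classes,
    recomputing everything at each step).
    """
    empties = sorted(z for z in zone_sets if not zone_sets[z])
    groups = {}
    for z in sorted(zone_sets):
        s = frozenset(zone_sets[z])
        if s:
            groups.setdefault(s, []).append(z)
    items = [
        {"set": s, "zones": tuple(sorted(groups[s])), "children": []}
        for s in sorted(groups, key=lambda s: tuple(sorted(s)))
    ]
    while len(items) > 1:
        best = None
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                inter = items[i]["set"] & items[j]["set"]
                pair_key = tuple(sorted((tuple(sorted(items[i]["set"])), tuple(sorted(items[j]["set"])))))
                cand = (-len(inter), pair_key)
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        _, i, j = best
        a, b = items[i], items[j]
        inter = a["set"] & b["set"]
        rest = [items[k] for k in range(len(items)) if k not in (i, j)]
        if inter == a["set"] and inter == b["set"]:
            merged = {"set": inter, "zones": tuple(sorted(a["zones"] + b["zones"])),
                      "children": a["children"] + b["children"]}
        elif inter == a["set"]:
            merged = {"set": a["set"], "zones": a["zones"], "children": a["children"] + [b]}
        elif inter == b["set"]:
            merged = {"set": b["set"], "zones": b["zones"], "children": b["children"] + [a]}
        else:
            merged = {"set": inter, "zones": (), "children": [a, b]}
        items = rest + [merged]
    root = items[0] if items else None
    empty_items = [{"set": frozenset(), "zones": (z,), "children": []} for z in empties]
    if empty_items:
        if root is None:
            root = empty_items[0] if len(empty_items) == 1 else {
                "set": frozenset(), "zones": (), "children": empty_items}
        elif not root["set"]:
            root = {"set": root["set"], "zones": root["zones"],
                    "children": root["children"] + empty_items}
        else:
            root = {"set": frozenset(), "zones": (), "children": [root] + empty_items}

    def canon(item):
        kids = tuple(sorted(canon(c) for c in item["children"]))
        return (tuple(sorted(item["zones"])), tuple(sorted(item["set"])), kids)

    return canon(root)


def test_exhaustive_four_zone_three_mutation_oracle():
    """Every 4-zone x 3-mutation presence matrix yields the same tree as the
    brute-force rule application (4096 cases)."""
    zones = ["Z1", "Z2", "Z3", "Z4"]
    muts = ["a", "b", "c"]
    for bits in itertools.product([0, 1], repeat=12):
        grid = np.array(bits, dtype=bool).reshape(4, 3)
        zone_sets = {z: {m for m, flag in zip(muts, row) if flag} for z, row in zip(zones, grid)}
        matrix = matrix_from_sets(zone_sets, mutations=muts)
        dendro = infer_ancestry(matrix)
        assert dendro.canonical() == brute_force_ancestry(zone_sets), zone_sets


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    bits=st.lists(st.booleans(), min_size=12, max_size=12),
    perm=st.permutations(["Z1", "Z2", "Z3", "Z4"]),
)
def test_relabeling_zones_permutes_but_preserves_topology(bits, perm):
    zones = ["Z1", "Z2", "Z3", "Z4"]
    muts = ["a", "b", "c"]
    grid = np.array(bits, dtype=bool).reshape(4, 3)
    zone_sets = {z: {m for m, flag in zip(muts, row) if flag} for z, row in zip(zones, grid)}
    base = infer_ancestry(matrix_from_sets(zone_sets, mutations=muts))
    relabeled = {new: zone_sets[old] for old, new in zip(zones, perm)}
    inverse = {new: old for old, new in zip(zones, perm)}
    permuted = infer_ancestry(matrix_from_sets(relabeled, mutations=muts))

    def canon_mapped(node):
        kids = tuple(sorted(canon_mapped(c) for c in node.children))
        return (tuple(sorted(inverse[z] for z in node.zones)), tuple(sorted(node.mutations)), kids)

    assert canon_mapped(permuted.root) == base.canonical()


class TestHeterogeneity:
    def test_all_ubiquitous_is_zero(self):
        matrix = matrix_from_sets({"Z1": {"a", "b"}, "Z2": {"a", "b"}})
        assert heterogeneity_fraction(matrix) == 0.0

    def test_one_truncal_two_private(self):
        matrix = matrix_from_sets({"Z1": {"t", "p1"}, "Z2": {"t", "p2"}})
        assert heterogeneity_fraction(matrix) == 67.0  # 2/3 -> 66.7 -> 67

    def test_seventeen_of_twentyone(self):
        zone_sets = {
            "Z1": {f"m{i}" for i in range(4)} | {f"p{i}" for i in range(9)},
            "Z2": {f"m{i}" for i in range(4)} | {f"q{i}" for i in range(8)},
        }
        matrix = matrix_from_sets(zone_sets)
        assert len(matrix.mutations) == 21
        assert heterogeneity_fraction(matrix) == 81.0

    def test_zero_mutations_undefined(self):
        matrix = matrix_from_sets({"Z1": set()}, mutations=[])
        with pytest.raises(ValueError):
            heterogeneity_fraction(matrix)
        with pytest.raises(ValueError):
            cohort_heterogeneity([matrix])


class TestNewick:
    def test_chain_form(self):
        dendro = infer_ancestry(matrix_from_sets({"Z1": {"a"}, "Z2": {"a", "b"}}))
        assert to_newick(dendro) == "((Z2:1)Z1:0);"

    def test_single_zone(self):
        dendro = infer_ancestry(matrix_from_sets({"Z1": {"a"}}, mutations=["a"]))
        assert to_newick(dendro) == "(Z1:0);"

    def test_roundtrip_through_reference_parser(self):
        """A 4-zone two-sided topology survives a dendropy parse: labels,
        edge lengths and the nested structure all reconstruct."""
        zone_sets = {
            "Z1": {"t", "b1", "p1"},
            "Z2": {"t", "b1"},
            "Z3": {"t", "b2", "p3"},
            "Z4": {"t", "b2"},
        }
        dendro = infer_ancestry(matrix_from_sets(zone_sets))
        text = to_newick(dendro)
        tree = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=False)

        by_label = {}
        for node in tree:
            label = node.taxon.label if node.taxon else node.label
            if label:
                by_label[label] = node
        ours = {n.label: n for n in dendro.nodes()}
        assert set(by_label) >= set(ours)
        for label, node in ours.items():
            parsed = by_label[label]
            expected_len = 0 if node is dendro.root else len(node.gained)
            assert int(parsed.edge.length or 0) == expected_len

        def canon_parsed(node):
            label = node.taxon.label if node.taxon else node.label
            kids = tuple(sorted(canon_parsed(c) for c in node.child_nodes()))
            return (label or "", kids)

        def canon_ours(node):
            kids = tuple(sorted(canon_ours(c) for c in node.children))
            return (node.label, kids)

        # dendropy wraps our single root in its seed node
        (seed_child,) = tree.seed_node.child_nodes()
        assert canon_parsed(seed_child) == canon_ours(dendro.root)
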