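"""Clonal ordering across lesion zones from mutation presence sets.

The ancestry rule is pure set containment: a zone whose mutation set is a
strict subset of another zone's is its ancestor; zones with identical
non-empty sets merge into a single clade; where no zone qualifies as an
ancestor, a putative precursor is inferred carrying the mutations common to
the zones it joins, grouping zones that share the largest common subsets
first.  Zones with no alterations attach as parallel branches at the root by
default (an ``empty_as_ancestor`` switch instead places them as the common
ancestor of the mutated zones).

Also provides the intratumor-heterogeneity statistic: the percentage of
mutations not detectable in every zone of a lesion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import round_half_up
from .somatic_calling import SomaticCall


@dataclass
class MutationZoneMatrix:
    """Zones x mutations boolean presence matrix for one lesion."""

    lesion: str
    zones: list[str]
    mutations: list[str]
    presence: np.ndarray  # bool, shape (n_zones, n_mutations)

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if len(set(self.zones)) != len(self.zones):
            raise ValueError("duplicate zone labels")
        if len(set(self.mutations)) != len(self.mutations):
            raise ValueError("duplicate mutation labels")
        if self.presence.shape != (len(self.zones), len(self.mutations)):
            raise ValueError("presence matrix shape does not match labels")

    def zone_sets(self) -> dict[str, frozenset[str]]:
        return {
            zone: frozenset(m for m, flag in zip(self.mutations, row) if flag)
            for zone, row in zip(self.zones, self.presence)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence.astype(int), index=self.zones, columns=self.mutations)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, lesion: str = "lesion") -> "MutationZoneMatrix":
        return cls(
            lesion=lesion,
            zones=[str(z) for z in frame.index],
            mutations=[str(m) for m in frame.columns],
            presence=frame.to_numpy(dtype=bool),
        )


def mutation_label(call: SomaticCall) -> str:
    gene = call.gene or "?"
    return f"{gene}|{call.contig}:{call.pos}{call.ref}>{call.alt}"


def build_matrix(
    calls_per_zone: Mapping[str, Iterable[SomaticCall]],
    lesion: str = "lesion",
) -> MutationZoneMatrix:
    """Presence matrix over accepted, non-synonymous calls.

    Mutation identity is (gene, locus, ref, alt), so the same alteration
    called independently in two zones lands in a single column.  Rejected
    calls -- including silent and intronic ones -- never enter the matrix.
    """
    if not calls_per_zone:
        raise ValueError("need at least one zone")
    zones = list(calls_per_zone)
    per_zone_labels: dict[str, set[str]] = {}
    for zone, calls in calls_per_zone.items():
        per_zone_labels[zone] = {mutation_label(c) for c in calls if c.accepted}
    mutations = sorted(set().union(*per_zone_labels.values())) if per_zone_labels else []
    presence = np.array(
        [[m in per_zone_labels[z] for m in mutations] for z in zones], dtype=bool
    ).reshape(len(zones), len(mutations))
    return MutationZoneMatrix(lesion=lesion, zones=zones, mutations=mutations, presence=presence)


# ----------------------------------------------------------------------
# dendrogram
# ----------------------------------------------------------------------

@dataclass
class DendroNode:
    label: str
    zones: tuple[str, ...]                 # empty for inferred ancestors
    mutations: frozenset[str]
    children: list["DendroNode"] = field(default_factory=list)
    gained: frozenset[str] = frozenset()   # relative to parent; empty at root

    @property
    def inferred(self) -> bool:
        return not self.zones

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Dendrogram:
    lesion: str
    root: DendroNode

    def nodes(self) -> list[DendroNode]:
        return list(self.root.walk())

    def validate(self) -> None:
        seen_zones: list[str] = []
        seen_ids: set[int] = set()
        stack = [(self.root, None)]
        while stack:
            node, parent = stack.pop()
            if id(node) in seen_ids:
                raise ValueError("dendrogram contains a cycle or shared node")
            seen_ids.add(id(node))
            seen_zones.extend(node.zones)
            if parent is not None:
                if not node.mutations >= parent.mutations:
                    raise ValueError(f"node {node.label} is not a superset of its parent")
                if node.gained != node.mutations - parent.mutations:
                    raise ValueError(f"node {node.label}: edge gains inconsistent")
            for child in node.children:
                stack.append((child, node))
        if len(seen_zones) != len(set(seen_zones)):
            raise ValueError("a zone appears more than once")

    def ancestor_pairs(self) -> set[tuple[str, str]]:
        """All (ancestor zone, descendant zone) pairs implied by the topology.

        Zones merged in one clade are mutual ancestors of none; descent is
        strict (proper containment along the tree).
        """
        pairs: set[tuple[str, str]] = set()

        def descend(node: DendroNode, ancestors: tuple[str, ...]):
            for a in ancestors:
                for z in node.zones:
                    pairs.add((a, z))
            nxt = ancestors + node.zones
            for child in node.children:
                descend(child, nxt)

        descend(self.root, ())
        return pairs

    def canonical(self):
        """Label-free nested canonical form, for topology comparison."""

        def canon(node: DendroNode):
            kids = tuple(sorted(canon(c) for c in node.children))
            return (tuple(sorted(node.zones)), tuple(sorted(node.mutations)), kids)

        return canon(self.root)

    def to_json(self) -> str:
        def encode(node: DendroNode):
            return {
                "label": node.label,
                "zones": list(node.zones),
                "mutations": sorted(node.mutations),
                "gained": sorted(node.gained),
                "children": [encode(c) for c in node.children],
            }

        return json.dumps({"lesion": self.lesion, "root": encode(self.root)}, indent=2)


def _pair_key(a: DendroNode, b: DendroNode):
    """Deterministic, zone-label-free ordering key for candidate merges."""
    return tuple(sorted((tuple(sorted(a.mutations)), tuple(sorted(b.mutations)))))


def infer_ancestry(matrix: MutationZoneMatrix, empty_as_ancestor: bool = False) -> Dendrogram:
    """Infer the branched-evolution dendrogram for one lesion.

    Agglomerative application of the containment rule: repeatedly join the
    pair of clusters sharing the largest common mutation set.  If one
    cluster's set equals the intersection it is the ancestor; if both equal
    it they merge into a clade; otherwise an inferred precursor node holding
    the intersection is created.  Ties are broken on canonical mutation-set
    keys, so the topology is invariant under zone relabeling.
    """
    zone_sets = matrix.zone_sets()
    empty_zones = sorted(z for z, s in zone_sets.items() if not s)
    nonempty = {z: s for z, s in zone_sets.items() if s}

    groups: dict[frozenset, list[str]] = {}
    for zone, s in sorted(nonempty.items()):
        groups.setdefault(s, []).append(zone)
    clusters = [
        DendroNode(label="", zones=tuple(sorted(zs)), mutations=s)
        for s, zs in sorted(groups.items(), key=lambda kv: tuple(sorted(kv[0])))
    ]

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                inter = a.mutations & b.mutations
                key = (-len(inter), _pair_key(a, b))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        a, b = clusters[i], clusters[j]
        inter = a.mutations & b.mutations
        if inter == a.mutations and inter == b.mutations:
            merged = DendroNode(
                label="",
                zones=tuple(sorted(a.zones + b.zones)),
                mutations=a.mutations,
                children=a.children + b.children,
            )
        elif inter == a.mutations:
            a.children.append(b)
            merged = a
        elif inter == b.mutations:
            b.children.append(a)
            merged = b
        else:
            merged = DendroNode(label="", zones=(), mutations=inter, children=[a, b])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)

    root = clusters[0] if clusters else None
    empty_nodes = [DendroNode(label="", zones=(z,), mutations=frozenset()) for z in empty_zones]

    if empty_as_ancestor and empty_nodes and root is not None:
        if not root.mutations:
            root = DendroNode(
                label="",
                zones=tuple(sorted(root.zones + tuple(empty_zones))),
                mutations=frozenset(),
                children=root.children,
            )
        else:
            root = DendroNode(
                label="", zones=tuple(sorted(empty_zones)), mutations=frozenset(), children=[root]
            )
    elif empty_nodes:
        if root is None:
            if len(empty_nodes) == 1:
                root = empty_nodes[0]
            else:
                root = DendroNode(label="", zones=(), mutations=frozenset(), children=empty_nodes)
        elif not root.mutations and root.inferred:
            root.children.extend(empty_nodes)
        elif not root.mutations:
            root.children.extend(empty_nodes)
        else:
            root = DendroNode(
                label="", zones=(), mutations=frozenset(), children=[root] + empty_nodes
            )

    _finalize(root)
    dendro = Dendrogram(lesion=matrix.lesion, root=root)
    dendro.validate()
    return dendro


def _finalize(root: DendroNode) -> None:
    """Assign gains, sort children deterministically and label nodes."""
    counter = 0

    def visit(node: DendroNode, parent: DendroNode | None):
        nonlocal counter
        node.gained = node.mutations - parent.mutations if parent else frozenset()
        if node.zones:
            node.label = "+".join(node.zones)
        else:
            counter += 1
            node.label = f"A{counter}"
        node.children.sort(key=lambda c: (tuple(sorted(c.mutations)), c.zones))
        for child in node.children:
            visit(child, node)

    visit(root, None)


# ----------------------------------------------------------------------
# heterogeneity statistics
# ----------------------------------------------------------------------

def heterogeneity_fraction(matrix: MutationZoneMatrix) -> float:
    """Percent of mutations not detectable across every zone of the lesion."""
    if not matrix.mutations:
        raise ValueError("heterogeneity undefined for a lesion with zero mutations")
    ubiquitous = matrix.presence.all(axis=0).sum()
    total = len(matrix.mutations)
    return round_half_up(100.0 * (total - ubiquitous) / total)


def cohort_heterogeneity(matrices: Iterable[MutationZoneMatrix]) -> float:
    """Pooled heterogeneity over several lesions: heterogeneous / all mutations."""
    total = heterogeneous = 0
    for matrix in matrices:
        total += len(matrix.mutations)
        heterogeneous += len(matrix.mutations) - int(matrix.presence.all(axis=0).sum())
    if total == 0:
        raise ValueError("heterogeneity undefined for a cohort with zero mutations")
    return round_half_up(100.0 * heterogeneous / total)


# ----------------------------------------------------------------------
# Newick export
# ----------------------------------------------------------------------

def to_newick(dendro: Dendrogram) -> str:
    """Serialize with zone labels as tips/internal labels and edge lengths
    equal to the number of mutations gained on the edge."""

    def render(node: DendroNode, length: int) -> str:
        if node.children:
            inner = ",".join(render(c, len(c.gained)) for c in node.children)
            return f"({inner}){node.label}:{length}"
        return f"{node.label}:{length}"

    return f"({render(dendro.root, 0)});"
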