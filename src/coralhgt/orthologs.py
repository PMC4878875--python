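"""Ortholog-pair filtering, clustering and lineage categorization.

Pairwise ortholog assignments are filtered to unambiguous one-to-one pairs
with full confidence, clustered into multi-species groups as connected
components of the pair graph, and each group is assigned to the smallest
lineage of a fixed nested hierarchy (robust corals ⊂ Scleractinia ⊂
Hexacorallia ⊂ Anthozoa ⊂ Cnidaria ⊂ Root, with Actiniaria beside
Scleractinia and a disjoint non-cnidarian bin) that contains all of its
member species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

# Nine named lineages, smallest to largest along each chain.
LINEAGES = (
    "RobustCorals",
    "ComplexCorals",
    "Scleractinia",
    "Actiniaria",
    "Hexacorallia",
    "Anthozoa",
    "Cnidaria",
    "NonCnidaria",
    "Root",
)

# Leaf lineage -> chain of containing lineages, smallest first.
_CHAINS: dict[str, tuple[str, ...]] = {
    "RobustCorals": ("RobustCorals", "Scleractinia", "Hexacorallia", "Anthozoa", "Cnidaria", "Root"),
    "ComplexCorals": ("ComplexCorals", "Scleractinia", "Hexacorallia", "Anthozoa", "Cnidaria", "Root"),
    "Actiniaria": ("Actiniaria", "Hexacorallia", "Anthozoa", "Cnidaria", "Root"),
    "OtherHexacorallia": ("Hexacorallia", "Anthozoa", "Cnidaria", "Root"),
    "OtherAnthozoa": ("Anthozoa", "Cnidaria", "Root"),
    "OtherCnidaria": ("Cnidaria", "Root"),
    "NonCnidaria": ("NonCnidaria", "Root"),
}

LEAF_LINEAGES = tuple(_CHAINS)


@dataclass(frozen=True)
class OrthologPair:
    """A pairwise ortholog assignment between two species."""

    species_a: str
    seq_a: str
    species_b: str
    seq_b: str
    confidence: float
    set_size_a: int = 1
    set_size_b: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence out of [0,1]: {self.confidence}")
        if self.set_size_a < 1 or self.set_size_b < 1:
            raise ValueError("ortholog set sizes must be >= 1")


class GroupHierarchy:
    """The fixed nested lineage hierarchy over a species list.

    Built from a mapping species -> leaf lineage (one of
    ``LEAF_LINEAGES``); parent lineages are unions of their children.
    """

    def __init__(self, species_to_leaf: Mapping[str, str]) -> None:
        self._leaf: dict[str, str] = {}
        self._members: dict[str, set[str]] = {name: set() for name in LINEAGES}
        for species, leaf in species_to_leaf.items():
            if leaf not in _CHAINS:
                raise ValueError(
                    f"unknown leaf lineage {leaf!r} for species {species!r}"
                )
            self._leaf[species] = leaf
            for lineage in _CHAINS[leaf]:
                self._members[lineage].add(species)
        self._members["Root"] = set(self._leaf)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._leaf)

    def members(self, lineage: str) -> frozenset[str]:
        if lineage not in self._members:
            raise ValueError(f"unknown lineage: {lineage!r}")
        return frozenset(self._members[lineage])

    def chain(self, species: str) -> tuple[str, ...]:
        try:
            return _CHAINS[self._leaf[species]]
        except KeyError:
            raise KeyError(f"species {species!r} not in hierarchy") from None

    def smallest_containing(self, species_set: Iterable[str]) -> str:
        """Smallest named lineage whose species set contains all given species."""
        species_set = set(species_set)
        if not species_set:
            raise ValueError("empty species set")
        chains = [self.chain(s) for s in species_set]
        # Walk the first species' chain outward; the first lineage containing
        # every species is the smallest by nesting.
        for lineage in chains[0]:
            if species_set <= self._members[lineage]:
                return lineage
        return "Root"


@dataclass
class OrthologCluster:
    """A multi-species ortholog group with its lineage category."""

    id: str
    members: frozenset[tuple[str, str]]  # (species, seq_id)
    category: str = "Unassigned"

    @property
    def species(self) -> frozenset[str]:
        return frozenset(sp for sp, _ in self.members)


def filter_ortholog_pairs(pairs: Iterable[OrthologPair]) -> list[OrthologPair]:
    """Keep pairs with confidence exactly 1 and one sequence per species."""
    return [
        p
        for p in pairs
        if p.confidence == 1.0 and p.set_size_a == 1 and p.set_size_b == 1
    ]


def cluster_orthologs(pairs: Iterable[OrthologPair]) -> list[OrthologCluster]:
    """Cluster filtered pairs into connected components of the pair graph.

    Components in which one species contributes two different sequences are
    retained but flagged ``Unassigned-conflict`` (with a warning) and are
    excluded from categorization.
    """
    graph = nx.Graph()
    for p in pairs:
        graph.add_edge((p.species_a, p.seq_a), (p.species_b, p.seq_b))
    clusters: list[OrthologCluster] = []
    components = sorted(
        nx.connected_components(graph), key=lambda c: sorted(c)[0]
    )
    for i, component in enumerate(components):
        if len(component) < 2:
            continue
        members = frozenset(component)
        species = [sp for sp, _ in members]
        cluster = OrthologCluster(id=f"OG{i + 1:05d}", members=members)
        if len(set(species)) != len(species):
            warnings.warn(
                f"cluster {cluster.id}: a species contributes multiple sequences; "
                "flagged as conflict and excluded from categorization",
                stacklevel=2,
            )
            cluster.category = "Unassigned-conflict"
        clusters.append(cluster)
    return clusters


def classify_cluster(cluster: OrthologCluster, hierarchy: GroupHierarchy) -> str:
    """Assign the smallest lineage containing all of a cluster's species."""
    for sp in cluster.species:
        if sp not in hierarchy.species:
            raise KeyError(f"species {sp!r} not in hierarchy")
    return hierarchy.smallest_containing(cluster.species)


def categorize_clusters(
    clusters: Iterable[OrthologCluster], hierarchy: GroupHierarchy
) -> list[OrthologCluster]:
    """Set ``category`` on every non-conflicted cluster, in place."""
    out = []
    for cluster in clusters:
        if cluster.category != "Unassigned-conflict":
            cluster.category = classify_cluster(cluster, hierarchy)
        out.append(cluster)
    return out


def select_tree_orthologs(
    clusters: Iterable[OrthologCluster],
    hierarchy: GroupHierarchy,
    tree_ortholog_min_frac: float = 0.50,
) -> list[OrthologCluster]:
    """Select Root-category clusters covering >=50% of the species of some lineage.

    A cluster qualifies when there exists at least one named lineage L with
    |member species ∩ L| / |L| >= the threshold (inclusive).
    """
    selected = []
    for cluster in clusters:
        if cluster.category != "Root":
            continue
        species = cluster.species
        for lineage in LINEAGES:
            members = hierarchy.members(lineage)
            if not members:
                continue
            if len(species & members) / len(members) >= tree_ortholog_min_frac:
                selected.append(cluster)
                break
    return selected


PAIR_COLUMNS = [
    "species_a",
    "seq_a",
    "species_b",
    "seq_b",
    "confidence",
    "set_size_a",
    "set_size_b",
]


def read_ortholog_pairs(path) -> list[OrthologPair]:
    df = pd.read_csv(path, sep="\t", dtype={"seq_a": str, "seq_b": str})
    if list(df.columns) != PAIR_COLUMNS:
        raise ValueError(f"{path}: expected header {PAIR_COLUMNS}, got {list(df.columns)}")
    return [
        OrthologPair(
            species_a=r.species_a,
            seq_a=r.seq_a,
            species_b=r.species_b,
            seq_b=r.seq_b,
            confidence=float(r.confidence),
            set_size_a=int(r.set_size_a),
            set_size_b=int(r.set_size_b),
        )
        for r in df.itertuples(index=False)
    ]


def write_ortholog_pairs(pairs: Iterable[OrthologPair], path) -> str:
    rows = [
        (p.species_a, p.seq_a, p.species_b, p.seq_b, p.confidence, p.set_size_a, p.set_size_b)
        for p in pairs
    ]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)
    return str(path)


def write_clusters(clusters: Iterable[OrthologCluster], path) -> str:
    rows = []
    for c in clusters:
        members = ",".join(f"{sp}:{seq}" for sp, seq in sorted(c.members))
        rows.append((c.id, c.category, members))
    pd.DataFrame(rows, columns=["cluster_id", "category", "members"]).to_csv(
        path, sep="\t", index=False
    )
    return str(path)
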