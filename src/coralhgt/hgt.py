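"""Two-pass phylogenomic screen for horizontally transferred genes.

A coral query protein is screened in three tree-based stages. Pass 1 asks
whether the query is *nested within metazoan sequences* in an SH-supported
clade of its fast gene tree — such queries are vertical animal genes and are
discarded. Pass 2 asks, on a bootstrap-supported maximum-likelihood tree
over an expanded taxon set, whether the query is nested within
*non-metazoan* sequences; survivors are HGT candidates. Candidates are
confirmed on a third tree with ultrafast-bootstrap supports, candidates
private to a single species are dropped, donors are labelled from the
taxonomic composition of the foreign clade, each event is assigned a coral
or anthozoan ancestry, and redundant calls (shared events seen from two
query proteomes, or recent paralogs) are collapsed into non-redundant
events.

"Nested within group G" is operationalized on the unrooted gene tree: there
must exist an internal edge whose support meets the stage threshold and
whose induced bipartition has a side that contains every query sequence
plus at least two non-query leaves, all of which belong to G. The smallest
such side is reported as the nesting clade.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import math
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .types import (
    ANTHOZOAN_GROUPS,
    BlastHit,
    MSA,
    PipelineConfig,
    SupportTree,
    TaxonomyMap,
    is_metazoan,
)

# Abbreviated donor labels, as used in the published event table.
DONOR_ABBREVIATIONS = {
    "Bacteria": "Bact",
    "CAAlgae": "CA",
    "Dinoflagellata": "Dino",
    "Viridiplantae": "Viri",
    "RedAlgae": "Red algae",
    "Fungi": "Fungi",
    "Choanozoa": "Choano",
    "OtherEukaryote": "OtherEuk",
}

MODES = ("metazoan_nesting", "nonmetazoan_nesting")
_MODE_SCALES = {
    "metazoan_nesting": "sh_local",
    "nonmetazoan_nesting": ("bootstrap_pct", "ufboot_pct"),
}


@dataclass
class HitSelection:
    """Subjects selected for one query after identity/length filtering and
    taxonomic subsampling."""

    query_id: str
    subject_ids: list[str]
    subject_taxa: dict[str, tuple[str, str, str]]  # id -> (order, phylum, group)
    order_counts: Counter
    phylum_counts: Counter


@dataclass
class PlacementResult:
    """Outcome of interrogating one gene tree for query nesting."""

    query_id: str
    mode: str
    nested: bool
    supporting_edge_support: Optional[float] = None
    nesting_clade_leaves: frozenset[str] = frozenset()
    donor_groups: tuple[str, ...] = ()


@dataclass
class HGTCandidate:
    """A per-query transfer call with its stagewise supports."""

    query_id: str
    query_species: str
    pass2_support: float
    confirm_support: Optional[float]
    donor_label: str
    status: str  # candidate | confirmed | rejected
    clade_leaves: frozenset[str] = frozenset()
    tree_leaves: frozenset[str] = frozenset()
    cluster_id: Optional[str] = None


@dataclass
class HGTEvent:
    """A non-redundant transfer event covering one or more candidates."""

    event_id: str
    members: tuple[HGTCandidate, ...]
    ancestor: str  # Coral | Anthozoa
    donor_label: str
    gene_name: str = ""


def select_hits(
    hits: Sequence[BlastHit],
    taxonomy: TaxonomyMap,
    config: PipelineConfig = PipelineConfig(),
) -> HitSelection:
    """Filter and taxonomically subsample homology hits for one query.

    Hits under the identity floor are discarded; among the rest those
    meeting the alignment-length floor are sorted by identity descending
    (ties: bitscore descending, then subject id) and retrieved greedily,
    skipping subjects whose order already holds ``max_per_order`` selections
    or whose phylum holds ``max_per_phylum``, stopping at ``max_hits``.
    """
    if not hits:
        raise ValueError("select_hits requires at least one hit")
    queries = {h.query_id for h in hits}
    if len(queries) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    query_id = queries.pop()

    eligible = [
        h
        for h in hits
        if h.pct_identity >= config.min_hit_identity
        and h.aln_length >= config.min_hit_aln_len
    ]
    eligible.sort(key=lambda h: (-h.pct_identity, -h.bitscore, h.subject_id))

    selected: list[str] = []
    taxa: dict[str, tuple[str, str, str]] = {}
    order_counts: Counter = Counter()
    phylum_counts: Counter = Counter()
    seen: set[str] = set()
    for hit in eligible:
        if len(selected) >= config.max_hits:
            break
        sid = hit.subject_id
        if sid in seen:
            continue
        seen.add(sid)
        if sid not in taxonomy:
            raise KeyError(f"subject {sid!r} missing from taxonomy")
        entry = taxonomy[sid]
        if order_counts[entry.order] >= config.max_per_order:
            continue
        if phylum_counts[entry.phylum] >= config.max_per_phylum:
            continue
        selected.append(sid)
        taxa[sid] = (entry.order, entry.phylum, entry.major_group)
        order_counts[entry.order] += 1
        phylum_counts[entry.phylum] += 1
    return HitSelection(query_id, selected, taxa, order_counts, phylum_counts)


def trim_alignment(msa: MSA, max_col_gap_frac: float = 0.50) -> MSA:
    """Drop alignment columns whose gap fraction is >= the threshold."""
    n = msa.n_rows
    keep = [
        j
        for j in range(msa.n_columns)
        if msa.column(j).count("-") / n < max_col_gap_frac
    ]
    return MSA([(rid, "".join(row[j] for j in keep)) for rid, row in msa.rows])


def qc_alignment(msa: MSA, config: PipelineConfig = PipelineConfig()) -> dict:
    """Pass iff the trimmed alignment keeps enough sites and sequences."""
    if msa.n_columns < config.min_aln_sites:
        return {"pass": False, "reason": f"sites<{config.min_aln_sites}"}
    if msa.n_rows < config.min_aln_seqs:
        return {"pass": False, "reason": f"sequences<{config.min_aln_seqs}"}
    return {"pass": True, "reason": ""}


def classify_placement(
    tree: SupportTree,
    query_ids: Iterable[str],
    taxonomy: TaxonomyMap,
    mode: str,
    min_support: float,
) -> PlacementResult:
    """Decide whether the queries are nested within the mode's group.

    Enumerates every internal edge with support >= ``min_support``; a side
    of its bipartition qualifies when it contains all queries and its >=2
    non-query leaves all satisfy the group predicate (metazoan for
    ``metazoan_nesting``, non-metazoan for ``nonmetazoan_nesting``). The
    smallest qualifying side is the nesting clade.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode: {mode!r}")
    expected = _MODE_SCALES[mode]
    if isinstance(expected, tuple):
        if tree.support_scale not in expected:
            raise ValueError(
                f"mode {mode} expects a percent support scale, tree has "
                f"{tree.support_scale}"
            )
    elif tree.support_scale != expected:
        raise ValueError(
            f"mode {mode} expects {expected} supports, tree has {tree.support_scale}"
        )
    queries = frozenset(query_ids)
    if not queries:
        raise ValueError("no query ids given")
    missing = queries - tree.leaves
    if missing:
        raise KeyError(f"queries absent from tree: {sorted(missing)}")
    for leaf in tree.leaves:
        if leaf not in taxonomy:
            raise KeyError(f"tree leaf {leaf!r} missing from taxonomy")

    predicate = is_metazoan if mode == "metazoan_nesting" else (
        lambda g: not is_metazoan(g)
    )

    best: Optional[tuple[int, tuple, float, frozenset[str]]] = None
    for support, under, rest in tree.supported_bipartitions(min_support):
        for side in (under, rest):
            if not queries <= side:
                continue
            non_query = side - queries
            if len(non_query) < 2:
                continue
            if all(predicate(taxonomy.group(leaf)) for leaf in non_query):
                key = (len(side), tuple(sorted(side)), -support)
                if best is None or key < (best[0], best[1], -best[2]):
                    best = (len(side), tuple(sorted(side)), support, side)

    if best is None:
        return PlacementResult(
            query_id="|".join(sorted(queries)), mode=mode, nested=False
        )
    _, _, support, side = best
    donor_groups = tuple(
        sorted(taxonomy.group(leaf) for leaf in side - queries)
    )
    return PlacementResult(
        query_id="|".join(sorted(queries)),
        mode=mode,
        nested=True,
        supporting_edge_support=support,
        nesting_clade_leaves=side,
        donor_groups=donor_groups,
    )


def assign_donor(placement: PlacementResult) -> str:
    """Label the donor from the foreign clade's taxonomic composition.

    One major group gives its abbreviation; exactly two give a composite
    "A/B" label (alphabetical); three or more give "Unclear".
    """
    if not placement.nested or not placement.donor_groups:
        raise ValueError("donor assignment requires a nested placement")
    groups = sorted(set(placement.donor_groups))
    if len(groups) == 1:
        return DONOR_ABBREVIATIONS.get(groups[0], groups[0])
    if len(groups) == 2:
        labels = sorted(DONOR_ABBREVIATIONS.get(g, g) for g in groups)
        return "/".join(labels)
    return "Unclear"


def run_two_pass_screen(
    trees_pass1: Mapping[str, SupportTree],
    trees_pass2: Mapping[str, SupportTree],
    trees_confirm: Mapping[str, SupportTree],
    taxonomy: TaxonomyMap,
    config: PipelineConfig = PipelineConfig(),
) -> list[HGTCandidate]:
    """Run the full per-query screen and return candidate calls.

    A query is *confirmed* iff it is (i) not metazoan-nested at the SH
    threshold in pass 1, (ii) non-metazoan-nested at the bootstrap threshold
    in pass 2, (iii) non-metazoan-nested at the UFboot threshold on the
    confirmation tree, and (iv) not private to its own species — at least
    one other coral/anthozoan taxon must appear in the pass-2 tree (gene
    family membership). Queries failing (iii) or (iv) are reported with
    status ``rejected``; queries failing (i) or (ii) are silently vertical.
    """
    candidates: list[HGTCandidate] = []
    for query_id in sorted(trees_pass1):
        tree1 = trees_pass1[query_id]
        p1 = classify_placement(
            tree1, [query_id], taxonomy, "metazoan_nesting", config.pass1_min_sh
        )
        if p1.nested:
            continue  # vertical metazoan gene
        if query_id not in trees_pass2:
            raise KeyError(f"missing pass-2 tree for query {query_id!r}")
        tree2 = trees_pass2[query_id]
        p2 = classify_placement(
            tree2, [query_id], taxonomy, "nonmetazoan_nesting",
            config.pass2_min_bootstrap,
        )
        if not p2.nested:
            continue
        if query_id not in trees_confirm:
            raise KeyError(f"missing confirmation tree for query {query_id!r}")
        tree3 = trees_confirm[query_id]
        p3 = classify_placement(
            tree3, [query_id], taxonomy, "nonmetazoan_nesting",
            config.confirm_min_ufboot,
        )
        query_species = taxonomy.species(query_id)
        shared = _shared_with_other_anthozoan(tree2, query_id, query_species, taxonomy)
        if p3.nested and shared:
            status = "confirmed"
            placement = p3
        else:
            status = "rejected"
            placement = p3 if p3.nested else p2
        candidates.append(
            HGTCandidate(
                query_id=query_id,
                query_species=query_species,
                pass2_support=p2.supporting_edge_support,
                confirm_support=p3.supporting_edge_support if p3.nested else None,
                donor_label=assign_donor(placement),
                status=status,
                clade_leaves=p2.nesting_clade_leaves | placement.nesting_clade_leaves,
                tree_leaves=tree2.leaves,
            )
        )
    return candidates


def _shared_with_other_anthozoan(
    tree: SupportTree, query_id: str, query_species: str, taxonomy: TaxonomyMap
) -> bool:
    """True if the gene family contains another coral/anthozoan taxon."""
    for leaf in tree.leaves:
        if leaf == query_id:
            continue
        entry = taxonomy[leaf]
        if entry.major_group in ANTHOZOAN_GROUPS and entry.species != query_species:
            return True
    return False


def assign_ancestor(
    member_leaves: Iterable[str], taxonomy: TaxonomyMap
) -> str:
    """Date the transfer to the anthozoan ancestor or to corals.

    ``Anthozoa`` iff the event's gene family (nesting clade or alignment
    membership) includes a homolog from a sea anemone (Actiniaria) or
    another non-scleractinian anthozoan such as a sea fan; otherwise
    ``Coral``.
    """
    for leaf in member_leaves:
        if leaf in taxonomy and taxonomy[leaf].major_group in (
            "Actiniaria",
            "OtherAnthozoa",
        ):
            return "Anthozoa"
    return "Coral"


def collapse_redundant(
    candidates: Sequence[HGTCandidate],
    taxonomy: Optional[TaxonomyMap] = None,
    manual_links: Optional[Iterable[tuple[str, str]]] = None,
) -> list[HGTEvent]:
    """Group confirmed candidates into non-redundant transfer events.

    Two candidates are linked when (a) one's query sequence appears among
    the other's tree/clade leaves (the same ancient transfer seen from two
    query proteomes), or (b) they share an ortholog cluster (recent
    paralogs). ``manual_links`` adds curated (query_id, query_id) pairs.
    Events are the connected components of this link graph.
    """
    confirmed = [c for c in candidates if c.status == "confirmed"]
    graph = nx.Graph()
    for c in confirmed:
        graph.add_node(c.query_id)
    for i, a in enumerate(confirmed):
        for b in confirmed[i + 1 :]:
            linked = (
                a.query_id in b.tree_leaves
                or a.query_id in b.clade_leaves
                or b.query_id in a.tree_leaves
                or b.query_id in a.clade_leaves
                or (
                    a.cluster_id is not None and a.cluster_id == b.cluster_id
                )
            )
            if linked:
                graph.add_edge(a.query_id, b.query_id)
    if manual_links:
        for qa, qb in manual_links:
            if qa in graph and qb in graph:
                graph.add_edge(qa, qb)

    by_query = {c.query_id: c for c in confirmed}
    events: list[HGTEvent] = []
    for i, component in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    ):
        members = tuple(by_query[q] for q in sorted(component))
        family_leaves: set[str] = set()
        for m in members:
            family_leaves |= m.tree_leaves | m.clade_leaves
        ancestor = (
            assign_ancestor(family_leaves, taxonomy) if taxonomy is not None else "Coral"
        )
        donor_counts = Counter(m.donor_label for m in members)
        top = max(donor_counts.values())
        donor = sorted(l for l, n in donor_counts.items() if n == top)[0]
        events.append(
            HGTEvent(
                event_id=f"HGT{i + 1:03d}",
                members=members,
                ancestor=ancestor,
                donor_label=donor,
                gene_name=members[0].query_id,
            )
        )
    return events


def hgt_rate(n_hgt_trees: int, n_total_trees: int) -> float:
    """Percent of gene trees supporting transfer, rounded half-away-from-zero
    to one decimal."""
    if n_total_trees <= 0:
        raise ZeroDivisionError("total tree count must be positive")
    if not 0 <= n_hgt_trees <= n_total_trees:
        raise ValueError("0 <= n_hgt_trees <= n_total_trees required")
    pct = 100.0 * n_hgt_trees / n_total_trees
    return math.floor(pct * 10 + 0.5) / 10  # half away from zero, one decimal


def write_candidates(candidates: Iterable[HGTCandidate], path) -> str:
    rows = [
        (
            c.query_id,
            c.query_species,
            c.pass2_support,
            c.confirm_support if c.confirm_support is not None else "",
            c.donor_label,
            c.status,
        )
        for c in candidates
    ]
    pd.DataFrame(
        rows, columns=["query_id", "species", "pass2_support", "ufboot", "donor", "status"]
    ).to_csv(path, sep="\t", index=False)
    return str(path)


def write_events(events: Iterable[HGTEvent], path) -> str:
    rows = []
    for e in events:
        supports = [m.confirm_support for m in e.members if m.confirm_support is not None]
        support = max(supports) if supports else ""
        genes = ",".join(m.query_id for m in e.members)
        rows.append((e.event_id, e.ancestor, genes, e.gene_name, support, e.donor_label))
    pd.DataFrame(
        rows,
        columns=["event_id", "ancestor", "genes", "protein_product", "support", "source"],
    ).to_csv(path, sep="\t", index=False)
    return str(path)
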