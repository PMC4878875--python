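"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is deterministic under a fixed seed and emits the same file
dialects the pipeline reads (Newick, 12-column homology tables, FASTA,
ortholog-pair TSV) together with the ground truth needed to verify
recovery: planted transfer events in gene trees, subjects that survive hit
subsampling, per-protein acidity class labels, and per-family lineage
categories.

Tree topologies are uniform-random bifurcating joins (no birth–death
process): the screen interrogates bipartitions and supports only, so the
simplest topology null suffices. Supports off the transfer-relevant edge
are drawn uniformly on [50, 100] so that thresholding is non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import read_newick
from .types import (
    BlastHit,
    Moltype,
    PipelineConfig,
    SequenceRecord,
    SupportTree,
    TaxonEntry,
    TaxonomyMap,
)
from .orthologs import LEAF_LINEAGES, GroupHierarchy, OrthologPair

AMINO_ACIDS = list("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generators.

    The proteome classes mirror the acid-rich screen's regimes: a background
    class around 12% D+E (typical of ordinary proteomes) and an acid-rich
    class around 35% D+E, safely beyond the 28% criterion.
    """

    seed: int = 0
    # gene-tree simulation
    n_donor_leaves: int = 4
    n_metazoan_leaves: int = 8
    donor_group: str = "Bacteria"
    transfer_support: float = 100.0
    min_background_support: float = 50.0
    max_background_support: float = 100.0
    # homology-table simulation
    identity_bounds: tuple[float, float] = (20.0, 95.0)
    mean_aln_length: float = 160.0
    sd_aln_length: float = 40.0
    # proteome simulation
    n_proteins: int = 1000
    protein_length_bounds: tuple[int, int] = (200, 600)
    background_de_mean: float = 0.12
    acid_rich_de_mean: float = 0.35
    acid_rich_proportion: float = 0.10
    # ortholog-table simulation
    n_families: int = 500

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# gene trees with planted transfers


@dataclass
class TreeBundleTruth:
    query_id: str
    planted: bool
    donor_group: str = ""
    donor_clade_leaves: frozenset[str] = frozenset()


@dataclass
class SimulatedTreeBundle:
    """Matched pass-1/pass-2/confirmation trees for one query, plus truth."""

    query_id: str
    newick_pass1: str
    newick_pass2: str
    newick_confirm: str
    taxonomy_entries: dict[str, TaxonEntry]
    truth: TreeBundleTruth

    @property
    def trees(self) -> tuple[SupportTree, SupportTree, SupportTree]:
        return (
            read_newick(self.newick_pass1, "sh_local"),
            read_newick(self.newick_pass2, "bootstrap_pct"),
            read_newick(self.newick_confirm, "ufboot_pct"),
        )


def _random_join(leaves: list, rng: np.random.Generator) -> object:
    """Uniform random bifurcating topology by repeated random pairwise joins.

    Nodes are either leaf labels (str) or (left, right) tuples.
    """
    nodes: list = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append((left, right))
    return nodes[0]


def _to_newick(node, supports: dict) -> str:
    if isinstance(node, str):
        return node
    left = _to_newick(node[0], supports)
    right = _to_newick(node[1], supports)
    label = supports.get(id(node), "")
    return f"({left},{right}){label}"


def _collect_internal(node, out: list) -> frozenset:
    """Return the leaf set under ``node``, recording internal nodes."""
    if isinstance(node, str):
        return frozenset([node])
    leaves = _collect_internal(node[0], out) | _collect_internal(node[1], out)
    out.append((node, leaves))
    return leaves


def simulate_hgt_tree(
    sim: SimConfig,
    rng: Optional[np.random.Generator] = None,
    planted: bool = True,
    query_index: int = 0,
) -> SimulatedTreeBundle:
    """Build one matched tree bundle, optionally with a planted transfer.

    With a planted transfer the coral query is grafted inside a clade of
    ``n_donor_leaves`` donor-group sequences and the edge subtending that
    clade carries ``transfer_support`` (on each stage's scale); without one
    the query sits among the metazoan leaves. Every bundle contains a second
    coral species so the species-uniqueness discard does not trigger on true
    plants.
    """
    if rng is None:
        rng = sim.rng()
    qid = f"coralq_{query_index}"
    donors = [f"donor_{query_index}_{i}" for i in range(sim.n_donor_leaves)]
    if sim.n_donor_leaves < 2:
        raise ValueError("need at least 2 donor leaves to form a nesting clade")
    metazoans = [f"metaz_{query_index}_{i}" for i in range(sim.n_metazoan_leaves)]
    other_coral = f"coralx_{query_index}"

    entries: dict[str, TaxonEntry] = {
        qid: TaxonEntry("Acropora_q", "Scleractinia_o", "Cnidaria_p", "CoralComplex"),
        other_coral: TaxonEntry(
            "Seriatopora_x", "Scleractinia_o", "Cnidaria_p", "CoralRobust"
        ),
    }
    for d in donors:
        entries[d] = TaxonEntry(
            f"donor_sp_{d}", f"{sim.donor_group}_o", f"{sim.donor_group}_p", sim.donor_group
        )
    for m in metazoans:
        entries[m] = TaxonEntry(f"metaz_sp_{m}", "Metazoa_o", "Metazoa_p", "OtherMetazoa")

    if planted:
        # graft the query sister to one donor leaf, strictly inside the donor
        # clade: were it sister to all donors, the complement of the
        # donors-only clade (query + metazoans) would read as metazoan nesting
        metazoan_side = _random_join(metazoans + [other_coral], rng)
        carrier = donors[int(rng.integers(len(donors)))]
        rest_donors = [d for d in donors if d != carrier]
        donor_clade = _random_join(rest_donors + [(carrier, qid)], rng)
        topology = (donor_clade, metazoan_side)
        transfer_node = donor_clade
    else:
        # vertical placement: query sister to one metazoan leaf, deep inside
        # the metazoan clade, so no bipartition isolates it with the donors
        donor_clade = _random_join(donors, rng)
        host = metazoans[int(rng.integers(len(metazoans)))]
        rest = [m for m in metazoans if m != host] + [other_coral]
        metazoan_side = _random_join(rest + [(host, qid)], rng)
        topology = (donor_clade, metazoan_side)
        transfer_node = None

    internal: list = []
    _collect_internal(topology, internal)
    # root node carries no support (its edge is not an internal edge)
    internal = [(node, leaves) for node, leaves in internal if node is not topology]

    def _stage_newick(scale: float, stage_rng: np.random.Generator) -> str:
        supports = {}
        for node, _leaves in internal:
            raw = stage_rng.uniform(
                sim.min_background_support, sim.max_background_support
            )
            if node is transfer_node:
                raw = sim.transfer_support
            value = raw * scale
            supports[id(node)] = f"{value:.4g}" if scale != 1.0 else f"{value:.3g}"
        return _to_newick(topology, supports) + ";"

    bundle = SimulatedTreeBundle(
        query_id=qid,
        newick_pass1=_stage_newick(0.01, rng),
        newick_pass2=_stage_newick(1.0, rng),
        newick_confirm=_stage_newick(1.0, rng),
        taxonomy_entries=entries,
        truth=TreeBundleTruth(
            query_id=qid,
            planted=planted,
            donor_group=sim.donor_group if planted else "",
            donor_clade_leaves=frozenset(donors) if planted else frozenset(),
        ),
    )
    return bundle


def simulate_hgt_bundles(
    sim: SimConfig, n_bundles: int, planted_fraction: float = 0.5
) -> tuple[list[SimulatedTreeBundle], TaxonomyMap]:
    """Generate a batch of bundles, the first ``round(n*fraction)`` planted."""
    rng = sim.rng()
    n_planted = int(round(n_bundles * planted_fraction))
    bundles = []
    taxonomy = TaxonomyMap()
    for i in range(n_bundles):
        bundle = simulate_hgt_tree(sim, rng, planted=i < n_planted, query_index=i)
        bundles.append(bundle)
        for key, entry in bundle.taxonomy_entries.items():
            taxonomy.add(key, entry)
    return bundles, taxonomy


# ---------------------------------------------------------------------------
# homology tables


@dataclass
class SimulatedHits:
    query_id: str
    hits: list[BlastHit]
    taxonomy: TaxonomyMap
    selectable_subjects: list[str]  # truth under the screen's filter rules


def simulate_blast_table(
    sim: SimConfig,
    subjects_per_taxon: Sequence[tuple[str, str, int]],
    config: PipelineConfig = PipelineConfig(),
    query_id: str = "query_1",
) -> SimulatedHits:
    """Homology hits with controlled identity, length and taxonomy.

    ``subjects_per_taxon`` lists (order, phylum, n_subjects). Identities are
    uniform within ``identity_bounds``, lengths normal around
    ``mean_aln_length``. The truth field re-applies the filter rules
    (identity >= floor, length >= floor, identity-descending order with the
    stated tie-breaks, per-order/per-phylum caps, total cap) in an
    independent pass.
    """
    rng = sim.rng()
    hits: list[BlastHit] = []
    taxonomy = TaxonomyMap()
    idx = 0
    for order, phylum, n in subjects_per_taxon:
        for _ in range(n):
            sid = f"subj_{idx:05d}"
            idx += 1
            identity = float(rng.uniform(*sim.identity_bounds))
            length = max(30, int(rng.normal(sim.mean_aln_length, sim.sd_aln_length)))
            bitscore = round(identity * length / 50.0, 1)
            hits.append(
                BlastHit(
                    query_id=query_id,
                    subject_id=sid,
                    pct_identity=round(identity, 2),
                    aln_length=length,
                    mismatches=int(length * (100 - identity) / 100),
                    gap_opens=0,
                    q_start=1,
                    q_end=length,
                    s_start=1,
                    s_end=length,
                    evalue=1e-20,
                    bitscore=bitscore,
                )
            )
            taxonomy.add(sid, TaxonEntry(f"sp_{sid}", order, phylum, "Bacteria"))
    order_positions = rng.permutation(len(hits))
    hits = [hits[i] for i in order_positions]

    # independent truth: re-apply the rules with plain bookkeeping
    eligible = sorted(
        (
            h
            for h in hits
            if h.pct_identity >= config.min_hit_identity
            and h.aln_length >= config.min_hit_aln_len
        ),
        key=lambda h: (-h.pct_identity, -h.bitscore, h.subject_id),
    )
    per_order: dict[str, int] = {}
    per_phylum: dict[str, int] = {}
    truth: list[str] = []
    for h in eligible:
        if len(truth) >= config.max_hits:
            break
        entry = taxonomy[h.subject_id]
        if per_order.get(entry.order, 0) >= config.max_per_order:
            continue
        if per_phylum.get(entry.phylum, 0) >= config.max_per_phylum:
            continue
        truth.append(h.subject_id)
        per_order[entry.order] = per_order.get(entry.order, 0) + 1
        per_phylum[entry.phylum] = per_phylum.get(entry.phylum, 0) + 1

    return SimulatedHits(query_id, hits, taxonomy, truth)


# ---------------------------------------------------------------------------
# proteomes


def _class_frequencies(de_mean: float) -> np.ndarray:
    """Amino-acid frequency vector with D and E at de_mean/2 each and the
    remaining mass spread uniformly over the other 18 residues."""
    freqs = np.full(len(AMINO_ACIDS), (1.0 - de_mean) / 18.0)
    freqs[AMINO_ACIDS.index("D")] = de_mean / 2.0
    freqs[AMINO_ACIDS.index("E")] = de_mean / 2.0
    return freqs


def simulate_proteome(
    sim: SimConfig,
    species: str = "synthetic_coral",
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SequenceRecord], list[str]]:
    """Draw a proteome of background and acid-rich proteins.

    Residues are i.i.d. from class-specific frequency vectors; returns the
    records and the per-protein class labels ("background" / "acid_rich").
    """
    if rng is None:
        rng = sim.rng()
    records: list[SequenceRecord] = []
    labels: list[str] = []
    bg = _class_frequencies(sim.background_de_mean)
    rich = _class_frequencies(sim.acid_rich_de_mean)
    lo, hi = sim.protein_length_bounds
    for i in range(sim.n_proteins):
        is_rich = rng.random() < sim.acid_rich_proportion
        freqs = rich if is_rich else bg
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(AMINO_ACIDS, size=length, p=freqs))
        records.append(
            SequenceRecord(
                id=f"{species}_p{i:05d}",
                sequence=seq,
                moltype=Moltype.protein,
                species=species,
            )
        )
        labels.append("acid_rich" if is_rich else "background")
    return records, labels


def simulate_acidity_study(
    sim: SimConfig,
    n_coral_species: int = 20,
    n_noncoral_species: int = 12,
    enrichment: float = 2.0,
) -> tuple[dict[str, list[SequenceRecord]], dict[str, str]]:
    """Proteomes for a coral-vs-non-coral acidity comparison.

    Coral species carry the configured acid-rich proportion; non-coral
    species carry it divided by ``enrichment`` (default two-fold). The
    default panel sizes mirror the comparison's real design: 20 coral
    species against 12 non-calcifying invertebrates.
    """
    rng = sim.rng()
    records_by_species: dict[str, list[SequenceRecord]] = {}
    groups: dict[str, str] = {}
    for i in range(n_coral_species):
        name = f"coral_{i}"
        spc = SimConfig(**{**sim.__dict__})
        spc.acid_rich_proportion = sim.acid_rich_proportion
        records_by_species[name], _ = simulate_proteome(spc, name, rng)
        groups[name] = "RobustCoral" if i % 2 == 0 else "ComplexCoral"
    for i in range(n_noncoral_species):
        name = f"noncoral_{i}"
        spc = SimConfig(**{**sim.__dict__})
        spc.acid_rich_proportion = sim.acid_rich_proportion / enrichment
        records_by_species[name], _ = simulate_proteome(spc, name, rng)
        groups[name] = "NonCoral"
    return records_by_species, groups


# ---------------------------------------------------------------------------
# ortholog pair tables

# Default synthetic species panel: species name -> leaf lineage.
DEFAULT_SPECIES_PANEL: dict[str, str] = {
    **{f"robust_{i}": "RobustCorals" for i in range(4)},
    **{f"complex_{i}": "ComplexCorals" for i in range(3)},
    **{f"anemone_{i}": "Actiniaria" for i in range(2)},
    "ceriantharian_0": "OtherHexacorallia",
    "seafan_0": "OtherAnthozoa",
    "hydrozoan_0": "OtherCnidaria",
    **{f"outgroup_{i}": "NonCnidaria" for i in range(4)},
}

# For each target category: pools from which one species each must be drawn
# so the smallest containing lineage equals the category exactly.
_SPANNING_POOLS: dict[str, tuple[tuple[str, ...], ...]] = {
    "RobustCorals": (("RobustCorals",), ("RobustCorals",)),
    "ComplexCorals": (("ComplexCorals",), ("ComplexCorals",)),
    "Actiniaria": (("Actiniaria",), ("Actiniaria",)),
    "NonCnidaria": (("NonCnidaria",), ("NonCnidaria",)),
    "Scleractinia": (("RobustCorals",), ("ComplexCorals",)),
    "Hexacorallia": (("RobustCorals", "ComplexCorals"), ("Actiniaria", "OtherHexacorallia")),
    "Anthozoa": (("RobustCorals", "ComplexCorals", "Actiniaria"), ("OtherAnthozoa",)),
    "Cnidaria": (("RobustCorals", "ComplexCorals", "Actiniaria", "OtherAnthozoa"), ("OtherCnidaria",)),
    "Root": (("RobustCorals", "ComplexCorals", "Actiniaria", "OtherAnthozoa", "OtherCnidaria"), ("NonCnidaria",)),
}


@dataclass
class FamilyTruth:
    family_id: str
    category: str
    members: tuple[tuple[str, str], ...]  # (species, seq_id)


def simulate_ortholog_pairs(
    sim: SimConfig,
    categories: Optional[Sequence[str]] = None,
    species_panel: Optional[dict[str, str]] = None,
    noise_pairs: int = 0,
) -> tuple[list[OrthologPair], GroupHierarchy, list[FamilyTruth]]:
    """Pair tables for families with known lineage restriction.

    Each family draws one species from each spanning pool of its target
    category (so the smallest containing lineage is exactly that category),
    plus extra species from within the category, and emits all pairwise
    pairs at confidence 1 with one sequence per species. ``noise_pairs``
    adds confidence-0.9 cross-family pairs that the filter must remove.
    """
    rng = sim.rng()
    panel = dict(species_panel or DEFAULT_SPECIES_PANEL)
    hierarchy = GroupHierarchy(panel)
    by_leaf: dict[str, list[str]] = {}
    for sp, leaf in panel.items():
        by_leaf.setdefault(leaf, []).append(sp)
    for leaf in by_leaf:
        by_leaf[leaf].sort()

    if categories is None:
        categories = [
            str(rng.choice(list(_SPANNING_POOLS))) for _ in range(sim.n_families)
        ]

    pairs: list[OrthologPair] = []
    truths: list[FamilyTruth] = []
    for f, category in enumerate(categories):
        pools = _SPANNING_POOLS[category]
        members: list[str] = []
        for pool in pools:
            leaf = str(rng.choice(pool))
            options = [s for s in by_leaf.get(leaf, []) if s not in members]
            if not options:
                continue
            members.append(str(rng.choice(options)))
        # pad with extra species from within the category
        category_species = sorted(hierarchy.members(category) - set(members))
        n_extra = int(rng.integers(0, min(3, len(category_species)) + 1))
        if n_extra:
            extra = rng.choice(category_species, size=n_extra, replace=False)
            members.extend(str(s) for s in extra)
        member_seqs = tuple((sp, f"{sp}_g{f:04d}") for sp in sorted(members))
        truths.append(FamilyTruth(f"fam{f:04d}", category, member_seqs))
        for i in range(len(member_seqs)):
            for j in range(i + 1, len(member_seqs)):
                (sa, qa), (sb, qb) = member_seqs[i], member_seqs[j]
                pairs.append(OrthologPair(sa, qa, sb, qb, confidence=1.0))

    all_species = sorted(panel)
    for k in range(noise_pairs):
        sa, sb = rng.choice(all_species, size=2, replace=False)
        pairs.append(
            OrthologPair(
                str(sa), f"{sa}_noise{k}", str(sb), f"{sb}_noise{k}", confidence=0.9
            )
        )
    return pairs, hierarchy, truths
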