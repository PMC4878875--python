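"""Core domain types shared across the pipeline.

The central objects are sequences tied to taxa (:class:`SequenceRecord`),
the taxonomy lookup used by hit subsampling and tree-nesting logic
(:class:`TaxonomyMap`), homology hits (:class:`BlastHit`), alignments
(:class:`MSA`), support-annotated gene trees (:class:`SupportTree`) and the
single source of truth for every numeric threshold
(:class:`PipelineConfig`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import dendropy

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZ")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

# Major taxonomic groups used throughout; metazoan membership drives the
# two-pass nesting classification.
MAJOR_GROUPS = (
    "CoralRobust",
    "CoralComplex",
    "Actiniaria",
    "OtherHexacorallia",
    "OtherAnthozoa",
    "OtherCnidaria",
    "OtherMetazoa",
    "Choanozoa",
    "Bacteria",
    "Dinoflagellata",
    "CAAlgae",
    "RedAlgae",
    "Viridiplantae",
    "Fungi",
    "OtherEukaryote",
)

_METAZOAN_GROUPS = frozenset(
    {
        "CoralRobust",
        "CoralComplex",
        "Actiniaria",
        "OtherHexacorallia",
        "OtherAnthozoa",
        "OtherCnidaria",
        "OtherMetazoa",
    }
)

# Anthozoan groups relevant to the species-uniqueness discard and the
# Coral/Anthozoa ancestor assignment.
ANTHOZOAN_GROUPS = frozenset(
    {"CoralRobust", "CoralComplex", "Actiniaria", "OtherHexacorallia", "OtherAnthozoa"}
)
CORAL_GROUPS = frozenset({"CoralRobust", "CoralComplex"})


def is_metazoan(major_group: str) -> bool:
    """Total predicate: True for the animal groups, False for everything else."""
    if major_group not in MAJOR_GROUPS:
        raise ValueError(f"unknown major group: {major_group!r}")
    return major_group in _METAZOAN_GROUPS


class Moltype(str, Enum):
    protein = "protein"
    nucleotide = "nucleotide"


@dataclass
class SequenceRecord:
    """An identified amino-acid or nucleotide sequence tied to a taxon.

    Sequences are normalized to uppercase; a single trailing ``*`` (stop) is
    stripped from proteins, while internal stops are rejected.
    """

    id: str
    sequence: str
    moltype: Moltype = Moltype.protein
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.moltype = Moltype(self.moltype)
        seq = self.sequence.upper()
        if self.moltype is Moltype.protein:
            seq = seq.rstrip("*")
            if "*" in seq:
                raise ValueError(f"internal stop codon in protein {self.id!r}")
            alphabet = PROTEIN_ALPHABET
        else:
            alphabet = NUCLEOTIDE_ALPHABET
        if not seq:
            raise ValueError(f"empty sequence for id {self.id!r}")
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(
                f"invalid {self.moltype.value} characters {sorted(bad)} in {self.id!r}"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonEntry:
    species: str
    order: str
    phylum: str
    major_group: str

    def __post_init__(self) -> None:
        if self.major_group not in MAJOR_GROUPS:
            raise ValueError(f"unknown major group: {self.major_group!r}")


class TaxonomyMap:
    """Lookup from sequence id (or species id) to (species, order, phylum, group)."""

    def __init__(self, entries: Optional[Mapping[str, TaxonEntry]] = None) -> None:
        self._entries: dict[str, TaxonEntry] = {}
        if entries:
            for key, entry in entries.items():
                self.add(key, entry)

    def add(self, key: str, entry: TaxonEntry) -> None:
        existing = self._entries.get(key)
        if existing is not None and existing != entry:
            raise ValueError(f"conflicting taxonomy entries for {key!r}")
        self._entries[key] = entry

    def __contains__(self, key: str) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __getitem__(self, key: str) -> TaxonEntry:
        try:
            return self._entries[key]
        except KeyError:
            raise KeyError(f"sequence or species {key!r} missing from taxonomy") from None

    def species(self, key: str) -> str:
        return self[key].species

    def group(self, key: str) -> str:
        return self[key].major_group

    def is_metazoan(self, key: str) -> bool:
        return is_metazoan(self[key].major_group)


@dataclass(frozen=True)
class BlastHit:
    """One row of a 12-column tabular homology search result.

    Coordinates are 1-based inclusive as in the tabular standard.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")


class MSA:
    """A multiple sequence alignment: ordered rows of equal-length strings."""

    def __init__(self, rows: Iterable[tuple[str, str]]) -> None:
        self.rows: list[tuple[str, str]] = [(str(i), str(s).upper()) for i, s in rows]
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("alignment row ids are not unique")
        self.n_columns = lengths.pop()

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.rows)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MSA) and self.rows == other.rows


SUPPORT_SCALES = {
    "sh_local": (0.0, 1.0),
    "bootstrap_pct": (0.0, 100.0),
    "ufboot_pct": (0.0, 100.0),
}


class SupportTree:
    """A gene tree with per-internal-edge support values.

    The tree is treated as unrooted: each internal edge induces a bipartition
    of the leaf set, and the placement classifier interrogates those
    bipartitions together with their supports. Missing supports stay absent
    (``None``), never coerced to zero.
    """

    def __init__(self, tree: dendropy.Tree, support_scale: str) -> None:
        if support_scale not in SUPPORT_SCALES:
            raise ValueError(f"unknown support scale: {support_scale!r}")
        self.support_scale = support_scale
        self._tree = tree
        self.leaves: frozenset[str] = frozenset(
            leaf.taxon.label for leaf in tree.leaf_node_iter()
        )
        if len(self.leaves) != sum(1 for _ in tree.leaf_node_iter()):
            raise ValueError("duplicate leaf labels in tree")
        lo, hi = SUPPORT_SCALES[support_scale]
        self._edges: list[tuple[Optional[float], frozenset[str]]] = []
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            support = _node_support(node)
            if support is not None and not lo <= support <= hi:
                raise ValueError(
                    f"support {support} outside {support_scale} range [{lo}, {hi}]"
                )
            under = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
            self._edges.append((support, under))

    @property
    def edges(self) -> list[tuple[Optional[float], frozenset[str]]]:
        """(support, leaf set under the child node) per internal edge."""
        return list(self._edges)

    def supported_bipartitions(
        self, min_support: float
    ) -> Iterator[tuple[float, frozenset[str], frozenset[str]]]:
        """Yield (support, side_under, side_rest) for edges with support >= min."""
        for support, under in self._edges:
            if support is not None and support >= min_support:
                yield support, under, self.leaves - under

    def __len__(self) -> int:
        return len(self.leaves)


def _node_support(node: dendropy.Node) -> Optional[float]:
    label = node.label
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        raise ValueError(f"internal node label {label!r} is not a numeric support")


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline, in one place.

    Defaults are the screen's published cutoffs: homology hits need >=27.5%
    identity and >=120 aligned residues, subsampled to <=3 per order and <=12
    per phylum with at most 1000 kept; alignment columns with >=50% gaps are
    discarded and alignments with <80 sites or <10 sequences dropped;
    metazoan nesting requires SH support >=0.9 (pass 1), non-metazoan nesting
    >=60% bootstrap (pass 2) and >=90% UFboot (confirmation). Acid-rich
    proteins need >28% D+E and pI < 5; acidity summaries use the 30%/40%
    cutoffs; secreted acidic collagens need pI < 7.
    """

    min_contig_bp: int = 300
    min_orf_aa: int = 100
    min_hit_identity: float = 27.5
    min_hit_aln_len: int = 120
    max_hits: int = 1000
    max_per_order: int = 3
    max_per_phylum: int = 12
    max_col_gap_frac: float = 0.50
    min_aln_sites: int = 80
    min_aln_seqs: int = 10
    pass1_min_sh: float = 0.9
    pass2_min_bootstrap: float = 60.0
    confirm_min_ufboot: float = 90.0
    carp_de_frac: float = 0.28
    carp_max_pi: float = 5.0
    acidity_thresholds: tuple[float, ...] = (0.30, 0.40)
    collagen_max_pi: float = 7.0
    tree_ortholog_min_frac: float = 0.50
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_hit_identity <= 100:
            raise ValueError("min_hit_identity must be a percentage")
        if not 0 <= self.max_col_gap_frac <= 1:
            raise ValueError("max_col_gap_frac must be a fraction")
        if not 0 <= self.pass1_min_sh <= 1:
            raise ValueError("pass1_min_sh is on the 0-1 SH scale")
        for value in (self.pass2_min_bootstrap, self.confirm_min_ufboot):
            if not 0 <= value <= 100:
                raise ValueError("bootstrap thresholds are percentages")
        if not 0 < self.carp_de_frac < 1:
            raise ValueError("carp_de_frac must be a fraction")
        if not 0 <= self.tree_ortholog_min_frac <= 1:
            raise ValueError("tree_ortholog_min_frac must be a fraction")
        self.acidity_thresholds = tuple(float(t) for t in self.acidity_thresholds)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["acidity_thresholds"] = list(self.acidity_thresholds)
        return d
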