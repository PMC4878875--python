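"""Readers and writers for the standard file formats the pipeline consumes.

FASTA goes through Bio.SeqIO (wrapped at 60 columns on output), Newick
through dendropy, and the tabular formats (12-column homology tables,
taxonomy TSV, ortholog-pair TSV, annotation TSV) through pandas.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .types import (
    BlastHit,
    Moltype,
    SequenceRecord,
    SupportTree,
    TaxonEntry,
    TaxonomyMap,
)

BLAST_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]


def read_fasta(path, moltype: Moltype | str = Moltype.protein) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Raises on missing/empty files and on duplicate ids; description text
    after the first whitespace is preserved separately.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    moltype = Moltype(moltype)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(
            SequenceRecord(
                id=rec.id, sequence=str(rec.seq), moltype=moltype, description=desc
            )
        )
    if not records:
        raise ValueError(f"no sequences in FASTA file: {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> str:
    """Write records as 60-column wrapped FASTA; returns the path."""
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(bio, handle, "fasta")
    return str(path)


def read_newick(path_or_string, support_scale: str) -> SupportTree:
    """Parse a Newick tree whose internal node labels are numeric supports.

    Missing labels are recorded as absent supports, never as zero. Supports
    outside the named scale's range raise.
    """
    src = str(path_or_string)
    if os.path.exists(src):
        with open(src) as handle:
            src = handle.read()
    tree = dendropy.Tree.get(
        data=src,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return SupportTree(tree, support_scale)


def read_blast_tab(path) -> list[BlastHit]:
    """Read a 12-column tab-separated homology table, preserving row order."""
    hits: list[BlastHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            hits.append(
                BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path) -> str:
    rows = [[getattr(h, c) for c in BLAST_COLUMNS] for h in hits]
    pd.DataFrame(rows, columns=BLAST_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )
    return str(path)


def read_taxonomy(path) -> TaxonomyMap:
    """Read the taxonomy TSV ``id<TAB>species<TAB>order<TAB>phylum<TAB>major_group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["id", "species", "order", "phylum", "major_group"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(df.columns)}")
    tax = TaxonomyMap()
    for row in df.itertuples(index=False):
        tax.add(
            row.id,
            TaxonEntry(
                species=row.species,
                order=row.order,
                phylum=row.phylum,
                major_group=row.major_group,
            ),
        )
    return tax


def write_taxonomy(entries: dict[str, TaxonEntry], path) -> str:
    rows = [
        (key, e.species, e.order, e.phylum, e.major_group)
        for key, e in entries.items()
    ]
    pd.DataFrame(
        rows, columns=["id", "species", "order", "phylum", "major_group"]
    ).to_csv(path, sep="\t", index=False)
    return str(path)


def read_annotations(path) -> dict[str, dict[str, bool]]:
    """Read the per-protein annotation TSV with collagen-domain and
    secretion-signal flags (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    expected = ["protein_id", "has_collagen_domain", "has_secretion_signal"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(df.columns)}")
    return {
        row.protein_id: {
            "has_collagen_domain": bool(int(row.has_collagen_domain)),
            "has_secretion_signal": bool(int(row.has_secretion_signal)),
        }
        for row in df.itertuples(index=False)
    }
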