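"""Assembly preprocessing: contig length filtering, ORF extraction,
duplicate removal and GC-content bimodality validation.

The ORF extractor is a deliberate simplification of dedicated gene
predictors: it reports the single longest ATG-initiated open reading frame
across all six frames. Duplicate removal is exact string identity after
uppercasing. The GC bimodality check formalizes the visual
"two humps in the GC histogram" validation of host/symbiont separation as a
1-vs-2 component Gaussian-mixture comparison by BIC.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
from Bio.Seq import Seq
from sklearn.mixture import GaussianMixture

from .types import Moltype, SequenceRecord

_STOPS = {"TAA", "TAG", "TGA"}


def filter_contigs(
    records: Iterable[SequenceRecord], min_contig_bp: int = 300
) -> list[SequenceRecord]:
    """Drop nucleotide contigs shorter than ``min_contig_bp`` (boundary kept)."""
    records = list(records)
    for r in records:
        if r.moltype is not Moltype.nucleotide:
            raise TypeError(f"filter_contigs expects nucleotide records, got {r.id!r}")
    return [r for r in records if len(r) >= min_contig_bp]


def _orfs_in_frame(seq: str, offset: int):
    """Yield (start, aa_length, protein) for ATG-initiated ORFs in one frame."""
    codons = [seq[i : i + 3] for i in range(offset, len(seq) - 2, 3)]
    i = 0
    while i < len(codons):
        if codons[i] == "ATG":
            j = i
            while j < len(codons) and codons[j] not in _STOPS:
                j += 1
            aa = str(Seq("".join(codons[i:j])).translate())
            yield offset + 3 * i, len(aa), aa
            i = j  # ORFs starting inside this one are strictly shorter
        else:
            i += 1


def longest_orf(
    contig: SequenceRecord, min_aa: int = 100
) -> Optional[SequenceRecord]:
    """Translate the longest ATG-initiated ORF over all six reading frames.

    An ORF runs from ATG to the first in-frame stop (or the end of the
    sequence). Ties break by frame index (three forward frames first, then
    three on the reverse complement), then by start position. Returns None
    when the longest ORF is shorter than ``min_aa`` residues. Ambiguous
    bases (N) are not scanned through: codons containing N never start an
    ORF and translate to X within one.
    """
    if contig.moltype is not Moltype.nucleotide:
        raise TypeError("longest_orf expects a nucleotide record")
    seq = contig.sequence
    frames = [(seq, 0), (seq, 1), (seq, 2)]
    rc = str(Seq(seq).reverse_complement())
    frames += [(rc, 0), (rc, 1), (rc, 2)]
    best: Optional[tuple[int, int, int, str]] = None  # (-len, frame, start, aa)
    for frame_idx, (s, off) in enumerate(frames):
        for start, aa_len, aa in _orfs_in_frame(s, off):
            key = (-aa_len, frame_idx, start, aa)
            if best is None or key < best:
                best = key
    if best is None or -best[0] < min_aa:
        return None
    return SequenceRecord(
        id=contig.id,
        sequence=best[3],
        moltype=Moltype.protein,
        species=contig.species,
        description=f"frame={best[1]} start={best[2]}",
    )


def dedupe_exact(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Keep the first occurrence of each distinct sequence string."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.sequence not in seen:  # sequences are normalized to uppercase
            seen.add(r.sequence)
            out.append(r)
    return out


def gc_fraction(record: SequenceRecord) -> float:
    """(G+C)/(A+C+G+T); N excluded from the denominator."""
    seq = record.sequence
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError(f"no unambiguous bases in {record.id!r}")
    return gc / acgt


def gc_bimodality(
    records: Iterable[SequenceRecord], random_seed: int = 0
) -> dict:
    """Test whether per-contig GC fractions form two modes.

    Fits 1- and 2-component Gaussian mixtures to the GC values and calls the
    distribution bimodal when the 2-component model has the lower BIC — the
    signature of a mixed host/symbiont assembly.
    """
    records = list(records)
    if len(records) < 50:
        raise ValueError(
            f"gc_bimodality needs >=50 records for a stable fit, got {len(records)}"
        )
    values = np.array([gc_fraction(r) for r in records]).reshape(-1, 1)
    bics = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=random_seed)
        gm.fit(values)
        bics[k] = gm.bic(values)
    return {
        "gc_values": values.ravel().tolist(),
        "bimodal": bool(bics[2] < bics[1]),
        "bic_1": float(bics[1]),
        "bic_2": float(bics[2]),
    }
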