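"""Acid-rich proteome scoring: D+E composition, isoelectric points, and the
coral acid-rich protein (CARP) and secreted acidic-collagen screens.

Corals nucleate their aragonite skeleton on a matrix of highly acidic
proteins. The screens here quantify that signal: the fraction of
negatively charged residues (aspartate + glutamate) per protein, the
isoelectric point from a Henderson–Hasselbalch charge model solved by
bisection, the CARP criterion (>28% D+E and pI < 5), and the secreted
acidic-collagen criterion (collagen domain + secretion signal + pI < 7,
with domain/signal annotations supplied as input).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import Moltype, PipelineConfig, SequenceRecord


@dataclass(frozen=True)
class PKaTable:
    """Dissociation constants for the ionizable groups (pH units).

    The widely used nine-group set; every value can be overridden.
    """

    n_terminus: float = 8.6
    c_terminus: float = 3.6
    K: float = 10.8
    R: float = 12.5
    H: float = 6.5
    D: float = 3.9
    E: float = 4.1
    C: float = 8.5
    Y: float = 10.1

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa {name}={value} outside (0, 14)")

    BASIC_RESIDUES = ("K", "R", "H")
    ACIDIC_RESIDUES = ("D", "E", "C", "Y")


@dataclass
class AcidityRecord:
    """Per-protein acidity: D+E count/fraction and isoelectric point."""

    protein_id: str
    length: int
    de_count: int
    de_fraction: float
    pi: Optional[float] = None


def de_fraction(protein: SequenceRecord) -> AcidityRecord:
    """Fraction of aspartate+glutamate residues; ambiguity codes (X/B/Z)
    count toward length but never toward D+E."""
    if protein.moltype is not Moltype.protein:
        raise TypeError("de_fraction expects a protein record")
    seq = protein.sequence
    de = seq.count("D") + seq.count("E")
    return AcidityRecord(
        protein_id=protein.id,
        length=len(seq),
        de_count=de,
        de_fraction=de / len(seq),
    )


def net_charge(sequence: str, ph: float, pka: PKaTable = PKaTable()) -> float:
    """Net charge at a given pH under the Henderson–Hasselbalch model.

    Positive groups (N-terminus, K, R, H) contribute 1/(1+10^(pH−pKa));
    negative groups (C-terminus, D, E, C, Y) contribute −1/(1+10^(pKa−pH)).
    """
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka.n_terminus))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - ph))
    for res in PKaTable.BASIC_RESIDUES:
        n = sequence.count(res)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - getattr(pka, res)))
    for res in PKaTable.ACIDIC_RESIDUES:
        n = sequence.count(res)
        if n:
            charge -= n / (1.0 + 10.0 ** (getattr(pka, res) - ph))
    return charge


def isoelectric_point(
    protein: SequenceRecord | str,
    pka: PKaTable = PKaTable(),
    tol: float = 1e-3,
) -> float:
    """pH at which the modeled net charge crosses zero, by bisection on [0, 14].

    The charge curve is monotone decreasing in pH, so the crossing is
    unique when it exists; a curve with no sign change (possible only under
    pKa overrides that remove all ionizable groups of one sign) raises.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    seq = protein.sequence if isinstance(protein, SequenceRecord) else str(protein).upper()
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(seq, lo, pka), net_charge(seq, hi, pka)
    if c_lo < 0 or c_hi > 0:
        raise ValueError("net charge has no zero crossing on [0, 14]; pI undefined")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def acidity_profile(
    records: Iterable[SequenceRecord],
    pka: PKaTable = PKaTable(),
    tol: float = 1e-3,
    with_pi: bool = True,
) -> list[AcidityRecord]:
    """Per-protein D+E fraction, optionally with isoelectric points."""
    out = []
    for rec in records:
        acid = de_fraction(rec)
        if with_pi:
            acid.pi = isoelectric_point(rec, pka, tol)
        out.append(acid)
    return out


@dataclass
class SpeciesAciditySummary:
    species: str
    n_proteins: int
    percent_above: dict[float, float]  # threshold -> percent (strict >)
    group: str = ""


def proteome_acidity_summary(
    records_by_species: Mapping[str, Sequence[SequenceRecord]],
    thresholds: Sequence[float] = (0.30, 0.40),
    group_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[SpeciesAciditySummary], pd.DataFrame]:
    """Per-species percent of proteins above each D+E threshold, plus
    per-group mean and sample (n−1) standard deviation across species.

    Thresholds are strict: a protein at exactly 30% D+E does not count
    toward the 30% cutoff.
    """
    summaries: list[SpeciesAciditySummary] = []
    for species, records in records_by_species.items():
        if not records:
            raise ValueError(f"no proteins for species {species!r}")
        fractions = np.array([de_fraction(r).de_fraction for r in records])
        pct = {
            float(t): 100.0 * float(np.mean(fractions > t)) for t in thresholds
        }
        group = group_map.get(species, "") if group_map else ""
        summaries.append(
            SpeciesAciditySummary(
                species=species,
                n_proteins=len(records),
                percent_above=pct,
                group=group,
            )
        )
    rows = []
    for s in summaries:
        for t, pct in s.percent_above.items():
            rows.append((s.species, s.group, t, pct))
    df = pd.DataFrame(rows, columns=["species", "group", "threshold", "percent_above"])
    group_stats = (
        df.groupby(["group", "threshold"])["percent_above"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    return summaries, group_stats


def carp_candidate(
    record: AcidityRecord, config: PipelineConfig = PipelineConfig()
) -> bool:
    """CARP criterion: strictly more than 28% D+E and pI strictly below 5."""
    if record.pi is None:
        raise ValueError(f"pI not computed for {record.protein_id!r}")
    return record.de_fraction > config.carp_de_frac and record.pi < config.carp_max_pi


def acidic_collagen_screen(
    records: Sequence[AcidityRecord],
    annotations: Mapping[str, Mapping[str, bool]],
    config: PipelineConfig = PipelineConfig(),
) -> list[AcidityRecord]:
    """Secreted acidic collagens: collagen Pfam domain + secretion signal
    (both supplied as annotations) and pI strictly below 7."""
    out = []
    for rec in records:
        if rec.protein_id not in annotations:
            raise KeyError(f"annotation missing for protein {rec.protein_id!r}")
        if rec.pi is None:
            raise ValueError(f"pI not computed for {rec.protein_id!r}")
        ann = annotations[rec.protein_id]
        if (
            ann["has_collagen_domain"]
            and ann["has_secretion_signal"]
            and rec.pi < config.collagen_max_pi
        ):
            out.append(rec)
    return out
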