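# coralhgt

Comparative-genomics toolkit for reef-building corals: a two-pass
phylogenomic screen for horizontally transferred genes, lineage-based
ortholog-group categorization, and acid-rich proteome scoring, together
with synthetic-data generators so every stage can be exercised offline with
known ground truth.

## Who this is for

Researchers analyzing coral (and more broadly anthozoan) genome and
transcriptome assemblies who want a tested, scriptable implementation of
three standard analyses:

1. **Horizontal gene transfer (HGT) screening.** Given per-query gene trees
   built at three stages (a fast tree with Shimodaira–Hasegawa-like local
   supports, a maximum-likelihood tree with bootstrap supports, and a
   confirmation tree with ultrafast-bootstrap supports), decide for each
   coral query protein whether it is *nested* inside a well-supported clade
   of non-metazoan sequences — the phylogenomic signature of a foreign gene.
2. **Ortholog-group categorization.** Cluster filtered pairwise ortholog
   assignments into multi-species groups and place each group at the
   smallest lineage of the fixed hierarchy (robust corals / complex corals ⊂
   Scleractinia; Scleractinia, Actiniaria ⊂ Hexacorallia ⊂ Anthozoa ⊂
   Cnidaria; plus a disjoint non-cnidarian bin and the root).
3. **Acid-rich proteome scoring.** Quantify negatively charged residue
   content (aspartate + glutamate), compute isoelectric points from a
   Henderson–Hasselbalch charge model, and apply the coral acid-rich
   protein (CARP) criterion (>28% D+E and pI < 5) and the secreted
   acidic-collagen criterion (collagen domain + secretion signal + pI < 7).

## The core statistic: tree nesting

For a query *q* and a gene tree *T* with per-edge supports, *q* is **nested
within group G at threshold s** iff some internal edge of the unrooted tree
has support ≥ *s* and induces a bipartition with a side *C* such that

- *q* ∈ *C*,
- |*C* \ {q}| ≥ 2, and
- every non-query leaf of *C* belongs to *G*.

The smallest such side is the nesting clade. The screen discards queries
that are metazoan-nested at SH ≥ 0.9 (pass 1, vertical animal genes), keeps
queries that are non-metazoan-nested at bootstrap ≥ 60% (pass 2), confirms
them at UFboot ≥ 90%, drops calls private to a single species, labels the
donor from the nesting clade's taxonomic composition, assigns each event to
the coral or anthozoan ancestor, and collapses redundant calls (the same
transfer seen from two query proteomes, or recent paralogs) into
non-redundant events.

Net charge for the isoelectric point is modeled as

Z(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))

over the N-terminus, C-terminus and K, R, H, D, E, C, Y side chains, and
the pI is the unique zero crossing found by bisection on [0, 14].

## Worked example

```python
from coralhgt import (read_newick, classify_placement, TaxonomyMap,
                      TaxonEntry, hgt_rate, isoelectric_point,
                      de_fraction, SequenceRecord)
from coralhgt.hgt import assign_donor

tax = TaxonomyMap({
    "acro_q": TaxonEntry("Acropora_digitifera", "Scleractinia", "Cnidaria", "CoralComplex"),
    "ecoli":  TaxonEntry("Escherichia_coli", "Enterobacterales", "Proteobacteria", "Bacteria"),
    "bsub":   TaxonEntry("Bacillus_subtilis", "Bacillales", "Firmicutes", "Bacteria"),
    "vibrio": TaxonEntry("Vibrio_sp", "Vibrionales", "Proteobacteria", "Bacteria"),
    "human":  TaxonEntry("Homo_sapiens", "Primates", "Chordata", "OtherMetazoa"),
    "fly":    TaxonEntry("Drosophila", "Diptera", "Arthropoda", "OtherMetazoa"),
})
tree = read_newick("(((acro_q,ecoli)97,(bsub,vibrio)88)95,(human,fly)90);", "ufboot_pct")
placement = classify_placement(tree, ["acro_q"], tax, "nonmetazoan_nesting", 90)
print("nested:", placement.nested)
print("nesting clade:", sorted(placement.nesting_clade_leaves))
print("edge support:", placement.supporting_edge_support)
print("donor label:", assign_donor(placement))
print("screen-wide rate:", hgt_rate(62, 32956), "%")

carp = SequenceRecord("carp_like", "DDEDDSEDDEDGSDEDDAEDDE")
rec = de_fraction(carp)
print("D+E fraction:", round(rec.de_fraction, 3), " pI:", round(isoelectric_point(carp), 2))
```

prints

```
nested: True
nesting clade: ['acro_q', 'bsub', 'ecoli', 'vibrio']
edge support: 95.0
donor label: Bact
screen-wide rate: 0.2 %
D+E fraction: 0.818  pI: 2.68
```

The coral query sits inside a clade of three bacteria on an edge with 95%
ultrafast-bootstrap support, so it is called non-metazoan-nested with donor
label "Bact"; 62 supporting trees out of 32,956 screened is an HGT rate of
0.2%; and the highly acidic example protein (81.8% D+E, pI 2.7) satisfies
the CARP criterion.

## Command line

The `coralhgt` entry point exposes `preprocess`, `orthologs`, `hgt-screen`,
`acidity` and `simulate` subcommands with common `--config`, `--seed` and
`--out-dir` flags. Each run writes a `manifest.json` with the config
snapshot, input checksums and per-stage counts; identical manifests
reproduce identical outputs.

```
coralhgt simulate --n-bundles 6 --seed 7 --out-dir sim
coralhgt hgt-screen --trees-dir sim --taxonomy sim/taxonomy.tsv --out-dir screen
```

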