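# Methods

## The screening model

The HGT screen treats gene trees as the primary evidence. A transfer is
never inferred from sequence similarity alone: a coral query protein must
sit *inside* a supported clade of foreign sequences in its gene tree. The
package formalizes "nested within group G" on the unrooted tree: an internal
edge with support at or above the stage threshold must induce a bipartition
with a side containing the query, at least two non-query leaves, and no
non-query leaf outside G. The smallest qualifying side is reported as the
nesting clade. Requiring two non-query group leaves prevents a single
long-branch neighbour from producing a call; requiring purity of the side
makes the criterion conservative — one metazoan inside an otherwise
bacterial clade vetoes the call.

A consequence of working with bipartitions is worth spelling out: a query
that is *sister to* a complete foreign clade is not inside it. The
complement of that clade (query plus all remaining taxa) is itself a
bipartition side, and if the remaining taxa are all metazoan the query reads
as metazoan-nested. Only queries grafted strictly within the foreign clade
produce unambiguous non-metazoan nesting. The synthetic generator therefore
plants transfers by attaching the query sister to one donor leaf inside the
donor clade.

The two-pass structure mirrors how such screens are run in practice:

1. **Pass 1 (discard vertical genes).** On fast gene trees with SH-like
   local supports (scale 0–1), queries metazoan-nested at ≥ 0.9 are
   vertical animal genes and leave the pipeline.
2. **Pass 2 (candidate call).** On ML trees with bootstrap supports over an
   expanded taxon set, queries non-metazoan-nested at ≥ 60% become
   candidates.
3. **Confirmation.** On independently rebuilt trees with ultrafast
   bootstrap supports, candidates must be non-metazoan-nested at ≥ 90%.
4. **Species-uniqueness discard.** A call private to the query's own
   species (no other coral or anthozoan taxon in the pass-2 gene family) is
   rejected — a guard against contamination and assembly artifacts.
5. **Donor labelling.** One major group in the nesting clade gives its
   abbreviation (Bact, CA, Dino, Viri, …); exactly two give a composite
   "A/B" label in alphabetical order; three or more give "Unclear". The
   1/2/≥3-group rule is this package's explicit operationalization of what
   is otherwise a manual judgement.
6. **Ancestor assignment.** An event is dated to the anthozoan common
   ancestor when its gene family includes a homolog from a sea anemone
   (Actiniaria) or another non-scleractinian anthozoan (e.g. a sea fan);
   otherwise it is coral-specific.
7. **Redundancy collapse.** Confirmed candidates are linked when one's
   query appears among the other's tree leaves (the same ancient transfer
   seen from two query proteomes) or when they share an ortholog cluster
   (recent paralogs); events are the connected components of this link
   graph. Manual curation can be injected as extra links.

Tree building itself (FastTree/RAxML/IQtree-class programs) is outside the
package: each stage consumes Newick files whose internal node labels are
numeric supports, validated against the declared support scale
(`sh_local` 0–1, `bootstrap_pct` and `ufboot_pct` 0–100). Missing supports
stay absent and can never satisfy a threshold; they are not coerced to zero.

## Hit selection and alignment QC

Homology hits feed the tree-building stages. For each query, hits below
27.5% identity are discarded; among the rest, hits with ≥ 120 aligned
residues are sorted by identity descending (ties broken by bitscore
descending, then subject id — the tie-break is this package's choice, made
explicit so selection is invariant to input row order) and retrieved
greedily with at most 3 subjects per taxonomic order, 12 per phylum and
1000 in total. The caps force taxonomic breadth into the alignments:
without them a query's tree would be dominated by its densest-sampled
relatives. Alignment columns with ≥ 50% gaps are discarded, and trimmed
alignments with fewer than 80 sites or fewer than 10 sequences are dropped.
All threshold comparisons keep the printed inequality directions (≥ 27.5,
≥ 120, ≥ 50% discarded, < 80 and < 10 removed, ≥ 0.9, ≥ 60, ≥ 90).

## Ortholog groups

Pairwise ortholog tables are filtered to confidence exactly 1 with one
sequence per species in each pair, then clustered as connected components
of the pair graph. A component in which one species contributes two
different sequences is flagged as a conflict and excluded from
categorization rather than resolved by guesswork. Each clean cluster is
assigned the *smallest containing lineage*: the smallest named lineage of
the fixed hierarchy whose species set contains every member species. This
reading makes the nine categories mutually exclusive and exhaustive; the
alternative literal reading ("present in this group and absent in all
others") is ambiguous for nested groups, and smallest-containing-lineage is
the interpretation that reproduces a mutually exclusive category structure.
For species-tree construction, root-category clusters qualify when at least
one lineage has ≥ 50% of its species represented (inclusive boundary,
existential over lineages — "any lineage" is read as ∃ one).

## Preprocessing

Contigs shorter than 300 bp are removed (boundary kept). ORF extraction is
a deliberate simplification of dedicated predictors: the single longest
ATG-initiated open reading frame over all six frames, ending at the first
in-frame stop or the sequence end, with ties broken by frame index then
start position; the default minimum is 100 residues. Duplicate removal is
exact string identity after uppercasing, keeping the first occurrence.
Host/symbiont separation is validated — not performed — here: per-contig GC
fractions (N excluded from the denominator) are fitted with one- and
two-component Gaussian mixtures and the assembly is called bimodal when the
two-component model wins by BIC, formalizing the visual two-humps check. At
least 50 contigs are required for a stable fit.

## Acidity scoring

D+E fractions count aspartate and glutamate over the full residue length;
ambiguity codes (X/B/Z) count toward length but never toward D+E, a
conservative choice that can only lower a protein's measured acidity. The
isoelectric point solves Z(pH) = 0 by bisection on [0, 14] to a default
tolerance of 1e-3 pH under a nine-group pKa table (N-terminus 8.6,
C-terminus 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1), stated
explicitly and overridable since published pI values vary with the chosen
table. The charge curve is strictly decreasing in pH, so the crossing is
unique; a curve with no sign change (possible only under overrides that
silence all groups of one sign) raises rather than returning a boundary
value. Proteome summaries report the percentage of proteins strictly above
each D+E cutoff (0.30 and 0.40 by default) per species, with group means
and sample (n−1) standard deviations across species. The CARP criterion is
strict on both sides (> 0.28 D+E, pI < 5), as is the secreted
acidic-collagen criterion (pI < 7, with collagen-domain and
secretion-signal annotations supplied as input — domain and signal
prediction are upstream of this package). No minimum protein length is
imposed on the summaries.

## Synthetic data: what it does and does not emulate

The generators produce inputs with the *decision-relevant* structure of
each stage, not realistic sequence evolution.

- **Tree bundles** use uniform-random bifurcating topologies (repeated
  random pairwise joins), not a birth–death process: the classifier only
  interrogates bipartitions and supports, so the simplest topology null
  suffices. Off the transfer edge, supports are uniform on [50, 100] so
  that thresholds actually bite. A planted bundle grafts the coral query
  sister to one donor leaf inside a clade of 4 donor-group leaves
  (default: Bacteria) among 8 metazoan leaves plus a second coral species
  (so the species-uniqueness discard never masks a true plant); the edge
  subtending the donor clade carries the configured transfer support
  (default 100, the maximal-support regime). A no-transfer bundle grafts
  the query sister to one metazoan leaf deep inside the metazoan clade,
  which makes non-metazoan nesting structurally impossible — the
  false-positive rate of the screen on such bundles is therefore a test of
  the implementation, not of sampling luck.
- **Homology tables** draw identities uniformly (default 20–95%) and
  lengths normally (mean 160, SD 40 residues) across configured
  order/phylum blocks, with the ground-truth selectable set computed by an
  independent re-application of the filter rules.
- **Proteomes** draw residues i.i.d. from class-specific frequency vectors:
  a background class at 12% D+E (typical of real proteomes) and an
  acid-rich class at 35% D+E, safely beyond the 28% CARP bound; protein
  lengths are uniform on 200–600 residues so that compositional noise
  around the class mean (SD ≈ 0.027 at 300 residues) rarely crosses the
  cutoffs. Real acid-rich proteins have low-complexity domain structure,
  not i.i.d. composition; the generator validates the *counting*, not the
  biology. The two-fold enrichment study gives coral species an acid-rich
  proportion of 0.10 and non-coral species 0.05, over a default panel of 20
  coral and 12 non-calcifying species — the comparison's real design — with
  1000 proteins per species; the group-mean ratio at the 30% cutoff then
  carries a simulation SD of about 0.07, so the recovery test's ±0.4 band
  is a wide (>5-sigma) acceptance region. The 40% cutoff is
  computed in summaries but not used for the ratio check: the acid-rich
  class mean (0.35) sits below it, leaving only unstable tail counts.
- **Ortholog tables** build each family by drawing one species from each
  spanning pool of its target category (so the smallest containing lineage
  equals the target exactly), padding with extra species from within the
  category, and emitting all pairwise pairs at confidence 1. Noise pairs at
  confidence 0.9 exercise the filter. The default species panel (4 robust
  corals, 3 complex corals, 2 anemones, 1 ceriantharian, 1 sea fan,
  1 hydrozoan, 4 outgroups) is a scaled-down stand-in for a realistic taxon
  sample; it covers every lineage of the hierarchy.

All generators are bit-reproducible under a fixed seed.

## Numerical and design choices

- **Rounding of the screen-wide rate:** half away from zero at one decimal,
  so 1/400 = 0.25% reports as 0.3%.
- **Support comparisons** are inclusive (≥) everywhere, matching the stated
  thresholds; the CARP/collagen criteria are strict (>, <).
- **Root edges in rooted Newick input:** the two children of the root
  describe the same unrooted bipartition and may carry different labels;
  both are enumerated, and where the same side qualifies twice the larger
  support is reported.
- **Tie-break for the nesting clade:** smallest side first, then
  lexicographic leaf order, then larger support — fully deterministic.
- **Event donor label:** the most common member donor label, ties broken
  alphabetically.
- **Degenerate inputs:** empty FASTA, duplicate ids, ragged alignments,
  unknown taxa, missing stage trees and annotation gaps all raise errors
  naming the offending record rather than proceeding silently.

## Problem sizes used in the checks

The bundled checks run at desk scale by design: 1,000 random trees of ≤ 15
leaves for oracle agreement, 200 tree bundles for planted-transfer
recovery, 500 synthetic ortholog families, and 32 proteomes of 1,000
proteins for the enrichment recovery. These sizes make the binomial error
bands quoted above small enough for the stated tolerances while keeping the
whole suite runnable in seconds.

## Known limitations

- The ORF extractor ignores codon usage, coding potential and partial ORFs;
  it is a stand-in adequate for pipeline plumbing, not a gene predictor.
- Exact-duplicate removal does not cluster near-identical sequences; the
  ~85%-identity clustering used to build reference databases is a separate,
  out-of-scope operation.
- The GC bimodality check validates that host/symbiont separation happened;
  it does not perform the separation.
- "Nested within" is one formalization of a criterion that is applied
  partly by manual inspection in practice; the brute-force oracle
  guarantees internal consistency, not equivalence to any particular
  curator's judgement.
- The synthetic generators share the package's vocabulary of taxonomic
  groups; recovery results demonstrate correctness of the decision logic
  under the stated conditions, not performance on real mixed assemblies.
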