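"""Hit subsampling, alignment QC, nesting classification and event calling.

The nesting classifier is checked against an independent brute-force oracle
built on a separate minimal Newick parser: every supported bipartition is
enumerated and the nesting rule applied directly.
"""

import numpy as np
import pytest

from coralhgt.hgt import (
    HGTCandidate,
    assign_ancestor,
    assign_donor,
    classify_placement,
    collapse_redundant,
    hgt_rate,
    qc_alignment,
    run_two_pass_screen,
    select_hits,
    trim_alignment,
)
from coralhgt.io import read_newick
from coralhgt.types import (
    BlastHit,
    MSA,
    PipelineConfig,
    TaxonEntry,
    TaxonomyMap,
    is_metazoan,
)

CFG = PipelineConfig()


def hit(query="q1", subject="s1", identity=40.0, length=150, bitscore=100.0):
    return BlastHit(query, subject, identity, length, 0, 0, 1, length, 1, length,
                    1e-20, bitscore)


def flat_taxonomy(subjects):
    """subjects: dict id -> (order, phylum); all bacteria."""
    tax = TaxonomyMap()
    for sid, (order, phylum) in subjects.items():
        tax.add(sid, TaxonEntry(f"sp_{sid}", order, phylum, "Bacteria"))
    return tax


class TestSelectHits:
    def test_per_order_cap_three(self):
        hits = [hit(subject=f"s{i}", identity=40 - 2 * i) for i in range(5)]
        tax = flat_taxonomy({f"s{i}": ("o1", "p1") for i in range(5)})
        sel = select_hits(hits, tax, CFG)
        assert sel.subject_ids == ["s0", "s1", "s2"]

    def test_per_phylum_cap_twelve(self):
        # 13 eligible hits over 5 orders (<=3 each) in one phylum
        subjects = {}
        hits = []
        i = 0
        for order in range(5):
            for _ in range(3 if order < 4 else 1):
                sid = f"s{i:02d}"
                subjects[sid] = (f"o{order}", "p1")
                hits.append(hit(subject=sid, identity=90 - i))
                i += 1
        sel = select_hits(hits, flat_taxonomy(subjects), CFG)
        assert len(sel.subject_ids) == 12

    def test_identity_boundary_inclusive(self):
        hits = [hit(subject="a", identity=27.5), hit(subject="b", identity=27.49)]
        tax = flat_taxonomy({"a": ("o1", "p1"), "b": ("o2", "p2")})
        sel = select_hits(hits, tax, CFG)
        assert sel.subject_ids == ["a"]

    def test_length_boundary_inclusive(self):
        hits = [hit(subject="a", length=120), hit(subject="b", length=119)]
        tax = flat_taxonomy({"a": ("o1", "p1"), "b": ("o2", "p2")})
        assert select_hits(hits, tax, CFG).subject_ids == ["a"]

    def test_row_order_invariance(self, rng):
        subjects = {f"s{i:02d}": (f"o{i % 4}", f"p{i % 2}") for i in range(20)}
        tax = flat_taxonomy(subjects)
        hits = [
            hit(subject=s, identity=float(rng.uniform(20, 95)),
                length=int(rng.integers(100, 300)),
                bitscore=float(rng.uniform(50, 400)))
            for s in subjects
        ]
        base = select_hits(hits, tax, CFG).subject_ids
        for _ in range(5):
            shuffled = [hits[i] for i in rng.permutation(len(hits))]
            assert select_hits(shuffled, tax, CFG).subject_ids == base

    def test_missing_taxonomy_names_subject(self):
        hits = [hit(subject="mystery")]
        with pytest.raises(KeyError, match="mystery"):
            select_hits(hits, flat_taxonomy({}), CFG)


class TestTrimAndQC:
    def test_column_at_half_gaps_removed(self):
        msa = MSA([("a", "MK"), ("b", "M-"), ("c", "MK"), ("d", "M-")])
        trimmed = trim_alignment(msa, 0.50)
        assert trimmed.n_columns == 1

    def test_column_below_half_kept_and_gap_free_identity(self):
        msa = MSA([("a", "MK"), ("b", "M-"), ("c", "MK"), ("d", "MK")])
        assert trim_alignment(msa, 0.50).n_columns == 2
        clean = MSA([("a", "MKL"), ("b", "MKV")])
        assert trim_alignment(clean, 0.50) == clean

    def test_trim_idempotent(self):
        msa = MSA([("a", "M-KL"), ("b", "M--L"), ("c", "MK-L"), ("d", "M-KL")])
        once = trim_alignment(msa, 0.50)
        assert trim_alignment(once, 0.50) == once

    @pytest.mark.parametrize(
        "cols,rows,passed,reason",
        [(80, 10, True, ""), (79, 12, False, "sites"), (120, 9, False, "sequences")],
    )
    def test_qc_boundaries(self, cols, rows, passed, reason):
        msa = MSA([(f"r{i}", "A" * cols) for i in range(rows)])
        result = qc_alignment(msa, CFG)
        assert result["pass"] is passed
        assert reason in result["reason"]


# ---------------------------------------------------------------------------
# independent brute-force nesting oracle


def _parse_newick(newick):
    """Minimal independent Newick parser: returns (leaves, [(support, side)])."""
    s = newick.strip().rstrip(";")
    pos = 0

    def parse_node():
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = [parse_node()]
            while s[pos] == ",":
                pos += 1
                children.append(parse_node())
            assert s[pos] == ")"
            pos += 1
            label = ""
            while pos < len(s) and s[pos] not in ",()":
                label += s[pos]
                pos += 1
            leaves = frozenset().union(*(c[0] for c in children))
            edges = [e for c in children for e in c[1]]
            support = float(label) if label else None
            return leaves, edges + [(support, leaves)]
        label = ""
        while pos < len(s) and s[pos] not in ",()":
            label += s[pos]
            pos += 1
        return frozenset([label]), []

    leaves, edges = parse_node()
    # drop the root pseudo-edge (covers all leaves)
    edges = [(sup, side) for sup, side in edges if side != leaves]
    return leaves, edges


def oracle_placement(newick, queries, group_of, mode, min_support):
    """Brute force: enumerate both sides of every supported bipartition."""
    queries = frozenset(queries)
    leaves, edges = _parse_newick(newick)
    predicate = is_metazoan if mode == "metazoan_nesting" else (
        lambda g: not is_metazoan(g)
    )
    best = None
    for support, side in edges:
        if support is None or support < min_support:
            continue
        for candidate in (side, leaves - side):
            if not queries <= candidate:
                continue
            non_query = candidate - queries
            if len(non_query) < 2:
                continue
            if all(predicate(group_of[leaf]) for leaf in non_query):
                key = (len(candidate), tuple(sorted(candidate)), -support)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    return best[1], -best[2]


def random_tree_case(rng, scale):
    """A random supported tree over <=15 leaves with random groups."""
    n = int(rng.integers(5, 16))
    labels = ["q"] + [f"L{i}" for i in range(n - 1)]
    groups = ["OtherMetazoa", "Bacteria", "CAAlgae", "Dinoflagellata",
              "Viridiplantae", "OtherCnidaria", "CoralRobust"]
    group_of = {"q": "CoralComplex"}
    tax = TaxonomyMap()
    tax.add("q", TaxonEntry("query_sp", "o_q", "p_q", "CoralComplex"))
    for label in labels[1:]:
        g = str(rng.choice(groups))
        group_of[label] = g
        tax.add(label, TaxonEntry(f"sp_{label}", f"o_{g}", f"p_{g}", g))

    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if rng.random() < 0.8:
            sup = rng.uniform(0, 1) if scale == "sh_local" else rng.uniform(0, 100)
            label = f"{sup:.3f}"
        else:
            label = ""
        nodes.append(f"({a},{b}){label}")
    return nodes[0] + ";", group_of, tax


class TestClassifyPlacement:
    def test_nested_in_bacterial_clade(self, taxonomy):
        tree = read_newick("((q,(b1,b2)95)98,(m1,(m2,m3)80)90);", "bootstrap_pct")
        result = classify_placement(tree, ["q"], taxonomy, "nonmetazoan_nesting", 60)
        assert result.nested
        assert result.nesting_clade_leaves == {"q", "b1", "b2"}
        assert result.supporting_edge_support == 98
        assert result.donor_groups == ("Bacteria", "Bacteria")

    def test_not_nested_when_metazoan_blocks(self, taxonomy):
        tree = read_newick("((q,m1)99,(b1,b2)97);", "bootstrap_pct")
        result = classify_placement(tree, ["q"], taxonomy, "nonmetazoan_nesting", 60)
        assert not result.nested

    def test_metazoan_nesting_vertical_signal(self, taxonomy):
        tree = read_newick("((q,(m1,m2)0.95)0.99,(b1,b2));", "sh_local")
        result = classify_placement(tree, ["q"], taxonomy, "metazoan_nesting", 0.9)
        assert result.nested

    def test_query_absent_raises(self, taxonomy):
        tree = read_newick("((m1,m2)90,(b1,b2)90);", "bootstrap_pct")
        with pytest.raises(KeyError):
            classify_placement(tree, ["q"], taxonomy, "nonmetazoan_nesting", 60)

    def test_scale_mode_mismatch_raises(self, taxonomy):
        tree = read_newick("((q,m1)0.9,(b1,b2)0.9);", "sh_local")
        with pytest.raises(ValueError, match="scale|support"):
            classify_placement(tree, ["q"], taxonomy, "nonmetazoan_nesting", 60)

    def test_agrees_with_bipartition_oracle_on_random_trees(self, rng):
        """100% agreement with brute-force enumeration on 1,000 random trees."""
        agree = 0
        for trial in range(1000):
            mode = "metazoan_nesting" if trial % 2 else "nonmetazoan_nesting"
            scale = "sh_local" if mode == "metazoan_nesting" else "bootstrap_pct"
            min_support = (
                float(rng.uniform(0.5, 0.95)) if scale == "sh_local"
                else float(rng.uniform(50, 95))
            )
            newick, group_of, tax = random_tree_case(rng, scale)
            expected = oracle_placement(newick, ["q"], group_of, mode, min_support)
            tree = read_newick(newick, scale)
            got = classify_placement(tree, ["q"], tax, mode, min_support)
            if expected is None:
                agree += not got.nested
            else:
                agree += (
                    got.nested
                    and tuple(sorted(got.nesting_clade_leaves)) == expected[0]
                    and got.supporting_edge_support == pytest.approx(expected[1])
                )
        assert agree == 1000

    def test_threshold_monotonicity(self, rng):
        """Raising the support threshold never creates new nested calls."""
        flips = 0
        for trial in range(200):
            newick, group_of, tax = random_tree_case(rng, "bootstrap_pct")
            tree = read_newick(newick, "bootstrap_pct")
            nested_low = classify_placement(
                tree, ["q"], tax, "nonmetazoan_nesting", 50
            ).nested
            nested_high = classify_placement(
                tree, ["q"], tax, "nonmetazoan_nesting", 80
            ).nested
            assert not (nested_high and not nested_low)
            flips += nested_low != nested_high
        assert flips > 0  # thresholds actually bite on this ensemble


class TestDonorAndAncestor:
    def _placement(self, donor_groups):
        from coralhgt.hgt import PlacementResult

        return PlacementResult(
            query_id="q", mode="nonmetazoan_nesting", nested=True,
            supporting_edge_support=95.0,
            nesting_clade_leaves=frozenset(["q"]),
            donor_groups=tuple(donor_groups),
        )

    def test_single_group_abbreviated(self):
        assert assign_donor(self._placement(["Bacteria"] * 4)) == "Bact"

    def test_two_groups_composite_alphabetical(self):
        assert assign_donor(self._placement(["CAAlgae", "Bacteria"])) == "Bact/CA"

    def test_three_groups_unclear(self):
        assert assign_donor(
            self._placement(["Bacteria", "Dinoflagellata", "Viridiplantae"])
        ) == "Unclear"

    def test_empty_donor_set_errors(self):
        with pytest.raises(ValueError):
            assign_donor(self._placement([]))

    def test_ancestor_anthozoa_with_anemone(self, taxonomy):
        assert assign_ancestor(["q", "anem", "b1"], taxonomy) == "Anthozoa"

    def test_ancestor_anthozoa_with_sea_fan_only(self, taxonomy):
        assert assign_ancestor(["q", "fan", "b1"], taxonomy) == "Anthozoa"

    def test_ancestor_coral_when_scleractinian_only(self, taxonomy):
        assert assign_ancestor(["q", "q2", "b1"], taxonomy) == "Coral"


class TestTwoPassScreen:
    def _trees(self, taxonomy, pass1_sh, confirm_support):
        # query grafted inside the bacterial clade, sister to b1
        p1 = read_newick(
            f"(((q,b1)0.95,(b2,b3)0.9)0.99,((m1,m2){pass1_sh},(q2,m3)0.8)0.9);",
            "sh_local",
        )
        p2 = read_newick(
            "(((q,b1)95,(b2,b3)90)98,((m1,m2)90,(q2,m3)85)90);", "bootstrap_pct"
        )
        # note: the two root-child labels annotate the same unrooted edge, so
        # the metazoan-side label is kept below threshold
        p3 = read_newick(
            f"(((q,b1)95,(b2,b3)89){confirm_support},((m1,m2)89,(q2,m3)85)85);",
            "ufboot_pct",
        )
        return {"q": p1}, {"q": p2}, {"q": p3}

    def test_confirmed_through_all_stages(self, taxonomy):
        p1, p2, p3 = self._trees(taxonomy, 0.5, 95)
        candidates = run_two_pass_screen(p1, p2, p3, taxonomy, CFG)
        assert len(candidates) == 1
        c = candidates[0]
        assert c.status == "confirmed"
        assert c.donor_label == "Bact"
        assert c.query_species == "Acropora_digitifera"

    def test_metazoan_nested_query_discarded_in_pass1(self, taxonomy):
        tree1 = read_newick("((q,(m1,m2)0.95)0.92,(b1,b2)0.9);", "sh_local")
        candidates = run_two_pass_screen({"q": tree1}, {}, {}, taxonomy, CFG)
        assert candidates == []

    def test_ufboot_below_90_rejected(self, taxonomy):
        p1, p2, p3 = self._trees(taxonomy, 0.5, 89)
        candidates = run_two_pass_screen(p1, p2, p3, taxonomy, CFG)
        assert candidates[0].status == "rejected"

    def test_ufboot_at_90_boundary_confirmed(self, taxonomy):
        p1, p2, p3 = self._trees(taxonomy, 0.5, 90)
        assert run_two_pass_screen(p1, p2, p3, taxonomy, CFG)[0].status == "confirmed"

    def test_species_unique_case_rejected(self, taxonomy):
        # no other coral/anthozoan anywhere in the pass-2 tree
        p1 = read_newick("(((q,b1)0.95,(b2,b3)0.9)0.99,(m1,(m2,m3)0.8)0.9);", "sh_local")
        p2 = read_newick("(((q,b1)95,(b2,b3)90)98,(m1,(m2,m3)80)90);", "bootstrap_pct")
        p3 = read_newick("(((q,b1)95,(b2,b3)90)98,(m1,(m2,m3)80)90);", "ufboot_pct")
        candidates = run_two_pass_screen({"q": p1}, {"q": p2}, {"q": p3}, taxonomy, CFG)
        assert candidates[0].status == "rejected"

    def test_missing_stage_tree_errors(self, taxonomy):
        p1, p2, p3 = self._trees(taxonomy, 0.5, 95)
        with pytest.raises(KeyError, match="q"):
            run_two_pass_screen(p1, {}, p3, taxonomy, CFG)


def candidate(query, species="sp1", tree_leaves=(), cluster=None):
    return HGTCandidate(
        query_id=query, query_species=species, pass2_support=90.0,
        confirm_support=95.0, donor_label="Bact", status="confirmed",
        tree_leaves=frozenset(tree_leaves), cluster_id=cluster,
    )


class TestCollapseRedundant:
    def test_cross_proteome_link_by_leaf_membership(self):
        a = candidate("adig_1", "A_digitifera", tree_leaves=["seri_9", "b1"])
        b = candidate("seri_9", "Seriatopora_sp", tree_leaves=["b1", "b2"])
        events = collapse_redundant([a, b])
        assert len(events) == 1
        assert {m.query_id for m in events[0].members} == {"adig_1", "seri_9"}

    def test_paralogs_linked_by_ortholog_cluster(self):
        a = candidate("seri_1", cluster="OG1")
        b = candidate("seri_2", cluster="OG1")
        assert len(collapse_redundant([a, b])) == 1

    def test_unlinked_candidates_stay_separate(self):
        assert len(collapse_redundant([candidate("x"), candidate("y")])) == 2

    def test_component_count_matches_union_find_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            cands = [candidate(f"c{i}") for i in range(n)]
            links = []
            for _ in range(int(rng.integers(0, n))):
                i, j = rng.choice(n, size=2, replace=False)
                links.append((int(i), int(j)))
                # realize the link through leaf membership
                cands[i] = candidate(
                    f"c{i}", tree_leaves=set(cands[i].tree_leaves) | {f"c{j}"}
                )
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i, j in links:
                parent[find(i)] = find(j)
            expected = len({find(i) for i in range(n)})
            assert len(collapse_redundant(cands)) == expected

    def test_rejected_candidates_excluded(self):
        bad = candidate("x")
        bad.status = "rejected"
        assert collapse_redundant([bad]) == []


class TestRate:
    def test_published_rate(self):
        assert hgt_rate(62, 32956) == 0.2

    def test_zero_and_half_away_rounding(self):
        assert hgt_rate(0, 100) == 0.0
        assert hgt_rate(1, 400) == 0.3  # 0.25 rounds half away from zero

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            hgt_rate(1, 0)
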