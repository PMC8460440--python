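"""The staged HGT screen: each stage against its oracle, then end-to-end."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import comb

from conftest import (
    all_rooted_topologies,
    clade_oracle,
    mk_gene,
    mk_hit,
    tuple_to_newick,
)
from potworm.hgt import (
    BestHitSummary,
    HgtConfig,
    attribute_origin,
    check_context_linkage,
    clade_test,
    classify_by_bitscore,
    enrich_go,
    filter_candidates,
    run_hgt_pipeline,
    summarize_best_hits,
)
from potworm.io import GeneTree, ReadInterval


class TestSummarizeBestHits:
    def test_h_score_is_nonmet_minus_met(self):
        hits = [mk_hit("g", "bacteria", 150.0), mk_hit("g", "metazoa_excl_annelida", 110.0)]
        s = summarize_best_hits(hits, {"g"})["g"]
        assert s.h_score == pytest.approx(40.0)
        assert s.best_nonmetazoan_group == "bacteria"

    def test_equal_best_scores_give_zero(self):
        hits = [mk_hit("g", "plants", 90.0), mk_hit("g", "metazoa_excl_annelida", 90.0)]
        assert summarize_best_hits(hits, {"g"})["g"].h_score == 0.0

    def test_missing_metazoan_hits_default_zero(self):
        s = summarize_best_hits([mk_hit("g", "fungi", 120.0)], {"g"})["g"]
        assert s.best_metazoan_bitscore == 0.0
        assert s.h_score == pytest.approx(120.0)

    def test_max_over_multiple_hits(self):
        hits = [mk_hit("g", "bacteria", 80.0), mk_hit("g", "bacteria", 130.0),
                mk_hit("g", "protists", 100.0)]
        s = summarize_best_hits(hits, {"g"})["g"]
        assert s.best_nonmetazoan_bitscore == 130.0
        assert s.best_nonmetazoan_group == "bacteria"

    def test_tie_broken_by_evalue_then_subject(self):
        hits = [
            mk_hit("g", "plants", 100.0, subject="zzz", evalue=1e-40),
            mk_hit("g", "bacteria", 100.0, subject="aaa", evalue=1e-20),
        ]
        assert summarize_best_hits(hits, {"g"})["g"].best_nonmetazoan_group == "plants"
        hits = [
            mk_hit("g", "plants", 100.0, subject="zzz", evalue=1e-20),
            mk_hit("g", "bacteria", 100.0, subject="aaa", evalue=1e-20),
        ]
        assert summarize_best_hits(hits, {"g"})["g"].best_nonmetazoan_group == "bacteria"

    def test_annelid_hits_tracked_but_not_nonmetazoan(self):
        hits = [mk_hit("g", "annelida", 500.0), mk_hit("g", "bacteria", 120.0)]
        s = summarize_best_hits(hits, {"g"})
        assert s["g"].best_annelid_bitscore == 500.0
        assert s["g"].best_nonmetazoan_bitscore == 120.0
        s2 = summarize_best_hits(hits, {"g"}, annelida_nonmetazoan=True)
        assert s2["g"].best_nonmetazoan_bitscore == 500.0

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            summarize_best_hits([mk_hit("nope", "plants", 10.0)], {"g"})

    def test_antisymmetry_under_table_swap(self):
        """Swapping the metazoan and non-metazoan hit tables negates h."""
        rng = np.random.default_rng(31)
        genes = {f"g{i}" for i in range(30)}
        hits, swapped = [], []
        for g in sorted(genes):
            for _ in range(int(rng.integers(1, 4))):
                b = float(rng.uniform(10, 300))
                grp = "bacteria" if rng.random() < 0.5 else "metazoa_excl_annelida"
                other = "metazoa_excl_annelida" if grp == "bacteria" else "bacteria"
                hits.append(mk_hit(g, grp, b))
                swapped.append(mk_hit(g, other, b))
        a = summarize_best_hits(hits, genes)
        b = summarize_best_hits(swapped, genes)
        for g in genes:
            assert a[g].h_score == pytest.approx(-b[g].h_score)


class TestCandidateFilter:
    @pytest.mark.parametrize(
        "h,nonmet,expected",
        [
            (30.0, 100.0, True),   # both boundaries inclusive
            (29.9, 500.0, False),
            (80.0, 99.0, False),
            (30.1, 100.0, True),
        ],
    )
    def test_threshold_boundaries(self, h, nonmet, expected):
        s = {"g": BestHitSummary("g", best_metazoan_bitscore=nonmet - h,
                                 best_nonmetazoan_bitscore=nonmet)}
        assert (("g" in filter_candidates(s)) is expected)

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(32)
        summaries = {
            f"g{i}": BestHitSummary(
                f"g{i}",
                best_metazoan_bitscore=float(rng.uniform(0, 200)),
                best_nonmetazoan_bitscore=float(rng.uniform(0, 300)),
            )
            for i in range(200)
        }
        thresholds = [0, 20, 30, 50, 100, 150]
        for h1, h2 in itertools.combinations(thresholds, 2):
            for m1, m2 in itertools.combinations(thresholds, 2):
                loose = filter_candidates(summaries, h_min=h1, nonmet_min=m1)
                tight = filter_candidates(summaries, h_min=h2, nonmet_min=m2)
                assert tight <= loose


class TestContextLinkage:
    def _genes(self):
        return [
            mk_gene("cand", "s1", 2001, 4000, order=1),
            mk_gene("left", "s1", 100, 1800, order=0),
            mk_gene("right", "s1", 5001, 7000, order=2),
        ]

    def test_bridging_read_passes(self):
        reads = [ReadInterval("r1", "s1", 3500, 5200)]  # 500 bp on cand, 200 on right
        ok, ev = check_context_linkage("cand", self._genes(), {"cand"}, reads)
        assert ok and ev["neighbor"] == "right" and ev["read"] == "r1"

    def test_only_gene_on_scaffold_fails(self):
        genes = [mk_gene("cand", "s1", 2001, 4000, order=0)]
        ok, ev = check_context_linkage("cand", genes, {"cand"},
                                       [ReadInterval("r", "s1", 0, 9000)])
        assert not ok and ev["reason"] == "no_native_neighbor"

    def test_reads_overlapping_one_span_only_fail(self):
        reads = [ReadInterval("r1", "s1", 2000, 4100),   # candidate only
                 ReadInterval("r2", "s1", 5000, 7100)]   # neighbor only
        ok, ev = check_context_linkage("cand", self._genes(), {"cand"}, reads)
        assert not ok and ev["reason"] == "no_bridging_read"

    def test_min_overlap_enforced_on_both_spans(self):
        # 50 bp on the neighbor side: below the 100 bp requirement
        reads = [ReadInterval("r1", "s1", 3000, 5050)]
        ok, _ = check_context_linkage("cand", self._genes(), {"cand"}, reads)
        assert not ok
        ok, _ = check_context_linkage("cand", self._genes(), {"cand"}, reads,
                                      min_overlap_bp=50)
        assert ok

    def test_candidate_neighbor_not_native(self):
        reads = [ReadInterval("r1", "s1", 1000, 7000)]
        ok, _ = check_context_linkage("cand", self._genes(), {"cand", "left", "right"},
                                      reads)
        assert not ok

    def test_noncoding_neighbor_not_native(self):
        genes = self._genes()
        for g in genes:
            if g.gene_id != "cand":
                g.biotype = "rRNA"
        ok, ev = check_context_linkage("cand", genes, {"cand"},
                                       [ReadInterval("r", "s1", 0, 9000)])
        assert not ok and ev["reason"] == "no_native_neighbor"

    def test_nonadjacent_gene_not_a_neighbor(self):
        genes = [
            mk_gene("cand", "s1", 2001, 4000, order=0),
            mk_gene("far", "s1", 20001, 22000, order=2),
        ]
        ok, ev = check_context_linkage("cand", genes, {"cand"},
                                       [ReadInterval("r", "s1", 0, 30000)])
        assert not ok

    def test_unknown_candidate_errors(self):
        with pytest.raises(KeyError):
            check_context_linkage("nope", self._genes(), set(), [])


class TestBitscoreConfirmation:
    @pytest.mark.parametrize(
        "met,expected",
        [(49.9, "confirmed"), (50.0, "needs_phylo"), (0.0, "confirmed"),
         (120.0, "needs_phylo")],
    )
    def test_strict_cutoff(self, met, expected):
        s = BestHitSummary("g", best_metazoan_bitscore=met,
                           best_nonmetazoan_bitscore=200.0)
        assert classify_by_bitscore(s) == expected


MET = "metazoa_excl_annelida|m"
BAC = "bacteria|b"


class TestCladeTest:
    def test_nonmetazoan_sibling_confirms(self):
        t = GeneTree.from_newick(f"((cand,{BAC}1),{MET}1);")
        ok, clade = clade_test(t, "cand")
        assert ok and clade == sorted(["cand", f"{BAC}1"])

    def test_metazoan_sibling_rejects(self):
        t = GeneTree.from_newick(f"((cand,{MET}1),{BAC}1);")
        assert clade_test(t, "cand")[0] is False

    def test_five_leaf_example(self):
        t = GeneTree.from_newick(
            f"(((cand,plants|p1),plants|p2),({MET}1,{MET}2));"
        )
        ok, clade = clade_test(t, "cand")
        assert ok and clade == sorted(["cand", "plants|p1"])

    def test_annelid_counts_as_metazoan(self):
        t = GeneTree.from_newick("((cand,annelida|a1),bacteria|b1);")
        assert clade_test(t, "cand")[0] is False

    def test_missing_candidate_errors(self):
        t = GeneTree.from_newick(f"(({BAC}1,{BAC}2),{MET}1);")
        with pytest.raises(KeyError):
            clade_test(t, "cand")

    def test_duplicate_candidate_errors(self):
        t = GeneTree.from_newick(f"((cand,other),{MET}1);")
        t.find_leaf("other").taxon.label = "cand"
        with pytest.raises(ValueError, match="occurs"):
            clade_test(t, "cand")

    def test_exhaustive_small_trees_match_oracle(self):
        """On every rooted binary topology with <= 6 leaves and every
        metazoan/bacterial labelling, the parent-subtree rule agrees with
        'some metazoan-free ancestor clade exists'."""
        checked = 0
        for n in range(2, 7):
            names = ["cand"] + [f"x{i}" for i in range(1, n)]
            for topo in all_rooted_topologies(names):
                for labels in itertools.product([MET, BAC], repeat=n - 1):
                    relab = dict(zip(names[1:], [f"{l}{i}" for i, l in enumerate(labels)]))

                    def rename(t):
                        if isinstance(t, str):
                            return relab.get(t, t)
                        return (rename(t[0]), rename(t[1]))

                    labelled = rename(topo)
                    tree = GeneTree.from_newick(tuple_to_newick(labelled))
                    got, _ = clade_test(tree, "cand")
                    want = clade_oracle(
                        labelled, "cand",
                        lambda l: l.startswith("metazoa") or l.startswith("annelida"),
                    )
                    assert got == want, tuple_to_newick(labelled)
                    checked += 1
        # (2n-3)!! topologies x 2^(n-1) labelings for n = 2..6
        assert checked == sum([1 * 2, 3 * 4, 15 * 8, 105 * 16, 945 * 32])


class TestOriginAttribution:
    def test_published_composition_is_unique_and_rounds_correctly(self):
        """19/8/4/1 of 32 is the unique 4-part composition whose one-decimal
        percentages are 59.4/25.0/12.5/3.1 (brute-force over compositions)."""
        target = (59.4, 25.0, 12.5, 3.1)

        def pct(k):
            return math.floor(1000 * k / 32 + 0.5) / 10

        matches = [
            (a, b, c, d)
            for a in range(1, 33) for b in range(1, 33 - a)
            for c in range(1, 33 - a - b)
            for d in [32 - a - b - c] if d >= 1
            if (pct(a), pct(b), pct(c), pct(d)) == target
        ]
        assert matches == [(19, 8, 4, 1)]

        summaries, confirmed = {}, set()
        comp = {"bacteria": 19, "plants": 8, "fungi": 4, "archaea": 1}
        i = 0
        for grp, k in comp.items():
            for _ in range(k):
                gid = f"g{i:02d}"; i += 1
                summaries[gid] = BestHitSummary(
                    gid, best_nonmetazoan_bitscore=200.0, best_nonmetazoan_group=grp
                )
                confirmed.add(gid)
        origin = attribute_origin(confirmed, summaries)
        assert {g: p for g, (n, p) in origin.items()} == {
            "bacteria": 59.4, "plants": 25.0, "fungi": 12.5, "archaea": 3.1
        }

    def test_single_gene_hundred_percent(self):
        s = {"g": BestHitSummary("g", best_nonmetazoan_bitscore=150.0,
                                 best_nonmetazoan_group="plants")}
        assert attribute_origin({"g"}, s) == {"plants": (1, 100.0)}

    def test_empty_confirmed_set(self):
        assert attribute_origin(set(), {}) == {}


class TestGoEnrichment:
    def test_foreground_equals_background_nothing_significant(self):
        genes = {f"g{i}" for i in range(20)}
        ann = {g: {"GO:1"} for g in genes}
        assert enrich_go(genes, genes, ann) == []

    def test_closed_form_tail(self):
        # all 5 foreground genes carry a term private to them among 100:
        # p = 1 / C(100,5)
        bg = {f"g{i}" for i in range(100)}
        fg = {f"g{i}" for i in range(5)}
        ann = {g: {"GO:x"} for g in fg}
        (res,) = enrich_go(fg, bg, ann)
        assert res.p_value == pytest.approx(1.0 / comb(100, 5, exact=True), rel=1e-9)
        assert (res.k_fg, res.n_fg, res.k_bg, res.n_bg) == (5, 5, 5, 100)

    def test_empty_annotations(self):
        assert enrich_go({"a"}, {"a", "b"}, {}) == []

    def test_foreground_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            enrich_go({"a"}, {"b"}, {})

    def test_bh_correction_per_namespace(self):
        bg = {f"g{i}" for i in range(50)}
        fg = {f"g{i}" for i in range(5)}
        ann = {g: {"GO:bp", "GO:mf"} for g in fg}
        res = enrich_go(fg, bg, ann, namespaces={"GO:bp": "BP", "GO:mf": "MF"})
        assert {r.namespace for r in res} == {"BP", "MF"}
        for r in res:
            assert r.q_value >= r.p_value - 1e-12


class TestPipeline:
    def test_empty_hit_table(self):
        genes = [mk_gene("g1", "s1", 1, 100, order=0)]
        decisions, report = run_hgt_pipeline([], genes, [], {})
        assert report.n_candidates == report.n_confirmed_total == 0
        assert decisions[0].stage == "not_candidate"

    def test_hand_built_micro_fixture(self):
        """Ten genes whose stages were worked out by hand at each stage."""
        genes = [
            # scaffold A: a bitscore-confirmable candidate with a neighbor
            mk_gene("a_cand", "A", 2001, 4000, order=0),
            mk_gene("a_nat", "A", 5001, 7000, order=1),
            # scaffold B: a phylo-confirmable candidate
            mk_gene("b_cand", "B", 2001, 4000, order=0),
            mk_gene("b_nat", "B", 5001, 7000, order=1),
            # scaffold C: candidate with no neighbor at all
            mk_gene("c_cand", "C", 2001, 4000, order=0),
            # scaffold D: candidate whose tree places it inside metazoa
            mk_gene("d_cand", "D", 2001, 4000, order=0),
            mk_gene("d_nat", "D", 5001, 7000, order=1),
            # plain background genes
            mk_gene("e_bg", "E", 1, 900, order=0),
            mk_gene("e_bg2", "E", 2000, 2900, order=1),
            mk_gene("f_bg", "F", 1, 900, order=0),
        ]
        hits = [
            mk_hit("a_cand", "bacteria", 180.0),                      # h=180, met 0 -> confirm
            mk_hit("b_cand", "plants", 200.0),
            mk_hit("b_cand", "metazoa_excl_annelida", 90.0),          # h=110, met>=50 -> phylo
            mk_hit("c_cand", "fungi", 150.0),                         # candidate, no linkage
            mk_hit("d_cand", "archaea", 160.0),
            mk_hit("d_cand", "metazoa_excl_annelida", 70.0),          # phylo, rejected tree
            mk_hit("e_bg", "metazoa_excl_annelida", 250.0),           # h<0
            mk_hit("f_bg", "bacteria", 90.0),                         # nonmet < 100
        ]
        reads = [
            ReadInterval("rA", "A", 3000, 5500),
            ReadInterval("rB", "B", 3000, 5500),
            ReadInterval("rD", "D", 3000, 5500),
        ]
        trees = {
            "b_cand": GeneTree.from_newick(f"((b_cand,plants|p1),{MET}1);"),
            "d_cand": GeneTree.from_newick(f"((d_cand,{MET}1),archaea|a1);"),
        }
        decisions, report = run_hgt_pipeline(hits, genes, reads, trees)
        stages = {d.gene_id: d.stage for d in decisions}
        assert stages == {
            "a_cand": "confirmed_bitscore",
            "b_cand": "phylo_confirmed",
            "c_cand": "rejected_no_linkage",
            "d_cand": "phylo_rejected",
            "a_nat": "not_candidate", "b_nat": "not_candidate",
            "d_nat": "not_candidate", "e_bg": "not_candidate",
            "e_bg2": "not_candidate", "f_bg": "not_candidate",
        }
        assert (report.n_candidates, report.n_rejected_linkage,
                report.n_confirmed_bitscore, report.n_phylo_tested,
                report.n_confirmed_total) == (4, 1, 1, 2, 2)
        assert report.origin_percentages == {"bacteria": 50.0, "plants": 50.0}

    def test_missing_tree_reported_not_confirmed(self):
        genes = [
            mk_gene("cand", "A", 2001, 4000, order=0),
            mk_gene("nat", "A", 5001, 7000, order=1),
        ]
        hits = [mk_hit("cand", "bacteria", 200.0),
                mk_hit("cand", "metazoa_excl_annelida", 80.0)]
        reads = [ReadInterval("r", "A", 3000, 5500)]
        decisions, report = run_hgt_pipeline(hits, genes, reads, {})
        assert decisions[0].stage == "phylo_missing"
        assert report.n_phylo_missing == 1 and report.n_confirmed_total == 0
        assert report.n_phylo_tested == 1  # conservation still holds

    def test_determinism_bit_for_bit(self):
        from potworm.simulate import HgtFixtureSpec, generate_hgt_fixture

        fx = generate_hgt_fixture(HgtFixtureSpec(
            class_sizes={"confirmed_bitscore": 2, "rejected_no_linkage": 1,
                         "phylo_rejected": 1},
            n_background=5, seed=7,
        ))
        r1 = run_hgt_pipeline(fx.hits, fx.genes, fx.reads, fx.trees)
        r2 = run_hgt_pipeline(fx.hits, fx.genes, fx.reads, fx.trees)
        assert r1 == r2
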