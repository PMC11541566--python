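"""Template query construction, exhaustive-oracle scanner equivalence,
selection and classification rules, and position pileups."""

import math

import numpy as np
import pytest

from svjunction.junctions import revcomp
from svjunction.simulate import (
    JunctionPlan,
    SimConfig,
    _Ref,
    _small_reference,
    plant_junction,
    simulate_junction_set,
)
from svjunction.templates import (
    NotAnInsertionError,
    TemplateDataError,
    TemplateHit,
    TemplateSearchResult,
    build_query,
    classify_template,
    flank_per_side,
    modal_distance_by_class,
    scan_templates,
    select_template,
    template_position_pileup,
)

from conftest import make_del_call


class TestBuildQuery:
    @pytest.mark.parametrize(
        "insert_size,flank,total",
        [(1, 3, 7), (2, 3, 8), (3, 2, 7), (4, 2, 8), (5, 1, 7), (10, 1, 12)],
    )
    def test_flank_rule(self, insert_size, flank, total):
        """A 1 bp insertion is queried with 3 bp flanks, a 4 bp insertion
        with 2 bp, and >=5 bp insertions with a single base per side, always
        totalling >= 7 query bases."""
        assert flank_per_side(insert_size) == flank
        mol = "A" * 200 + "C" * insert_size + "A" * 200
        call = make_del_call(offset=insert_size, inserted="C" * insert_size,
                             molecule_seq=mol)
        q = build_query(call)
        assert q.flank_per_side == flank
        assert q.n_template_bases == total
        assert q.query_seq == "A" * flank + "C" * insert_size + "A" * flank

    def test_not_an_insertion(self):
        call = make_del_call(offset=-2, molecule_seq="A" * 400)
        with pytest.raises(NotAnInsertionError):
            build_query(call)

    def test_missing_molecule_sequence(self):
        call = make_del_call(offset=3, inserted="AAA")
        with pytest.raises(TemplateDataError):
            build_query(call)


def _oracle_scan(query, reference, call, window=500):
    """Exhaustive oracle: try every start position on both strands of both
    breakpoint windows by direct slice comparison, then extend each raw match
    base by base with an independent character walk."""
    q = query.query_seq
    n = len(q)
    up, down = query.up_context, query.down_context
    L = len(reference)
    found = set()
    for bp_index, bp in ((1, call.bp1), (2, call.bp2)):
        c = bp.ref_pos
        lo, hi = max(1, c - window), min(L, c + window)
        for t in range(lo, hi - n + 2):
            seg = reference[t - 1 : t - 1 + n]
            for strand in ("top", "bottom"):
                target = q if strand == "top" else revcomp(q)
                if seg != target:
                    continue
                # independent maximal extension
                if strand == "top":
                    e_up = 0
                    while (e_up < window and e_up < len(up)
                           and t - e_up - 2 >= 0
                           and up[len(up) - 1 - e_up] == reference[t - e_up - 2]
                           and reference[t - e_up - 2] in "ACGT"):
                        e_up += 1
                    e_dn = 0
                    while (e_dn < window and e_dn < len(down)
                           and t + n + e_dn - 1 < L
                           and down[e_dn] == reference[t + n + e_dn - 1]
                           and reference[t + n + e_dn - 1] in "ACGT"):
                        e_dn += 1
                    span = (t - e_up, t + n - 1 + e_dn)
                else:
                    e_up = 0
                    while (e_up < window and e_up < len(up)
                           and t + n + e_up - 1 < L
                           and up[len(up) - 1 - e_up]
                           == revcomp(reference[t + n + e_up - 1])
                           and reference[t + n + e_up - 1] in "ACGT"):
                        e_up += 1
                    e_dn = 0
                    while (e_dn < window and e_dn < len(down)
                           and t - e_dn - 2 >= 0
                           and down[e_dn] == revcomp(reference[t - e_dn - 2])
                           and reference[t - e_dn - 2] in "ACGT"):
                        e_dn += 1
                    span = (t - e_dn, t + n - 1 + e_up)
                found.add((bp_index, strand, span[0], span[1]))
    return found


class TestScannerOracleEquivalence:
    def test_matches_exhaustive_search(self, insertion_junctions):
        """Production scanner finds exactly the hits of a brute-force scan of
        every offset/strand/side on simulated insertion junctions."""
        checked = 0
        for pj in insertion_junctions[:250]:
            call = pj.call
            q = build_query(call)
            res = scan_templates(q, pj.reference, call)
            got = {
                (h.breakpoint_index, h.strand, h.ref_start, h.ref_end)
                for h in res.all_hits
            }
            expected = _oracle_scan(q, pj.reference, call)
            assert got == expected, f"{pj.truth}"
            checked += 1
        assert checked == 250

    def test_extension_maximality(self, insertion_junctions):
        """The base just beyond each reported flank mismatches, unless the
        extension stopped at a window or molecule-context boundary."""
        for pj in insertion_junctions[:150]:
            call = pj.call
            q = build_query(call)
            res = scan_templates(q, pj.reference, call)
            for h in res.all_hits:
                ref = pj.reference
                if h.strand == "top":
                    if not h.priming_capped:
                        j = h.priming_mh - q.flank_per_side + 1
                        assert q.up_context[-j] != ref[h.ref_start - 2]
                    if not h.resolving_capped:
                        j = h.resolving_mh - q.flank_per_side
                        assert q.down_context[j] != ref[h.ref_end]
                else:
                    if not h.priming_capped:
                        j = h.priming_mh - q.flank_per_side + 1
                        assert q.up_context[-j] != revcomp(ref[h.ref_end])
                    if not h.resolving_capped:
                        j = h.resolving_mh - q.flank_per_side
                        assert q.down_context[j] != revcomp(ref[h.ref_start - 2])

    def test_window_edge_match_included(self):
        """A query matching at the very edge base of the 500 bp window is
        reported."""
        ref = bytearray(_small_reference(55, 8_000))
        p1, p2 = 2_000, 5_000
        plan = JunctionPlan(
            sv_id="e1", sample_id="S", sv_type="DEL", p1=p1, size=3_000,
            mechanism="insertion", insert_size=8,
        )
        rng = np.random.default_rng(5)
        r = _Ref(ref)
        pj = plant_junction(r, plan, rng)
        q = build_query(pj.call)
        # copy the query so it ends exactly at the window edge
        edge_start = p1 - 500
        r.set_slice(edge_start, q.query_seq)
        reference = r.slice(1, 8_000)
        res = scan_templates(q, reference, pj.call)
        assert any(h.ref_start <= edge_start + len(q.query_seq) - 1
                   and h.ref_start >= edge_start - 500
                   for h in res.all_hits)


def _hit(span=10, dist=-5, bp=1, strand="top", start=100, retained=None,
         seq="ACGTACGTAC"):
    n_ret = retained if retained is not None else span
    return TemplateHit(
        breakpoint_index=bp, strand=strand, ref_start=start,
        ref_end=start + span - 1, distance_to_junction=dist,
        priming_mh=2, resolving_mh=2, total_span=span,
        n_retained=n_ret, n_lost=span - n_ret, template_seq=seq[:span],
    )


class TestSelection:
    def test_longest_span_wins(self):
        res = TemplateSearchResult(all_hits=[_hit(span=9, dist=2), _hit(span=12, dist=40)])
        assert select_template(res).total_span == 12

    def test_distance_breaks_span_ties(self):
        res = TemplateSearchResult(all_hits=[_hit(dist=30), _hit(dist=5)])
        assert select_template(res).distance_to_junction == 5

    def test_deterministic_final_tiebreak(self):
        hits = [
            _hit(bp=2, strand="top", start=50),
            _hit(bp=1, strand="bottom", start=50),
            _hit(bp=1, strand="top", start=80),
            _hit(bp=1, strand="top", start=60),
        ]
        win = select_template(TemplateSearchResult(all_hits=hits))
        assert (win.breakpoint_index, win.strand, win.ref_start) == (1, "top", 60)

    def test_empty_returns_none(self):
        assert select_template(TemplateSearchResult()) is None


class TestClassification:
    def test_bottom_retained_is_foldback(self):
        call = make_del_call()
        assert classify_template(_hit(strand="bottom"), call) == "foldback"

    def test_palindromic_foldback_subclassified(self):
        call = make_del_call()
        h = _hit(strand="bottom", span=6, seq="ACGCGT")
        assert revcomp("ACGCGT") == "ACGCGT"
        assert classify_template(h, call) == "palindrome"

    def test_top_retained_is_cross_junction(self):
        assert classify_template(_hit(strand="top"), make_del_call()) == "cross_junction"

    def test_bottom_partially_lost_is_strand_switching(self):
        h = _hit(strand="bottom", retained=4)
        assert classify_template(h, make_del_call()) == "strand_switching"

    def test_top_crossing_is_expansion(self):
        h = _hit(strand="top", retained=4, dist=0)
        assert classify_template(h, make_del_call()) == "expansion"

    def test_top_fully_lost_unclassified_and_flagged(self):
        h = _hit(strand="top", retained=0, dist=12)
        call = make_del_call()
        assert classify_template(h, call) == "unclassified"
        assert h.low_confidence

    def test_non_deletion_classes_flagged_low_confidence(self):
        call = make_del_call(sv_type="DUP")
        h = _hit(strand="bottom")
        classify_template(h, call)
        assert h.low_confidence
        h2 = _hit(strand="top")
        classify_template(h2, call)
        assert not h2.low_confidence  # cross-junction stays confident


class TestPileup:
    def test_direct_construction(self):
        """A single 8-base hit at distance -10 from the left breakpoint piles
        up one count at each of positions -10..-17."""
        call = make_del_call(p1=700, p2=3100)
        h = TemplateHit(
            breakpoint_index=1, strand="top",
            ref_start=700 - 17, ref_end=700 - 10,
            distance_to_junction=-10, priming_mh=2, resolving_mh=2,
            total_span=8, n_retained=8, n_lost=0, template_seq="A" * 8,
            template_class="cross_junction",
        )
        df = template_position_pileup([h], [call])
        assert len(df) == 8
        assert set(df["distance"]) == set(range(-17, -9))
        assert (df["count"] == 1).all()
        assert (df["side"] == "left").all()

    def test_oriented_call_flips_side(self):
        import dataclasses

        call = dataclasses.replace(make_del_call(p1=700, p2=3100), oriented=True)
        h = TemplateHit(
            breakpoint_index=1, strand="bottom", ref_start=680, ref_end=690,
            distance_to_junction=-10, priming_mh=2, resolving_mh=2,
            total_span=11, n_retained=11, n_lost=0, template_seq="A" * 11,
            template_class="foldback",
        )
        df = template_position_pileup([h], [call])
        # bottom strand is preserved through orientation; the side flips
        assert (df["side"] == "right").all()

    def test_empty(self):
        df = template_position_pileup([], [])
        assert df.empty

    def test_modal_distance(self):
        call = make_del_call(p1=700, p2=3100)
        hits = [
            TemplateHit(1, "top", 690, 695, -5, 2, 2, 6, 6, 0, "ACACAC",
                        template_class="cross_junction"),
            TemplateHit(1, "bottom", 682, 689, -11, 2, 2, 8, 8, 0, "ACACACAC",
                        template_class="foldback"),
        ]
        df = template_position_pileup(hits, [call, call])
        modal = modal_distance_by_class(df)
        assert modal["cross_junction"] == -5
        assert modal["foldback"] == -11


class TestPlantedRecovery:
    def test_planted_foldback_recovered_at_coordinates(self):
        """Spec-style round trip: a templated foldback at distance 10 with
        2/2 priming/resolving microhomology yields a bottom-strand
        retained-side hit at the planted coordinates."""
        ref = _Ref(bytearray(_small_reference(77, 8_000)))
        plan = JunctionPlan(
            sv_id="f1", sample_id="S", sv_type="DEL", p1=2_000, size=3_000,
            mechanism="insertion", insert_size=8, templated=True,
            template_class="foldback", template_side=1, template_distance=10,
            priming_mh=2, resolving_mh=2,
        )
        rng = np.random.default_rng(8)
        pj = plant_junction(ref, plan, rng)
        t = pj.truth
        q = build_query(pj.call)
        res = scan_templates(q, ref.slice(1, 8_000), pj.call)
        match = [
            h for h in res.all_hits
            if (h.breakpoint_index, h.strand, h.ref_start, h.ref_end)
            == (1, "bottom", t["template_ref_start"], t["template_ref_end"])
        ]
        assert len(match) == 1
        h = match[0]
        assert h.priming_mh == t["priming_mh"]
        assert h.resolving_mh == t["resolving_mh"]
        assert h.distance_to_junction == -t["template_distance"]
        assert classify_template(h, pj.call) == "foldback"

    def test_recovery_rate_and_class_agreement(self, insertion_junctions):
        """>=90% of discoverable planted templates (query >= 8 bases,
        distance <= 50) are selected at exact coordinates with the planted
        class."""
        rec = tot = cls_ok = 0
        for pj in insertion_junctions:
            t = pj.truth
            if not t["templated"] or t["template_class"] == "expansion":
                continue
            q = build_query(pj.call)
            if q.n_template_bases < 8 or t["template_distance"] > 50:
                continue
            tot += 1
            res = scan_templates(q, pj.reference, pj.call)
            sel = res.selected_hit
            if (
                sel is not None
                and sel.ref_start == t["template_ref_start"]
                and sel.ref_end == t["template_ref_end"]
            ):
                rec += 1
                if classify_template(sel, pj.call) == t["template_class"]:
                    cls_ok += 1
        assert tot >= 50
        assert rec / tot >= 0.90
        assert cls_ok >= 0.95 * rec  # palindromic foldbacks may subclassify


class TestRandomMatchCalibration:
    def test_hit_probability_matches_poisson_rate(self):
        """On random references the per-junction probability of >=1 template
        candidate is within 3 SE of 1 - exp(-4000 / 4^n) for an n = 8 query."""
        cfg = SimConfig(
            mechanism_mix={"microhomology": 0.0, "blunt": 0.0, "insertion": 1.0},
            insertion_size_dist={6: 1.0},   # 6 bp insert -> 8 query bases
            templated_fraction=0.0,
        )
        pjs = simulate_junction_set(500, cfg, seed=404)
        hits = 0
        for pj in pjs:
            q = build_query(pj.call)
            assert q.n_template_bases == 8
            res = scan_templates(q, pj.reference, pj.call)
            hits += res.n_candidates > 0
        p_expected = -math.expm1(-4000 / 4 ** 8)
        se = math.sqrt(p_expected * (1 - p_expected) / len(pjs))
        assert abs(hits / len(pjs) - p_expected) <= 3 * se
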