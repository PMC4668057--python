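"""Cassette design: segment extraction, candidate enumeration, chimeric
assembly, orchestration, and the published worked examples' structure."""

import pytest

from seamdel import (
    DEFAULT_CONSTRAINTS,
    FixtureSpec,
    generate_locus,
    worked_example_fixture,
)
from seamdel.design import (
    DesignFailure,
    PrimerSet,
    assemble_p3,
    assemble_p4,
    candidate_p1,
    candidate_p2,
    choose_marker_amplicon,
    design_confirmation,
    design_target,
    extract_R,
    extract_right_homology,
    plan_cassette,
)
from seamdel.errors import DesignError
from seamdel.seqio import LocusRecord, MarkerTemplate, reverse_complement
from seamdel.simulate import simulate_pcr


class TestSegmentExtraction:
    def test_r_is_first_40_of_downstream(self, happy_locus, constraints):
        r = extract_R(happy_locus, constraints)
        assert r == happy_locus.downstream[:40]
        assert len(r) == 40

    def test_short_downstream_is_flank_too_short(self, constraints):
        locus = LocusRecord("X", "A" * 1000, "ATG" + "C" * 50 + "TAA",
                            "G" * 39)
        with pytest.raises(DesignError) as err:
            extract_R(locus, constraints)
        assert err.value.code == "FLANK_TOO_SHORT"

    def test_published_r_segment_is_the_annotated_40mer(self):
        t1 = worked_example_fixture()
        _, r, _ = t1.segments[("YIR013C", "PCR2_F")]
        assert r == "CCCATTATACTTTTTCAGCTTTCAACCTATCGGGACAAAA"
        assert len(r) == 40

    def test_right_homology_ends_at_stop_codon(self, happy_locus,
                                               constraints):
        rh = extract_right_homology(happy_locus, constraints)
        assert rh == happy_locus.orf[-44:]
        assert reverse_complement(rh)[:3] in ("TTA", "CTA", "TCA")

    def test_published_p4_starts_with_rc_of_stop(self):
        t1 = worked_example_fixture()
        for orf in t1.primers:
            assert t1.primers[orf]["PCR2_R"][:3] in ("TTA", "CTA", "TCA")

    def test_short_orf_rejected(self, constraints):
        locus = LocusRecord("X", "A" * 1000, "ATG" + "C" * 24 + "TAA",
                            "G" * 1000)
        with pytest.raises(DesignError) as err:
            extract_right_homology(locus, constraints)
        assert err.value.code == "ORF_TOO_SHORT"


class TestPcr1Candidates:
    def test_p2_candidates_abut_orf_start(self, happy_locus, marker,
                                          constraints):
        flank = happy_locus.flank_len
        for cand in candidate_p2(happy_locus, constraints, marker):
            length = len(cand.seq)
            assert cand.seq == reverse_complement(
                happy_locus.upstream[flank - length:])
            assert cand.start == flank - length
            assert constraints.p2_len_min <= length <= constraints.p2_len_max

    def test_at_rich_window_yields_no_p2(self, marker, constraints):
        locus = LocusRecord("X", "ACGT" * 235 + "AT" * 30,
                            "ATG" + "ACC" * 200 + "TAA", "ACGT" * 250)
        assert candidate_p2(locus, constraints, marker) == []

    def test_p1_amplicon_lengths_within_bounds(self, happy_locus, marker,
                                               constraints):
        p2 = candidate_p2(happy_locus, constraints, marker)[0]
        for cand in candidate_p1(happy_locus, p2, constraints, marker,
                                 limit=5):
            amplicon = happy_locus.flank_len - cand.start
            assert constraints.amplicon_min <= amplicon \
                <= constraints.amplicon_max
            assert constraints.p1_len_min <= len(cand.seq) \
                <= constraints.p1_len_max
            assert cand.seq == happy_locus.upstream[
                cand.start:cand.start + len(cand.seq)]

    def test_insufficient_upstream_gives_no_p1(self, marker, constraints):
        # every start that satisfies the amplicon range lies in an A/T
        # desert; only the pre-ORF window is usable sequence
        from seamdel.fixtures import Lcg
        rng = Lcg(99)
        locus = LocusRecord("X", "AT" * 280 + rng.seq(440, 0.45),
                            "ATG" + rng.seq(594, 0.45) + "TAA",
                            rng.seq(1000, 0.45))
        p2s = candidate_p2(locus, constraints, marker)
        assert p2s
        assert candidate_p1(locus, p2s[0], constraints, marker, limit=3) == []


class TestMarkerAmplicon:
    def _marker(self, pairs, forbidden):
        return MarkerTemplate(marker_name="m", plasmid="ACGT" * 1000,
                              anchor_pairs=pairs,
                              forbidden_intervals=forbidden)

    def test_pair_overlapping_forbidden_interval_skipped(self, constraints):
        marker = self._marker(((100, 1200), (200, 1200)), ((150, 184),))
        idx, amplicon = choose_marker_amplicon(marker, constraints)
        assert idx == 1
        assert amplicon == marker.plasmid[200:1200]

    def test_all_pairs_forbidden_is_no_marker_pair(self, constraints):
        marker = self._marker(((100, 1200), (200, 1300)), ((500, 534),))
        with pytest.raises(DesignError) as err:
            choose_marker_amplicon(marker, constraints)
        assert err.value.code == "NO_MARKER_PAIR"

    def test_chosen_amplicon_disjoint_from_forbidden(self, marker,
                                                     constraints):
        idx, _ = choose_marker_amplicon(marker, constraints)
        start, end = marker.anchor_pairs[idx]
        for f_start, f_end in marker.forbidden_intervals:
            assert end <= f_start or f_end <= start


class TestChimericAssembly:
    def test_published_geometry_25_40_17(self):
        # the printed worked examples use a 25 nt overlap + 40 nt repeat
        # + 17-18 nt marker anchor, i.e. 82-83 nt total, under the 100 cap
        t1 = worked_example_fixture()
        for orf in t1.primers:
            overlap, r, marker5 = t1.segments[(orf, "PCR2_F")]
            assert len(overlap) == 25
            assert len(r) == 40
            assert 17 <= len(marker5) <= 20
            assert len(t1.primers[orf]["PCR2_F"]) <= 100

    def test_overlap_is_rc_of_p2_prefix(self, designed, constraints):
        overlap = designed.p3_segments[0]
        assert constraints.overlap_len <= len(overlap) \
            <= constraints.overlap_max
        assert overlap == reverse_complement(designed.p2[:len(overlap)])

    def test_boundary_arithmetic_at_max_overlap(self, constraints):
        # 40 + 40 + 20 = 100 is accepted exactly at the cap
        p2 = "GC" * 30
        r = "A" * 20 + "GCGC" * 5  # 40 nt
        amplicon = "ACGTG" * 100
        p3 = assemble_p3(p2, r, amplicon,
                         constraints.with_overrides(overlap_len=40))
        assert len(p3.seq) == 100
        assert p3.seq == reverse_complement(p2[:40]) + r + amplicon[:20]

    def test_gc_poor_overlap_extends_toward_max(self, constraints):
        p2 = "AT" * 14 + "GC" * 16  # GC-poor 5' end
        r = "GCGC" * 10
        amplicon = "GCAT" * 100
        p3 = assemble_p3(p2, r, amplicon, constraints)
        overlap = p3.segments[0]
        assert len(overlap) > constraints.overlap_len

    def test_impossible_cap_is_p3_too_long(self, constraints):
        # a GC-poor overlap forces extension to 40 nt; with a tightened cap
        # no marker-anchor length can fit any more
        tight = constraints.with_overrides(p3_max_len=85)
        p2 = "AT" * 14 + "GC" * 16
        with pytest.raises(DesignError) as err:
            assemble_p3(p2, "GCGC" * 10, "AGCT" * 100, tight)
        assert err.value.code == "P3_TOO_LONG"

    def test_p4_is_62nt_with_shared_marker_suffix(self, marker, constraints):
        loci = [generate_locus(FixtureSpec(seed=s, orf_len=300, gc=0.42))
                for s in (21, 22, 23)]
        _, amplicon = choose_marker_amplicon(marker, constraints)
        p4s = [assemble_p4(locus, amplicon, constraints).seq
               for locus in loci]
        assert all(len(p) == 44 + 18 for p in p4s)
        suffix = p4s[0][-18:]
        assert all(p.endswith(suffix) for p in p4s)
        assert suffix == reverse_complement(amplicon[-18:])

    def test_published_p4s_share_18nt_marker_suffix(self):
        t1 = worked_example_fixture()
        from seamdel.fixtures import longest_common_suffix
        lcs = longest_common_suffix(
            [t1.primers[o]["PCR2_R"] for o in t1.primers])
        assert lcs == "GATCCCAATACAACAGAT"


class TestDesignTarget:
    def test_happy_design_satisfies_all_invariants(self, happy_locus,
                                                   marker, designed,
                                                   constraints):
        overlap, r, marker5 = designed.p3_segments
        assert designed.p3 == overlap + r + marker5
        assert len(designed.p3) <= 100
        assert overlap == reverse_complement(
            designed.p2[:len(overlap)])
        assert r == happy_locus.downstream[:40]
        rh_rc, marker3_rc = designed.p4_segments
        assert designed.p4 == rh_rc + marker3_rc
        assert rh_rc == reverse_complement(happy_locus.orf[-44:])
        assert designed.p4[:3] == reverse_complement(
            happy_locus.orf[-3:])
        amplicon = marker.amplicon(designed.marker_pair_id)
        assert marker5 == amplicon[:len(marker5)]
        assert marker3_rc == reverse_complement(amplicon[-18:])

    def test_determinism_byte_identical(self, happy_locus, marker,
                                        constraints):
        a = design_target(happy_locus, marker, constraints)
        b = design_target(happy_locus, marker, constraints)
        assert a == b

    def test_at_rich_p2_window_fails_with_reason(self, marker, constraints):
        locus = LocusRecord("X", "ACGT" * 235 + "AT" * 30,
                            "ATG" + "ACC" * 200 + "TAA", "ACGT" * 250)
        outcome = design_target(locus, marker, constraints)
        assert isinstance(outcome, DesignFailure)
        assert outcome.reason_code == "NO_P2_CANDIDATE"

    def test_orf_too_short_classified(self, marker, constraints):
        locus = LocusRecord("X", "ACGT" * 250, "ATG" + "CAC" * 8 + "TAA",
                            "ACGT" * 250)
        outcome = design_target(locus, marker, constraints)
        assert isinstance(outcome, DesignFailure)
        assert outcome.reason_code == "ORF_TOO_SHORT"

    def test_failure_classification_is_total(self, marker):
        from seamdel.batch import design_batch
        from seamdel.errors import REASON_CODES
        from seamdel.fixtures import batch_locus_specs
        loci = [generate_locus(s) for s in batch_locus_specs(12, base_seed=60)]
        result = design_batch(loci, marker)
        assert len(result.rows) == len(loci)
        for failure in result.failures:
            assert failure.reason_code in REASON_CODES

    def test_tightening_constraints_never_rescues_a_locus(self, marker,
                                                          constraints):
        from seamdel.fixtures import batch_locus_specs
        loci = [generate_locus(s) for s in batch_locus_specs(10, base_seed=1)]

        def designed_ids(cons):
            return {l.locus_id for l in loci
                    if isinstance(design_target(l, marker, cons), PrimerSet)}

        loose = designed_ids(constraints)
        for tight in (constraints.with_overrides(gc_last8_min=3),
                      constraints.with_overrides(dimer_score_max=20)):
            assert designed_ids(tight) <= loose


@pytest.fixture(scope="module")
def conf_setup(marker):
    # cap the amplicon so there is upstream room outside the cassette
    cons = DEFAULT_CONSTRAINTS.with_overrides(amplicon_max=650)
    locus = generate_locus(FixtureSpec(seed=2, flank_len=1000,
                                       orf_len=900, gc=0.40))
    outcome = design_target(locus, marker, cons)
    assert isinstance(outcome, PrimerSet)
    return cons, locus, outcome


class TestConfirmationPrimers:

    def test_cps_a_sits_outside_the_cassette_footprint(self, marker,
                                                       conf_setup):
        cons, locus, primer_set = conf_setup
        conf = design_confirmation(locus, marker, cons, primer_set.p1_start)
        end = conf.cps_a_start + len(conf.cps_a)
        assert end <= primer_set.p1_start - cons.conf_offset_min
        assert locus.upstream[conf.cps_a_start:end] == conf.cps_a

    def test_cps_a_x_rincass_amplifies_only_after_integration(self, marker,
                                                              conf_setup):
        cons, locus, primer_set = conf_setup
        conf = design_confirmation(locus, marker, cons, primer_set.p1_start)
        plan = plan_cassette(primer_set, locus, marker)
        wild = simulate_pcr({"wt": locus.record}, conf.cps_a, conf.rin_cass)
        integrated = simulate_pcr({"ko": plan.post_integration},
                                  conf.cps_a, conf.rin_cass)
        assert wild == []
        assert len(integrated) == 1

    def test_cps_product_shrinks_by_orf_length_after_popout(self, marker,
                                                            conf_setup):
        cons, locus, primer_set = conf_setup
        conf = design_confirmation(locus, marker, cons, primer_set.p1_start)
        plan = plan_cassette(primer_set, locus, marker)
        wt = simulate_pcr({"wt": locus.record}, conf.cps_a, conf.cps_d)
        ko = simulate_pcr({"ko": plan.post_popout}, conf.cps_a, conf.cps_d)
        assert len(wt) == 1 and len(ko) == 1
        assert wt[0].size - ko[0].size == locus.orf_len

    def test_no_room_is_flank_too_short(self, marker, happy_locus,
                                        constraints):
        with pytest.raises(DesignError) as err:
            design_confirmation(happy_locus, marker, constraints, p1_start=60)
        assert err.value.code == "FLANK_TOO_SHORT"


class TestCassettePlan:
    def test_fusion_length_algebra(self, designed, happy_locus, marker):
        plan = plan_cassette(designed, happy_locus, marker)
        assert plan.pcr3_size == plan.pcr1_size + plan.pcr2_size \
            - plan.overlap_len
        assert plan.pcr1_product == happy_locus.upstream[designed.p1_start:]
        assert plan.pcr3_product.startswith(plan.pcr1_product)
        assert plan.pcr3_product.endswith(plan.pcr2_product)

    def test_pcr2_product_near_1250bp(self, designed, happy_locus, marker):
        plan = plan_cassette(designed, happy_locus, marker)
        assert 1150 <= plan.pcr2_size <= 1300

    def test_pcr3_in_observed_size_range(self, designed, happy_locus,
                                         marker):
        plan = plan_cassette(designed, happy_locus, marker)
        assert 1700 <= plan.pcr3_size <= 2400

    def test_mass_uses_660_per_bp_rule(self, designed, happy_locus, marker):
        from seamdel.design import product_mass_ng
        plan = plan_cassette(designed, happy_locus, marker)
        assert plan.pcr3_mass_ng == pytest.approx(
            3.0 * 0.66 * plan.pcr3_size, abs=0.05)
        assert product_mass_ng(1000) == 1980.0
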