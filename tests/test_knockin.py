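"""Knock-in scenario generation against brute-force enumeration oracles."""

import pytest

import armkit as ak
from armkit.arm_factory import ArmStore, DesignParams
from armkit.knockin import make_scenario, similar

from .oracles import (
    ki_best_key,
    ki_key,
    ki_oracle,
    ki_valid,
    make_arm,
)

EXON = (5000, 5100)


@pytest.fixture(scope="module")
def spread_arms():
    """Hand-placed arms, pairwise far apart so every DBSCAN cluster is a
    singleton and the cluster heuristic reduces to full enumeration."""
    spans = [
        make_arm(4200, 5200, 1.0),
        make_arm(4100, 5300, 2.0),
        make_arm(4000, 5150, 3.0),
    ]
    lefts = [make_arm(3100, 4100, 1.0), make_arm(3000, 4000, 2.0)]
    rights = [make_arm(5300, 6300, 1.0), make_arm(5400, 6400, 2.0)]
    return spans + lefts + rights


OTHER_EXONS = [(4150, 4160), (3500, 3600)]


class TestSpanAndFlankSelection:
    @pytest.mark.parametrize(
        "arm_start, arm_end, is_span",
        [
            (4980, 5980, True),  # margins exactly 20 on the left
            (4981, 5980, False),  # margin 19
            (4200, 5119, False),  # right margin 19
        ],
    )
    def test_span_margin_boundary(self, arm_start, arm_end, is_span):
        store = ArmStore(1, [make_arm(arm_start, arm_end)])
        got = ak.find_span_arms(EXON, store, margin=20)
        assert bool(got) is is_span

    def test_oversized_exon_has_no_span_arm(self):
        # max product 1200 minus two 20 b margins: exon > 1160 cannot be spanned
        store = ArmStore(1, [make_arm(3900, 5100)])
        assert ak.find_span_arms((3950, 5111), store, margin=20) == []

    @pytest.mark.parametrize(
        "flank_end, included",
        [(4200, True), (3501, True), (3500, False)],  # gaps 0, 699, 700
    )
    def test_left_reach_boundary(self, flank_end, included):
        span = make_arm(4200, 5200)
        store = ArmStore(1, [make_arm(flank_end - 1000, flank_end), span])
        got = ak.candidate_flank_arms(span, store, "left", reach=700)
        assert (len(got) == 1) is included

    def test_overlapping_arm_excluded(self):
        span = make_arm(4200, 5200)
        store = ArmStore(1, [make_arm(3300, 4201), span])
        assert ak.candidate_flank_arms(span, store, "left") == []


class TestScoring:
    def base(self, **kw):
        params = DesignParams()
        span = make_arm(4200, 5200)
        flank = make_arm(kw.get("flank_start", 3200), kw.get("flank_end", 4200))
        return make_scenario(1, "1", EXON, "LS", flank, span, [], params)

    def test_smaller_gap_wins(self):
        a = self.base(flank_end=4200)  # gap 0
        b = self.base(flank_start=3190, flank_end=4190)  # gap 10
        assert ak.score_key(a) < ak.score_key(b)

    def test_split_distance_breaks_gap_ties(self):
        params = DesignParams()
        near = make_scenario(
            1, "1", EXON, "LS", make_arm(3980, 4980), make_arm(4980, 5980), [], params
        )
        far = make_scenario(
            1, "1", EXON, "LS", make_arm(3960, 4960), make_arm(4960, 5960), [], params
        )
        assert near.split_distance == 20
        assert far.split_distance == 40
        assert ak.score_key(near) < ak.score_key(far)

    def test_longer_cumulative_length_breaks_remaining_ties(self):
        params = DesignParams()
        long = make_scenario(
            1, "1", EXON, "LS", make_arm(3000, 4200), make_arm(4200, 5200), [], params
        )
        short = make_scenario(
            1, "1", EXON, "LS", make_arm(3200, 4200), make_arm(4200, 5200), [], params
        )
        assert ak.score_key(long) < ak.score_key(short)


class TestScreens:
    params = DesignParams()

    def test_exon_in_gap_rejected(self):
        scen = make_scenario(
            1,
            "1",
            EXON,
            "LS",
            make_arm(3100, 4100),
            make_arm(4200, 5200),
            [(4150, 4160)],
            self.params,
        )
        assert scen is None

    def test_arm_ending_inside_other_exon_rejected(self):
        scen = make_scenario(
            1,
            "1",
            EXON,
            "LS",
            make_arm(3100, 4100),
            make_arm(4200, 5200),
            [(4050, 4150)],  # left arm end 4100 falls inside
            self.params,
        )
        assert scen is None

    def test_negative_gap_rejected(self):
        scen = make_scenario(
            1, "1", EXON, "LS", make_arm(3300, 4300), make_arm(4200, 5200), [], self.params
        )
        assert scen is None


class TestGroupSimilar:
    params = DesignParams()

    def scen(self, flank_start, span_start, penalty=1.0):
        flank = make_arm(flank_start, flank_start + 1000, penalty)
        span = make_arm(span_start, span_start + 1000, penalty)
        return make_scenario(1, "1", EXON, "LS", flank, span, [], self.params)

    def test_shared_identical_span_arm_collapses(self):
        a = self.scen(3200, 4200)
        b = make_scenario(
            1,
            "1",
            EXON,
            "LS",
            make_arm(3100, 4100),
            a.span_arm,
            [],
            self.params,
        )
        survivors = ak.group_similar([a, b], end_tolerance=5)
        assert len(survivors) == 1

    def test_six_base_shift_keeps_both(self):
        a, b = self.scen(3200, 4200), self.scen(3206, 4206)
        assert not similar(a, b, 5)
        assert len(ak.group_similar([a, b], end_tolerance=5)) == 2

    def test_similarity_chain_collapses_transitively(self):
        a, b, c = self.scen(3200, 4200), self.scen(3204, 4204), self.scen(3208, 4208)
        assert similar(a, b, 5) and similar(b, c, 5) and not similar(a, c, 5)
        survivors = ak.group_similar([a, b, c], end_tolerance=5)
        assert len(survivors) == 1


class TestDesignPipeline:
    def test_no_span_arm_means_no_scenarios(self):
        store = ArmStore(1, [make_arm(3000, 4000)])
        assert ak.design_knockin(EXON, store, [], DesignParams()) == []

    def test_exact_match_with_brute_force_on_singleton_clusters(self, spread_arms):
        params = DesignParams()
        store = ArmStore(1, spread_arms)
        got = ak.design_knockin(
            EXON, store, OTHER_EXONS, params, gene_id=1, chrom="1"
        )
        expected = ki_oracle(EXON, spread_arms, OTHER_EXONS, params)
        for cat in ("LS", "SR"):
            mine = [s for s in got if s.category == cat]
            ref = expected[cat]
            assert [
                (s.flank_arm.key, s.span_arm.key, s.gap, s.split_distance)
                for s in mine
            ] == [
                (f.key, sp.key, *ki_key(EXON, cat, f, sp)[:2])
                for (_, f, sp) in ref
            ]
            assert [s.rank for s in mine] == list(range(1, len(ref) + 1))

    def test_engine_store_rank1_is_global_optimum(self, micro_ki):
        """The cluster heuristic never loses the globally best scenario."""
        exon = tuple(micro_ki.fx.expected["target_exon"])
        other = [tuple(e) for e in micro_ki.fx.expected["other_exons"]]
        got = ak.design_knockin(
            exon, micro_ki.store, other, micro_ki.params, gene_id=1, chrom="1"
        )
        arms = micro_ki.store.arms
        for cat in ("LS", "SR"):
            mine = [s for s in got if s.category == cat]
            best = ki_best_key(exon, arms, other, micro_ki.params, cat)
            if best is None:
                assert mine == []
                continue
            assert ak.score_key(mine[0]) == best

    def test_engine_store_output_invariants(self, micro_ki):
        exon = tuple(micro_ki.fx.expected["target_exon"])
        other = [tuple(e) for e in micro_ki.fx.expected["other_exons"]]
        params = micro_ki.params
        got = ak.design_knockin(
            exon, micro_ki.store, other, params, gene_id=1, chrom="1"
        )
        assert got, "micro fixture is built to admit knock-in designs"
        for cat in ("LS", "SR"):
            mine = [s for s in got if s.category == cat]
            assert len(mine) <= params.max_scenarios_per_category
            # emitted scenarios are valid and mutually non-similar
            for s in mine:
                assert ki_valid(exon, cat, s.flank_arm, s.span_arm, other, params)
                assert s.split_distance >= params.span_margin
                assert 0 <= s.gap < params.flank_reach
            for i, a in enumerate(mine):
                for b in mine[i + 1 :]:
                    assert not similar(a, b, params.end_tolerance)
        assert len(got) <= 2 * params.max_scenarios_per_category
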