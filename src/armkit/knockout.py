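"""Knock-out scenario generation: partial exon deletion and whole-exon excision.

Knock-out targeting is restricted to *eligible* exons — present in every
transcript variant of the gene (so skipping cannot rescue expression) with a
length not divisible by 3 (so excision shifts the frame).  Two deletion modes
exist:

* **partial deletion** — left arm ends strictly inside the exon, right arm
  starts strictly inside it, putting the split point inside the exon; the
  deleted segment is the gap between them (gap mod 3 is reported, not
  filtered — a frame-preserving internal deletion may still be wanted);
* **whole-exon excision** — attempted only for exons of at most 700 bases,
  with the left arm ending more than 20 bases before the exon start and the
  right arm starting more than 20 bases after the exon end (strict margins).

Both modes reuse the knock-in machinery: DBSCAN clusters per side, the single
smallest-gap design per cluster pair, ranking by gap then cumulative arm
length, similarity-graph grouping, and at most five stored scenarios per exon
per mode.  Knock-in scenarios for the same exon additionally serve as
*stop-codon* knock-out candidates and are linked as complementary designs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .arm_factory import ArmStore, DesignParams, HomologyArm
from .clustering import ArmCluster, cluster_arms
from .gene_models import GeneModelSet, UniqueExon, knockout_eligible_exons
from .knockin import (
    Interval,
    KnockinScenario,
    _arm_termini_ok,
    _arms_similar,
    group_similar,
)


@dataclass(frozen=True)
class KnockoutScenario:
    gene_id: int
    chrom: str
    exon_start: int
    exon_end: int
    mode: str  # partial_deletion | whole_exon
    left_arm: HomologyArm
    right_arm: HomologyArm
    gap: int
    cumulative_length: int
    rank: int = 0

    @property
    def arm1(self) -> HomologyArm:
        return self.left_arm

    @property
    def arm2(self) -> HomologyArm:
        return self.right_arm

    @property
    def gap_interval(self) -> Interval:
        return (self.left_arm.end, self.right_arm.start)

    @property
    def gap_mod3(self) -> int:
        """Frame shift of the deleted segment; exported for user judgment."""
        return self.gap % 3

    @property
    def start(self) -> int:
        return self.left_arm.start


def ko_score_key(scenario: KnockoutScenario):
    """Minimize gap, maximize cumulative arm length, deterministic tie-break."""
    return (scenario.gap, -scenario.cumulative_length, scenario.start)


def ko_similar(a: KnockoutScenario, b: KnockoutScenario, tol: int) -> bool:
    arms_a, arms_b = (a.left_arm, a.right_arm), (b.left_arm, b.right_arm)
    if any(x.key == y.key for x in arms_a for y in arms_b):
        return True
    return _arms_similar(a.left_arm, b.left_arm, tol) and _arms_similar(
        a.right_arm, b.right_arm, tol
    )


def _match_ko_clusters(
    left_clusters: Sequence[ArmCluster],
    right_clusters: Sequence[ArmCluster],
    exon: Interval,
    other_exons: Sequence[Interval],
    mode: str,
    gene_id: int,
    chrom: str,
    params: DesignParams,
    max_gap: int | None,
) -> list[KnockoutScenario]:
    """Smallest-gap survivor per (left cluster x right cluster) pair."""
    out: list[KnockoutScenario] = []
    for lc in left_clusters:
        l_start = np.array([a.start for a in lc.members])
        l_end = np.array([a.end for a in lc.members])
        l_ok = np.array([_arm_termini_ok(a, other_exons) for a in lc.members])
        l_len = l_end - l_start
        for rc in right_clusters:
            r_start = np.array([a.start for a in rc.members])
            r_end = np.array([a.end for a in rc.members])
            r_ok = np.array(
                [_arm_termini_ok(a, other_exons) for a in rc.members]
            )
            r_len = r_end - r_start
            gap = r_start[None, :] - l_end[:, None]
            valid = gap >= 0
            if max_gap is not None:
                valid &= gap < max_gap
            valid &= l_ok[:, None] & r_ok[None, :]
            if mode == "whole_exon":
                for es, ee in other_exons:
                    valid &= ~(
                        (es < r_start[None, :]) & (ee > l_end[:, None])
                    )
            if not valid.any():
                continue
            li, ri = np.nonzero(valid)
            cum = l_len[li] + r_len[ri]
            order = np.lexsort((l_start[li], -cum, gap[li, ri]))
            k = order[0]
            left = lc.members[int(li[k])]
            right = rc.members[int(ri[k])]
            out.append(
                KnockoutScenario(
                    gene_id,
                    chrom,
                    exon[0],
                    exon[1],
                    mode,
                    left,
                    right,
                    right.start - left.end,
                    left.length + right.length,
                )
            )
    return out


def _finalize(
    scenarios: list[KnockoutScenario], params: DesignParams
) -> list[KnockoutScenario]:
    scenarios = group_similar(
        scenarios, params.end_tolerance, key=ko_score_key, sim=ko_similar
    )
    return [
        replace(s, rank=rank)
        for rank, s in enumerate(
            scenarios[: params.max_scenarios_per_category], start=1
        )
    ]


def _check_eligible(exon: UniqueExon, gene_models: GeneModelSet) -> None:
    eligible = knockout_eligible_exons(gene_models, exon.gene_id)
    if exon not in eligible:
        raise ValueError(
            f"exon {exon.chrom}:{exon.start}-{exon.end} of gene "
            f"{exon.gene_id} is not knockout-eligible"
        )


def design_partial_deletion(
    exon: UniqueExon,
    arm_store: ArmStore,
    gene_models: GeneModelSet,
    params: DesignParams,
) -> list[KnockoutScenario]:
    """Deletion designs with the split point inside the exon.

    Left arms end strictly inside the exon, right arms start strictly inside;
    per cluster pair the smallest-gap design survives; ranking minimizes the
    gap and maximizes cumulative arm length; top 5 after similarity grouping.
    Raises for an ineligible exon — callers must pre-filter.
    """
    _check_eligible(exon, gene_models)
    other = _other_exon_intervals(exon, gene_models)
    lefts = arm_store.ending_in(exon.start, exon.end)
    rights = arm_store.starting_in(exon.start, exon.end)
    if not lefts or not rights:
        return []
    lc = cluster_arms(lefts, "left", params.cluster_eps, params.cluster_min_pts)
    rc = cluster_arms(rights, "right", params.cluster_eps, params.cluster_min_pts)
    scenarios = _match_ko_clusters(
        lc,
        rc,
        exon.interval,
        other,
        "partial_deletion",
        exon.gene_id,
        exon.chrom,
        params,
        max_gap=params.flank_reach,
    )
    return _finalize(scenarios, params)


def design_whole_exon(
    exon: UniqueExon,
    arm_store: ArmStore,
    gene_models: GeneModelSet,
    params: DesignParams,
) -> list[KnockoutScenario]:
    """Whole-exon excision designs; not attempted for exons over 700 bases.

    Left arms end >20 bases before the exon start and right arms start >20
    bases after the exon end (strict margins); inner ends must lie within
    ``flank_reach`` of the exon borders.  The deletion interval therefore
    contains the whole exon plus more than 20 bases on each side.
    """
    if exon.length > 700:
        return []
    other = _other_exon_intervals(exon, gene_models)
    margin = params.span_margin
    lefts = [
        a
        for a in arm_store.arms
        if exon.start - a.end > margin
        and exon.start - a.end < params.flank_reach
    ]
    rights = [
        a
        for a in arm_store.arms
        if a.start - exon.end > margin
        and a.start - exon.end < params.flank_reach
    ]
    if not lefts or not rights:
        return []
    lc = cluster_arms(lefts, "left", params.cluster_eps, params.cluster_min_pts)
    rc = cluster_arms(rights, "right", params.cluster_eps, params.cluster_min_pts)
    scenarios = _match_ko_clusters(
        lc,
        rc,
        exon.interval,
        other,
        "whole_exon",
        exon.gene_id,
        exon.chrom,
        params,
        max_gap=None,
    )
    return _finalize(scenarios, params)


def _other_exon_intervals(
    exon: UniqueExon, gene_models: GeneModelSet
) -> list[Interval]:
    """Intervals of the gene's other exons (the target itself excluded)."""
    return [
        e.interval
        for e in gene_models.unique_exons(exon.gene_id)
        if e.chrom == exon.chrom and e.interval != exon.interval
    ]


def complementary_knockin(
    exon: UniqueExon,
    knockin_results: Sequence[KnockinScenario],
) -> list[KnockinScenario]:
    """Knock-in scenarios of the exon flagged as stop-codon knock-out options.

    A premature stop codon introduced through any knock-in scenario covering
    the exon disables the gene, so the knock-in database doubles as a
    knock-out source for exons where no deletion design exists.
    """
    return [
        replace(s, stop_codon_knockout=True)
        for s in knockin_results
        if s.exon_start < exon.end and s.exon_end > exon.start
    ]


def knockout_options(
    deletions: Sequence[KnockoutScenario],
    complementary: Sequence[KnockinScenario],
) -> bool:
    """Whether the exon has at least one knock-out option of any kind."""
    return bool(deletions) or bool(complementary)
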