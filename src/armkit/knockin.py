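"""Knock-in scenario generation, scoring and ranking.

A knock-in scenario pairs a *span arm* — a homology arm covering the whole
target exon (or exon projection) with at least 20 bases of margin beyond each
border — with a flanking arm on one side: left-arm:span-arm (LS) or
span-arm:right-arm (SR).  The selection cassette integrates at the junction
between the two arms (the *split point*); the genomic interval between the
adjacent arm ends (the *gap*) is replaced by the cassette.

Valid scenarios require 0 <= gap < 700, no other exon of the gene inside the
gap, and no arm terminus strictly inside another exon.  Ranking prefers a
smaller gap, then a split point closer to the target exon border, then a
longer cumulative arm length (retention of the knock-in decays with distance
from the integration site, and longer homology increases targeting
efficiency).  Near-identical alternatives are collapsed: DBSCAN clusters of
arms are matched cluster-against-cluster keeping only the best pair per
cluster pair, similar scenarios are grouped as an undirected graph keeping
the best per connected component, and at most five scenarios per category are
emitted (10 per exon).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np

from .arm_factory import ArmStore, DesignParams, HomologyArm
from .clustering import ArmCluster, cluster_arms

Interval = tuple[int, int]


@dataclass(frozen=True)
class KnockinScenario:
    gene_id: int
    chrom: str
    exon_start: int
    exon_end: int
    category: str  # LS | SR
    flank_arm: HomologyArm
    span_arm: HomologyArm
    gap: int
    split_distance: int
    cumulative_length: int
    rank: int = 0
    stop_codon_knockout: bool = False  # flagged when reused as a KO strategy

    @property
    def arm1(self) -> HomologyArm:
        """Leftmost arm (genomic order), the one amplified as HA1."""
        return self.flank_arm if self.category == "LS" else self.span_arm

    @property
    def arm2(self) -> HomologyArm:
        return self.span_arm if self.category == "LS" else self.flank_arm

    @property
    def gap_interval(self) -> Interval:
        return (self.arm1.end, self.arm2.start)

    @property
    def start(self) -> int:
        return self.arm1.start


def score_key(scenario: KnockinScenario):
    """Total ranking order: gap asc, split distance asc, cumulative length
    desc, genomic start asc as a deterministic tie-break."""
    return (
        scenario.gap,
        scenario.split_distance,
        -scenario.cumulative_length,
        scenario.start,
    )


def find_span_arms(
    exon: Interval, arm_store: ArmStore, margin: int = 20
) -> list[HomologyArm]:
    """Arms spanning the whole exon and ending >= ``margin`` bases outside
    both borders (margin inclusive: an arm ending exactly 20 beyond spans)."""
    return arm_store.spanning(exon[0], exon[1], margin)


def candidate_flank_arms(
    span_arm: HomologyArm, arm_store: ArmStore, side: str, reach: int = 700
) -> list[HomologyArm]:
    """Arms within ``reach`` bases of the span arm's end on the given side.

    Left candidates end at or before the span start with a gap strictly under
    ``reach``; right candidates are symmetric.  Overlapping arms (negative
    gap) are excluded.
    """
    if side == "left":
        return [
            a
            for a in arm_store.arms
            if a.end <= span_arm.start and span_arm.start - a.end < reach
        ]
    if side == "right":
        return [
            a
            for a in arm_store.arms
            if a.start >= span_arm.end and a.start - span_arm.end < reach
        ]
    raise ValueError(f"side must be left or right, got {side!r}")


def _terminus_in_exon(pos: int, exons: Sequence[Interval]) -> bool:
    return any(s < pos < e for s, e in exons)


def _arm_termini_ok(arm: HomologyArm, other_exons: Sequence[Interval]) -> bool:
    return not (
        _terminus_in_exon(arm.start, other_exons)
        or _terminus_in_exon(arm.end, other_exons)
    )


def _exon_in_gap(gap_lo: int, gap_hi: int, other_exons: Sequence[Interval]) -> bool:
    return any(s < gap_hi and e > gap_lo for s, e in other_exons)


def make_scenario(
    gene_id: int,
    chrom: str,
    exon: Interval,
    category: str,
    flank: HomologyArm,
    span: HomologyArm,
    other_exons: Sequence[Interval],
    params: DesignParams,
) -> KnockinScenario | None:
    """Build a scenario if the arm pair satisfies every screen, else None."""
    if category == "LS":
        gap = span.start - flank.end
        split = exon[0] - span.start
        gap_lo, gap_hi = flank.end, span.start
    elif category == "SR":
        gap = flank.start - span.end
        split = span.end - exon[1]
        gap_lo, gap_hi = span.end, flank.start
    else:
        raise ValueError(f"unknown category {category!r}")
    if not 0 <= gap < params.flank_reach:
        return None
    if _exon_in_gap(gap_lo, gap_hi, other_exons):
        return None
    if not (_arm_termini_ok(flank, other_exons) and _arm_termini_ok(span, other_exons)):
        return None
    return KnockinScenario(
        gene_id,
        chrom,
        exon[0],
        exon[1],
        category,
        flank,
        span,
        gap,
        split,
        flank.length + span.length,
    )


def match_clusters(
    span_clusters: Sequence[ArmCluster],
    flank_clusters: Sequence[ArmCluster],
    exon: Interval,
    other_exons: Sequence[Interval],
    category: str,
    gene_id: int,
    chrom: str,
    params: DesignParams,
) -> list[KnockinScenario]:
    """Screen every arm x arm combination per (span cluster x flank cluster)
    pair and keep exactly the best survivor per pair, by :func:`score_key`.

    The inner screen is vectorized: gap, exon-in-gap and terminus conditions
    reduce to broadcast comparisons on the member coordinate arrays.
    """
    out: list[KnockinScenario] = []
    oe = np.array(other_exons, dtype=np.int64).reshape(-1, 2)

    def arrs(cluster: ArmCluster):
        s = np.array([a.start for a in cluster.members])
        e = np.array([a.end for a in cluster.members])
        ok = np.array([_arm_termini_ok(a, other_exons) for a in cluster.members])
        return s, e, ok

    for sc in span_clusters:
        s_start, s_end, s_ok = arrs(sc)
        s_len = s_end - s_start
        split = (
            exon[0] - s_start if category == "LS" else s_end - exon[1]
        )
        for fc in flank_clusters:
            f_start, f_end, f_ok = arrs(fc)
            f_len = f_end - f_start
            if category == "LS":
                gap = s_start[None, :] - f_end[:, None]
                glo, ghi = f_end[:, None], s_start[None, :]
            else:
                gap = f_start[:, None] - s_end[None, :]
                glo, ghi = s_end[None, :], f_start[:, None]
            valid = (gap >= 0) & (gap < params.flank_reach)
            valid &= f_ok[:, None] & s_ok[None, :]
            for es, ee in oe:
                valid &= ~((es < ghi) & (ee > glo))
            if not valid.any():
                continue
            fi, si = np.nonzero(valid)
            cum = f_len[fi] + s_len[si]
            start = np.minimum(f_start[fi], s_start[si])
            order = np.lexsort((start, -cum, split[si], gap[fi, si]))
            k = order[0]
            scen = make_scenario(
                gene_id,
                chrom,
                exon,
                category,
                fc.members[int(fi[k])],
                sc.members[int(si[k])],
                other_exons,
                params,
            )
            assert scen is not None
            out.append(scen)
    return out


def _arms_similar(a: HomologyArm, b: HomologyArm, tol: int) -> bool:
    return abs(a.start - b.start) <= tol and abs(a.end - b.end) <= tol


def similar(a: KnockinScenario, b: KnockinScenario, tol: int) -> bool:
    """Scenarios sharing an identical arm, or whose corresponding arms both
    differ by at most ``tol`` bases at each end."""
    arms_a, arms_b = (a.flank_arm, a.span_arm), (b.flank_arm, b.span_arm)
    if any(x.key == y.key for x in arms_a for y in arms_b):
        return True
    return _arms_similar(a.flank_arm, b.flank_arm, tol) and _arms_similar(
        a.span_arm, b.span_arm, tol
    )


def group_similar(
    scenarios: Sequence, end_tolerance: int = 5, key=score_key, sim=similar
) -> list:
    """Best scenario per connected component of the similarity graph."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(scenarios)))
    for i in range(len(scenarios)):
        for j in range(i + 1, len(scenarios)):
            if sim(scenarios[i], scenarios[j], end_tolerance):
                graph.add_edge(i, j)
    out = []
    for component in nx.connected_components(graph):
        out.append(min((scenarios[i] for i in component), key=key))
    out.sort(key=key)
    return out


def design_knockin(
    exon: Interval,
    arm_store: ArmStore,
    other_exons: Sequence[Interval],
    params: DesignParams,
    gene_id: int = 0,
    chrom: str = "",
) -> list[KnockinScenario]:
    """Full knock-in pipeline for one exon or projection.

    span arms -> DBSCAN clusters -> cluster-cluster matching (LS and SR
    separately) -> similarity grouping -> ranking -> top 5 per category.
    Emitted scenarios carry rank 1..5 within their category.
    """
    spans = find_span_arms(exon, arm_store, params.span_margin)
    if not spans:
        return []
    span_clusters = cluster_arms(
        spans, "span", params.cluster_eps, params.cluster_min_pts
    )
    results: list[KnockinScenario] = []
    for category, side in (("LS", "left"), ("SR", "right")):
        candidates: dict[tuple, HomologyArm] = {}
        for span in spans:
            for arm in candidate_flank_arms(
                span, arm_store, side, params.flank_reach
            ):
                candidates[arm.key] = arm
        flank_arms = sorted(
            candidates.values(), key=lambda a: (a.start, a.end, a.key)
        )
        if not flank_arms:
            continue
        flank_clusters = cluster_arms(
            flank_arms, side, params.cluster_eps, params.cluster_min_pts
        )
        scenarios = match_clusters(
            span_clusters,
            flank_clusters,
            exon,
            other_exons,
            category,
            gene_id,
            chrom,
            params,
        )
        scenarios = group_similar(scenarios, params.end_tolerance)
        for rank, scen in enumerate(
            scenarios[: params.max_scenarios_per_category], start=1
        ):
            results.append(replace(scen, rank=rank))
    return results
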