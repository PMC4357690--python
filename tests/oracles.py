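"""Independent brute-force oracles and small builders used across tests.

Everything here is deliberately written from first principles (plain loops,
transitive closures, streaming minima) and never calls the pipeline's own
clustering/matching/grouping code paths, so it can serve as the reference the
pipeline is checked against.
"""

from __future__ import annotations

from itertools import combinations

from armkit.arm_factory import DesignParams, HomologyArm, PrimerPair

VALID_PRIMER = "ACGTACGTACGTACGTACGT"  # 20-mer, no mono-run > 1


def make_arm(
    start: int, end: int, penalty: float = 1.0, chrom: str = "1"
) -> HomologyArm:
    """A synthetic homology arm with placeholder (filter-clean) primers."""
    pair = PrimerPair(
        chrom=chrom,
        fwd_seq=VALID_PRIMER,
        fwd_start=start,
        fwd_end=start + 20,
        rev_seq=VALID_PRIMER,
        rev_start=end - 20,
        rev_end=end,
        penalty=penalty,
    )
    return HomologyArm(pair, start, end, 0.0)


# -- DBSCAN ------------------------------------------------------------------


def brute_dbscan(points, eps, min_pts):
    """Textbook density-reachability DBSCAN; labels, -1 = noise."""
    n = len(points)

    def cheb(a, b):
        return max(abs(x - y) for x, y in zip(a, b))

    neigh = [
        {j for j in range(n) if cheb(points[i], points[j]) <= eps}
        for i in range(n)
    ]
    core = [len(neigh[i]) >= min_pts for i in range(n)]
    labels = [-1] * n
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        frontier = [i]
        while frontier:
            q = frontier.pop()
            if not core[q]:
                continue
            for j in neigh[q]:
                if labels[j] == -1:
                    labels[j] = cid
                    frontier.append(j)
        cid += 1
    return labels


def partition_of(labels):
    """Cluster partition as a set of frozensets of point indices (noise kept
    as singletons), invariant to label numbering."""
    groups: dict[int, set[int]] = {}
    noise = []
    for i, lab in enumerate(labels):
        if lab == -1:
            noise.append(frozenset([i]))
        else:
            groups.setdefault(lab, set()).add(i)
    return set(map(frozenset, groups.values())) | set(noise)


# -- knock-in ----------------------------------------------------------------


def ki_valid(exon, cat, flank, span, other_exons, params: DesignParams):
    m = params.span_margin
    if not (span.start <= exon[0] - m and span.end >= exon[1] + m):
        return False
    if cat == "LS":
        gap_lo, gap_hi = flank.end, span.start
    else:
        gap_lo, gap_hi = span.end, flank.start
    gap = gap_hi - gap_lo
    if not 0 <= gap < params.flank_reach:
        return False
    for es, ee in other_exons:
        if es < gap_hi and ee > gap_lo:  # exon inside the gap
            return False
        for arm in (flank, span):
            if es < arm.start < ee or es < arm.end < ee:
                return False
    return True


def ki_key(exon, cat, flank, span):
    if cat == "LS":
        gap = span.start - flank.end
        split = exon[0] - span.start
    else:
        gap = flank.start - span.end
        split = span.end - exon[1]
    return (
        gap,
        split,
        -(flank.length + span.length),
        min(flank.start, span.start),
    )


def ki_enumerate(exon, arms, other_exons, params):
    """All valid (category, flank, span) triples, unranked."""
    m = params.span_margin
    spans = [
        a for a in arms if a.start <= exon[0] - m and a.end >= exon[1] + m
    ]
    out = []
    for cat in ("LS", "SR"):
        for span in spans:
            for flank in arms:
                if flank.key == span.key:
                    continue
                if ki_valid(exon, cat, flank, span, other_exons, params):
                    out.append((cat, flank, span))
    return out


def ki_best_key(exon, arms, other_exons, params, cat):
    """Streaming global optimum of the ranking key for one category."""
    best = None
    for c, flank, span in ki_enumerate(exon, arms, other_exons, params):
        if c != cat:
            continue
        key = ki_key(exon, c, flank, span)
        if best is None or key < best:
            best = key
    return best


def arms_similar(a, b, tol):
    return abs(a.start - b.start) <= tol and abs(a.end - b.end) <= tol


def ki_similar(x, y, tol):
    (_, fa, sa), (_, fb, sb) = x, y
    if any(p.key == q.key for p in (fa, sa) for q in (fb, sb)):
        return True
    return arms_similar(fa, fb, tol) and arms_similar(sa, sb, tol)


def group_best(items, key, sim, tol):
    """Connected components of the similarity relation (transitive closure),
    best item per component, sorted by key."""
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        if sim(items[i], items[j], tol):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    comps: dict[int, list] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(items[i])
    return sorted((min(c, key=key) for c in comps.values()), key=key)


def ki_oracle(exon, arms, other_exons, params):
    """Full brute-force knock-in result: per category, all valid pairs ->
    similarity grouping -> ranking -> top 5.  Tractable for tens of arms."""
    result = {}
    for cat in ("LS", "SR"):
        cands = [
            t for t in ki_enumerate(exon, arms, other_exons, params) if t[0] == cat
        ]
        grouped = group_best(
            cands,
            key=lambda t: ki_key(exon, *t),
            sim=ki_similar,
            tol=params.end_tolerance,
        )
        result[cat] = grouped[: params.max_scenarios_per_category]
    return result


# -- knock-out ---------------------------------------------------------------


def _terminus_in_any(arm, other_exons):
    return any(
        es < arm.start < ee or es < arm.end < ee for es, ee in other_exons
    )


def ko_partial_enumerate(exon, arms, other_exons, params):
    lefts = [a for a in arms if exon[0] < a.end < exon[1]]
    rights = [a for a in arms if exon[0] < a.start < exon[1]]
    out = []
    for left in lefts:
        for right in rights:
            gap = right.start - left.end
            if not 0 <= gap < params.flank_reach:
                continue
            if _terminus_in_any(left, other_exons) or _terminus_in_any(
                right, other_exons
            ):
                continue
            out.append((left, right))
    return out


def ko_whole_enumerate(exon, arms, other_exons, params):
    m = params.span_margin
    lefts = [
        a
        for a in arms
        if m < exon[0] - a.end < params.flank_reach
    ]
    rights = [
        a
        for a in arms
        if m < a.start - exon[1] < params.flank_reach
    ]
    out = []
    for left in lefts:
        for right in rights:
            if right.start < left.end:
                continue
            bad = False
            for es, ee in other_exons:
                if es < right.start and ee > left.end:
                    bad = True
                for arm in (left, right):
                    if es < arm.start < ee or es < arm.end < ee:
                        bad = True
            if not bad:
                out.append((left, right))
    return out


def ko_key(pair):
    left, right = pair
    return (
        right.start - left.end,
        -(left.length + right.length),
        left.start,
    )


def ko_similar_pairs(x, y, tol):
    (la, ra), (lb, rb) = x, y
    if any(p.key == q.key for p in (la, ra) for q in (lb, rb)):
        return True
    return arms_similar(la, lb, tol) and arms_similar(ra, rb, tol)


def ko_oracle(pairs, params):
    grouped = group_best(
        pairs, key=ko_key, sim=ko_similar_pairs, tol=params.end_tolerance
    )
    return grouped[: params.max_scenarios_per_category]
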