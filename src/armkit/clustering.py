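"""DBSCAN clustering of homology arms by genomic position.

Arms are embedded as 2-D points (product start, product end) and clustered
with DBSCAN under the Chebyshev metric, so two arms are eps-neighbors exactly
when both endpoints differ by at most eps — the same geometry as the
downstream "differing by no more than 5 bases in each end" similarity rule.
With min_pts=1 (the default) no arm is discarded as noise and the partition
is simply the connected components of the eps-neighbor graph, which makes it
independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .arm_factory import HomologyArm


@dataclass(frozen=True)
class ArmCluster:
    role: str  # span | left | right
    members: tuple[HomologyArm, ...]
    extent: tuple[int, int]  # (min start, max end) over members

    def __len__(self) -> int:
        return len(self.members)


def dbscan(points: Sequence[Sequence[float]], eps: float, min_pts: int) -> np.ndarray:
    """Standard DBSCAN labels under the Chebyshev metric; -1 marks noise.

    With ``min_pts`` = 1 every point is a core point, so no noise exists.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        return np.empty(0, dtype=int)
    model = DBSCAN(eps=eps, min_samples=min_pts, metric="chebyshev")
    return model.fit_predict(arr)


def cluster_arms(
    arms: Sequence[HomologyArm], role: str, eps: float, min_pts: int = 1
) -> list[ArmCluster]:
    """Partition same-role arms into clusters, deterministically ordered.

    Noise points (possible only when min_pts > 1) become singleton clusters so
    the result is always a partition of the input.  Clusters are sorted by
    representative extent, then by first member key.
    """
    if not arms:
        return []
    pts = [(a.start, a.end) for a in arms]
    labels = dbscan(pts, eps, min_pts)
    groups: dict[int, list[HomologyArm]] = {}
    next_noise = labels.max(initial=-1) + 1
    for arm, label in zip(arms, labels):
        if label == -1:
            groups[next_noise] = [arm]
            next_noise += 1
        else:
            groups.setdefault(int(label), []).append(arm)
    clusters = []
    for members in groups.values():
        members = sorted(members, key=lambda a: (a.start, a.end, a.key))
        extent = (min(a.start for a in members), max(a.end for a in members))
        clusters.append(ArmCluster(role, tuple(members), extent))
    clusters.sort(key=lambda c: (c.extent, c.members[0].key))
    return clusters
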