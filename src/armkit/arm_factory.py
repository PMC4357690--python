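"""Candidate homology-arm enumeration and coverage statistics.

A homology arm is a candidate PCR product of 700-1200 bp that survives three
filters: no primer base in a repeat (soft-masked lowercase) or N, no
mononucleotide run longer than 3 in either primer as synthesized, and at most
25% repeat content in the product.  Candidates are generated by tiling each
target region with a sliding window (size SW, step SS) and asking the primer
engine for the NPP best pairs in each 50 bp product-size bin; the union over
windows and bins is filtered and deduplicated into a per-gene arm store.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .engine import EnginePair, PrimerEngine
from .sequence_store import TargetRegion, repeat_fraction

log = logging.getLogger(__name__)


def default_size_ranges() -> tuple[tuple[int, int], ...]:
    """700-1200 bp tiled in 50 bp half-open bins; the last bin closes at 1200."""
    bins = [(lo, lo + 50) for lo in range(700, 1150, 50)]
    bins.append((1150, 1201))
    return tuple(bins)


@dataclass(frozen=True)
class DesignParams:
    """Every knob of arm generation and scenario design, with field defaults.

    sw/ss/npp are the sliding-window size, step size and retained pairs per
    (window x size-range) round.  ``flank_reach`` bounds how far a flanking arm
    may sit from a span arm (and equals the maximum inter-arm gap).
    """

    sw: int = 1300
    ss: int = 50
    npp: int = 50
    size_ranges: tuple[tuple[int, int], ...] = field(
        default_factory=default_size_ranges
    )
    primer_len: tuple[int, int] = (18, 30)
    max_monorun: int = 3
    max_product_repeat_fraction: float = 0.25
    flank_size: int = 3000
    cluster_eps: float = 50.0
    cluster_min_pts: int = 1
    span_margin: int = 20
    flank_reach: int = 700
    end_tolerance: int = 5
    max_scenarios_per_category: int = 5

    def __post_init__(self) -> None:
        max_product = max(hi for _, hi in self.size_ranges) - 1
        if self.sw < max_product:
            raise ValueError("sliding window must exceed the maximum product size")
        if self.ss < 1 or self.npp < 1:
            raise ValueError("ss and npp must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "DesignParams":
        """Read key=value lines; unknown keys error; CLI overrides win."""
        values: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (p.strip() for p in line.split("=", 1))
            values[key] = _coerce(key, val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(key: str, val: str):
    if key == "size_ranges":
        return tuple(
            tuple(int(x) for x in part.split("-")) for part in val.split(",")
        )
    if key == "primer_len":
        return tuple(int(x) for x in val.split("-"))
    if key in ("cluster_eps", "max_product_repeat_fraction"):
        return float(val)
    return int(val)


@dataclass(frozen=True)
class PrimerPair:
    """An engine pair lifted to genomic coordinates."""

    chrom: str
    fwd_seq: str
    fwd_start: int
    fwd_end: int
    rev_seq: str
    rev_start: int
    rev_end: int
    penalty: float


@dataclass(frozen=True)
class HomologyArm:
    """A filtered candidate PCR product usable as a homology arm."""

    pair: PrimerPair
    start: int  # product interval = [fwd_start, rev_end)
    end: int
    repeat_fraction: float

    @property
    def chrom(self) -> str:
        return self.pair.chrom

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[int, int, int, int]:
        """Dedupe identity: the genomic coordinate quadruple of both primers."""
        p = self.pair
        return (p.fwd_start, p.fwd_end, p.rev_start, p.rev_end)


@dataclass(frozen=True)
class CoverageStats:
    sequence_coverage: float  # fraction of target bases inside >=1 arm
    average_depth: float  # mean per-base arm count over the target
    average_penalty: float | None  # None when the store is empty
    n_arms: int

    @property
    def depth_per_penalty(self) -> float | None:
        if self.average_penalty is None or self.average_penalty == 0:
            return None
        return self.average_depth / self.average_penalty


# ---------------------------------------------------------------------------


def windows(region_length: int, sw: int, ss: int) -> list[tuple[int, int]]:
    """Window offsets 0, ss, 2ss, ... while they fit; a final window anchored
    at the region end covers any remainder; a short region is one window."""
    if region_length < 1:
        raise ValueError("region length must be >= 1")
    if region_length <= sw:
        return [(0, region_length)]
    out = [(off, off + sw) for off in range(0, region_length - sw + 1, ss)]
    if out[-1][1] < region_length:
        out.append((region_length - sw, region_length))
    return out


def design_in_window(
    window_seq: str,
    size_range: tuple[int, int],
    npp: int,
    engine: PrimerEngine,
) -> list[EnginePair]:
    """Engine invocation for one window and size bin; failures are logged and
    yield an empty list (a skipped window is never fatal)."""
    if not window_seq:
        return []
    try:
        return engine.design(window_seq, size_range, npp)
    except Exception:  # engine plug-ins may fail arbitrarily
        log.warning("primer engine failed on a window; skipped", exc_info=True)
        return []


_RUN_RE = re.compile(r"(.)\1*")


def max_mononucleotide_run(seq: str) -> int:
    if not seq:
        return 0
    return max(len(m.group(0)) for m in _RUN_RE.finditer(seq.upper()))


def _primer_ok(seq: str, params: DesignParams) -> bool:
    lo, hi = params.primer_len
    if not lo <= len(seq) <= hi:
        return False
    if not all(c in "ACGT" for c in seq):  # masked (lowercase) or N base
        return False
    return max_mononucleotide_run(seq) <= params.max_monorun


def filter_pairs(
    pairs: Sequence[PrimerPair],
    region_seq: str,
    region_start: int,
    params: DesignParams,
) -> list[HomologyArm]:
    """Apply the three arm filters; survivors carry their repeat fraction.

    (i) no primer nucleotide in a repeat or N — checked on the primer
    sequences as synthesized (reverse primer is the reverse complement, which
    preserves case and runs); (ii) mononucleotide runs in primers <= 3;
    (iii) product repeat fraction <= 25% (boundary kept).
    """
    lo = min(a for a, _ in params.size_ranges)
    hi = max(b for _, b in params.size_ranges) - 1
    out = []
    for p in pairs:
        if not (_primer_ok(p.fwd_seq, params) and _primer_ok(p.rev_seq, params)):
            continue
        length = p.rev_end - p.fwd_start
        if not lo <= length <= hi:
            continue
        product = region_seq[p.fwd_start - region_start : p.rev_end - region_start]
        frac = repeat_fraction(product)
        if frac > params.max_product_repeat_fraction:
            continue
        out.append(HomologyArm(p, p.fwd_start, p.rev_end, round(frac, 6)))
    return out


class ArmStore:
    """Per-gene collection of homology arms, indexed for interval queries."""

    def __init__(self, gene_id: int, arms: Iterable[HomologyArm]):
        self.gene_id = gene_id
        self.arms: list[HomologyArm] = sorted(
            arms, key=lambda a: (a.start, a.end, a.key)
        )
        self._starts = np.array([a.start for a in self.arms], dtype=np.int64)
        self._ends = np.array([a.end for a in self.arms], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.arms)

    @property
    def is_empty(self) -> bool:
        """True for genes with no suitable primer pairs under the filters."""
        return not self.arms

    def spanning(self, start: int, end: int, margin: int) -> list[HomologyArm]:
        """Arms covering [start, end) with >= margin bases beyond each border."""
        mask = (self._starts <= start - margin) & (self._ends >= end + margin)
        return [self.arms[i] for i in np.nonzero(mask)[0]]

    def ending_in(self, start: int, end: int) -> list[HomologyArm]:
        """Arms whose product end falls strictly inside (start, end)."""
        mask = (self._ends > start) & (self._ends < end)
        return [self.arms[i] for i in np.nonzero(mask)[0]]

    def starting_in(self, start: int, end: int) -> list[HomologyArm]:
        mask = (self._starts > start) & (self._starts < end)
        return [self.arms[i] for i in np.nonzero(mask)[0]]

    # -- persistence ------------------------------------------------------
    _COLUMNS = (
        "chrom start end length penalty repeat_fraction "
        "fwd_seq fwd_start fwd_end rev_seq rev_start rev_end"
    ).split()

    def write_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(self._COLUMNS)]
        for a in self.arms:
            p = a.pair
            lines.append(
                "\t".join(
                    [
                        p.chrom,
                        str(a.start),
                        str(a.end),
                        str(a.length),
                        repr(p.penalty),
                        repr(a.repeat_fraction),
                        p.fwd_seq,
                        str(p.fwd_start),
                        str(p.fwd_end),
                        p.rev_seq,
                        str(p.rev_start),
                        str(p.rev_end),
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, gene_id: int, path: str | Path) -> "ArmStore":
        lines = Path(path).read_text().splitlines()
        header = lines[0].split("\t")
        arms = []
        for line in lines[1:]:
            rec = dict(zip(header, line.split("\t")))
            pair = PrimerPair(
                chrom=rec["chrom"],
                fwd_seq=rec["fwd_seq"],
                fwd_start=int(rec["fwd_start"]),
                fwd_end=int(rec["fwd_end"]),
                rev_seq=rec["rev_seq"],
                rev_start=int(rec["rev_start"]),
                rev_end=int(rec["rev_end"]),
                penalty=float(rec["penalty"]),
            )
            arms.append(
                HomologyArm(
                    pair,
                    int(rec["start"]),
                    int(rec["end"]),
                    float(rec["repeat_fraction"]),
                )
            )
        return cls(gene_id, arms)


def build_arm_database(
    gene_id: int,
    regions: Sequence[TargetRegion],
    params: DesignParams,
    engine: PrimerEngine,
) -> ArmStore:
    """Union over windows x size ranges of all filtered arms for one gene.

    Identical primer-coordinate quadruples collapse to the lowest-penalty
    arm (global dedupe across windows, bins and regions).
    """
    best: dict[tuple, HomologyArm] = {}
    for region in regions:
        seq = region.sequence.bases
        for wstart, wend in windows(region.length, params.sw, params.ss):
            wseq = seq[wstart:wend]
            pairs: list[PrimerPair] = []
            for size_range in params.size_ranges:
                for ep in design_in_window(wseq, size_range, params.npp, engine):
                    shift = region.start + wstart
                    pairs.append(
                        PrimerPair(
                            chrom=region.chrom,
                            fwd_seq=ep.fwd_seq,
                            fwd_start=ep.fwd_start + shift,
                            fwd_end=ep.fwd_end + shift,
                            rev_seq=ep.rev_seq,
                            rev_start=ep.rev_start + shift,
                            rev_end=ep.rev_end + shift,
                            penalty=ep.penalty,
                        )
                    )
            for arm in filter_pairs(pairs, seq, region.start, params):
                prev = best.get(arm.key)
                if prev is None or arm.pair.penalty < prev.pair.penalty:
                    best[arm.key] = arm
    store = ArmStore(gene_id, best.values())
    if store.is_empty:
        log.info("gene %d: no suitable primer pairs", gene_id)
    return store


def coverage_stats(
    store: ArmStore, target_interval: tuple[int, int]
) -> CoverageStats:
    """Coverage of the target interval by stored arms.

    sequence_coverage is the fraction of target bases inside at least one arm;
    average_depth the mean number of arms over a target base; average_penalty
    the mean engine pair penalty (undefined, not zero, for an empty store).
    """
    t0, t1 = target_interval
    if t1 <= t0:
        raise ValueError("empty target interval")
    if store.is_empty:
        return CoverageStats(0.0, 0.0, None, 0)
    depth = np.zeros(t1 - t0 + 1, dtype=np.int64)
    for a in store.arms:
        lo, hi = max(a.start, t0), min(a.end, t1)
        if hi > lo:
            depth[lo - t0] += 1
            depth[hi - t0] -= 1
    depth = np.cumsum(depth[:-1])
    penalties = [a.pair.penalty for a in store.arms]
    return CoverageStats(
        sequence_coverage=float((depth > 0).mean()),
        average_depth=float(depth.mean()),
        average_penalty=float(np.mean(penalties)),
        n_arms=len(store),
    )
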