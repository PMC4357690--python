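"""Wet-lab-ready outputs: attB-tailed primers and scenario reports.

For Gateway cloning each homology arm is PCR-amplified with primers carrying
an attB recombination tail, so the products drop into pDONR entry vectors by
BP recombination.  Tail sequences live purely in configuration; the shipped
defaults are the canonical Gateway attB1/attB2 (arm 1, pDONR P1-P2) and
attB3/attB4 (arm 2) sites and are expected to be replaced to match the user's
donor vectors.  Tailing is pure concatenation — the genomic primer is never
modified — so stripping a configured tail recovers the stored primer exactly.

Scenario reports are written as TSV (lossless round-trip), JSON, or BED
(0-based half-open; one record per arm plus one per gap/deletion interval).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .arm_factory import HomologyArm, PrimerPair
from .knockin import KnockinScenario
from .knockout import KnockoutScenario

#: Canonical Gateway attB tails — user-replaceable via configuration.
DEFAULT_ATT_CONFIG = {
    "arm1_forward": "GGGGACAAGTTTGTACAAAAAAGCAGGCT",  # attB1
    "arm1_reverse": "GGGGACCACTTTGTACAAGAAAGCTGGGT",  # attB2
    "arm2_forward": "GGGGACAACTTTGTATAATAAAGTTG",  # attB3
    "arm2_reverse": "GGGGACAACTTTGTATAGAAAAGTTG",  # attB4
}


@dataclass(frozen=True)
class TailedPrimer:
    label: str  # e.g. arm1_forward
    tail: str
    genomic: str

    @property
    def sequence(self) -> str:
        return self.tail + self.genomic


@dataclass(frozen=True)
class TailedPrimerSet:
    scenario_id: str
    primers: tuple[TailedPrimer, TailedPrimer, TailedPrimer, TailedPrimer]


def scenario_id(scenario) -> str:
    kind = getattr(scenario, "category", None) or scenario.mode
    return (
        f"gene{scenario.gene_id}|{scenario.chrom}:{scenario.exon_start}-"
        f"{scenario.exon_end}|{kind}|rank{scenario.rank}"
    )


def tail_primers(scenario, att_config: dict | None = None) -> TailedPrimerSet:
    """Four attB-tailed amplification primers for a scenario's two arms.

    ``att_config`` must supply all four tails (arm1/arm2 x forward/reverse);
    a missing key is an error.  Arm 1 is the genomically leftmost arm.
    """
    config = DEFAULT_ATT_CONFIG if att_config is None else att_config
    missing = [k for k in DEFAULT_ATT_CONFIG if k not in config]
    if missing:
        raise ValueError(f"att_config missing tail(s): {missing}")
    primers = []
    for arm_name, arm in (("arm1", scenario.arm1), ("arm2", scenario.arm2)):
        for direction, seq in (
            ("forward", arm.pair.fwd_seq),
            ("reverse", arm.pair.rev_seq),
        ):
            label = f"{arm_name}_{direction}"
            primers.append(TailedPrimer(label, config[label], seq))
    return TailedPrimerSet(scenario_id(scenario), tuple(primers))


# ---------------------------------------------------------------------------

_KI_COLUMNS = (
    "gene_id chrom exon_start exon_end category rank gap split_distance "
    "cumulative_length stop_codon_knockout "
    "flank_start flank_end flank_fwd_seq flank_fwd_start flank_fwd_end "
    "flank_rev_seq flank_rev_start flank_rev_end flank_penalty "
    "flank_repeat_fraction "
    "span_start span_end span_fwd_seq span_fwd_start span_fwd_end "
    "span_rev_seq span_rev_start span_rev_end span_penalty "
    "span_repeat_fraction"
).split()

_KO_COLUMNS = (
    "gene_id chrom exon_start exon_end mode rank gap gap_mod3 "
    "cumulative_length "
    "left_start left_end left_fwd_seq left_fwd_start left_fwd_end "
    "left_rev_seq left_rev_start left_rev_end left_penalty "
    "left_repeat_fraction "
    "right_start right_end right_fwd_seq right_fwd_start right_fwd_end "
    "right_rev_seq right_rev_start right_rev_end right_penalty "
    "right_repeat_fraction"
).split()


def _arm_fields(arm: HomologyArm) -> list[str]:
    p = arm.pair
    return [
        str(arm.start),
        str(arm.end),
        p.fwd_seq,
        str(p.fwd_start),
        str(p.fwd_end),
        p.rev_seq,
        str(p.rev_start),
        str(p.rev_end),
        repr(p.penalty),
        repr(arm.repeat_fraction),
    ]


def _ki_row(s: KnockinScenario) -> list[str]:
    return (
        [
            str(s.gene_id),
            s.chrom,
            str(s.exon_start),
            str(s.exon_end),
            s.category,
            str(s.rank),
            str(s.gap),
            str(s.split_distance),
            str(s.cumulative_length),
            str(int(s.stop_codon_knockout)),
        ]
        + _arm_fields(s.flank_arm)
        + _arm_fields(s.span_arm)
    )


def _ko_row(s: KnockoutScenario) -> list[str]:
    return (
        [
            str(s.gene_id),
            s.chrom,
            str(s.exon_start),
            str(s.exon_end),
            s.mode,
            str(s.rank),
            str(s.gap),
            str(s.gap_mod3),
            str(s.cumulative_length),
        ]
        + _arm_fields(s.left_arm)
        + _arm_fields(s.right_arm)
    )


def _parse_arm(rec: dict, prefix: str, chrom: str) -> HomologyArm:
    pair = PrimerPair(
        chrom=chrom,
        fwd_seq=rec[f"{prefix}_fwd_seq"],
        fwd_start=int(rec[f"{prefix}_fwd_start"]),
        fwd_end=int(rec[f"{prefix}_fwd_end"]),
        rev_seq=rec[f"{prefix}_rev_seq"],
        rev_start=int(rec[f"{prefix}_rev_start"]),
        rev_end=int(rec[f"{prefix}_rev_end"]),
        penalty=float(rec[f"{prefix}_penalty"]),
    )
    return HomologyArm(
        pair,
        int(rec[f"{prefix}_start"]),
        int(rec[f"{prefix}_end"]),
        float(rec[f"{prefix}_repeat_fraction"]),
    )


def export(scenarios: Sequence, fmt: str, path: str | Path) -> None:
    """Write scenarios as ``tsv``, ``json`` or ``bed``; stable order and
    columns, valid (header-only) output for an empty list."""
    path = Path(path)
    kinds = {type(s).__name__ for s in scenarios}
    if len(kinds) > 1:
        raise ValueError("cannot mix knock-in and knock-out scenarios")
    is_ko = kinds == {"KnockoutScenario"}
    columns = _KO_COLUMNS if is_ko else _KI_COLUMNS
    rows = [(_ko_row if is_ko else _ki_row)(s) for s in scenarios]
    if fmt == "tsv":
        lines = ["\t".join(columns)] + ["\t".join(r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        path.write_text(
            json.dumps(
                [dict(zip(columns, r)) for r in rows], indent=1, sort_keys=True
            )
            + "\n"
        )
    elif fmt == "bed":
        lines = []
        for s in scenarios:
            sid = scenario_id(s)
            lines.append(f"{s.chrom}\t{s.arm1.start}\t{s.arm1.end}\t{sid}|arm1\t0\t.")
            glo, ghi = s.gap_interval
            lines.append(f"{s.chrom}\t{glo}\t{ghi}\t{sid}|gap\t0\t.")
            lines.append(f"{s.chrom}\t{s.arm2.start}\t{s.arm2.end}\t{sid}|arm2\t0\t.")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_scenarios_tsv(path: str | Path) -> list:
    """Parse back a TSV export; lossless inverse of ``export(..., 'tsv')``."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    is_ko = "mode" in header
    out = []
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        chrom = rec["chrom"]
        if is_ko:
            out.append(
                KnockoutScenario(
                    gene_id=int(rec["gene_id"]),
                    chrom=chrom,
                    exon_start=int(rec["exon_start"]),
                    exon_end=int(rec["exon_end"]),
                    mode=rec["mode"],
                    left_arm=_parse_arm(rec, "left", chrom),
                    right_arm=_parse_arm(rec, "right", chrom),
                    gap=int(rec["gap"]),
                    cumulative_length=int(rec["cumulative_length"]),
                    rank=int(rec["rank"]),
                )
            )
        else:
            out.append(
                KnockinScenario(
                    gene_id=int(rec["gene_id"]),
                    chrom=chrom,
                    exon_start=int(rec["exon_start"]),
                    exon_end=int(rec["exon_end"]),
                    category=rec["category"],
                    flank_arm=_parse_arm(rec, "flank", chrom),
                    span_arm=_parse_arm(rec, "span", chrom),
                    gap=int(rec["gap"]),
                    split_distance=int(rec["split_distance"]),
                    cumulative_length=int(rec["cumulative_length"]),
                    rank=int(rec["rank"]),
                    stop_codon_knockout=bool(int(rec["stop_codon_knockout"])),
                )
            )
    return out
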