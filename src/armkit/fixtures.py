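"""Deterministic synthetic genomes and CCDS-style annotation with ground truth.

The generator emulates the statistical shape of the real inputs — a
soft-masked chromosome with tunable repeat density, and a multi-transcript
CCDS-dialect annotation table with shared, overlapping and dropped exons
across transcript variants plus non-Public decoy records — so that every
pipeline stage is testable with no download.  A truth record accompanies each
instance listing, per gene, the expected unique exons, exon projections,
knockout-eligible exons and the placed repeat tracts; every truth field is
recomputable from the emitted files by the corresponding pipeline operation.

Exon lengths are drawn log-normally around a ~120 b median (the scale of real
coding exons) and introns uniformly in the few-hundred-to-few-kb range;
repeats are independent geometric-length tracts merged where they overlap.
All randomness flows from one seed: the same seed yields byte-identical files.
"""

from __future__ import annotations

import json
import textwrap
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

CCDS_HEADER = (
    "#chromosome\tnc_accession\tgene\tgene_id\tccds_id\tccds_status\t"
    "cds_strand\tcds_from\tcds_to\tcds_locations\tmatch_type"
)

_DECOY_STATUSES = ("Withdrawn", "Public, under review", "Reviewed, update pending")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom_name: str = "1"
    chrom_length: int = 200_000
    gc_fraction: float = 0.41
    repeat_density: float = 0.2
    repeat_mean_length: int = 300
    n_genes: int = 8
    transcripts_per_gene: tuple[int, int] = (1, 3)  # inclusive range
    exons_per_transcript: tuple[int, int] = (3, 7)
    exon_length_log_mean: float = 4.8  # exp(4.8) ~ 120 b median
    exon_length_log_sigma: float = 0.6
    exon_length_bounds: tuple[int, int] = (30, 800)
    intron_length: tuple[int, int] = (300, 2500)
    p_shared: float = 0.7  # per-exon fate in an alternative transcript
    p_overlap: float = 0.2  # boundary-shifted, overlapping variant exon
    frac_non_public: float = 0.15  # decoy records per gene

    def __post_init__(self) -> None:
        for frac in (
            self.gc_fraction,
            self.repeat_density,
            self.p_shared,
            self.p_overlap,
            self.frac_non_public,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0,1]")
        if self.p_shared + self.p_overlap > 1:
            raise ValueError("p_shared + p_overlap must be <= 1")


@dataclass
class SimResult:
    fasta_path: Path
    table_path: Path
    truth_path: Path
    truth: dict


# ---------------------------------------------------------------------------


def _draw_exon_chain(rng: np.random.Generator, cfg: SimConfig, cursor: int):
    n_exons = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
    exons = []
    pos = cursor
    for _ in range(n_exons):
        length = int(
            np.clip(
                rng.lognormal(cfg.exon_length_log_mean, cfg.exon_length_log_sigma),
                *cfg.exon_length_bounds,
            )
        )
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(*cfg.intron_length))
    return exons


def _variant_exons(
    rng: np.random.Generator, cfg: SimConfig, canonical: list[tuple[int, int]]
):
    """An alternative transcript: exons kept, boundary-shifted or dropped."""
    out = []
    for i, (start, end) in enumerate(canonical):
        r = rng.random()
        if r < cfg.p_shared or len(canonical) == 1:
            out.append((start, end))
        elif r < cfg.p_shared + cfg.p_overlap:
            prev_end = canonical[i - 1][1] if i else -(10**9)
            next_start = canonical[i + 1][0] if i + 1 < len(canonical) else 10**9
            max_left = min(30, start - prev_end - 1, start)
            max_right = min(30, next_start - end - 1)
            d_start = int(rng.integers(0, max(max_left, 0) + 1))
            d_end = int(rng.integers(0, max(max_right, 0) + 1))
            if d_start == 0 and d_end == 0:
                d_end = min(1, max(max_right, 0))
            out.append((start - d_start, end + d_end))
        # else: dropped in this variant
    if not out:  # a transcript needs at least one exon
        out.append(canonical[0])
    return out


def _merge_intervals(intervals):
    merged = []
    for start, end in sorted(intervals):
        if merged and start < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


def _ccds_row(cfg, symbol, gene_id, ccds_id, status, exons):
    locations = "[" + ", ".join(f"{s}-{e - 1}" for s, e in exons) + "]"
    return "\t".join(
        [
            cfg.chrom_name,
            "NC_SYN.1",
            symbol,
            str(gene_id),
            ccds_id,
            status,
            "+",
            str(exons[0][0]),
            str(exons[-1][1] - 1),
            locations,
            "Identical",
        ]
    )


def simulate(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Emit {FASTA, CCDS-style table, truth JSON} for the configured genome."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # -- annotation -------------------------------------------------------
    rows: list[str] = []
    truth_genes: dict[str, dict] = {}
    cursor = 4000
    ccds_counter = 1
    for g in range(config.n_genes):
        gene_id = 1000 + g
        symbol = f"SYN{g + 1}"
        canonical = _draw_exon_chain(rng, config, cursor)
        if canonical[-1][1] + 4000 > config.chrom_length:
            raise ValueError(
                f"infeasible config: gene {symbol} exceeds the chromosome "
                f"({canonical[-1][1] + 4000} > {config.chrom_length})"
            )
        n_tx = int(
            rng.integers(
                config.transcripts_per_gene[0], config.transcripts_per_gene[1] + 1
            )
        )
        tx_exons = [canonical] + [
            _variant_exons(rng, config, canonical) for _ in range(n_tx - 1)
        ]
        transcripts = {}
        for exons in tx_exons:
            ccds_id = f"CCDS{ccds_counter}.1"
            ccds_counter += 1
            rows.append(_ccds_row(config, symbol, gene_id, ccds_id, "Public", exons))
            transcripts[ccds_id] = [list(iv) for iv in exons]
        if rng.random() < config.frac_non_public:
            status = _DECOY_STATUSES[int(rng.integers(len(_DECOY_STATUSES)))]
            rows.append(
                _ccds_row(
                    config, symbol, gene_id, f"CCDS{ccds_counter}.1", status, canonical
                )
            )
            ccds_counter += 1

        # ground truth, computed independently of the parser
        occur: dict[tuple[int, int], set[str]] = {}
        for ccds_id, exons in transcripts.items():
            for s, e in exons:
                occur.setdefault((s, e), set()).add(ccds_id)
        unique = sorted(occur)
        projections = _merge_intervals(unique)
        eligible = [
            [s, e]
            for (s, e) in unique
            if len(occur[(s, e)]) == n_tx and (e - s) % 3 != 0
        ]
        truth_genes[str(gene_id)] = {
            "symbol": symbol,
            "chrom": config.chrom_name,
            "n_transcripts": n_tx,
            "transcripts": transcripts,
            "unique_exons": [
                [s, e, sorted(occur[(s, e)])] for (s, e) in unique
            ],
            "projections": [list(iv) for iv in projections],
            "ko_eligible": eligible,
        }
        cursor = canonical[-1][1] + int(rng.integers(3000, 8000))

    # -- sequence ---------------------------------------------------------
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.chrom_length, p=probs)
    mask = np.zeros(config.chrom_length, dtype=bool)
    target = config.repeat_density * config.chrom_length
    while mask.sum() < target:
        start = int(rng.integers(0, config.chrom_length))
        length = 1 + int(rng.geometric(1.0 / config.repeat_mean_length))
        mask[start : start + length] = True
    seq = bases.copy()
    seq[mask] += 32  # lowercase the repeat tracts
    sequence = seq.tobytes().decode("ascii")

    tracts = _mask_to_intervals(mask)
    truth = {
        "config": asdict(config),
        "chrom": config.chrom_name,
        "chrom_length": config.chrom_length,
        "realized_repeat_fraction": float(mask.mean()),
        "repeat_tracts": tracts,
        "genes": truth_genes,
    }

    fasta_path = out_dir / "genome.fa"
    table_path = out_dir / "annotation.txt"
    truth_path = out_dir / "truth.json"
    _write_fasta(fasta_path, config.chrom_name, sequence)
    table_path.write_text("\n".join([CCDS_HEADER] + rows) + "\n")
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return SimResult(fasta_path, table_path, truth_path, truth)


def _mask_to_intervals(mask: np.ndarray) -> list[list[int]]:
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if mask.size and mask[0]:
        starts.insert(0, 0)
    if mask.size and mask[-1]:
        ends.append(mask.size)
    return [[int(s), int(e)] for s, e in zip(starts, ends)]


def _write_fasta(path: Path, name: str, sequence: str) -> None:
    body = "\n".join(textwrap.wrap(sequence, 60)) if sequence else ""
    path.write_text(f">{name}\n{body}\n")
    for suffix in (".fai",):  # stale indexes poison pyfaidx
        idx = path.with_suffix(path.suffix + suffix)
        if idx.exists():
            idx.unlink()


# ---------------------------------------------------------------------------

MICRO_FIXTURES = ("one-gene-knockin", "ko-eligible", "all-masked")


@dataclass
class MicroFixture:
    name: str
    fasta_path: Path
    table_path: Path
    expected: dict


def micro_fixture(name: str, out_dir: str | Path) -> MicroFixture:
    """Hand-constructed <=20 kb instances with fully known expectations.

    ``one-gene-knockin`` — one two-transcript gene on an unmasked 20 kb
    chromosome; the 100 b shared target exon sits mid-chromosome with the
    only other exon far outside its design window, so knock-in designs are
    checkable against brute-force enumeration.  ``ko-eligible`` — exon
    lengths constructed so that exactly one exon passes the all-transcripts
    and mod-3 rules.  ``all-masked`` — a fully soft-masked chromosome on
    which the pipeline must yield zero arms.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(777)
    length = 20_000
    bases = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=[0.25] * 4
    )
    sequence = bases.tobytes().decode("ascii")
    fasta_path = out_dir / f"{name}.fa"
    table_path = out_dir / f"{name}.txt"

    if name == "one-gene-knockin":
        cfg = SimConfig(chrom_name="1")
        exon_a = (9000, 9100)  # target: shared, length 100 (KO-eligible too)
        exon_b = (2000, 2090)
        rows = [
            _ccds_row(cfg, "MICRO1", 1, "CCDS1.1", "Public", [exon_b, exon_a]),
            _ccds_row(cfg, "MICRO1", 1, "CCDS2.1", "Public", [exon_a]),
        ]
        expected = {
            "gene_id": 1,
            "target_exon": list(exon_a),
            "other_exons": [list(exon_b)],
            "unique_exons": [list(exon_b), list(exon_a)],
            "projections": [list(exon_b), list(exon_a)],
            "ko_eligible": [list(exon_a)],
        }
    elif name == "ko-eligible":
        cfg = SimConfig(chrom_name="1")
        shared_eligible = (5000, 5100)  # in both transcripts, 100 % 3 != 0
        shared_in_frame = (8000, 8099)  # in both transcripts, 99 % 3 == 0
        private = (11_000, 11_100)  # length 100 but only in one transcript
        rows = [
            _ccds_row(
                cfg,
                "MICRO2",
                2,
                "CCDS3.1",
                "Public",
                [shared_eligible, shared_in_frame, private],
            ),
            _ccds_row(
                cfg, "MICRO2", 2, "CCDS4.1", "Public", [shared_eligible, shared_in_frame]
            ),
        ]
        expected = {
            "gene_id": 2,
            "ko_eligible": [list(shared_eligible)],
            "ineligible": [list(shared_in_frame), list(private)],
        }
    elif name == "all-masked":
        cfg = SimConfig(chrom_name="1")
        sequence = sequence.lower()
        exon = (9000, 9100)
        rows = [_ccds_row(cfg, "MICRO3", 3, "CCDS5.1", "Public", [exon])]
        expected = {"gene_id": 3, "target_exon": list(exon)}
    else:
        raise ValueError(f"unknown micro fixture {name!r}; choose from {MICRO_FIXTURES}")

    _write_fasta(fasta_path, "1", sequence)
    table_path.write_text("\n".join([CCDS_HEADER] + rows) + "\n")
    return MicroFixture(name, fasta_path, table_path, expected)
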