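"""Gene models from CCDS-style annotation.

Parses the tab-separated CCDS dialect (``CCDS.20131129.txt``-style), keeps
status-"Public" transcripts with a GeneID, and derives the two per-gene exon
databases the downstream designers run on:

* **unique exons** — exons of one gene sharing identical genomic coordinates
  across transcript variants are compressed to a single record that remembers
  every contributing CCDS accession;
* **exon projections** — transitively overlapping unique exons merged to their
  outermost coordinates, the unit of knock-in design (editing a projection
  cannot disturb a splice junction of any transcript variant).

All coordinates are held internally as 0-based half-open intervals.  The CCDS
``cds_locations`` field is read as 0-based with inclusive end (length =
to - from + 1), the convention of the real release files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "#chromosome",
    "gene",
    "gene_id",
    "ccds_id",
    "ccds_status",
    "cds_strand",
    "cds_from",
    "cds_to",
    "cds_locations",
)

_LOCATION_RE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")


@dataclass(frozen=True)
class Transcript:
    """One Public CCDS transcript: an ordered chain of coding exon intervals."""

    ccds_id: str
    gene_id: int
    gene_symbol: str
    chrom: str
    strand: str
    status: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted by start

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if start < prev_end:
                raise ValueError(
                    f"{self.ccds_id}: exons overlap or are unsorted at {start}"
                )
            if end <= start:
                raise ValueError(f"{self.ccds_id}: empty exon [{start},{end})")
            prev_end = end


@dataclass(frozen=True)
class UniqueExon:
    """An exon coordinate shared by one or more transcripts of a gene."""

    gene_id: int
    chrom: str
    start: int
    end: int
    ccds_ids: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ExonProjection:
    """Outermost boundaries of a set of transitively overlapping unique exons."""

    gene_id: int
    chrom: str
    start: int
    end: int
    members: tuple[UniqueExon, ...]
    commonality: int  # transcripts of the gene containing >=1 member exon

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


class GeneModelSet:
    """Public transcripts plus the per-gene unique-exon and projection stores."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: list[Transcript] = list(transcripts)
        self._by_gene: dict[int, list[Transcript]] = {}
        for tx in self.transcripts:
            self._by_gene.setdefault(tx.gene_id, []).append(tx)
        self._unique_cache: dict[int, list[UniqueExon]] = {}
        self._projection_cache: dict[int, list[ExonProjection]] = {}

    # -- totals -----------------------------------------------------------
    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def n_genes(self) -> int:
        return len(self._by_gene)

    @property
    def n_exons(self) -> int:
        """Raw exon occurrences summed over all Public transcripts."""
        return sum(len(tx.exons) for tx in self.transcripts)

    def gene_ids(self) -> list[int]:
        return sorted(self._by_gene)

    def transcripts_of(self, gene_id: int) -> list[Transcript]:
        self._require(gene_id)
        return list(self._by_gene[gene_id])

    def transcript_count(self, gene_id: int) -> int:
        self._require(gene_id)
        return len(self._by_gene[gene_id])

    def _require(self, gene_id: int) -> None:
        if gene_id not in self._by_gene:
            raise KeyError(f"unknown gene_id {gene_id}")

    # -- derived stores ---------------------------------------------------
    def unique_exons(self, gene_id: int) -> list[UniqueExon]:
        self._require(gene_id)
        if gene_id not in self._unique_cache:
            self._unique_cache[gene_id] = _compress(self._by_gene[gene_id])
        return list(self._unique_cache[gene_id])

    def projections(self, gene_id: int) -> list[ExonProjection]:
        self._require(gene_id)
        if gene_id not in self._projection_cache:
            self._projection_cache[gene_id] = _project(
                gene_id, self.unique_exons(gene_id), self._by_gene[gene_id]
            )
        return list(self._projection_cache[gene_id])

    def n_unique_exons(self) -> int:
        return sum(len(self.unique_exons(g)) for g in self._by_gene)

    def n_projections(self) -> int:
        """Count of exon-projection records (singleton projections included)."""
        return sum(len(self.projections(g)) for g in self._by_gene)

    def projection_lengths(self) -> list[int]:
        return [p.length for g in self._by_gene for p in self.projections(g)]


# ---------------------------------------------------------------------------


def _compress(transcripts: list[Transcript]) -> list[UniqueExon]:
    seen: dict[tuple[str, int, int], set[str]] = {}
    for tx in transcripts:
        for start, end in tx.exons:
            seen.setdefault((tx.chrom, start, end), set()).add(tx.ccds_id)
    gene_id = transcripts[0].gene_id
    out = [
        UniqueExon(gene_id, chrom, start, end, frozenset(ids))
        for (chrom, start, end), ids in seen.items()
    ]
    out.sort(key=lambda e: (e.chrom, e.start, e.end))
    return out


def _project(
    gene_id: int, exons: list[UniqueExon], transcripts: list[Transcript]
) -> list[ExonProjection]:
    out: list[ExonProjection] = []
    for chrom in sorted({e.chrom for e in exons}):
        group = [e for e in exons if e.chrom == chrom]  # sorted by start
        block: list[UniqueExon] = []
        block_end = -1
        for exon in group + [None]:  # type: ignore[list-item]
            if exon is not None and (not block or exon.start < block_end):
                block.append(exon)
                block_end = max(block_end, exon.end)
                continue
            if block:
                member_ids = frozenset().union(*(m.ccds_ids for m in block))
                commonality = sum(
                    1 for tx in transcripts if tx.ccds_id in member_ids
                )
                out.append(
                    ExonProjection(
                        gene_id,
                        chrom,
                        min(m.start for m in block),
                        block_end,
                        tuple(block),
                        commonality,
                    )
                )
            if exon is not None:
                block = [exon]
                block_end = exon.end
    return out


def compress_exons(gene_models: GeneModelSet, gene_id: int) -> list[UniqueExon]:
    """Merge coordinate-identical exons of one gene across its transcripts."""
    return gene_models.unique_exons(gene_id)


def project_exons(gene_models: GeneModelSet, gene_id: int) -> list[ExonProjection]:
    """Merge transitively overlapping unique exons to their outermost bounds."""
    return gene_models.projections(gene_id)


def knockout_eligible_exons(
    gene_models: GeneModelSet, gene_id: int
) -> list[UniqueExon]:
    """Exons present in every transcript variant with length not divisible by 3.

    Presence in all variants rules out rescue by exon skipping; a length not
    divisible by 3 guarantees that excision shifts the reading frame.  For a
    single-transcript gene every exon is trivially present in all variants.
    Decidable from the annotation alone — no genome sequence is touched.
    """
    n_tx = gene_models.transcript_count(gene_id)
    return [
        e
        for e in gene_models.unique_exons(gene_id)
        if len(e.ccds_ids) == n_tx and e.length % 3 != 0
    ]


# ---------------------------------------------------------------------------


def _parse_locations(raw: str, line_no: int) -> tuple[tuple[int, int], ...]:
    body = raw.strip()
    if not (body.startswith("[") and body.endswith("]")):
        raise ValueError(f"line {line_no}: malformed cds_locations {raw!r}")
    intervals = []
    for part in body[1:-1].split(","):
        m = _LOCATION_RE.match(part)
        if not m:
            raise ValueError(f"line {line_no}: malformed interval {part!r}")
        start, to = int(m.group(1)), int(m.group(2))
        if to < start:
            raise ValueError(f"line {line_no}: inverted interval {part!r}")
        intervals.append((start, to + 1))  # inclusive end -> half-open
    intervals.sort()
    return tuple(intervals)


def parse_ccds(table_path: str | Path) -> GeneModelSet:
    """Parse a CCDS-dialect table into a :class:`GeneModelSet`.

    Keeps only records whose ``ccds_status`` is exactly ``Public`` and which
    carry an integer GeneID; withdrawn, under-review and putative records are
    dropped.  Records with a ``-`` location field or non-integer GeneID are
    skipped with a warning; a kept record with unparsable locations raises
    naming the offending line.
    """
    table_path = Path(table_path)
    df = pd.read_csv(
        table_path, sep="\t", dtype=str, keep_default_na=False, comment=None
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{table_path}: missing required column(s) {missing}")

    transcripts: list[Transcript] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        rec = dict(zip(df.columns, row))
        if rec["ccds_status"] != "Public":
            continue
        gene_id_raw = rec["gene_id"].strip()
        if not gene_id_raw.isdigit():
            log.warning("line %d: no integer GeneID, skipped", line_no)
            continue
        if rec["cds_locations"].strip() == "-":
            log.warning("line %d: no cds_locations, skipped", line_no)
            continue
        exons = _parse_locations(rec["cds_locations"], line_no)
        try:
            transcripts.append(
                Transcript(
                    ccds_id=rec["ccds_id"],
                    gene_id=int(gene_id_raw),
                    gene_symbol=rec["gene"],
                    chrom=rec["#chromosome"],
                    strand=rec["cds_strand"],
                    status=rec["ccds_status"],
                    exons=exons,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {line_no}: {exc}") from exc
    return GeneModelSet(transcripts)


def projections_to_bed(gene_models: GeneModelSet, path: str | Path) -> None:
    """Write every exon projection as a BED6 record (0-based half-open)."""
    lines = []
    for gene_id in gene_models.gene_ids():
        for i, p in enumerate(gene_models.projections(gene_id)):
            name = f"gene{gene_id}|proj{i}|common{p.commonality}"
            lines.append(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t.")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
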