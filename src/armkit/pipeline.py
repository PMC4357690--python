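"""Per-gene orchestration: regions -> arm database -> scenario designs.

One arm store is built per gene over the target regions of its exon
projections (each projection plus 3 kb of flank, clipped at chromosome ends);
because every exon lies inside a projection, the same store serves both the
knock-in designer (which works on projections) and the knock-out designer
(which works on the uncompressed exons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .arm_factory import ArmStore, DesignParams, build_arm_database
from .engine import PrimerEngine, ThermoEngine
from .gene_models import GeneModelSet, knockout_eligible_exons
from .knockin import KnockinScenario, design_knockin
from .knockout import (
    KnockoutScenario,
    complementary_knockin,
    design_partial_deletion,
    design_whole_exon,
)
from .sequence_store import SequenceStore, TargetRegion


@dataclass
class GeneDesign:
    gene_id: int
    arm_store: ArmStore
    knockin: list[KnockinScenario] = field(default_factory=list)
    knockout: list[KnockoutScenario] = field(default_factory=list)
    #: per eligible exon interval: knock-in scenarios usable for stop-codon KO
    complementary: dict[tuple[int, int], list[KnockinScenario]] = field(
        default_factory=dict
    )

    @property
    def no_suitable_primer_pairs(self) -> bool:
        return self.arm_store.is_empty


def gene_regions(
    gene_models: GeneModelSet,
    sequences: SequenceStore,
    gene_id: int,
    params: DesignParams,
) -> list[TargetRegion]:
    """Target regions (projection +/- flank) for one gene."""
    return [
        sequences.target_region(p.chrom, p.start, p.end, params.flank_size)
        for p in gene_models.projections(gene_id)
    ]


def build_gene_arm_store(
    gene_models: GeneModelSet,
    sequences: SequenceStore,
    gene_id: int,
    params: DesignParams,
    engine: PrimerEngine | None = None,
) -> ArmStore:
    engine = engine if engine is not None else ThermoEngine(params.primer_len)
    regions = gene_regions(gene_models, sequences, gene_id, params)
    return build_arm_database(gene_id, regions, params, engine)


def design_gene(
    gene_models: GeneModelSet,
    sequences: SequenceStore,
    gene_id: int,
    params: DesignParams | None = None,
    engine: PrimerEngine | None = None,
    arm_store: ArmStore | None = None,
) -> GeneDesign:
    """Full knock-in + knock-out design for one gene."""
    params = params or DesignParams()
    if arm_store is None:
        arm_store = build_gene_arm_store(
            gene_models, sequences, gene_id, params, engine
        )
    design = GeneDesign(gene_id, arm_store)
    if arm_store.is_empty:
        return design

    unique = gene_models.unique_exons(gene_id)
    for projection in gene_models.projections(gene_id):
        other = [
            e.interval
            for e in unique
            if e.chrom == projection.chrom
            and not (e.start >= projection.start and e.end <= projection.end)
        ]
        design.knockin.extend(
            design_knockin(
                projection.interval,
                arm_store,
                other,
                params,
                gene_id=gene_id,
                chrom=projection.chrom,
            )
        )

    for exon in knockout_eligible_exons(gene_models, gene_id):
        design.knockout.extend(
            design_partial_deletion(exon, arm_store, gene_models, params)
        )
        design.knockout.extend(
            design_whole_exon(exon, arm_store, gene_models, params)
        )
        design.complementary[exon.interval] = complementary_knockin(
            exon, design.knockin
        )
    return design
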