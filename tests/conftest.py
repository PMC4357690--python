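from types import SimpleNamespace

import pytest

import armkit as ak
from armkit.pipeline import build_gene_arm_store


@pytest.fixture(scope="session")
def micro_ki(tmp_path_factory):
    """one-gene-knockin micro instance with a prebuilt arm store (npp=8)."""
    fx = ak.micro_fixture("one-gene-knockin", tmp_path_factory.mktemp("fx_ki"))
    gms = ak.parse_ccds(fx.table_path)
    seqs = ak.SequenceStore(fx.fasta_path)
    params = ak.DesignParams(npp=8)
    store = build_gene_arm_store(gms, seqs, fx.expected["gene_id"], params)
    return SimpleNamespace(
        fx=fx, gms=gms, seqs=seqs, params=params, store=store
    )


@pytest.fixture(scope="session")
def sim_instance(tmp_path_factory):
    """A seeded synthetic genome + annotation + truth for cross-module tests."""
    cfg = ak.SimConfig(seed=11, chrom_length=100_000, n_genes=4)
    res = ak.simulate(cfg, tmp_path_factory.mktemp("sim"))
    gms = ak.parse_ccds(res.table_path)
    seqs = ak.SequenceStore(res.fasta_path)
    return SimpleNamespace(cfg=cfg, res=res, gms=gms, seqs=seqs)
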