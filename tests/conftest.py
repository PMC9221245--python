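import pytest

from minisplice.acmg import RuleConfig
from minisplice.gene_model import (
    build_rad51c_fixture,
    rad51c_domain_table,
    rad51c_minigene_layout,
)
from minisplice.io import load_readout_table, load_variant_table
from minisplice.synthetic_data import SimulationConfig, simulate_gene


@pytest.fixture(scope="session")
def rad51c_model():
    return build_rad51c_fixture()


@pytest.fixture(scope="session")
def rad51c_layout():
    return rad51c_minigene_layout()


@pytest.fixture(scope="session")
def rad51c_domains():
    return rad51c_domain_table()


@pytest.fixture(scope="session")
def readout_df():
    return load_readout_table()


@pytest.fixture(scope="session")
def variant_df():
    return load_variant_table()


@pytest.fixture(scope="session")
def rules():
    return RuleConfig()


@pytest.fixture(scope="session")
def toy_model():
    """Deterministic 5-exon sequence-bearing model for consequence tests."""
    return simulate_gene(SimulationConfig(seed=11, n_exons=5))


def make_patched_model(exon_lengths, stop_codon_index=None, seed=7):
    """Synthetic model whose CDS has a stop engineered at a chosen codon
    (0-based), leaving every earlier codon stop-free by construction."""
    cfg = SimulationConfig(seed=seed, n_exons=len(exon_lengths), exon_lengths=exon_lengths)
    model = simulate_gene(cfg)
    if stop_codon_index is None:
        return model
    spliced = "".join(model.exon_sequences[e.index] for e in model.exons)
    i = stop_codon_index * 3
    patched = spliced[:i] + "TAA" + spliced[i + 3 :]
    seqs = {}
    for e in model.exons:
        seqs[e.index] = patched[e.c_start - 1 : e.c_end]
    model.attach_sequences(seqs, model.intron_flanks)
    return model
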