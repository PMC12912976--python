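import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from paleosynteny.io import GenomeAnnotation
from paleosynteny.simulate import SimulationConfig, simulate_clade


def make_annotation(species, chrom_genes, strands=None):
    """Annotation from {chrom: [gene ids]} with synthetic coordinates."""
    rows = []
    for chrom, genes in chrom_genes.items():
        for i, g in enumerate(genes):
            strand = strands.get(g, "+") if strands else "+"
            rows.append(dict(gene_id=g, chrom=chrom, start=(i + 1) * 100,
                             end=(i + 1) * 100 + 50, strand=strand))
    return GenomeAnnotation.from_genes(species, rows)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition clade shared across read-only tests."""
    return simulate_clade(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def lossfree_sim():
    """Loss-free, rearrangement-free outgroup + one descendant."""
    cfg = SimulationConfig(seed=5, retention_mean=1.0, rtg_fraction=0.0,
                           n_fissions=0, n_fusions=0, n_inversions=0,
                           n_translocations=0, n_species=2)
    return simulate_clade(cfg)


@pytest.fixture(scope="session")
def small_lossfree_sim():
    """Small loss-free clade for fast structural tests."""
    cfg = SimulationConfig(seed=9, n_chrom=2, genes_per_chrom=60,
                           retention_mean=1.0, rtg_fraction=0.0,
                           n_fissions=0, n_fusions=0, n_inversions=0,
                           n_translocations=0, n_species=3)
    return simulate_clade(cfg)
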