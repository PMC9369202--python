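import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mirffl import SimulationConfig, simulate_annotation, simulate_chip_experiment, \
    simulate_expression, simulate_promoters
from mirffl.expression import records_from_frame
from mirffl.ffl import network_from_tables


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=11, n_chroms=1, chrom_length=400_000,
                            n_genes=40, n_mirna_genes=6, n_bound_genes=10,
                            n_planted_c4=8, targets_per_mirna=4,
                            planted_loops_per_mirna=4,
                            n_noise_peaks_per_replicate=5)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    genes, truth = simulate_annotation(small_cfg)
    rep1, rep2 = simulate_chip_experiment(genes, truth, small_cfg)
    gene_de, mirna_de, target_map = simulate_expression(genes, truth, small_cfg)
    promoters = simulate_promoters(genes, truth, small_cfg)
    return {"cfg": small_cfg, "genes": genes, "truth": truth,
            "rep1": rep1, "rep2": rep2, "gene_de": gene_de,
            "mirna_de": mirna_de, "target_map": target_map,
            "promoters": promoters}


def build_network(seed: int, **overrides):
    """Default-condition network straight from the generators."""
    cfg = SimulationConfig(seed=seed, **overrides)
    genes, truth = simulate_annotation(cfg)
    gene_de, mirna_de, target_map = simulate_expression(genes, truth, cfg)
    net = network_from_tables(
        "TF1",
        records_from_frame(mirna_de, feature_class="mirna"),
        records_from_frame(gene_de),
        target_map,
    )
    return net, truth
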