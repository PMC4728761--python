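import numpy as np
import pytest

from asbscan.model import HetSNP
from asbscan.synthetic_data import (
    SimulationConfig,
    generate_reference,
    plant_het_snps,
    simulate_reads,
    write_sam,
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small error-free simulated dataset with its truth table and SAM."""
    seed = 11
    contig_length, n_sites, read_length = 50_000, 100, 36
    reference = generate_reference(contig_length, seed)
    snps = plant_het_snps(reference, n_sites, seed, read_length=read_length)
    rng = np.random.default_rng(seed)
    imbalance = {
        snps[i].snp_id: 0.85 for i in rng.choice(n_sites, size=10, replace=False)
    }
    config = SimulationConfig(
        contig_length=contig_length,
        n_het_snps=n_sites,
        read_length=read_length,
        mean_depth=30,
        error_rate=0.0,
        imbalance_map=imbalance,
        seed=seed,
    )
    reads, truth = simulate_reads(config, reference, snps)
    sam = tmp_path_factory.mktemp("small") / "reads.sam"
    write_sam(reads, sam, config.contig, contig_length)
    return {
        "config": config,
        "reference": reference,
        "snps": snps,
        "reads": reads,
        "truth": truth,
        "sam": str(sam),
    }


@pytest.fixture
def toy_snps():
    return [
        HetSNP("rs1", "chr1", 100, "A", "C"),
        HetSNP("rs2", "chr1", 500, "G", "T"),
        HetSNP("rs3", "chr2", 250, "C", "A"),
    ]
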