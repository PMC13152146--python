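import numpy as np
import pytest

from geotrace import GenotypeMatrix, SimulationConfig, simulate_clusters, simulate_ibd_landscape


def make_matrix(dosage, sample_ids=None, contig="chr1"):
    """Small GenotypeMatrix from a plain dosage array (one contig)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    ids = sample_ids or [f"S{i}" for i in range(n)]
    return GenotypeMatrix(
        dosage, ids, np.array([contig] * L), np.arange(1, L + 1) * 10
    )


@pytest.fixture
def two_cluster_dataset():
    """Moderately differentiated two-cluster dataset (fast to fit)."""
    cfg = SimulationConfig(seed=11, n_loci=400, drift_f=0.2)
    return simulate_clusters(cfg, [30, 30])


@pytest.fixture
def ibd_dataset():
    cfg = SimulationConfig(seed=7, n_loci=300, cline_strength=2.0)
    return simulate_ibd_landscape(cfg, 80)
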