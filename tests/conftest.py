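import numpy as np
import pytest

from sortscreen import SimConfig, make_truth, simulate_screen
from sortscreen.simulate import synthetic_manifest


@pytest.fixture
def toy_manifest(tmp_path):
    """3-row manifest TSV: 2 sgRNAs for gene A, 1 NTC."""
    path = tmp_path / "toy.tsv"
    path.write_text(
        "element_id\tgene\tprotospacer\tcategory\n"
        "A_sg0\tA\tACGTACGTACGTACGTACGT\ttargeting\n"
        "A_sg1\tA\tTTTTACGTACGTACGTACGT\ttargeting\n"
        "NTC_sg0\tNTC\tGGGGACGTACGTACGTACGT\tnon_targeting\n"
    )
    return path


@pytest.fixture(scope="session")
def small_manifest():
    """30 genes × 5 sgRNAs + 10 NTC, session-wide."""
    return synthetic_manifest(30, 5, 10, seed=7)


@pytest.fixture(scope="session")
def neutral_screen(small_manifest):
    """One all-neutral simulated screen on the small manifest."""
    cfg = SimConfig(seed=7, n_genes=30, sgrnas_per_gene=5, n_ntc=10)
    truth = make_truth(small_manifest, cfg)
    return simulate_screen(small_manifest, cfg, truth=truth), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
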