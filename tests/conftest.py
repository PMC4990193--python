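import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gbsimpute import io_vcf, synth_gbs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset() -> synth_gbs.SyntheticDataset:
    """A small but structured population: 30 founders, 15 crosses, 120 sites."""
    cfg = synth_gbs.breeding_program_preset(
        seed=11, n_founders=30, n_parents=12, n_crosses=15,
        offspring_per_cross=4, n_sites=120)
    return synth_gbs.generate_dataset(cfg)


@pytest.fixture
def tiny_adm() -> io_vcf.AlleleDepthMatrix:
    """2 sites x 3 samples with one zero-depth entry."""
    sites = [io_vcf.Site("1", 100, "A", "G"), io_vcf.Site("1", 250, "C", "T")]
    depths = np.array(
        [[[3, 5], [2, 0], [0, 0]],
         [[0, 7], [1, 1], [4, 4]]], dtype=np.int32)
    return io_vcf.AlleleDepthMatrix(sites=sites, samples=["a", "b", "c"],
                                    depths=depths)
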