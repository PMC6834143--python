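import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import polyadmix as pa

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def arch_h50():
    """Default h2=0.5 architecture (~930 loci)."""
    return pa.build_architecture(0.5, seed=20)


@pytest.fixture(scope="session")
def mapping_h50_k1pct(arch_h50):
    """Mapping for K=1% on the default architecture (400k calibration draws)."""
    sample = arch_h50.sample_prs(400_000, rng=np.random.default_rng(21))
    return pa.calibrate_mapping(sample, 0.01, reps=4, seed=22, arch=arch_h50)


@pytest.fixture()
def tiny_arch():
    """Hand-built 4-locus architecture for exact-value tests."""
    rr = np.array([1.1, 1.2, 1.05, 1.15])
    return pa.Architecture(
        locus_id=np.arange(4),
        position=np.array([0.1, 0.35, 0.6, 0.85]),
        rr=rr,
        effect=np.log(rr),
        freq=np.array([0.5, 0.2, 0.3, 0.4])[:, None],
        heritability_target=0.5,
        mean_rr=1.125,
    )
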