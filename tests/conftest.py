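import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protomer():
    """12-residue idealized helical protomer with a cysteine at position 6."""
    from cysdimer.synthetic_data import make_protomer

    return make_protomer(12, 6, seed=1)


@pytest.fixture(scope="session")
def aromatic_protomer():
    """Protomer decorated with Trp/Tyr for interface and quencher tests."""
    from cysdimer.synthetic_data import make_protomer

    return make_protomer(12, 6, seed=1, aromatics={3: "TRP", 9: "TYR"})


@pytest.fixture(scope="session")
def dimer85(protomer):
    """Synthetic two-chain dimer with a bridging cystine at chi3 = +85 deg."""
    from cysdimer.synthetic_data import make_disulfide_dimer

    return make_disulfide_dimer(protomer, 85.0, seed=2)


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Ten-dimer synthetic corpus with its truth sidecar."""
    from cysdimer.synthetic_data import make_library_corpus

    out = tmp_path_factory.mktemp("corpus")
    paths, sidecar = make_library_corpus(10, "bimodal", seed=3, out_dir=out)
    return paths, sidecar


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
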