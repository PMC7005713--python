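import numpy as np
import pytest

from dhpscan.simulate import SimulatedStructureSpec, build_structure
from dhpscan.structures import read_structure
from dhpscan.survey import load_manifest


@pytest.fixture(scope="session")
def manifest():
    return load_manifest()


@pytest.fixture()
def dimer_with_sulfate(tmp_path):
    """Two-chain fixture: gauche-/trans dimer, pH 7.5, sulfate 3.2 A from Ne2."""
    path = build_structure(
        SimulatedStructureSpec(
            chain_chi1=((-60.0,), (180.0,)),
            crystallization_ph=7.5,
            sulfate_distance=3.2,
        ),
        tmp_path / "dimer.pdb",
    )
    return read_structure(path)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
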