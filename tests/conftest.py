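import numpy as np
import pytest

from calsteer import synthetic
from calsteer.structure_io import StructureEnsemble


@pytest.fixture(scope="session")
def ideal_helix() -> StructureEnsemble:
    """12-residue poly-Ala alpha-helix with ideal backbone geometry."""
    return synthetic.build_helix(synthetic.HelixSpec(n_res=12))


@pytest.fixture(scope="session")
def helix20() -> StructureEnsemble:
    return synthetic.build_helix(synthetic.HelixSpec(n_res=20))


@pytest.fixture(scope="session")
def dimer() -> StructureEnsemble:
    """Two-helix complex: chains A (20 res) and B (16 res), 120 deg crossing."""
    return synthetic.build_two_helix(
        synthetic.HelixSpec(n_res=20), synthetic.HelixSpec(n_res=16),
        crossing_angle=120.0, separation=10.0)


@pytest.fixture()
def jittered_ensemble(dimer) -> StructureEnsemble:
    """Five-model ensemble: the dimer plus small Gaussian coordinate noise."""
    rng = np.random.default_rng(11)
    extra = dimer.coords + rng.normal(0, 0.2, size=(4,) + dimer.coords.shape[1:])
    return StructureEnsemble(
        atoms=list(dimer.atoms),
        coords=np.concatenate([dimer.coords, extra]),
        chain_map=dict(dimer.chain_map),
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR-based)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
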