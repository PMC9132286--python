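import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from flexiscreen import (AtomSelection, Ensemble, EnsembleSpec, build_toy_protein,
                         generate_ensemble)


@pytest.fixture(scope="session")
def helix12():
    return build_toy_protein(12, "helix")


@pytest.fixture(scope="session")
def small_gaussian_ensemble():
    """8-residue helix, σ = 0.3 Å per coordinate, 400 frames."""
    return generate_ensemble(EnsembleSpec(n_residues=8, n_frames=400,
                                          amplitude_profile=0.3, seed=11))


@pytest.fixture
def rigid_copies(helix12):
    """5 frames: rigid rotations + translations of one helix."""
    rng = np.random.default_rng(3)
    frames = [helix12.coords]
    from scipy.spatial.transform import Rotation
    for _ in range(4):
        rot = Rotation.random(rng=rng)
        frames.append(rot.apply(helix12.coords) + rng.uniform(-5, 5, 3))
    return Ensemble(helix12, np.stack(frames))


@pytest.fixture(scope="session")
def calpha():
    return AtomSelection("calpha")
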