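import numpy as np
import pytest

from spinrelax.decay import RelaxationRecord
from spinrelax.physics import (
    DiffusionTensor,
    FieldParameters,
    NHOrientation,
    ResidueDynamics,
    forward_rates,
)


@pytest.fixture(scope="session")
def field() -> FieldParameters:
    return FieldParameters()


@pytest.fixture(scope="session")
def apo_tensor() -> DiffusionTensor:
    return DiffusionTensor(
        tau_m=13.929e-9, anisotropy_ratio=1.190, axis_theta=1.0, axis_phi=0.5
    )


@pytest.fixture()
def orientation() -> NHOrientation:
    v = np.array([0.3, 0.4, np.sqrt(1 - 0.09 - 0.16)])
    return NHOrientation(1, v)


def record_from_dynamics(
    dyn: ResidueDynamics,
    tensor: DiffusionTensor,
    orient: NHOrientation | None,
    field: FieldParameters,
    frac: float = 0.01,
    rng: np.random.Generator | None = None,
) -> RelaxationRecord:
    """Noise-free (or Gaussian-perturbed) record from planted dynamics."""
    r1, r2, noe = forward_rates(dyn, tensor, orient, field)
    s1, s2, sn = frac * r1, frac * r2, frac
    if rng is not None:
        r1, r2, noe = rng.normal(r1, s1), rng.normal(r2, s2), rng.normal(noe, sn)
    return RelaxationRecord(dyn.residue_id, r1, s1, r2, s2, noe, sn)


def uniform_orientations(n: int, seed: int) -> dict[int, NHOrientation]:
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return {i + 1: NHOrientation(i + 1, v[i]) for i in range(n)}
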