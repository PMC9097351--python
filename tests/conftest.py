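import numpy as np
import pytest

from synscreen import DoseMatrix, SurfaceSpec, simulate_matrix


@pytest.fixture
def noiseless_plate():
    """One noiseless Bliss-null 6x6 plate with its truth objects."""
    return simulate_matrix(SurfaceSpec(noise_sigma=0.0, seed=7))


@pytest.fixture
def synergistic_plate():
    """Noiseless 6x6 plate with a +0.15 inhibition offset on combo wells."""
    return simulate_matrix(SurfaceSpec(noise_sigma=0.0, bliss_offset=0.15, seed=7))


def matrix_from_grid(viability, doses_a=None, doses_b=None, **kw) -> DoseMatrix:
    """Build a DoseMatrix from a raw viability grid with placeholder doses."""
    viability = np.asarray(viability, dtype=float)
    na, nb = viability.shape
    if doses_a is None:
        doses_a = np.arange(na, dtype=float)
    if doses_b is None:
        doses_b = np.arange(nb, dtype=float)
    kw.setdefault("compound_a", "A")
    kw.setdefault("compound_b", "B")
    return DoseMatrix(doses_a=doses_a, doses_b=doses_b, viability=viability, **kw)
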