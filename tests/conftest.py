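import numpy as np
import pytest

from pcfdc import TemplateGrid, default_study, make_lesion


@pytest.fixture(scope="session")
def grid8() -> TemplateGrid:
    return TemplateGrid.isotropic((8, 8, 8), 2.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced-size study cohort shared across tests."""
    return default_study(rng_seed=3, n_subjects=10, n_timepoints=100)


@pytest.fixture(scope="session")
def small_lesion(small_cohort):
    return make_lesion(
        small_cohort.grid,
        small_cohort.tissue,
        small_cohort.atlas[0],
        n_gm_voxels=10,
        n_wm_voxels=10,
        rng_seed=11,
    )


def correlated_vectors(corrs, length=16, rng_seed=0):
    """Centred unit-variance vectors whose correlations with the first
    returned vector equal ``corrs`` exactly (Gram-Schmidt construction)."""
    rng = np.random.default_rng(rng_seed)
    raw = rng.normal(size=(len(corrs) + 1, length))
    raw -= raw.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(raw.T)
    basis = q.T  # orthonormal; spans centred vectors, hence centred
    base = basis[0]
    out = [base]
    for i, r in enumerate(corrs):
        out.append(r * base + np.sqrt(1 - r**2) * basis[i + 1])
    return out
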