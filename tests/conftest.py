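import numpy as np
import pytest

from oxyradiomics.radiomics.discretize import DiscretizedVOI


def voi_from_labels(labels, n_bins=None, spacing=(1.0, 1.0, 1.0)):
    """Wrap an integer label volume (0 = outside VOI) as a DiscretizedVOI.

    Raw values are taken equal to the bin labels, which makes hand
    verification of first-order/texture interplay straightforward.
    """
    labels = np.asarray(labels, dtype=np.int64)
    mask = labels > 0
    if n_bins is None:
        n_bins = int(labels.max())
    return DiscretizedVOI(labels=labels, voi_mask=mask,
                          raw_values=labels[mask].astype(np.float64),
                          voxel_spacing=spacing, n_bins=int(n_bins))


@pytest.fixture(scope="session")
def oracle_fixtures():
    """Deterministic small label volumes used for brute-force verification."""
    from oxyradiomics.pipeline import make_fixtures
    vols = make_fixtures(seed=11)
    rng = np.random.default_rng(23)
    vols["random_3x3x3"] = rng.integers(1, 4, size=(3, 3, 3))
    vols["random_4x4x4_masked"] = rng.integers(1, 6, size=(4, 4, 4))
    vols["random_4x4x4_masked"][1:4:2, 1, 1] = 0   # irregular VOI with gaps
    return vols
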