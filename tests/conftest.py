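import numpy as np
import pytest

from catomo.granule_detect import Granule, GranuleCatalog


def make_catalog(centroids, diameters=None):
    """Catalog from bare centroids (μm); morphometry filled consistently."""
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if diameters is None:
        diameters = np.full(len(centroids), 15.0)
    granules = []
    for i, (c, d) in enumerate(zip(centroids, diameters), start=1):
        v = np.pi / 6.0 * d**3
        s = np.pi * d**2
        granules.append(
            Granule(
                id=i,
                centroid=tuple(c),
                voxel_count=0,
                volume_um3=v,
                surface_um2=s,
                sphericity=1.0,
                diameter_um=float(d),
            )
        )
    return GranuleCatalog(granules=granules)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
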