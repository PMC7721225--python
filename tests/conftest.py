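import numpy as np
import pandas as pd
import pytest

from gaitpls import CohortSpec, Parcellation, ThicknessMatrix, generate_cohort


@pytest.fixture(scope="session")
def canonical_parcellation():
    return Parcellation.canonical()


@pytest.fixture()
def toy_parcellation():
    """Three tiny networks (2 + 3 + 1 ROIs) with non-contiguous roi ids."""
    table = pd.DataFrame(
        {
            "roi_id": [5, 2, 9, 1, 7, 4],
            "network": ["A", "A", "B", "B", "B", "Unassigned"],
            "vertex_count": [10, 20, 5, 5, 5, 3],
        }
    )
    return Parcellation(table)


@pytest.fixture()
def toy_thickness(toy_parcellation):
    rng = np.random.default_rng(11)
    values = rng.uniform(2.0, 3.0, size=(4, 6))
    return ThicknessMatrix(
        ["s1", "s2", "s3", "s4"], np.sort(toy_parcellation.roi_ids), values
    )


@pytest.fixture(scope="session")
def default_cohort(canonical_parcellation):
    """One generated cohort at the default study-scale conditions."""
    return generate_cohort(CohortSpec(seed=123), canonical_parcellation)
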