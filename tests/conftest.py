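import numpy as np
import pandas as pd
import pytest

from igg_orient.spectra_io import PeakTable


def make_table(
    intensities,
    peaks=None,
    sample_ids=None,
    groups=None,
    substrate="APTES",
    normalized=False,
):
    """Build a small PeakTable with defaulted metadata."""
    intensities = np.asarray(intensities, dtype=float)
    n, p = intensities.shape
    peaks = peaks or [f"P{j}+" for j in range(p)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    groups = groups or ["igg"] * n
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "group": groups, "substrate": [substrate] * n}
    )
    return PeakTable(meta=meta, peaks=list(peaks), intensities=intensities,
                     normalized=normalized)


@pytest.fixture
def toy_table():
    return make_table([[2.0, 3.0, 5.0], [1.0, 1.0, 2.0], [4.0, 0.0, 6.0]])
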