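import numpy as np
import pandas as pd
import pytest

from lcmproteo import IntensityMatrix, SampleMetadata


@pytest.fixture
def small_metadata() -> SampleMetadata:
    """Three kidneys, Glom + PT each, one batch."""
    rows = []
    for k in range(1, 4):
        for comp in ("Glom", "PT"):
            rows.append(
                dict(sample_id=f"K{k}_{comp}", kidney_id=f"K{k}", compartment=comp,
                     batch="B1", preservation="OCT")
            )
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture
def small_matrix(small_metadata) -> IntensityMatrix:
    """4 proteins x 6 samples; P3 missing everywhere in PT, P4 sparse."""
    sample_ids = small_metadata.sample_ids  # K1_Glom, K1_PT, K2_Glom, ...
    values = np.array(
        [
            [23.0, 22.5, 23.2, 22.8, 22.9, 23.1],   # fully observed
            [24.0, 23.0, 24.2, 23.1, 24.1, 23.2],   # fully observed, Glom-leaning
            [25.0, np.nan, 25.3, np.nan, 24.8, np.nan],  # absent in PT
            [np.nan, np.nan, np.nan, np.nan, 21.0, np.nan],  # observed once
        ]
    )
    mask = ~np.isfinite(values)
    return IntensityMatrix(values, mask, ["P1", "P2", "P3", "P4"], sample_ids)
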