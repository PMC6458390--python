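import numpy as np
import pytest

# Reported group means at 7/11/15/21 days after germination: basal
# secondary-xylem area, cell count, and longitudinal extension.
TIMES = np.array([7.0, 11.0, 15.0, 21.0])
AREA_UM2 = np.array([1519.56, 9881.08, 89373.70, 352557.62])
CELLS = np.array([3.0, 8.92, 64.19, 231.57])
EXT_CM = np.array([0.2805, 1.975, 4.175, 8.06])


@pytest.fixture
def times():
    return TIMES.copy()


@pytest.fixture
def printed_means():
    return {"area_um2": AREA_UM2.copy(), "cells": CELLS.copy(),
            "extension_cm": EXT_CM.copy()}


@pytest.fixture
def printed_means_table():
    """Measurement table holding the group means, one replicate per day."""
    import pandas as pd

    return pd.DataFrame({
        "dag": TIMES,
        "replicate": 0,
        "area_mm2": AREA_UM2 / 1e6,
        "cell_count": CELLS,
        "extension_mm": EXT_CM * 10.0,
    })
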