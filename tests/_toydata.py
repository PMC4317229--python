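"""Hand-built toy datasets shared across test modules."""

import numpy as np
import pandas as pd

from tmddpk.synthetic import DATASET_COLUMNS, StudyDataset


def toy_exclusion_dataset(n: int = 1743, n_excl: int = 120) -> StudyDataset:
    """n observation rows; the first 200 are ADA-positive and the first
    n_excl of those deviate more than 3-fold below expectation."""
    dv = np.full(n, 10.0)
    expected = np.full(n, 10.0)
    ada = np.zeros(n, dtype=int)
    ada[:200] = 1
    dv[:n_excl] = 1.0
    tab = pd.DataFrame(
        {
            "ID": np.arange(n), "TIME": np.arange(n, dtype=float),
            "AMT": np.nan, "DV": dv, "EVID": 0, "MDV": 0, "ROUTE": "IV",
            "BW": 2.8, "STUDY": "T", "GROUP": 0, "DOSE_MGKG": 1.0,
            "LLOQ": 1e-9, "BLQ": 0, "ADA": ada, "EXCL": 0,
            "EXPECTED": expected,
        },
        columns=DATASET_COLUMNS,
    )
    return StudyDataset(tab)
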