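import numpy as np
import pandas as pd
import pytest

import ccsvsim as c

TREATMENTS = ("IPPV_first", "CCSV_A", "CCSV_B", "CCSV_C", "IPPV_last")

# Reference median levels (12-animal swine CPR cross-over magnitudes) used
# by the synthetic per-animal tables below.
PAO2_MEDIANS = dict(zip(TREATMENTS, (19.6, 48.9, 54.0, 46.0, 22.7)))  # kPa
MAP_MEDIANS = dict(zip(TREATMENTS, (42.5, 40.1, 39.2, 37.0, 22.4)))  # mmHg


@pytest.fixture
def lung():
    return c.LungParams()


@pytest.fixture
def compression():
    return c.CompressionProfile()


@pytest.fixture
def ippv():
    return c.IPPVSettings()


def _column(median: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    """12 per-animal values whose sample median is exactly ``median``.

    Symmetric offsets around zero (6th and 7th order statistics at -1 and +1
    scale units) guarantee the n=12 linear-interpolation median equals the
    target; the column is then shuffled.
    """
    offsets = np.array([-6, -5, -4, -3, -2, -1, 1, 2, 3, 4, 5, 6], dtype=float)
    values = median + scale * offsets
    return rng.permutation(values)


def make_s1_like_table(seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for a per-animal period spreadsheet (long form).

    Purely synthetic: per-animal values are constructed so each treatment
    column's median equals the reference median for that variable exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for variable, medians, scale in (
        ("PaO2", PAO2_MEDIANS, 2.0),
        ("MAP", MAP_MEDIANS, 1.5),
    ):
        for treatment, med in medians.items():
            col = _column(med, scale, rng)
            for animal, value in enumerate(col, start=1):
                rows.append(
                    {
                        "subject": f"animal{animal:02d}",
                        "treatment": treatment,
                        "variable": variable,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def s1_like_table():
    return make_s1_like_table()
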