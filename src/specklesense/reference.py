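"""Reference blood-glucose levels used as class labels.

The 13 levels span 86–198 mg/dl and are the finger-prick reference readings
the classifier treats as discrete classes. They ship with the package as a
CSV so analyses and fixtures can be regenerated without external data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_table", "reference_levels"]


def load_reference_table() -> pd.DataFrame:
    """The packaged reference table (columns: sample_no, glucose_mg_dl)."""
    with resources.files("specklesense.data").joinpath(
        "reference_levels.csv"
    ).open("r") as fh:
        table = pd.read_csv(fh)
    if (table["glucose_mg_dl"] <= 0).any():
        raise ValueError("reference glucose levels must be positive")
    if table["glucose_mg_dl"].duplicated().any():
        raise ValueError("reference glucose levels must be unique")
    return table


def reference_levels() -> tuple[float, ...]:
    """The ordered glucose levels [mg/dl]."""
    return tuple(float(v) for v in load_reference_table()["glucose_mg_dl"])
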