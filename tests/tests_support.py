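"""Shared study inputs for tests: the published per-quartile event counts
and person-years (rate, CI columns are the printed values)."""

import numpy as np
import pandas as pd

MORTALITY_TABLE = [
    ("Q1", 1577, 34142, 46, (44, 49)),
    ("Q2", 1178, 34758, 34, (32, 36)),
    ("Q3", 987, 35195, 28, (26, 30)),
    ("Q4", 775, 35747, 22, (20, 23)),
]
MACE_TABLE = [
    ("Q1", 1812, 28565, 63, (61, 66)),
    ("Q2", 1501, 28778, 52, (50, 55)),
    ("Q3", 1310, 29285, 45, (42, 47)),
    ("Q4", 1071, 29830, 36, (34, 38)),
]


def records_from_counts(rows):
    """Expand (group, events, person_years) rows into individual survival
    records with the stated totals."""
    frames = []
    for grp, events, py, _, _ in rows:
        t = np.full(events + 1, 1.0)
        t[-1] = py - events
        frames.append(
            pd.DataFrame(
                {
                    "time_years": t,
                    "status": ["event"] * events + ["censored"],
                    "quartile": grp,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
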