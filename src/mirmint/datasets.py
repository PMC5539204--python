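"""Bundled small datasets.

``anatomy_summary`` holds the published group summary (mean, SD, n = 6 per
group) of anatomical traits from the monocrotaline rat model of right-heart
failure with cardiac cachexia: body weight, chamber weights, hypertrophy
indexes and wet/dry organ ratios for the saline control group versus the
cachectic group.  These summaries serve as inputs for reproducing the
anatomical group comparisons (exact Mann-Whitney tests on values drawn to
match the summaries) and derived indexes such as RVW/BW in mg/g.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["anatomy_summary", "draw_group_values"]

_ROWS = [
    # trait, unit, control mean, control sd, case mean, case sd
    ("BW", "g", 344.6, 17.5, 255.0, 13.7),
    ("LVW", "g", 0.69, 0.03, 0.60, 0.06),
    ("LVW/BW", "mg/g", 1.99, 0.17, 2.35, 0.21),
    ("RVW", "g", 0.20, 0.03, 0.49, 0.04),
    ("RVW/BW", "mg/g", 0.58, 0.06, 1.94, 0.23),
    ("ATW", "g", 0.10, 0.01, 0.19, 0.03),
    ("ATW/BW", "mg/g", 0.28, 0.03, 0.76, 0.11),
    ("Liver W/D", "ratio", 3.09, 0.04, 3.53, 0.13),
    ("Lung W/D", "ratio", 4.61, 0.19, 4.98, 0.22),
]


def anatomy_summary() -> pd.DataFrame:
    """Anatomical trait summary (mean +/- SD, n = 6 per group)."""
    df = pd.DataFrame(
        _ROWS, columns=["trait", "unit", "control_mean", "control_sd", "case_mean", "case_sd"]
    )
    df["n_per_group"] = 6
    return df.set_index("trait")


def draw_group_values(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n values from N(mean, sd) — sample-level stand-ins for a trait
    reported only as a group summary."""
    return rng.normal(mean, sd, size=n)
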