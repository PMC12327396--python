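"""Published per-animal milk parameters used as worked-example inputs.

These are the per-goat milk NCA parameters printed for a multiple-dose
oral meloxicam study in lactating dairy goats (1 mg/kg every 24 h for 6
doses, n = 10; assay LOD 4 ng/mL, LLOQ 15 ng/mL, 12 h milkings).  They are
desk-scale inputs for the geometric-summary and half-life WDI worked
examples; the raw per-sample concentrations behind them were not published.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["goat_milk_parameters", "GOAT_IDS"]

GOAT_IDS = [f"Goat {i}" for i in range(1, 11)]

_MILK_TABLE = {
    # per-goat values, goats 1..10
    "cmax_ug_ml": [0.87, 0.56, 0.60, 0.81, 0.36, 0.30, 0.62, 1.00, 0.52, 0.26],
    "tmax_post_dose_h": [10, 10, 10, 10, 10, 10, 10, 10, 10, 10],
    "t_half_theo_h": [6.85, 7.05, 9.56, 9.34, 7.26, 6.57, 5.47, 6.49, 6.34, 5.77],
    "auc_last_to_inf_ug_h_ml": [13.01, 8.64, 9.49, 12.66, 4.98, 4.30, 8.49, 17.21, 7.06, 3.65],
    "milk_plasma_auc_ratio": [0.37, 0.23, 0.35, 0.36, 0.21, 0.11, 0.39, 0.35, 0.29, 0.19],
}


def goat_milk_parameters() -> pd.DataFrame:
    """The published 10-goat milk parameter table as a DataFrame."""
    df = pd.DataFrame(_MILK_TABLE, index=GOAT_IDS)
    df.index.name = "animal_id"
    return df.reset_index()
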