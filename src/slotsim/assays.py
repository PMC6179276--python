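"""Plate-assay normalizations: MTT metabolic activity and LDH cytotoxicity.

Inputs are absorbance readings (OD, assumed already reference-wavelength
corrected).  Results outside [0, 100] are returned as computed, not
clipped — e.g. spontaneous LDH release below the low-toxicity control is
informative.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def mtt_metabolic_activity(sample, blank, control):
    """Metabolic activity (%) relative to a control set to 100%.

    ``100 · (sample − blank) / (control − blank)``, where ``blank`` is the
    reading of wells without cells.
    """
    sample = np.asarray(sample, dtype=float)
    if np.any(np.asarray(control) <= np.asarray(blank)):
        raise ValueError("control absorbance must exceed the blank")
    out = 100.0 * (sample - blank) / (np.asarray(control, dtype=float) - blank)
    return float(out) if out.ndim == 0 else out

def ldh_cytotoxicity(experimental, low_control, high_control):
    """Cytotoxicity (%) = (experimental − low control) / (high control − low control) × 100.

    The low control is spontaneous LDH release; the high control is the
    fully lysed (detergent-treated) culture.
    """
    experimental = np.asarray(experimental, dtype=float)
    if np.any(np.asarray(high_control) == np.asarray(low_control)):
        raise ValueError("high and low toxicity controls must differ")
    out = (
        100.0
        * (experimental - low_control)
        / (np.asarray(high_control, dtype=float) - low_control)
    )
    return float(out) if out.ndim == 0 else out


def process_plate_csv(path_in: str | Path, path_out: str | Path) -> pd.DataFrame:
    """Compute assay percentages for a plate table, one row per well.

    The input CSV must have columns ``assay`` (``mtt`` or ``ldh``) and
    ``value``, plus ``blank``/``control`` for MTT rows and
    ``low_control``/``high_control`` for LDH rows.  Writes (and returns)
    the table with an added ``percent`` column.
    """
    df = pd.read_csv(path_in)
    if "assay" not in df or "value" not in df:
        raise ValueError("plate CSV needs 'assay' and 'value' columns")
    percent = np.full(len(df), np.nan)
    mtt = df["assay"].str.lower() == "mtt"
    ldh = df["assay"].str.lower() == "ldh"
    unknown = ~(mtt | ldh)
    if unknown.any():
        raise ValueError(f"unknown assay labels: {sorted(df.loc[unknown, 'assay'].unique())}")
    if mtt.any():
        percent[mtt] = mtt_metabolic_activity(
            df.loc[mtt, "value"], df.loc[mtt, "blank"], df.loc[mtt, "control"]
        )
    if ldh.any():
        percent[ldh] = ldh_cytotoxicity(
            df.loc[ldh, "value"], df.loc[ldh, "low_control"], df.loc[ldh, "high_control"]
        )
    out = df.assign(percent=percent)
    out.to_csv(path_out, index=False)
    return out
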