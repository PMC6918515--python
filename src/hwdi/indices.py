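"""Disparity indices and state rankings.

Both indices sum signed deviations of income-group mean BMIs from a
reference.  The national-standard index (HWDI) uses the fixed 24.9 top of
the healthy-BMI band; the state-referenced revision (RHWDI) uses the
state's own adjusted mean BMI.  Algebraically::

    hwdi  = low + mid - high - 24.9
    rhwdi = low + mid - high - state_mean

so ``rhwdi - hwdi = 24.9 - state_mean`` exactly.  States are ranked by
index magnitude (rank 1 = smallest |index|), with direction carried by a
negativity flag.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import _schema as S

__all__ = ["HEALTHY_BMI_REFERENCE", "hwdi", "rhwdi", "rank_states", "build_index_table"]

#: Top of the healthy-weight BMI band, the national reference.
HEALTHY_BMI_REFERENCE = 24.9


def hwdi(low_bmi, mid_bmi, high_bmi):
    """National-standard index: (24.9 - high) + (mid - 24.9) + (low - 24.9)."""
    return (
        (HEALTHY_BMI_REFERENCE - np.asarray(high_bmi, dtype=float))
        + (np.asarray(mid_bmi, dtype=float) - HEALTHY_BMI_REFERENCE)
        + (np.asarray(low_bmi, dtype=float) - HEALTHY_BMI_REFERENCE)
    )


def rhwdi(state_mean_bmi, low_bmi, mid_bmi, high_bmi):
    """State-referenced index: (mean - high) + (mid - mean) + (low - mean)."""
    mean = np.asarray(state_mean_bmi, dtype=float)
    return (
        (mean - np.asarray(high_bmi, dtype=float))
        + (np.asarray(mid_bmi, dtype=float) - mean)
        + (np.asarray(low_bmi, dtype=float) - mean)
    )


def rank_states(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Rank states by ascending index magnitude.

    Rank 1 is the smallest ``|value|``.  Ties in magnitude are broken by the
    signed (unrounded) value, then alphabetically by state label.  States
    with a non-finite value are omitted from the result.
    """
    s = pd.Series(dict(values), dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    s = s[np.isfinite(s)]
    if s.empty:
        return pd.Series(dtype=int)
    order = sorted(s.index, key=lambda st: (abs(s[st]), s[st], str(st)))
    return pd.Series({st: i + 1 for i, st in enumerate(order)}, dtype=int).reindex(order)


def build_index_table(means: pd.DataFrame) -> pd.DataFrame:
    """Compute both indices and magnitude rankings from per-state group means.

    Parameters
    ----------
    means : DataFrame with one row per state and columns ``state``,
        ``mean_overall``, ``hwdi_low``, ``hwdi_middle``, ``hwdi_high``,
        ``rhwdi_low``, ``rhwdi_middle``, ``rhwdi_high``.  Any NaN input marks
        the affected index non-computable for that state.

    Returns
    -------
    DataFrame with columns state, rhwdi, rhwdi_negative, rhwdi_rank, hwdi,
    hwdi_rank, computable — ranks are a bijection onto 1..n over the
    computable states; non-computable states keep NaN ranks.
    """
    df = means.copy()
    h = hwdi(df["hwdi_low"], df["hwdi_middle"], df["hwdi_high"])
    r = rhwdi(df["mean_overall"], df["rhwdi_low"], df["rhwdi_middle"], df["rhwdi_high"])
    out = pd.DataFrame(
        {
            S.STATE: df[S.STATE].to_numpy(),
            "rhwdi": np.asarray(r, dtype=float),
            "hwdi": np.asarray(h, dtype=float),
        }
    )
    out["computable"] = np.isfinite(out["rhwdi"]) & np.isfinite(out["hwdi"])
    out["rhwdi_negative"] = out["rhwdi"] < 0
    for col in ("hwdi", "rhwdi"):
        ranks = rank_states(out.set_index(S.STATE)[col][out.set_index(S.STATE)["computable"]])
        out[f"{col}_rank"] = out[S.STATE].map(ranks).astype("Int64")
    return out[[S.STATE, "rhwdi", "rhwdi_negative", "rhwdi_rank", "hwdi", "hwdi_rank", "computable"]]
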