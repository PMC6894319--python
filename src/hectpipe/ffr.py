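"""Force-frequency relationship (FFR) analysis.

Immature and failing myocardium shows a negative FFR: developed force
falls as pacing frequency rises.  The analysis here follows the standard
engineered-tissue protocol: each tissue's developed force is normalized
to its own value at the lowest pacing frequency (0.25 Hz); tissues that
never captured at that frequency are excluded; tissues that lost 1:1
capture partway retain their truncated series.  The group FFR slope is
estimated by ordinary least squares on all pooled tissue-frequency
points, with a t-test of slope = 0, and between-group slopes are compared
through the group x frequency interaction of a pooled regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mechanics import DataError, ParameterError

__all__ = ["FFRDataset", "SlopeResult", "build_ffr", "ffr_slope", "compare_slopes"]

REFERENCE_FREQ_HZ = 0.25


@dataclass
class FFRDataset:
    """Normalized per-tissue force-frequency measurements.

    ``data`` columns: tissue, group, pace_freq_hz, df_un, norm_df.
    ``excluded`` lists (tissue, reason) for tissues dropped for lacking a
    reference-frequency measurement.
    """

    data: pd.DataFrame
    excluded: list = field(default_factory=list)
    reference_freq_hz: float = REFERENCE_FREQ_HZ


def build_ffr(
    measurements: pd.DataFrame, reference_freq_hz: float = REFERENCE_FREQ_HZ
) -> FFRDataset:
    """Normalize developed force per tissue to its reference-frequency value.

    ``measurements`` needs columns tissue, group, pace_freq_hz, df_un.
    Tissues without a measurement at the reference frequency are excluded
    (with a logged reason); truncated series are retained as-is.  The
    normalized value at the reference frequency is exactly 1.
    """
    required = {"tissue", "group", "pace_freq_hz", "df_un"}
    missing = required - set(measurements.columns)
    if missing:
        raise DataError(f"measurements missing columns: {sorted(missing)}")
    rows = []
    excluded = []
    for tissue, sub in measurements.groupby("tissue", sort=False):
        ref = sub.loc[np.isclose(sub["pace_freq_hz"], reference_freq_hz), "df_un"]
        if ref.empty:
            excluded.append((tissue, f"no {reference_freq_hz} Hz capture"))
            continue
        ref_df = float(ref.iloc[0])
        if ref_df <= 0:
            raise DataError(f"non-positive reference DF for tissue {tissue}")
        out = sub.copy()
        out["norm_df"] = out["df_un"] / ref_df
        rows.append(out)
    data = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=list(required) + ["norm_df"])
    )
    return FFRDataset(data=data, excluded=excluded, reference_freq_hz=reference_freq_hz)


@dataclass(frozen=True)
class SlopeResult:
    group: str
    slope_per_hz: float
    intercept: float
    p_vs_zero: float
    slope_se: float
    slope_ci95: tuple[float, float]
    n_points: int


def ffr_slope(dataset: FFRDataset, group: Optional[str] = None) -> SlopeResult:
    """OLS slope of normalized DF on pacing frequency for one group.

    Pools every tissue-frequency point in the group and tests the slope
    against zero with a two-sided t-test.
    """
    data = dataset.data
    if group is not None:
        data = data[data["group"] == group]
    if len(data) < 3:
        raise DataError("need at least 3 points for a slope")
    x = data["pace_freq_hz"].to_numpy(dtype=float)
    y = data["norm_df"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ParameterError("degenerate design: all frequencies identical")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)
    return SlopeResult(
        group=group if group is not None else "all",
        slope_per_hz=float(fit.params[1]),
        intercept=float(fit.params[0]),
        p_vs_zero=float(fit.pvalues[1]),
        slope_se=float(fit.bse[1]),
        slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        n_points=int(len(data)),
    )


def compare_slopes(dataset: FFRDataset, group_a: str, group_b: str) -> dict:
    """Test whether two groups' FFR slopes differ.

    Fits a pooled regression of normalized DF on frequency, a group
    indicator, and their interaction; the two-sided t-test on the
    interaction coefficient is the slope-difference test (its squared t
    equals the ANCOVA F for equality of slopes).
    """
    data = dataset.data[dataset.data["group"].isin([group_a, group_b])]
    if data["group"].nunique() < 2:
        raise DataError("both groups must be present")
    x = data["pace_freq_hz"].to_numpy(dtype=float)
    g = (data["group"] == group_b).to_numpy(dtype=float)
    y = data["norm_df"].to_numpy(dtype=float)
    design = np.column_stack([np.ones_like(x), x, g, x * g])
    if np.linalg.matrix_rank(design) < 4:
        raise ParameterError("degenerate design for slope comparison")
    fit = sm.OLS(y, design).fit()
    return {
        "slope_difference": float(fit.params[3]),
        "t": float(fit.tvalues[3]),
        "p_slope_difference": float(fit.pvalues[3]),
        "df_resid": float(fit.df_resid),
    }
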