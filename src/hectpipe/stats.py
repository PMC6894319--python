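"""Shared statistics: the two-group comparison used across all readouts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .mechanics import DataError

__all__ = ["GroupComparison", "two_group_test"]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Equal-variance two-sided Student t comparison of two groups."""

    metric: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def two_group_test(a, b, metric: str = "", equal_var: bool = True) -> GroupComparison:
    """Student t-test (equal-variance by default) between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("need >= 2 values per group")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        metric=metric,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        t=float(t),
        p=float(p),
    )
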