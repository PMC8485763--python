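"""Shared descriptive statistics used by reversion-assay style summaries."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .errors import DataError

__all__ = ["descriptive_stats"]


def descriptive_stats(
    samples: Sequence[float],
    test_against: Sequence[float] | None = None,
    spread: str = "sem",
    welch: bool = False,
) -> dict:
    """Mean and spread of one sample, optionally t-tested against a second.

    ``spread`` is ``"sem"`` (standard error of the mean) or ``"sd"``. The
    optional test is an unpaired two-tailed t-test, pooled-variance by default
    or with Welch's correction when ``welch=True``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 1:
        raise DataError("need at least one observation")
    if spread not in ("sem", "sd"):
        raise DataError(f"unknown spread {spread!r}")
    sd = float(x.std(ddof=1)) if x.size > 1 else math.nan
    out = {
        "mean": float(x.mean()),
        "n": int(x.size),
        "sd": sd,
        "sem": sd / math.sqrt(x.size) if x.size > 1 else math.nan,
        "spread": sd if spread == "sd" else (sd / math.sqrt(x.size) if x.size > 1 else math.nan),
    }
    if test_against is not None:
        y = np.asarray(test_against, dtype=float)
        if x.size < 2 or y.size < 2:
            raise DataError("t-test requires at least 2 observations per sample")
        res = _stats.ttest_ind(x, y, equal_var=not welch)
        out["t"] = float(res.statistic)
        out["p"] = float(res.pvalue)
        out["df"] = float(res.df)
    return out
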