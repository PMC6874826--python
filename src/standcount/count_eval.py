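"""Counting-accuracy evaluation against manual field counts.

Algorithm counts are compared to human stand counts per video with a simple
linear regression (predicted on observed, with or without an intercept)
plus error summaries: root mean squared error of the regression residuals,
mean absolute error, and mean relative error in percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["CountPairs", "RegressionReport", "regress", "count_errors", "read_counts_csv"]


@dataclass
class CountPairs:
    """Paired (predicted, observed) counts per video."""

    video_ids: list[str]
    predicted: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if not (len(self.video_ids) == self.predicted.size == self.observed.size):
            raise ValueError("video_ids, predicted, observed must have equal lengths")

    def __len__(self) -> int:
        return self.predicted.size


@dataclass
class RegressionReport:
    slope: float
    intercept: float | None      # None for a through-origin fit
    adj_r2: float
    rmse: float
    mae: float
    mre_pct: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "adj_r2": self.adj_r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "mre_pct": self.mre_pct,
            "n": self.n,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def regress(pairs: CountPairs, through_origin: bool = False) -> RegressionReport:
    """Least-squares fit of predicted counts on observed counts.

    With an intercept the adjusted R^2 is the usual centered statistic; for
    a through-origin fit it is the uncentered R^2 with the same
    degrees-of-freedom adjustment (the statsmodels convention for models
    without a constant). RMSE is the root mean square of the fit residuals;
    MAE and MRE are computed on the raw predicted-observed differences.
    """
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 paired counts, got {len(pairs)}")
    x, y = pairs.observed, pairs.predicted
    if np.ptp(x) == 0:
        raise ValueError("observed counts have zero variance; slope is undefined")

    X = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    if through_origin:
        slope, intercept = float(fit.params[0]), None
    else:
        intercept, slope = float(fit.params[0]), float(fit.params[1])

    resid = fit.resid
    mae, mre = _mae_mre(y, x)
    return RegressionReport(
        slope=slope,
        intercept=intercept,
        adj_r2=float(fit.rsquared_adj),
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=mae,
        mre_pct=mre,
        n=len(pairs),
    )


def _mae_mre(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    if np.any(observed <= 0):
        raise ValueError("observed counts must be positive for relative error")
    abs_err = np.abs(predicted - observed)
    return float(abs_err.mean()), float(100.0 * (abs_err / observed).mean())


def count_errors(
    pairs: CountPairs, bins: int | Sequence[float] = 10
) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """MAE, MRE (%), and a histogram of absolute errors.

    MAE = mean |predicted - observed|; MRE = 100 * mean(|predicted -
    observed| / observed). The histogram (counts, bin edges) summarizes the
    absolute-error distribution across videos.
    """
    mae, mre = _mae_mre(pairs.predicted, pairs.observed)
    hist = np.histogram(np.abs(pairs.predicted - pairs.observed), bins=bins)
    return mae, mre, hist


def read_counts_csv(path: str | Path) -> CountPairs:
    """Read a counts CSV with columns video_id, predicted, observed."""
    df = pd.read_csv(path)
    missing = {"video_id", "predicted", "observed"} - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns: {sorted(missing)}")
    return CountPairs(
        video_ids=[str(v) for v in df["video_id"]],
        predicted=df["predicted"].to_numpy(dtype=float),
        observed=df["observed"].to_numpy(dtype=float),
    )
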