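"""Agreement statistics between estimated and observed tiller numbers.

Given paired series (estimated, observed), both in tillers per m2, the
report carries:

- RMSE: ``sqrt(mean((e - o)**2))``
- MAE: ``mean(|e - o|)``
- bias: ``mean(e - o)`` — negative values mean systematic
  underestimation by the image-based method
- R^2: coefficient of determination of the ordinary least-squares line
  of estimated on observed (with intercept; equals squared Pearson r)
- CCC: Lin's concordance correlation coefficient,
  ``2*s_eo / (s_e^2 + s_o^2 + (mean_e - mean_o)^2)``,
  with population (1/n) moment denominators — Lin's original estimator.

With 1/n moments the decomposition ``rmse^2 = bias^2 + var(e - o)``
holds exactly, and CCC penalises location and scale shifts that Pearson
correlation ignores.

:func:`error_in_days` converts an error magnitude into days of growth
given a daily tiller increase rate (typical rates around drainage
timing: 12.0-24.3 tillers/m2/day), which is how a fixed counting error
translates into a timing error for the drainage decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputDomainError

__all__ = [
    "PairedObservations",
    "AccuracyReport",
    "accuracy_report",
    "lins_ccc",
    "error_in_days",
    "read_pairs_csv",
]

#: Daily tiller increase range (tillers/m2/day) around drainage timing.
TYPICAL_DAILY_RATES = (12.0, 24.3)


@dataclass(frozen=True)
class PairedObservations:
    """Paired estimated/observed tiller series (tillers per m2)."""

    estimated: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.estimated, dtype=np.float64)
        o = np.asarray(self.observed, dtype=np.float64)
        if e.ndim != 1 or o.ndim != 1 or e.shape != o.shape:
            raise InputDomainError("estimated and observed must be equal-length 1-D")
        if e.size < 2:
            raise DegenerateInputError("need at least 2 pairs")
        if not (np.isfinite(e).all() and np.isfinite(o).all()):
            raise InputDomainError("all values must be finite")
        object.__setattr__(self, "estimated", e)
        object.__setattr__(self, "observed", o)

    @property
    def n(self) -> int:
        return int(self.estimated.size)


@dataclass(frozen=True)
class AccuracyReport:
    rmse: float
    mae: float
    bias: float
    r_squared: float
    ccc: float
    n: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "bias": self.bias,
            "r_squared": self.r_squared,
            "ccc": self.ccc,
            "n": self.n,
        }


def lins_ccc(estimated, observed) -> float:
    """Lin's concordance correlation coefficient (1/n moments)."""
    e = np.asarray(estimated, dtype=np.float64)
    o = np.asarray(observed, dtype=np.float64)
    s_e = e.var()  # population (1/n) variance
    s_o = o.var()
    s_eo = ((e - e.mean()) * (o - o.mean())).mean()
    denom = s_e + s_o + (e.mean() - o.mean()) ** 2
    if denom == 0:
        raise DegenerateInputError("both series constant and equal: CCC undefined")
    return float(2.0 * s_eo / denom)


def accuracy_report(pairs: PairedObservations | None = None, *, estimated=None,
                    observed=None) -> AccuracyReport:
    """Compute the full agreement report over paired series.

    Accepts either a :class:`PairedObservations` or the two series as
    keyword arguments.  Raises :class:`DegenerateInputError` when fewer
    than two pairs are given or either series has zero variance (the
    regression R^2 is then undefined).
    """
    if pairs is None:
        pairs = PairedObservations(np.asarray(estimated), np.asarray(observed))
    e, o = pairs.estimated, pairs.observed
    if o.var() == 0 or e.var() == 0:
        raise DegenerateInputError("zero variance: R^2 undefined")
    err = e - o
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    bias = float(np.mean(err))
    # OLS of estimated on observed with intercept: R^2 = squared Pearson r.
    r = float(np.corrcoef(e, o)[0, 1])
    return AccuracyReport(
        rmse=rmse,
        mae=mae,
        bias=bias,
        r_squared=r * r,
        ccc=lins_ccc(e, o),
        n=pairs.n,
    )


def error_in_days(error_magnitude: float, daily_rate: float) -> float:
    """Convert an error magnitude (tillers/m2) into days of growth."""
    if error_magnitude < 0:
        raise InputDomainError("error magnitude must be >= 0")
    if not daily_rate > 0:
        raise InputDomainError("daily rate must be positive")
    return float(error_magnitude) / float(daily_rate)


def read_pairs_csv(path: str | PathLike) -> PairedObservations:
    """Read paired values from a CSV with header ``estimated,observed``.

    Optional leading ``group`` and ``replicate`` columns are accepted;
    when a ``group`` column is present, replicates are averaged within
    each group before pairing (matching field protocols that report the
    mean of replicate images and counts per date/site).
    """
    df = pd.read_csv(path)
    missing = {"estimated", "observed"} - set(df.columns)
    if missing:
        raise InputDomainError(f"pairs CSV missing columns: {sorted(missing)}")
    if "group" in df.columns:
        df = df.groupby("group", sort=True)[["estimated", "observed"]].mean()
    return PairedObservations(
        df["estimated"].to_numpy(dtype=np.float64),
        df["observed"].to_numpy(dtype=np.float64),
    )
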