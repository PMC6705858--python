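"""Density and biomass per haul, and the aggregation ladder.

Density is fish per 100 m2 swept: ``100 * count / area``.  Biomass converts
the measured length subsample to weights with the allometric relationship
W = a * SL**b, extrapolates the mean measured weight to the unmeasured part
of the catch, and scales to g per 100 m2.  Monthly means feed everything
above them: climatologies (12 calendar-month means over years, the
intra-annual signal), anomalies (monthly value minus its climatology, the
inter-annual signal), annual and long-term means, standardized ratios, and
centered moving averages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSeriesError, InsufficientDataError
from .survey import HaulRecord, HaulTable, LengthWeightParams

log = logging.getLogger(__name__)

DENSITY = "density"
BIOMASS = "biomass"


# ---------------------------------------------------------------------------
# series containers


@dataclass
class MonthlySeries:
    """Estuary x (year, month) series of mean haul-level density or biomass.

    ``frame`` is indexed by (year, month) with columns ``mean``, ``se``,
    ``n`` — the across-haul mean, its standard error (sample sd / sqrt(n),
    NaN for a single haul), and the number of hauls.
    """

    estuary: str
    metric: str
    frame: pd.DataFrame

    def __post_init__(self):
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate (year, month) entries")
        self.frame = self.frame.sort_index()

    @property
    def values(self) -> pd.Series:
        return self.frame["mean"]

    def years(self):
        return sorted(set(self.frame.index.get_level_values(0)))


@dataclass
class Climatology:
    """Calendar-month means over years (exactly 12 entries)."""

    estuary: str
    metric: str
    frame: pd.DataFrame  # index month 1..12, columns mean, se

    def __post_init__(self):
        if list(self.frame.index) != list(range(1, 13)):
            raise ValueError("climatology must have exactly months 1..12")


# ---------------------------------------------------------------------------
# haul-level quantities


def haul_density(count: int, area_swept: float) -> float:
    """Fish per 100 m2 for a single haul."""
    if area_swept <= 0:
        raise ValueError(f"area_swept must be > 0, got {area_swept}")
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    return 100.0 * count / area_swept


def predict_weight(sl_mm, params: LengthWeightParams):
    """Allometric weight (g) at standard length ``sl_mm`` (mm)."""
    sl = np.asarray(sl_mm, dtype=float)
    if np.any(sl <= 0):
        raise ValueError("standard length must be positive")
    out = params.a * sl**params.b
    return float(out) if np.isscalar(sl_mm) else out


def fit_length_weight(lengths_mm, weights_g, estuary: str = "") -> LengthWeightParams:
    """Least-squares fit of ln W = ln a + b ln SL.

    Exact power-law data is recovered exactly; requires >= 3 positive pairs
    with spread in length.
    """
    sl = np.asarray(lengths_mm, dtype=float)
    w = np.asarray(weights_g, dtype=float)
    if sl.shape != w.shape:
        raise ValueError("lengths and weights must have equal length")
    if sl.size < 3:
        raise InsufficientDataError("need >= 3 length-weight pairs")
    if np.any(sl <= 0) or np.any(w <= 0):
        raise ValueError("lengths and weights must be positive")
    x = np.log(sl)
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("no spread in lengths")
    b, ln_a = np.polyfit(x, np.log(w), 1)
    return LengthWeightParams(estuary=estuary, a=float(np.exp(ln_a)), b=float(b))


def haul_biomass(
    record: HaulRecord,
    params: LengthWeightParams,
    fallback_mean_weight: float | None = None,
) -> float:
    """Biomass (g per 100 m2) for one haul.

    The mean weight of the measured subsample is extrapolated to the whole
    catch: ``count * mean(W(measured lengths))``, then scaled per 100 m2.
    A positive haul with no measured lengths uses ``fallback_mean_weight``
    (the estuary-month mean measured weight); with neither, it is an error.
    """
    if record.count == 0:
        return 0.0
    if record.lengths_mm:
        mean_w = float(np.mean(predict_weight(np.array(record.lengths_mm), params)))
    elif fallback_mean_weight is not None:
        mean_w = float(fallback_mean_weight)
    else:
        raise InsufficientDataError(
            f"haul {record.haul_id}: positive count with no measured lengths "
            "and no fallback mean weight"
        )
    return 100.0 * record.count * mean_w / record.area_swept_m2


def _haul_values(table: HaulTable, metric: str, lw_params: dict | None) -> pd.DataFrame:
    """Per-haul metric values with estuary/year/month labels."""
    rows = []
    pending = []  # hauls needing the estuary-month fallback mean weight
    for r in table:
        if metric == DENSITY:
            v = haul_density(r.count, r.area_swept_m2)
        elif metric == BIOMASS:
            if lw_params is None:
                raise ValueError("biomass requires length-weight parameters")
            p = lw_params[r.estuary]
            if r.count > 0 and not r.lengths_mm:
                pending.append(r)
                continue
            v = haul_biomass(r, p)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        rows.append((r.estuary, r.year, r.month, r.haul_id, v))
    df = pd.DataFrame(rows, columns=["estuary", "year", "month", "haul_id", "value"])
    if pending:
        # estuary-month mean measured weight from hauls that did report lengths
        mw_rows = []
        for r in table:
            if r.lengths_mm:
                p = lw_params[r.estuary]
                w = float(np.mean(predict_weight(np.array(r.lengths_mm), p)))
                mw_rows.append((r.estuary, r.month, w))
        mw = (
            pd.DataFrame(mw_rows, columns=["estuary", "month", "w"])
            .groupby(["estuary", "month"])["w"]
            .mean()
        )
        extra = []
        for r in pending:
            key = (r.estuary, r.month)
            if key not in mw.index:
                raise InsufficientDataError(
                    f"haul {r.haul_id}: no measured lengths anywhere in "
                    f"estuary {r.estuary} month {r.month} to extrapolate from"
                )
            log.warning(
                "haul %s: count=%d with no measured lengths; using estuary-month "
                "mean measured weight %.3f g",
                r.haul_id,
                r.count,
                mw[key],
            )
            v = haul_biomass(r, lw_params[r.estuary], fallback_mean_weight=mw[key])
            extra.append((r.estuary, r.year, r.month, r.haul_id, v))
        df = pd.concat(
            [df, pd.DataFrame(extra, columns=df.columns)], ignore_index=True
        )
    return df


# ---------------------------------------------------------------------------
# aggregation ladder


def monthly_mean(
    table: HaulTable, metric: str = DENSITY, lw_params: dict | None = None
) -> dict:
    """Per-estuary MonthlySeries of haul-level means.

    SE is the sample standard deviation (n-1) over hauls divided by sqrt(n);
    a single-haul month has SE recorded as missing (NaN).  Months with no
    hauls are simply absent.
    """
    df = _haul_values(table, metric, lw_params)
    out = {}
    for est, g in df.groupby("estuary", sort=True):
        agg = g.groupby(["year", "month"])["value"].agg(
            mean="mean", sd=lambda v: v.std(ddof=1), n="count"
        )
        frame = pd.DataFrame(
            {
                "mean": agg["mean"],
                "se": agg["sd"] / np.sqrt(agg["n"]),
                "n": agg["n"].astype(int),
            }
        )
        out[est] = MonthlySeries(est, metric, frame)
    return out


def climatology(series: MonthlySeries) -> Climatology:
    """Calendar-month means over years (SE over years per month)."""
    years = series.years()
    if len(years) < 2:
        raise InsufficientDataError("climatology needs >= 2 years")
    df = series.frame.reset_index()
    g = df.groupby("month")["mean"]
    frame = pd.DataFrame(
        {"mean": g.mean(), "se": g.std(ddof=1) / np.sqrt(g.count())}
    ).reindex(range(1, 13))
    frame.index.name = "month"
    return Climatology(series.estuary, series.metric, frame)


def anomalies(
    series: MonthlySeries, clim: Climatology | None = None, standardize: bool = False
) -> MonthlySeries:
    """Monthly value minus its calendar-month climatology (detrended series).

    ``standardize=True`` additionally divides each anomaly by the
    calendar-month standard deviation over years, removing the seasonal
    variance envelope as well as the seasonal mean (useful when anomalies
    feed correlation tests whose null calibration assumes homoscedasticity).
    """
    if clim is None:
        clim = climatology(series)
    frame = series.frame.copy()
    months = frame.index.get_level_values("month")
    anom = frame["mean"].to_numpy() - clim.frame["mean"].reindex(months).to_numpy()
    if standardize:
        sd = (
            pd.Series(anom, index=months)
            .groupby(level=0)
            .std(ddof=1)
            .reindex(months)
            .to_numpy()
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            anom = np.where(sd > 0, anom / sd, 0.0)
    frame["mean"] = anom
    return MonthlySeries(series.estuary, series.metric, frame)


def annual_mean(series: MonthlySeries) -> pd.Series:
    """Mean over the months present in each year."""
    if series.frame.empty:
        raise InsufficientDataError("empty series")
    return series.frame.groupby(level="year")["mean"].mean()


def long_term_mean(series: MonthlySeries) -> tuple:
    """Grand mean over all monthly entries, with SE over those entries."""
    if series.frame.empty:
        raise InsufficientDataError("empty series")
    v = series.frame["mean"]
    se = v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else float("nan")
    return float(v.mean()), float(se)


def standardized_ratio(series: MonthlySeries) -> pd.Series:
    """Annual mean over long-term mean (the long-term mean of annual means).

    With equally weighted years the ratios average to 1 exactly.
    """
    ann = annual_mean(series)
    lt = ann.mean()
    if lt == 0:
        raise DegenerateSeriesError("long-term mean is zero; ratio undefined")
    return ann / lt


def moving_average(values, window: int = 3) -> np.ndarray:
    """Centered moving average; edges use truncated (shorter) windows."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    v = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(v)
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        out[i] = v[lo:hi].mean()
    return out
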