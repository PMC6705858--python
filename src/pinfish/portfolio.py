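"""Coefficients of variation and the average-CV portfolio effect.

For a metapopulation of n local populations, CVPE = mean(local CVs) /
CV(metapopulation aggregate).  A value of 1 is what a single homogeneous
population would produce; values above 1 quantify variance dampening from
asynchrony among the locals.  CVs are taken over the series of annual
peaks of the 3-month moving average of monthly means, mirroring how peak
inter-annual dynamics are summarised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import MonthlySeries, moving_average
from .errors import DegenerateSeriesError, InsufficientDataError

#: Default groupings: the full four-estuary metapopulation, the two
#: northern estuaries combined, and the two southern ones combined.
DEFAULT_GROUPS = {
    "full": ("AB", "CK", "TB", "CH"),
    "northern": ("AB", "CK"),
    "southern": ("TB", "CH"),
}


def cv(values) -> float:
    """Coefficient of variation: sample sd (n-1) over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("CV needs >= 2 values")
    m = v.mean()
    if m == 0:
        raise DegenerateSeriesError("CV undefined for zero mean")
    return float(v.std(ddof=1) / m)


def annual_peak_series(series: MonthlySeries, window: int = 3) -> pd.Series:
    """Per-year maximum of the window-month moving average of monthly means.

    The moving average is taken over the full chronological series (so a
    window may straddle year boundaries) and the maximum extracted within
    each year; edge months use truncated windows.
    """
    frame = series.frame
    if frame.empty:
        raise InsufficientDataError("empty series")
    smooth = moving_average(frame["mean"].to_numpy(), window=window)
    years = frame.index.get_level_values("year")
    return pd.Series(smooth, index=years).groupby(level=0).max()


def metapopulation_series(members, weights=None) -> MonthlySeries:
    """Weighted mean of member monthly means on their common (year, month) grid."""
    if len(members) < 1:
        raise InsufficientDataError("need >= 1 member series")
    if weights is None:
        weights = np.ones(len(members))
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("weights must sum to a positive number")
    weights = weights / weights.sum()
    frames = [m.frame["mean"] for m in members]
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    if len(common) == 0:
        raise InsufficientDataError("member series share no (year, month) coverage")
    agg = sum(w * f.reindex(common) for w, f in zip(weights, frames))
    frame = pd.DataFrame(
        {"mean": agg, "se": np.nan, "n": len(members)}, index=common
    )
    name = "+".join(m.estuary for m in members)
    return MonthlySeries(name, members[0].metric, frame)


@dataclass
class PortfolioResult:
    """CVPE and its ingredients for one named metapopulation grouping."""

    group_name: str
    members: tuple
    local_cvs: dict
    metapop_cv: float
    cvpe: float
    peak_series: pd.DataFrame  # per-member and aggregate annual peaks

    def summary(self) -> str:
        lines = [f"Portfolio {self.group_name!r}: members {', '.join(self.members)}"]
        for m, c in self.local_cvs.items():
            lines.append(f"  CV[{m}] = {c:.4f}")
        lines.append(f"  CV[metapopulation] = {self.metapop_cv:.4f}")
        lines.append(f"  CVPE = {self.cvpe:.4f}")
        return "\n".join(lines)


def cvpe(
    member_series,
    group_name: str = "",
    window: int = 3,
    weights=None,
    use_peaks: bool = True,
) -> PortfolioResult:
    """Average-CV portfolio effect over the given member series.

    Local CVs come from each member's annual-peak series; the
    metapopulation CV from the annual-peak series of the equally weighted
    aggregate (restricted to the shared coverage so member and aggregate
    CVs measure the same months).  ``use_peaks=False`` uses raw annual
    means instead of peaks of the moving average.
    """
    if len(member_series) < 2:
        raise InsufficientDataError("a portfolio needs >= 2 member populations")
    agg = metapopulation_series(member_series, weights=weights)
    common = agg.frame.index

    def peaks(s: MonthlySeries) -> pd.Series:
        restricted = MonthlySeries(s.estuary, s.metric, s.frame.loc[common])
        if use_peaks:
            return annual_peak_series(restricted, window=window)
        return restricted.frame.groupby(level="year")["mean"].mean()

    local_peaks = {s.estuary: peaks(s) for s in member_series}
    agg_peaks = peaks(agg)
    local_cvs = {name: cv(p.to_numpy()) for name, p in local_peaks.items()}
    m_cv = cv(agg_peaks.to_numpy())
    pe = float(np.mean(list(local_cvs.values())) / m_cv)
    peak_frame = pd.DataFrame({**local_peaks, "metapopulation": agg_peaks})
    return PortfolioResult(
        group_name=group_name or agg.estuary,
        members=tuple(s.estuary for s in member_series),
        local_cvs=local_cvs,
        metapop_cv=m_cv,
        cvpe=pe,
        peak_series=peak_frame,
    )
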