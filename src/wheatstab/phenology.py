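"""Thermal time, BBCH stage timing, logistic canopy senescence, and GCD.

Thermal time (TT, degree-days above a base temperature) is the developmental
clock of the crop: TT = sum over days of max(0, (Tmin + Tmax)/2 - Tbase), with
Tbase = 0 degC for winter wheat.  Daily contributions are clipped at zero, the
standard growing-degree-day convention (with a 0 degC base, winter days would
otherwise subtract development).

Green canopy area (GCA) after anthesis declines along a logistic in thermal
time, GCA(TT) = GCA_max / (1 + exp(k * (TT - TT50))).  Green canopy duration
(GCD) — the stay-green measure — is the thermal time from anthesis (BBCH61)
to the point where the fitted curve crosses half of its asymptote:
GCD = TT50 - TT_anthesis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SenescenceFit",
    "WeatherRangeError",
    "StageCoverageError",
    "SenescenceFitError",
    "thermal_time",
    "stage_tt",
    "logistic_gca",
    "fit_senescence",
    "green_canopy_duration",
]


class WeatherRangeError(ValueError):
    """A requested date falls outside the weather series."""


class StageCoverageError(ValueError):
    """A BBCH stage is not bracketed by the scouting observations."""


class SenescenceFitError(RuntimeError):
    """The logistic senescence fit failed or the data cannot support one."""


@dataclass(frozen=True)
class SenescenceFit:
    """Fitted logistic senescence curve: GCA_max / (1 + exp(k*(TT - TT50)))."""

    gca_max: float   # asymptotic green canopy area, fraction
    tt50: float      # thermal time at 50% of the asymptote, degC d
    k: float         # senescence rate, per degC d
    sse: float       # residual sum of squares of the fit

    def __post_init__(self) -> None:
        if not (0.0 < self.gca_max <= 1.2):
            raise ValueError(f"gca_max {self.gca_max} outside (0, 1.2]")
        if self.k <= 0:
            raise ValueError("senescence rate k must be positive")

    def predict(self, tt) -> np.ndarray:
        return logistic_gca(np.asarray(tt, dtype=float), self.gca_max, self.tt50, self.k)


def _coerce_weather(weather: pd.DataFrame) -> pd.DataFrame:
    need = {"date", "tmin_C", "tmax_C"}
    missing = need - set(weather.columns)
    if missing:
        raise ValueError(f"weather series missing column(s): {sorted(missing)}")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    if not w["date"].is_monotonic_increasing or w["date"].duplicated().any():
        raise ValueError("weather dates must be strictly increasing")
    if (w["tmax_C"] < w["tmin_C"]).any():
        raise ValueError("tmax_C < tmin_C in weather series")
    return w


def thermal_time(weather: pd.DataFrame, from_date, to_date, t_base: float = 0.0) -> float:
    """Accumulated degree-days over [from_date, to_date], both inclusive.

    Daily contribution is max(0, (Tmin + Tmax)/2 - t_base); additive over
    adjacent windows by construction.
    """
    w = _coerce_weather(weather)
    start, end = pd.Timestamp(from_date), pd.Timestamp(to_date)
    if start > end:
        raise ValueError("from_date must not be after to_date")
    if start < w["date"].iloc[0] or end > w["date"].iloc[-1]:
        raise WeatherRangeError(
            f"window [{start.date()}, {end.date()}] outside weather series "
            f"[{w['date'].iloc[0].date()}, {w['date'].iloc[-1].date()}]"
        )
    mask = (w["date"] >= start) & (w["date"] <= end)
    daily = (w.loc[mask, "tmin_C"] + w.loc[mask, "tmax_C"]) / 2.0 - t_base
    return float(np.clip(daily, 0.0, None).sum())


def stage_tt(stages: dict, weather: pd.DataFrame, bbch: float,
             sowing_date=None, t_base: float = 0.0) -> float:
    """Thermal time from sowing to a BBCH stage.

    ``stages`` maps BBCH codes to observation dates (weekly scouting).  A stage
    that was not observed exactly is placed by linear interpolation on the
    BBCH-versus-date line between the bracketing visits; the interpolated date
    is rounded to the nearest day.  Sowing defaults to the first day of the
    weather series.
    """
    if not stages:
        raise StageCoverageError("no stage observations")
    codes = sorted(stages)
    dates = [pd.Timestamp(stages[c]) for c in codes]
    if any(b > a for a, b in zip(dates[1:], dates[:-1])):
        raise ValueError("stage dates must be non-decreasing with BBCH code")
    if bbch < codes[0] or bbch > codes[-1]:
        raise StageCoverageError(
            f"BBCH {bbch} not bracketed by observed codes [{codes[0]}, {codes[-1]}]"
        )
    w = _coerce_weather(weather)
    sowing = pd.Timestamp(sowing_date) if sowing_date is not None else w["date"].iloc[0]

    if bbch in stages:
        stage_date = pd.Timestamp(stages[bbch])
    else:
        hi = next(i for i, c in enumerate(codes) if c >= bbch)
        lo = hi - 1
        frac = (bbch - codes[lo]) / (codes[hi] - codes[lo])
        span = (dates[hi] - dates[lo]).days
        stage_date = dates[lo] + pd.Timedelta(days=round(frac * span))
    return thermal_time(weather, sowing, stage_date, t_base=t_base)


def logistic_gca(tt, gca_max, tt50, k):
    """Declining logistic: GCA_max / (1 + exp(k * (TT - TT50)))."""
    return gca_max / (1.0 + np.exp(np.clip(k * (np.asarray(tt) - tt50), -500, 500)))


def fit_senescence(tt, gca) -> SenescenceFit:
    """Least-squares logistic fit of the post-anthesis GCA decline.

    Initialisation: GCA_max = max observed; TT50 = TT of the point closest to
    half-max; k = 4 / TT range.  k is bounded to (0, 1] per degC d.
    """
    tt = np.asarray(tt, dtype=float)
    gca = np.asarray(gca, dtype=float)
    if tt.shape != gca.shape or tt.ndim != 1:
        raise ValueError("tt and gca must be 1-d arrays of equal length")
    if len(tt) < 4:
        raise SenescenceFitError(f"need >= 4 points spanning the decline, got {len(tt)}")
    order = np.argsort(tt)
    tt, gca = tt[order], gca[order]
    slope = np.polyfit(tt, gca, 1)[0]
    if slope > 0 and gca[-1] > gca[0]:
        raise SenescenceFitError("GCA increases with TT; no senescence to fit")

    g0 = float(gca.max())
    if g0 <= 0:
        raise SenescenceFitError("all GCA observations non-positive")
    tt50_0 = float(tt[np.argmin(np.abs(gca - g0 / 2.0))])
    span = float(tt.max() - tt.min()) or 1.0
    k0 = min(4.0 / span, 1.0)
    try:
        popt, _ = curve_fit(
            logistic_gca, tt, gca,
            p0=[g0, tt50_0, k0],
            bounds=([1e-6, tt.min() - 5 * span, 1e-9], [1.2, tt.max() + 5 * span, 1.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise SenescenceFitError(f"logistic fit did not converge: {exc}") from exc
    resid = gca - logistic_gca(tt, *popt)
    sse = float(resid @ resid)
    if not np.isfinite(sse):
        raise SenescenceFitError("non-finite residual sum of squares")
    return SenescenceFit(gca_max=float(popt[0]), tt50=float(popt[1]),
                         k=float(popt[2]), sse=sse)


def green_canopy_duration(fit: SenescenceFit, tt_anthesis: float) -> float:
    """Stay-green duration: thermal time from anthesis to 50% of fitted GCA_max.

    The half-way point is relative to the fitted asymptote, which makes GCD
    invariant to vertical scaling of the canopy series.
    """
    if tt_anthesis >= fit.tt50:
        raise ValueError(
            f"anthesis TT ({tt_anthesis}) must precede TT50 ({fit.tt50})"
        )
    return float(fit.tt50 - tt_anthesis)
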