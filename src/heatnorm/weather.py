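"""Temperature-humidity index (THI) heat-load covariates.

Hourly dry-bulb temperature and relative humidity are combined into the
livestock THI, averaged to calendar days, and lagged onto test days.  The
heat-load covariate f(THI) used by the reaction-norm model is the
broken-stick excess ``max(0, THI - threshold)`` with a default threshold of
68, below which milk production is assumed unaffected by heat.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: THI value above which lactating cows are considered heat stressed.
DEFAULT_THI_THRESHOLD = 68.0


@dataclass(frozen=True)
class HourlyWeather:
    """One hourly weather observation.

    Parameters
    ----------
    timestamp : pandas.Timestamp
        Observation time.
    temp : float
        Dry-bulb air temperature in degrees Celsius.
    rh : float
        Relative humidity as a proportion in [0, 1].
    """

    timestamp: pd.Timestamp
    temp: float
    rh: float


@dataclass(frozen=True)
class DailyThi:
    """Mean THI of one calendar day."""

    date: date
    thi: float


@dataclass(frozen=True)
class HeatLoad:
    """Broken-stick heat load f(THI) = max(0, THI - threshold)."""

    f: float
    thr: float = DEFAULT_THI_THRESHOLD


def hourly_thi(temp: float, rh: float) -> float:
    """THI from temperature (degC) and relative humidity (proportion).

    ``THI = (1.8*temp + 32) - (0.55 - 0.55*rh) * (1.8*temp - 26)``

    At ``rh = 1`` the humidity adjustment vanishes and THI reduces to the
    Fahrenheit temperature; at ``temp = 130/9`` degC (where
    ``1.8*temp = 26``) THI is independent of humidity.

    Raises
    ------
    ValueError
        If ``rh`` lies outside [0, 1] (guards against percent-scale input).
    """
    temp = np.asarray(temp, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(~np.isfinite(temp)):
        raise ValueError("temperature must be finite")
    if np.any((rh < 0.0) | (rh > 1.0)):
        bad = np.atleast_1d(rh)[(np.atleast_1d(rh) < 0) | (np.atleast_1d(rh) > 1)]
        raise ValueError(
            f"relative humidity must be a proportion in [0, 1]; got {bad[0]!r}. "
            "Percent-scale input should be divided by 100 (rh_percent option)."
        )
    out = (1.8 * temp + 32.0) - (0.55 - 0.55 * rh) * (1.8 * temp - 26.0)
    return float(out) if out.ndim == 0 else out


def daily_mean_thi(hourly: Iterable[HourlyWeather]) -> list[DailyThi]:
    """Average hourly THI within each calendar day.

    Days with no observations are simply absent from the output; all
    available hours of a day are weighted equally.
    """
    rows = [(h.timestamp, h.temp, h.rh) for h in hourly]
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["timestamp", "temp", "rh"])
    df["thi"] = hourly_thi(df["temp"].to_numpy(), df["rh"].to_numpy())
    df["day"] = pd.to_datetime(df["timestamp"]).dt.date
    daily = df.groupby("day", sort=True)["thi"].mean()
    return [DailyThi(date=d, thi=float(v)) for d, v in daily.items()]


def assign_test_day_thi(daily: Sequence[DailyThi], test_date: date, n_days: int = 3) -> float:
    """Mean daily THI over the ``n_days`` calendar days preceding a test day.

    The test day itself is excluded: for the default 3-day lag the days
    ``test_date - 3 .. test_date - 1`` are averaged, reflecting the lag
    between heat exposure and its expression in milk yield.

    Raises
    ------
    KeyError
        If any required day is missing from ``daily`` (all missing dates are
        listed in the message).
    """
    lookup = {d.date: d.thi for d in daily}
    wanted = [test_date - timedelta(days=k) for k in range(n_days, 0, -1)]
    missing = [d for d in wanted if d not in lookup]
    if missing:
        raise KeyError(
            f"no daily THI for {', '.join(str(d) for d in missing)} "
            f"(required for test day {test_date})"
        )
    return float(np.mean([lookup[d] for d in wanted]))


def heat_load(thi: float, thr: float = DEFAULT_THI_THRESHOLD) -> HeatLoad:
    """Broken-stick heat load ``f = max(0, thi - thr)``."""
    if not np.isfinite(thi):
        raise ValueError(f"THI must be finite, got {thi!r}")
    return HeatLoad(f=max(0.0, float(thi) - float(thr)), thr=float(thr))


def read_hourly_weather(path, rh_percent: bool = False) -> list[HourlyWeather]:
    """Read hourly weather from delimited text (timestamp, temp, rh).

    With ``rh_percent=True`` the humidity column is divided by 100 on
    ingest; otherwise it must already be a proportion in [0, 1].
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    ts = pd.to_datetime(df["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("weather timestamps must be non-decreasing")
    rh = df["rh"].to_numpy(dtype=float)
    if rh_percent:
        rh = rh / 100.0
    if np.any((rh < 0.0) | (rh > 1.0)):
        bad = rh[(rh < 0.0) | (rh > 1.0)][0]
        raise ValueError(
            f"relative humidity must be a proportion in [0, 1]; got {bad!r}. "
            "Use rh_percent=True (--rh-percent) for percent-scale input."
        )
    return [
        HourlyWeather(timestamp=t, temp=float(tp), rh=float(r))
        for t, tp, r in zip(ts, df["temp"].to_numpy(dtype=float), rh)
    ]


def write_daily_thi(daily: Sequence[DailyThi], path) -> None:
    """Write a daily THI series as TSV (date, thi)."""
    pd.DataFrame(
        {"date": [d.date for d in daily], "thi": [d.thi for d in daily]}
    ).to_csv(path, sep="\t", index=False)


def read_daily_thi(path) -> list[DailyThi]:
    df = pd.read_csv(path, sep="\t")
    return [
        DailyThi(date=pd.Timestamp(d).date(), thi=float(t))
        for d, t in zip(df["date"], df["thi"])
    ]
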