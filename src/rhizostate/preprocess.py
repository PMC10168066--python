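"""Data preparation: dekadal aggregation, disturbance exclusion, alignment.

Raw inputs are (a) a daily forcing table (``date, soil_temp_c,
soil_moist_pct``) and (b) a long production table (``scan_date, scanner_id,
image_id, production_mm2_cm2_d, installation_date, stand``) where each row is
the mean daily production rate over the interval ending at ``scan_date``.
Both are recalculated onto month terciles ("dekads": days 1-10, 11-20,
21-end; 36 per year) before modelling.

Scan intervals rarely coincide with dekad boundaries; rates are attributed to
dekads by interval-overlap weighting, which conserves time-integrated
production. Missing dekads stay absent — never imputed, never zero-filled.
"""

from __future__ import annotations

import calendar as _cal
import datetime as _dt
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EnvForcingSeries, ProductionObservations

__all__ = [
    "DekadCalendar",
    "scanned_area_cm2",
    "aggregate_to_dekads",
    "assign_production_to_dekads",
    "exclude_disturbance_window",
    "align_dataset",
    "ModelData",
]

TERCILE_NAMES = ("early", "mid", "late")

#: Disturbance-window defaults (days after scanner installation with unstable
#: root dynamics) for the two study stands.
DEFAULT_EXCLUSION_DAYS = {"cypress": 307, "oak": 68}


def scanned_area_cm2(image_width_cm: float = 5.0, image_depth_cm: float = 20.0,
                     n_depthwise_images: int = 2) -> float:
    """Analyzed soil-profile area per scan: the cropped depth-wise images.

    Two 5 cm x 20 cm depth-wise crops per scanner image give 200 cm^2.
    """
    return image_width_cm * image_depth_cm * n_depthwise_images


class DekadCalendar:
    """Maps calendar dates to (year, month, tercile) periods."""

    @staticmethod
    def period_of(date) -> tuple[int, int, str]:
        d = pd.Timestamp(date)
        if d.day <= 10:
            tc = "early"
        elif d.day <= 20:
            tc = "mid"
        else:
            tc = "late"
        return (d.year, d.month, tc)

    @staticmethod
    def bounds(period: tuple[int, int, str]) -> tuple[_dt.date, _dt.date]:
        """Inclusive (first_day, last_day) of a period."""
        y, m, tc = period
        last_dom = _cal.monthrange(y, m)[1]
        start_day = {"early": 1, "mid": 11, "late": 21}[tc]
        end_day = {"early": 10, "mid": 20, "late": last_dom}[tc]
        return _dt.date(y, m, start_day), _dt.date(y, m, end_day)

    @classmethod
    def length_days(cls, period) -> int:
        a, b = cls.bounds(period)
        return (b - a).days + 1

    @classmethod
    def periods_between(cls, start, end) -> list[tuple[int, int, str]]:
        """All periods touching [start, end], in chronological order."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        out = []
        y, m, ti = start.year, start.month, TERCILE_NAMES.index(
            cls.period_of(start)[2])
        while True:
            period = (y, m, TERCILE_NAMES[ti])
            out.append(period)
            if cls.bounds(period)[1] >= end.date():
                break
            ti += 1
            if ti == 3:
                ti = 0
                m += 1
                if m == 13:
                    m, y = 1, y + 1
        return out


def aggregate_to_dekads(daily: pd.DataFrame, date_col: str = "date",
                        value_cols: tuple[str, ...] = ("soil_temp_c",
                                                       "soil_moist_pct"),
                        min_year_coverage: float = 0.5) -> EnvForcingSeries:
    """Average a daily forcing table onto dekads.

    The dekadal value is the arithmetic mean of available daily values; the
    interval length V is the calendar length of the dekad regardless of
    coverage. Dekads with no daily values get NaN (flagged missing). Years
    with less than ``min_year_coverage`` daily coverage raise.
    """
    df = daily.copy()
    df[date_col] = pd.to_datetime(df[date_col])
    if df[date_col].duplicated().any():
        raise ValueError("duplicate dates in daily series")
    df = df.sort_values(date_col)
    # coverage check per calendar year present
    for y, grp in df.groupby(df[date_col].dt.year):
        ndays = 366 if _cal.isleap(int(y)) else 365
        if len(grp) / ndays < min_year_coverage:
            raise ValueError(
                f"year {y}: only {len(grp)} daily values "
                f"(< {min_year_coverage:.0%} coverage)")
    periods = DekadCalendar.periods_between(df[date_col].min(),
                                            df[date_col].max())
    key = df[date_col].map(DekadCalendar.period_of)
    means = df[list(value_cols)].groupby(key.values).mean()
    st = np.full(len(periods), np.nan)
    sm = np.full(len(periods), np.nan)
    v = np.array([DekadCalendar.length_days(p) for p in periods], dtype=float)
    for i, p in enumerate(periods):
        if p in means.index:
            st[i] = means.loc[[p], value_cols[0]].iloc[0]
            sm[i] = means.loc[[p], value_cols[1]].iloc[0]
    return EnvForcingSeries(periods=periods, st=st, sm=sm, v=v)


def exclude_disturbance_window(raw: pd.DataFrame,
                               exclusion_days_by_stand: dict[str, int]
                               | None = None) -> pd.DataFrame:
    """Drop scans within the post-installation disturbance window.

    A record is removed when ``scan_date - installation_date`` is at most the
    stand's exclusion length (307 days for the cypress stand, 68 for the oak
    stand by default). Returns the filtered table; the number of dropped rows
    is attached as ``.attrs['n_excluded']``.
    """
    excl = dict(DEFAULT_EXCLUSION_DAYS)
    if exclusion_days_by_stand:
        excl.update(exclusion_days_by_stand)
    df = raw.copy()
    scan = pd.to_datetime(df["scan_date"])
    inst = pd.to_datetime(df["installation_date"])
    age = (scan - inst).dt.days
    if (age < 0).any():
        raise ValueError("scan_date earlier than installation_date")
    days = df["stand"].map(lambda s: excl.get(s, 0)).astype(int)
    keep = age > days
    out = df[keep].reset_index(drop=True)
    out.attrs["n_excluded"] = int((~keep).sum())
    return out


def assign_production_to_dekads(raw: pd.DataFrame,
                                gap_warning_days: int = 45) -> pd.DataFrame:
    """Attribute scan-interval production rates to dekads by overlap weighting.

    Each row's rate applies over the interval from the previous scan of the
    same (scanner, image) — or the installation date for the first scan —
    to its ``scan_date``. A dekad's value is the overlap-weighted mean rate
    of all intervals touching it. Dekads without any overlap stay absent.

    Returns a long table ``(year, month, tercile, scanner_id, image_id,
    production)``.
    """
    df = raw.copy()
    df["scan_date"] = pd.to_datetime(df["scan_date"])
    df["installation_date"] = pd.to_datetime(df["installation_date"])
    rows = []
    for (sid, iid), grp in df.groupby(["scanner_id", "image_id"], sort=True):
        grp = grp.sort_values("scan_date")
        prev = grp["installation_date"].iloc[0]
        num: dict[tuple, float] = {}
        den: dict[tuple, float] = {}
        for _, rec in grp.iterrows():
            start, end = prev, rec["scan_date"]
            ndays = (end - start).days
            if ndays <= 0:
                raise ValueError(
                    f"non-positive scan interval for {sid}/{iid} at {end}")
            if ndays > gap_warning_days:
                warnings.warn(
                    f"scan gap of {ndays} days for scanner {sid} image {iid}",
                    stacklevel=2)
            rate = float(rec["production_mm2_cm2_d"])
            for period in DekadCalendar.periods_between(
                    start + pd.Timedelta(days=1), end):
                a, b = DekadCalendar.bounds(period)
                lo = max(pd.Timestamp(a), start + pd.Timedelta(days=1))
                hi = min(pd.Timestamp(b), end)
                overlap = (hi - lo).days + 1
                if overlap <= 0:
                    continue
                num[period] = num.get(period, 0.0) + rate * overlap
                den[period] = den.get(period, 0.0) + overlap
            prev = end
        for period, w in den.items():
            rows.append({"year": period[0], "month": period[1],
                         "tercile": period[2], "scanner_id": sid,
                         "image_id": iid, "production": num[period] / w})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["year", "month", "tercile", "scanner_id", "image_id"]
        ).reset_index(drop=True)
    return out


@dataclass
class ModelData:
    """Model-ready bundle: aligned forcing + observations and index maps."""

    forcing: EnvForcingSeries
    obs: ProductionObservations
    scanner_ids: list
    image_ids: list

    @property
    def T(self) -> int:
        return self.forcing.T

    @property
    def S(self) -> int:
        return self.obs.S

    @property
    def C(self) -> int:
        return self.obs.C

    def manifest(self) -> dict:
        return {
            "T": self.T, "S": self.S, "C": self.C,
            "periods": [list(p) for p in self.forcing.periods],
            "scanner_ids": [str(s) for s in self.scanner_ids],
            "image_ids": [str(c) for c in self.image_ids],
            "n_obs": self.obs.n_obs,
        }

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.forcing.to_frame().to_csv(outdir / "forcing_dekadal.csv",
                                       index=False)
        obs_df = self.obs.to_frame()
        obs_df["scanner_id"] = [self.scanner_ids[s] for s in self.obs.s]
        obs_df["image_id"] = [self.image_ids[c] for c in self.obs.c]
        obs_df.to_csv(outdir / "production_dekadal.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=1))


def align_dataset(forcing: EnvForcingSeries,
                  production: pd.DataFrame) -> ModelData:
    """Trim forcing and dekadal production to their common period range.

    ``production`` is the long table from :func:`assign_production_to_dekads`.
    Periods in the overlap must have finite forcing values.
    """
    if not len(production):
        raise ValueError("no production records to align")
    period_index = {p: i for i, p in enumerate(forcing.periods)}
    prod_periods = [
        (int(r.year), int(r.month), str(r.tercile))
        for r in production.itertuples()
    ]
    present = [p for p in prod_periods if p in period_index]
    if not present:
        raise ValueError("forcing and production periods do not overlap")
    lo = min(period_index[p] for p in present)
    hi = max(period_index[p] for p in present)
    sl = slice(lo, hi + 1)
    sub_periods = forcing.periods[sl]
    st, sm, v = forcing.st[sl], forcing.sm[sl], forcing.v[sl]
    if np.isnan(st).any() or np.isnan(sm).any():
        raise ValueError("missing forcing values inside the overlap range")
    trimmed = EnvForcingSeries(periods=sub_periods, st=st, sm=sm, v=v)
    sub_index = {p: i for i, p in enumerate(sub_periods)}
    scanner_ids = sorted(production["scanner_id"].unique().tolist())
    image_ids = sorted(production["image_id"].unique().tolist())
    s_map = {x: i for i, x in enumerate(scanner_ids)}
    c_map = {x: i for i, x in enumerate(image_ids)}
    keep = [i for i, p in enumerate(prod_periods) if p in sub_index]
    sub = production.iloc[keep]
    t = np.array([sub_index[prod_periods[i]] for i in keep])
    s = np.array([s_map[x] for x in sub["scanner_id"]])
    c = np.array([c_map[x] for x in sub["image_id"]])
    obs = ProductionObservations(t=t, s=s, c=c,
                                 value=sub["production"].to_numpy(float),
                                 S=len(scanner_ids), C=len(image_ids))
    return ModelData(forcing=trimmed, obs=obs, scanner_ids=scanner_ids,
                     image_ids=image_ids)
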