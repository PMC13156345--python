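"""Nicotine-metabolite-ratio (NMR) endpoints and the slope approach.

The NMR — the plasma concentration ratio 3-hydroxycotinine/cotinine — is a
phenotypic index of CYP2A6 activity (3-hydroxycotinine formation is
CYP2A6-specific).  Beyond the classic fixed-time NMR, this module computes:

- the 3–8 h partial-AUC ratio of the two metabolites, and
- the "slope approach": the OLS slope of NMR vs. time, over all
  quantifiable points and over the most-linear window running from the tmax
  of cotinine to the tmax of 3-hydroxycotinine (the interval where cotinine
  is past its peak and 3-hydroxycotinine is still forming, so the ratio
  rises without curvature).

Comparing the slope between study periods (as a geometric mean ratio)
distinguishes time-dependent enzyme inactivation (slope falls) from no
inhibition or an inhibitor that was itself cleared (slopes parallel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nca import ConcentrationTimeProfile, auc_interval, cmax_tmax, profile_from_records

__all__ = [
    "NMRSeries",
    "NMRSlopeResult",
    "classify_pattern",
    "fit_nmr_slope",
    "nmr_at_times",
    "nmr_dataset",
    "nmr_series",
    "partial_auc_ratio",
]

DEFAULT_NMR_TIMES_H = (4.0, 6.0, 8.0)
PARTIAL_AUC_WINDOW_H = (3.0, 8.0)


@dataclass
class NMRSeries:
    """Metabolite ratio at the nominal times where both analytes are quantifiable."""

    times_h: np.ndarray
    nmr_values: np.ndarray

    @property
    def n_points(self) -> int:
        return int(self.times_h.size)


@dataclass
class NMRSlopeResult:
    """Slope-approach endpoints for one subject × period."""

    slope_all: float = math.nan
    slope_linear: float = math.nan
    window: tuple[float, float] = (math.nan, math.nan)
    n_points_all: int = 0
    n_points_linear: int = 0
    pauc_ratio_3_8: float = math.nan
    nmr_at: dict = field(default_factory=dict)


def _check_shared_grid(cot: ConcentrationTimeProfile, ohc: ConcentrationTimeProfile) -> None:
    if cot.times_h.size != ohc.times_h.size or not np.allclose(cot.times_h, ohc.times_h):
        raise ValueError("cotinine and 3-hydroxycotinine profiles must share the nominal grid")


def nmr_series(
    cot_profile: ConcentrationTimeProfile, ohc_profile: ConcentrationTimeProfile
) -> NMRSeries:
    """NMR at every nominal time where both metabolites are quantifiable.

    Points where either analyte is censored, or cotinine is zero, are
    excluded (never an infinity).
    """
    _check_shared_grid(cot_profile, ohc_profile)
    ok = (
        ~cot_profile.censored
        & ~ohc_profile.censored
        & (cot_profile.conc_nM > 0)
    )
    return NMRSeries(
        times_h=cot_profile.times_h[ok],
        nmr_values=ohc_profile.conc_nM[ok] / cot_profile.conc_nM[ok],
    )


def nmr_at_times(
    cot_profile: ConcentrationTimeProfile,
    ohc_profile: ConcentrationTimeProfile,
    times=DEFAULT_NMR_TIMES_H,
) -> dict[float, float]:
    """NMR at the requested nominal times; missing times map to NaN."""
    series = nmr_series(cot_profile, ohc_profile)
    lookup = dict(zip(series.times_h, series.nmr_values))
    return {float(t): float(lookup.get(float(t), math.nan)) for t in times}


def partial_auc_ratio(
    cot_profile: ConcentrationTimeProfile,
    ohc_profile: ConcentrationTimeProfile,
    t_start: float = PARTIAL_AUC_WINDOW_H[0],
    t_end: float = PARTIAL_AUC_WINDOW_H[1],
    convention: str = "metabolite_auc_ratio",
) -> float:
    """Partial-AUC ratio over [t_start, t_end] (default 3–8 h).

    ``metabolite_auc_ratio`` (default) computes AUC(3-hydroxycotinine) /
    AUC(cotinine), each metabolite integrated separately.  The alternative
    ``auc_of_ratio`` integrates the NMR series itself and divides by the
    window length (a time-averaged NMR); both read ≈ the same number when
    the ratio is near-linear in time.  NaN when either integral is missing.
    """
    if convention == "metabolite_auc_ratio":
        auc_ohc = auc_interval(ohc_profile, t_start, t_end)
        auc_cot = auc_interval(cot_profile, t_start, t_end)
        if math.isnan(auc_ohc) or math.isnan(auc_cot) or auc_cot == 0:
            return math.nan
        return auc_ohc / auc_cot
    if convention == "auc_of_ratio":
        series = nmr_series(cot_profile, ohc_profile)
        prof = ConcentrationTimeProfile(
            analyte="nmr", times_h=series.times_h, conc_nM=series.nmr_values
        )
        auc = auc_interval(prof, t_start, t_end, method="linear")
        return auc / (t_end - t_start) if math.isfinite(auc) else math.nan
    raise ValueError(f"unknown convention {convention!r}")


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def fit_nmr_slope(
    cot_profile: ConcentrationTimeProfile,
    ohc_profile: ConcentrationTimeProfile,
    pauc_convention: str = "metabolite_auc_ratio",
) -> NMRSlopeResult:
    """Slope-approach fit for one subject × period.

    ``slope_all`` is the OLS slope of NMR vs. time over every usable point;
    ``slope_linear`` restricts to the window [tmax(cotinine),
    tmax(3-hydroxycotinine)].  Either slope needs at least three points, else
    it is NaN.  The partial-AUC ratio and the fixed-time NMRs ride along.
    """
    res = NMRSlopeResult()
    series = nmr_series(cot_profile, ohc_profile)
    res.n_points_all = series.n_points
    res.pauc_ratio_3_8 = partial_auc_ratio(
        cot_profile, ohc_profile, convention=pauc_convention
    )
    res.nmr_at = nmr_at_times(cot_profile, ohc_profile)
    if series.n_points < 3:
        return res
    res.slope_all = _ols_slope(series.times_h, series.nmr_values)

    _, tmax_cot = cmax_tmax(cot_profile)
    _, tmax_ohc = cmax_tmax(ohc_profile)
    if math.isnan(tmax_cot) or math.isnan(tmax_ohc) or not tmax_cot < tmax_ohc:
        return res
    res.window = (tmax_cot, tmax_ohc)
    in_win = (series.times_h >= tmax_cot) & (series.times_h <= tmax_ohc)
    res.n_points_linear = int(in_win.sum())
    if res.n_points_linear >= 3:
        res.slope_linear = _ols_slope(series.times_h[in_win], series.nmr_values[in_win])
    return res


def classify_pattern(
    baseline: NMRSlopeResult, exposure: NMRSlopeResult, rel_tol: float = 0.10
) -> str:
    """Classify the between-period slope pattern.

    ``parallel`` (ratio within ±rel_tol of 1): no inhibition, or the
    inhibitor was cleared so enzyme activity returned to baseline;
    ``reduced_slope`` (ratio < 1 − rel_tol): inhibition accrued with time;
    ``increased_slope`` otherwise.  Uses the linear-window slopes; undefined
    (raises) when either is missing.
    """
    if math.isnan(baseline.slope_linear) or math.isnan(exposure.slope_linear):
        raise ValueError("classification needs both linear-window slopes")
    if baseline.slope_linear == 0:
        raise ValueError("baseline slope is zero; pattern undefined")
    ratio = exposure.slope_linear / baseline.slope_linear
    if abs(ratio - 1.0) <= rel_tol:
        return "parallel"
    return "reduced_slope" if ratio < 1.0 else "increased_slope"


def nmr_dataset(
    records: pd.DataFrame,
    cotinine: str = "cotinine",
    hydroxycotinine: str = "3-hydroxycotinine",
    rel_tol: float = 0.10,
    pauc_convention: str = "metabolite_auc_ratio",
) -> pd.DataFrame:
    """Per-subject × period NMR endpoint table over a long-format dataset.

    Adds a ``pattern`` column (exposure rows) when both periods yield a
    linear-window slope.
    """
    rows = []
    results: dict[tuple[str, str], NMRSlopeResult] = {}
    for (subject, period), grp in records.groupby(["subject_id", "period"], sort=False):
        cot = grp[grp.analyte == cotinine]
        ohc = grp[grp.analyte == hydroxycotinine]
        if cot.empty or ohc.empty:
            continue
        res = fit_nmr_slope(
            profile_from_records(cot),
            profile_from_records(ohc),
            pauc_convention=pauc_convention,
        )
        results[(subject, period)] = res
        row = {
            "subject_id": subject,
            "period": period,
            "pauc_ratio_3_8": res.pauc_ratio_3_8,
            "slope_all": res.slope_all,
            "slope_linear": res.slope_linear,
            "window_start_h": res.window[0],
            "window_end_h": res.window[1],
            "n_points_all": res.n_points_all,
            "n_points_linear": res.n_points_linear,
            "pattern": "",
        }
        for t, v in res.nmr_at.items():
            row[f"nmr_{t:g}h"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    for i, row in df.iterrows():
        if row["period"] != "exposure":
            continue
        base = results.get((row["subject_id"], "baseline"))
        expo = results.get((row["subject_id"], "exposure"))
        if base is None or expo is None:
            continue
        if math.isnan(base.slope_linear) or math.isnan(expo.slope_linear) or base.slope_linear == 0:
            continue
        df.at[i, "pattern"] = classify_pattern(base, expo, rel_tol=rel_tol)
    return df
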