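"""Cross-study synthesis of acidification effects on larval mortality.

Works on a tidy table of published rearing experiments (one row per
replicate: study, species, experiment id, treatment label, pCO2 in
μatm, pH on the NBS scale, exposure duration in days, daily mortality
rate, optional species larval size in mm).  "Added mortality" — a
replicate's daily mortality minus the mean ambient-treatment mortality
of its own experiment — removes between-species baseline differences so
the acidification effect can be pooled across heterogeneous studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traits import relative_survival

META_COLUMNS = (
    "study",
    "species",
    "experiment_id",
    "treatment",
    "pco2_uatm",
    "ph_nbs",
    "duration_days",
    "daily_mortality",
)


def read_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"meta table missing columns: {missing}")
    return df


def added_mortality(meta: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``added_mortality`` column, per experiment.

    Subtracts each experiment's mean ambient daily mortality from all of
    its replicates; errors if an experiment has no ambient replicate.
    """
    out = meta.copy()
    keys = ["study", "experiment_id"]
    ambient_mean = (
        out[out["treatment"] == "ambient"].groupby(keys)["daily_mortality"].mean()
    )
    exp_keys = out.set_index(keys).index
    missing = set(exp_keys.unique()) - set(ambient_mean.index)
    if missing:
        raise ValueError(f"experiments without an ambient replicate: {sorted(missing)}")
    out["added_mortality"] = (
        out["daily_mortality"].to_numpy() - ambient_mean.reindex(exp_keys).to_numpy()
    )
    return out


@dataclass
class SensitivitySlopes:
    """Mean acidification sensitivities of daily larval mortality.

    ``per_pco2``: added daily mortality per μatm pCO2 increase;
    ``per_ph``: added daily mortality per unit pH *decrease* (the raw
    regression slope on pH is negated so that a positive value means
    more mortality in more acidic water).
    """

    per_pco2: float
    per_pco2_se: float
    per_ph: float
    per_ph_se: float
    n: int


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.unique(x).size < 2:
        raise ValueError("degenerate predictor: need >= 2 distinct values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr)


def sensitivity_slopes(meta: pd.DataFrame, per_species: bool = False) -> SensitivitySlopes:
    """OLS slopes of added mortality on pCO2 and (negated) on pH.

    By default a single pooled regression over all replicates; with
    ``per_species=True``, one slope per species is fitted and the plain
    average of species slopes is returned (the standard errors are then
    the standard errors of that mean).
    """
    df = meta if "added_mortality" in meta.columns else added_mortality(meta)
    if per_species:
        sl_co2, sl_ph = [], []
        for _, grp in df.groupby("species"):
            x1 = grp["pco2_uatm"].to_numpy(dtype=float)
            x2 = grp["ph_nbs"].to_numpy(dtype=float)
            y = grp["added_mortality"].to_numpy(dtype=float)
            if np.unique(x1).size >= 2:
                sl_co2.append(_ols_slope(x1, y)[0])
            if np.unique(x2).size >= 2:
                sl_ph.append(-_ols_slope(x2, y)[0])
        if not sl_co2 or not sl_ph:
            raise ValueError("no species with >= 2 distinct exposure levels")
        return SensitivitySlopes(
            per_pco2=float(np.mean(sl_co2)),
            per_pco2_se=float(np.std(sl_co2, ddof=1) / np.sqrt(len(sl_co2)))
            if len(sl_co2) > 1
            else np.nan,
            per_ph=float(np.mean(sl_ph)),
            per_ph_se=float(np.std(sl_ph, ddof=1) / np.sqrt(len(sl_ph)))
            if len(sl_ph) > 1
            else np.nan,
            n=len(df),
        )
    x1 = df["pco2_uatm"].to_numpy(dtype=float)
    x2 = df["ph_nbs"].to_numpy(dtype=float)
    y = df["added_mortality"].to_numpy(dtype=float)
    s1, se1 = _ols_slope(x1, y)
    s2, se2 = _ols_slope(x2, y)
    return SensitivitySlopes(
        per_pco2=s1, per_pco2_se=se1, per_ph=-s2, per_ph_se=se2, n=len(df)
    )


def project_survival_curve(
    slope: float, driver_rate_per_year: float, years, exposure_days: float
) -> np.ndarray:
    """Relative larval survival as an acidification driver accumulates.

    After ``years`` of driver change at ``driver_rate_per_year`` (μatm
    pCO2 per year, or pH units per year with the per-pH-decrease slope),
    the added daily mortality is slope * rate * years and relative
    survival over one larval episode of ``exposure_days`` is
    exp(-added_mortality * exposure_days).
    """
    if slope < 0 or driver_rate_per_year < 0 or exposure_days < 0:
        raise ValueError("slope, rate and exposure must be non-negative")
    years = np.asarray(years, dtype=float)
    if np.any(years < 0):
        raise ValueError("years must be non-negative")
    delta_m = slope * driver_rate_per_year * years
    return np.vectorize(lambda dm: relative_survival(dm, exposure_days))(delta_m)


def correlation_test(x, y) -> tuple[float, float, int, float]:
    """Pearson correlation with its t test.

    Returns (r, t, df, two-sided p) with t = r sqrt(df / (1 - r^2)) and
    df = n - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        return r, float(np.inf * np.sign(r)), df, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, float(t), df, p
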