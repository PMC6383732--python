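"""Tank-level trait estimation and treatment contrasts.

The two analysis traits per tank are (i) the daily mortality rate,
estimated as the negative slope of an ordinary least-squares regression
of ln(survivors) on day, and (ii) growth, the change in mean standard
length over the experiment.  Treatment-level contrasts use spawning-event
blocks as replicates in a paired t test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class TraitError(ValueError):
    """Raised when a trait cannot be estimated from the given records."""


def mortality_rate(counts) -> float:
    """Daily mortality rate from a survivor count series.

    OLS slope of ln(N_t) on t over the days with N_t > 0 (days after the
    tank empties carry no information and ln(0) is undefined); the rate
    is the negated slope.  At least two positive counts are required.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise TraitError("need a series of at least two daily counts")
    if np.any(np.diff(counts) > 0):
        raise TraitError("survivor counts must be non-increasing")
    if counts[0] <= 0:
        raise TraitError("initial count must be positive")
    days = np.nonzero(counts > 0)[0]
    if days.size < 2:
        raise TraitError("fewer than two positive counts; rate undefined")
    slope = np.polyfit(days, np.log(counts[days]), 1)[0]
    return -slope


def growth(day0_lengths, day14_lengths) -> float:
    """Change in mean standard length (mm) between day 0 and day 14."""
    day0 = np.asarray(day0_lengths, dtype=float)
    day14 = np.asarray(day14_lengths, dtype=float)
    if day0.size == 0 or day14.size == 0:
        raise TraitError("length samples must be non-empty")
    return float(day14.mean() - day0.mean())


def relative_survival(delta_m: float, days: float) -> float:
    """Survival relative to controls after `days` of added mortality.

    An added daily mortality rate Δm sustained for D days multiplies
    survivorship by exp(-Δm D); the percentage decrease in relative
    survival is 100 * (1 - exp(-Δm D)).
    """
    if days < 0:
        raise ValueError("days must be >= 0")
    return float(np.exp(-delta_m * days))


def survival_decrease_percent(delta_m: float, days: float) -> float:
    """Percentage decrease in relative survival, 100 * (1 - exp(-Δm D))."""
    return 100.0 * (1.0 - relative_survival(delta_m, days))


def paired_block_test(ambient_by_block, acidified_by_block):
    """Paired t test across blocks for a treatment effect.

    Returns (mean difference acidified - ambient, t, df, two-sided p)
    with df = n_blocks - 1.
    """
    amb = np.asarray(ambient_by_block, dtype=float)
    acid = np.asarray(acidified_by_block, dtype=float)
    if amb.shape != acid.shape or amb.ndim != 1:
        raise ValueError("block-mean vectors must be 1-D and equal length")
    n = amb.size
    if n < 2:
        raise ValueError("need at least two blocks")
    diff = acid - amb
    mean_diff = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if mean_diff == 0 else np.inf * np.sign(mean_diff)
    else:
        t = mean_diff / (sd / np.sqrt(n))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(mean_diff), float(t), df, p


def block_means(trait_table: pd.DataFrame, trait: str = "mortality_rate") -> pd.DataFrame:
    """Mean of a trait per block x treatment (blocks as replicates).

    Returns a frame indexed by block with one column per treatment.
    Raises if any block lacks tanks in either treatment.
    """
    if trait not in trait_table.columns:
        raise KeyError(f"trait column {trait!r} not in table")
    wide = (
        trait_table.groupby(["block", "treatment"], sort=True)[trait]
        .mean()
        .unstack("treatment")
    )
    for trt in ("ambient", "acidified"):
        if trt not in wide.columns:
            raise TraitError(f"no {trt} tanks in any block")
        missing = wide.index[wide[trt].isna()].tolist()
        if missing:
            raise TraitError(f"block(s) {missing} have no {trt} tanks")
    return wide[["ambient", "acidified"]]


def estimate_traits(
    tanks: pd.DataFrame, counts: pd.DataFrame, lengths: pd.DataFrame
) -> pd.DataFrame:
    """Per-tank trait table from raw count and length observations.

    Joins the tank metadata with the estimated daily mortality rate and
    growth of each tank; each tank observes the two traits of its own
    treatment only.
    """
    counts_by_tank = {
        tid: grp.sort_values("day")["n_alive"].to_numpy()
        for tid, grp in counts.groupby("tank_id")
    }
    day_max = int(lengths["day"].max())
    rows = []
    for rec in tanks.itertuples():
        if rec.tank_id not in counts_by_tank:
            raise TraitError(f"tank {rec.tank_id} has no count records")
        sub = lengths[lengths["tank_id"] == rec.tank_id]
        l0 = sub.loc[sub["day"] == 0, "length_mm"].to_numpy()
        l1 = sub.loc[sub["day"] == day_max, "length_mm"].to_numpy()
        rows.append(
            {
                "tank_id": rec.tank_id,
                "family_id": rec.family_id,
                "sire_id": rec.sire_id,
                "dam_id": rec.dam_id,
                "block": rec.block,
                "treatment": rec.treatment,
                "mortality_rate": mortality_rate(counts_by_tank[rec.tank_id]),
                "growth": growth(l0, l1),
            }
        )
    return pd.DataFrame(rows)
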