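"""Schema and referential-integrity checks for the pipeline's CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SCHEMAS = {
    "pedigree": ["id", "sire", "dam"],
    "tanks": ["tank_id", "family_id", "sire_id", "dam_id", "block", "treatment"],
    "counts": ["tank_id", "day", "n_alive"],
    "lengths": ["tank_id", "day", "length_mm"],
}
TREATMENT_VOCAB = {"ambient", "acidified"}


def validate_tables(paths: dict[str, str | Path]) -> list[str]:
    """Validate the simulate/observe tables; return a list of violations.

    Checks column schemas, tank -> pedigree and counts/lengths -> tanks
    referential integrity, non-increasing survivor counts, and the
    treatment vocabulary.  An empty list means all checks passed.
    """
    violations: list[str] = []
    frames: dict[str, pd.DataFrame] = {}
    for name, cols in SCHEMAS.items():
        if name not in paths:
            violations.append(f"{name}: path not provided")
            continue
        path = Path(paths[name])
        if not path.exists():
            violations.append(f"{name}: file {path} does not exist")
            continue
        df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str, "tank_id": str})
        missing = [c for c in cols if c not in df.columns]
        if missing:
            violations.append(f"{path.name}: missing columns {missing}")
            continue
        frames[name] = df

    ped = frames.get("pedigree")
    tanks = frames.get("tanks")
    if ped is not None:
        ids = set(ped["id"])
        for col in ("sire", "dam"):
            for row, parent in enumerate(ped[col].fillna("")):
                if parent and parent not in ids:
                    violations.append(
                        f"pedigree.csv row {row + 2} column {col}: unknown parent {parent!r}"
                    )
    if tanks is not None:
        for row, trt in enumerate(tanks["treatment"]):
            if trt not in TREATMENT_VOCAB:
                violations.append(
                    f"tanks.csv row {row + 2} column treatment: "
                    f"{trt!r} not in {sorted(TREATMENT_VOCAB)}"
                )
        if ped is not None:
            ids = set(ped["id"])
            for row, rec in enumerate(tanks.itertuples()):
                for col, val in (
                    ("tank_id", rec.tank_id),
                    ("sire_id", rec.sire_id),
                    ("dam_id", rec.dam_id),
                ):
                    if str(val) not in ids:
                        violations.append(
                            f"tanks.csv row {row + 2} column {col}: "
                            f"{val!r} not in pedigree"
                        )
        tank_ids = set(tanks["tank_id"].astype(str))
        for name in ("counts", "lengths"):
            df = frames.get(name)
            if df is None:
                continue
            unknown = sorted(set(df["tank_id"].astype(str)) - tank_ids)
            if unknown:
                violations.append(f"{name}.csv column tank_id: unknown tanks {unknown[:5]}")

    counts = frames.get("counts")
    if counts is not None:
        for tid, grp in counts.sort_values("day").groupby("tank_id"):
            series = grp["n_alive"].to_numpy()
            if np.any(np.diff(series) > 0):
                day = int(grp["day"].to_numpy()[np.argmax(np.diff(series) > 0) + 1])
                violations.append(
                    f"counts.csv tank {tid} day {day} column n_alive: count increased"
                )
            if np.any(series < 0):
                violations.append(f"counts.csv tank {tid}: negative count")
    return violations
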