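"""Tidy-CSV readers and writers for dissolution profiles.

The on-disk format is long/tidy, one measurement per row, with columns
``formulation, sav_mm_inv, replicate, time_min, released_pct`` (comma
separated, dot decimal, UTF-8).  Profiles are grouped by
(formulation, SA/V, replicate).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .profiles import ReleaseProfile

__all__ = ["PROFILE_COLUMNS", "read_profiles", "write_profiles", "profiles_to_frame"]

PROFILE_COLUMNS = ("formulation", "sav_mm_inv", "replicate", "time_min", "released_pct")


def read_profiles(path: str | Path) -> list[ReleaseProfile]:
    """Parse a tidy profile CSV into validated :class:`ReleaseProfile` groups.

    Raises :class:`~savrelease.exceptions.DomainError` naming the offending
    row (1-based, counting the header) for missing columns, non-numeric
    cells or duplicated time points within one replicate.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    missing = set(PROFILE_COLUMNS) - set(frame.columns)
    if missing:
        raise DomainError(f"{path.name}: missing column(s) {sorted(missing)}")
    for column in ("sav_mm_inv", "time_min", "released_pct"):
        converted = pd.to_numeric(frame[column], errors="coerce")
        bad = frame.index[converted.isna() & frame[column].notna()]
        if frame[column].isna().any():
            bad = bad.union(frame.index[frame[column].isna()])
        if len(bad):
            raise DomainError(
                f"{path.name}: non-numeric {column} at row {int(bad[0]) + 2}"
            )
        frame[column] = converted
    frame["replicate"] = pd.to_numeric(frame["replicate"], errors="coerce").astype("Int64")
    if frame["replicate"].isna().any():
        row = int(frame.index[frame["replicate"].isna()][0]) + 2
        raise DomainError(f"{path.name}: non-numeric replicate at row {row}")

    profiles = []
    for (formulation, sav, replicate), group in frame.groupby(
        ["formulation", "sav_mm_inv", "replicate"], sort=True
    ):
        dup = group["time_min"].duplicated()
        if dup.any():
            row = int(group.index[dup][0]) + 2
            raise DomainError(
                f"{path.name}: duplicated time point in profile "
                f"({formulation}, SA/V={sav}, rep={replicate}) at row {row}"
            )
        group = group.sort_values("time_min")
        profiles.append(
            ReleaseProfile(
                times=group["time_min"].to_numpy(dtype=float),
                releases=group["released_pct"].to_numpy(dtype=float),
                replicate=int(replicate),
                formulation=str(formulation),
                sav=float(sav),
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[ReleaseProfile]) -> pd.DataFrame:
    """Long/tidy DataFrame of a profile collection."""
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.releases):
            rows.append(
                {
                    "formulation": p.formulation or "",
                    "sav_mm_inv": p.sav if p.sav is not None else np.nan,
                    "replicate": p.replicate if p.replicate is not None else 1,
                    "time_min": t,
                    "released_pct": c,
                }
            )
    return pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))


def write_profiles(profiles: Sequence[ReleaseProfile], path: str | Path) -> None:
    """Write profiles as tidy CSV (full float precision, reproducible)."""
    profiles_to_frame(profiles).to_csv(path, index=False, float_format="%.10g")
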