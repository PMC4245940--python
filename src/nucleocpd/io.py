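"""Reading and writing the tabular formats the pipeline consumes."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .footprint import CleavageProfile
from .kinetics import BandMeasurement, DeaminationFit, TimeCourse

__all__ = [
    "read_time_courses",
    "write_time_courses",
    "read_cleavage_profile",
    "write_cleavage_profile",
    "fits_to_frame",
    "write_fit_report",
    "read_fit_report",
]

_TC_COLUMNS = ["site_id", "time_h", "intensity_mC", "intensity_T", "is_terminal"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_time_courses(path: str | Path) -> list[TimeCourse]:
    """Load per-aliquot band intensities (CSV or TSV).

    Expected columns: ``site_id, time_h, intensity_mC, intensity_T,
    is_terminal`` with exactly one terminal row per site.
    """
    df = _read_table(path)
    missing = [c for c in _TC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    courses = []
    for site_id, group in df.groupby("site_id", sort=False):
        terminal_rows = group[group.is_terminal.astype(int) == 1]
        if len(terminal_rows) != 1:
            raise ValueError(
                f"{path}: site {site_id!r} needs exactly one terminal row, "
                f"found {len(terminal_rows)}"
            )
        timed = group[group.is_terminal.astype(int) == 0].sort_values("time_h")
        measurements = tuple(
            BandMeasurement(row.time_h, row.intensity_mC, row.intensity_T)
            for row in timed.itertuples()
        )
        term = terminal_rows.iloc[0]
        courses.append(
            TimeCourse(
                site_id=str(site_id),
                measurements=measurements,
                terminal=BandMeasurement(
                    term.time_h, term.intensity_mC, term.intensity_T
                ),
            )
        )
    return courses


def write_time_courses(courses: Iterable[TimeCourse], path: str | Path) -> None:
    rows = []
    for tc in courses:
        for m in tc.measurements:
            rows.append((tc.site_id, m.time_h, m.intensity_mC, m.intensity_T, 0))
        t = tc.terminal
        rows.append((tc.site_id, t.time_h, t.intensity_mC, t.intensity_T, 1))
    df = pd.DataFrame(rows, columns=_TC_COLUMNS)
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)


def read_cleavage_profile(path: str | Path) -> CleavageProfile:
    """Load a (position, intensity) table as a cleavage profile."""
    df = _read_table(path)
    for col in ("position", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.sort_values("position")
    return CleavageProfile(
        positions=df.position.to_numpy(dtype=float),
        intensities=df.intensity.to_numpy(dtype=float),
    )


def write_cleavage_profile(profile: CleavageProfile, path: str | Path) -> None:
    df = pd.DataFrame({"position": profile.positions, "intensity": profile.intensities})
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)


def fits_to_frame(fits: Sequence[DeaminationFit]) -> pd.DataFrame:
    """Tabulate fits with units in the column names."""
    return pd.DataFrame(
        {
            "site_id": [f.site_id for f in fits],
            "k_per_h": [f.k for f in fits],
            "k_se_per_h": [f.k_se for f in fits],
            "half_life_h": [f.half_life_h for f in fits],
            "half_life_se_h": [f.half_life_se_h for f in fits],
            "yield_percent": [f.yield_percent for f in fits],
            "intercept": [f.intercept for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "n_points": [f.n_points for f in fits],
            "n_excluded": [f.n_excluded for f in fits],
            "valid": [f.valid for f in fits],
        }
    )


def write_fit_report(fits: Sequence[DeaminationFit], path: str | Path) -> None:
    """Write a fit table as TSV/CSV or JSON, by extension."""
    df = fits_to_frame(fits)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2))
    else:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df.to_csv(path, sep=sep, index=False)


def read_fit_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return _read_table(path)
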