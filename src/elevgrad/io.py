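"""Reading and writing the survey's tabular files.

All tables are comma-separated (``.tsv`` paths switch to tabs), UTF-8,
with a header row and ``.`` as the decimal mark.  Reported elevations
are snapped to the nearest design band when within a tolerance (default
±25 m, matching a trapping design whose stations sit within 25 m of each
transect line); anything further off is an error, never silently
dropped.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CaptureRecord, SpeciesTraits
from .drivers import BandCovariates

__all__ = [
    "read_captures",
    "read_traits",
    "read_covariates",
    "write_captures",
    "write_traits",
    "write_covariates",
]

CAPTURE_COLUMNS = ("species", "slope", "elevation", "season", "count")
TRAIT_COLUMNS = ("species", "taxon_group", "endemic")
COVARIATE_COLUMNS = ("slope", "elevation", "area", "MAT", "MAH", "NDVI", "PSR")


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    return df


def snap_elevation(value: float, bands: Sequence[int], tolerance: float = 25.0) -> int:
    """Nearest design band within ``tolerance`` meters, else an error."""
    bands = np.asarray(sorted(bands), dtype=float)
    idx = int(np.argmin(np.abs(bands - value)))
    if abs(bands[idx] - value) > tolerance:
        raise ValueError(
            f"elevation {value} is more than {tolerance} m from every "
            f"design band {bands.astype(int).tolist()}"
        )
    return int(bands[idx])


def read_captures(
    path, bands: Sequence[int], tolerance: float = 25.0
) -> list[CaptureRecord]:
    """Parse a captures CSV/TSV into validated records.

    Elevations are snapped to design bands within ``tolerance``; rows
    that fail validation are reported with their (1-based, header
    excluded) line number.
    """
    df = _read_table(path, CAPTURE_COLUMNS)
    records = []
    for i, row in df.iterrows():
        try:
            elev = snap_elevation(float(row["elevation"]), bands, tolerance)
            records.append(
                CaptureRecord(
                    species=str(row["species"]),
                    slope=str(row["slope"]),
                    elevation=elev,
                    season=str(row["season"]),
                    count=int(row["count"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{Path(path).name}, row {i + 1}: {exc}") from exc
    return records


def read_traits(path) -> dict[str, SpeciesTraits]:
    df = _read_table(path, TRAIT_COLUMNS)
    out: dict[str, SpeciesTraits] = {}
    for i, row in df.iterrows():
        sp = str(row["species"])
        if sp in out:
            raise ValueError(f"{Path(path).name}: duplicate species {sp!r}")
        endemic = row["endemic"]
        if isinstance(endemic, str):
            endemic = endemic.strip().lower() in ("true", "1", "yes")
        out[sp] = SpeciesTraits(
            species=sp, taxon_group=str(row["taxon_group"]), endemic=bool(endemic)
        )
    return out


def read_covariates(path) -> pd.DataFrame:
    """One row per slope x band; duplicates and out-of-range values error.

    Missing numeric cells are kept as NaN and reported, never dropped.
    """
    df = _read_table(path, COVARIATE_COLUMNS)
    dup = df.duplicated(subset=["slope", "elevation"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["slope", "elevation"]].drop_duplicates()
        raise ValueError(
            f"{Path(path).name}: duplicate slope x band row(s): "
            f"{[tuple(r) for r in keys.to_numpy()]}"
        )
    for _, row in df.iterrows():
        # validates area > 0 and NDVI in [-1, 1]
        BandCovariates(
            slope=str(row["slope"]),
            elevation=int(row["elevation"]),
            area=float(row["area"]),
            MAT=float(row["MAT"]),
            MAH=float(row["MAH"]),
            NDVI=float(row["NDVI"]),
            PSR=float(row["PSR"]),
        )
    na = df[list(COVARIATE_COLUMNS)].isna()
    if na.to_numpy().any():
        cells = [(int(i), c) for i, c in zip(*np.where(na.to_numpy()))]
        raise ValueError(f"{Path(path).name}: missing value(s) at {cells}")
    return df


def write_captures(records, path) -> None:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "species": r.species,
                "slope": r.slope,
                "elevation": r.elevation,
                "season": r.season,
                "count": r.count,
            }
            for r in records
        ],
        columns=list(CAPTURE_COLUMNS),
    ).to_csv(path, sep=_sep(path), index=False)


def write_traits(traits, path) -> None:
    path = Path(path)
    pd.DataFrame(
        [
            {"species": t.species, "taxon_group": t.taxon_group, "endemic": t.endemic}
            for t in sorted(traits.values(), key=lambda t: t.species)
        ],
        columns=list(TRAIT_COLUMNS),
    ).to_csv(path, sep=_sep(path), index=False)


def write_covariates(covariates: pd.DataFrame, path) -> None:
    path = Path(path)
    covariates.to_csv(path, sep=_sep(path), index=False)
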