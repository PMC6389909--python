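"""Reading and writing plate exports and ligand maps.

Melt tables are wide delimited text as exported by RT-PCR instruments:
the first column is temperature in Celsius, every further column one
well, with the header row carrying well labels.  ``.tsv``/``.txt`` files
are read tab-separated, anything else comma-separated.

The ligand map is a CSV with columns ``well``, ``ligand_conc_molar``
and ``replicate_group`` linking wells to assay conditions.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curves import MeltCurve

__all__ = [
    "MeltTableError",
    "read_melt_table",
    "write_melt_table",
    "read_ligand_map",
    "write_ligand_map",
]

_MAP_COLUMNS = ("well", "ligand_conc_molar", "replicate_group")


class MeltTableError(ValueError):
    """A plate export or ligand map could not be parsed."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_ligand_map(path) -> pd.DataFrame:
    """Ligand map as a DataFrame indexed by well label."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MAP_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise MeltTableError(f"ligand map {path} lacks column(s) {missing}")
    if "replicate_group" not in df.columns:
        df["replicate_group"] = df["well"]
    dup = df["well"][df["well"].duplicated()]
    if not dup.empty:
        raise MeltTableError(f"duplicate well(s) in ligand map: {sorted(set(dup))}")
    if not np.issubdtype(df["ligand_conc_molar"].dtype, np.number):
        bad = df.loc[pd.to_numeric(df["ligand_conc_molar"], errors="coerce").isna(), "well"]
        raise MeltTableError(
            f"non-numeric ligand_conc_molar for well(s) {list(bad)}"
        )
    if (df["ligand_conc_molar"] < 0).any():
        raise MeltTableError("negative ligand concentrations in map")
    return df.set_index("well")


def read_melt_table(
    path,
    ligand_map_path=None,
    *,
    normalized: bool = False,
) -> list[MeltCurve]:
    """Read a wide melt table (plus optional ligand map) into curves.

    Without a map every column becomes a zero-ligand curve labelled by its
    well.  With a map, only mapped wells are returned (unmapped columns
    are warned about and skipped); a map entry pointing to an absent well
    raises :class:`MeltTableError` naming the well.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise MeltTableError(f"{path}: need a temperature column plus >= 1 well")
    cols = list(df.columns)
    dupes = {c for c in cols if cols.count(c) > 1}
    if dupes:
        raise MeltTableError(f"{path}: duplicate well column(s) {sorted(dupes)}")
    for c in cols:
        if not np.issubdtype(df[c].dtype, np.number):
            bad_rows = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            raise MeltTableError(
                f"{path}: non-numeric value in column {c!r}, row(s) "
                f"{list(bad_rows[:5])}"
            )
    temp = df.iloc[:, 0].to_numpy(dtype=float)
    wells = cols[1:]

    if ligand_map_path is None:
        return [
            MeltCurve(temp, df[w].to_numpy(dtype=float), ligand_conc_total=0.0,
                      replicate_id=w, well=w, normalized=normalized)
            for w in wells
        ]

    lmap = read_ligand_map(ligand_map_path)
    absent = [w for w in lmap.index if w not in wells]
    if absent:
        raise MeltTableError(
            f"ligand map references well(s) {absent} not present in {path}"
        )
    unmapped = [w for w in wells if w not in lmap.index]
    if unmapped:
        warnings.warn(f"skipping unmapped well(s): {unmapped}", stacklevel=2)
    curves = []
    for w in lmap.index:
        row = lmap.loc[w]
        curves.append(MeltCurve(
            temp, df[w].to_numpy(dtype=float),
            ligand_conc_total=float(row["ligand_conc_molar"]),
            replicate_id=str(row["replicate_group"]), well=w,
            normalized=normalized,
        ))
    return curves


def write_melt_table(path, curves: Sequence[MeltCurve]) -> None:
    """Write curves as a wide melt table; all curves must share a grid."""
    path = Path(path)
    t0 = curves[0].temperature
    for c in curves[1:]:
        if not np.array_equal(c.temperature, t0):
            raise MeltTableError("curves must share one temperature grid")
    data = {"temperature_C": t0}
    for i, c in enumerate(curves):
        data[c.well or f"W{i + 1:02d}"] = c.signal
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False)


def write_ligand_map(path, curves: Sequence[MeltCurve]) -> None:
    rows = [
        {"well": c.well or f"W{i + 1:02d}",
         "ligand_conc_molar": c.ligand_conc_total,
         "replicate_group": c.replicate_id or (c.well or f"W{i + 1:02d}")}
        for i, c in enumerate(curves)
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
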