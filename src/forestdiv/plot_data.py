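"""Stem-level inventory handling.

Reads and validates stem records from permanent-plot surveys, applies the
DBH inclusion threshold, and builds the species x sampling-unit abundance
and incidence tables that every downstream analysis consumes.

The reference survey design is two altitudinal belts (birch and pine-oak),
each with five stand types and five 30 x 30 m plots per stand; all stems
with diameter at breast height (DBH, 1.3 m) >= 5 cm are recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BIRCH",
    "PINEOAK",
    "STAND_BELT",
    "StemRecord",
    "PlotInfo",
    "AbundanceTable",
    "IncidenceTable",
    "read_stems",
    "read_plots",
    "write_stems",
    "write_plots",
    "filter_dbh",
    "abundance_table",
    "incidence_table",
    "basal_area",
    "load_taxonomy",
    "stand_summary",
]

BIRCH = "birch"
PINEOAK = "pine-oak"

#: Stand codes of the reference design and the belt each belongs to.
STAND_BELT: dict[str, str] = {
    "BA": BIRCH,
    "TCBA": BIRCH,
    "PABA": BIRCH,
    "CTBA": BIRCH,
    "AFBA": BIRCH,
    "PA": PINEOAK,
    "PT": PINEOAK,
    "QA": PINEOAK,
    "PAQA": PINEOAK,
    "PTQA": PINEOAK,
}

_STEM_COLUMNS = ["plot_id", "stand_code", "belt", "species", "dbh_cm", "height_m", "crown_m"]
_PLOT_COLUMNS = ["plot_id", "stand_code", "area_m2", "elevation_m"]


@dataclass(frozen=True)
class StemRecord:
    """One measured tree: where it stands, what it is, how big it is."""

    plot_id: str
    stand_code: str
    belt: str
    species: str
    dbh: float  # cm, > 0
    height: float | None = None  # m
    crown: float | None = None  # m

    def __post_init__(self) -> None:
        if not self.dbh > 0:
            raise ValueError(f"dbh must be positive, got {self.dbh!r} (plot {self.plot_id})")


@dataclass(frozen=True)
class PlotInfo:
    """A sampling unit (quadrat); the reference design uses 900 m2 plots."""

    plot_id: str
    stand_code: str
    area_m2: float = 900.0
    elevation_m: float | None = None

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise ValueError(f"area_m2 must be positive, got {self.area_m2!r}")


class AbundanceTable:
    """Species x sampling-unit count matrix with pooled totals.

    Parameters
    ----------
    counts
        DataFrame indexed by species, one column per unit (plot, stand or
        belt), nonnegative integer entries.
    """

    def __init__(self, counts: pd.DataFrame):
        if (counts.to_numpy() < 0).any():
            raise ValueError("abundance counts must be nonnegative")
        self.counts = counts.astype(int)

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def units(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def pooled(self) -> pd.Series:
        """Per-species totals n_i across all units."""
        return self.counts.sum(axis=1)

    @property
    def N(self) -> int:
        """Total number of individuals."""
        return int(self.counts.to_numpy().sum())

    @property
    def S_obs(self) -> int:
        """Number of species with at least one individual."""
        return int((self.pooled > 0).sum())

    def pooled_vector(self) -> np.ndarray:
        """Positive per-species totals as a plain array (order: table index)."""
        pooled = self.pooled
        return pooled[pooled > 0].to_numpy()

    def subset(self, units: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.counts[list(units)])

    def to_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AbundanceTable":
        return cls(pd.read_csv(path, index_col="species"))

    def __repr__(self) -> str:  # pragma: no cover
        return f"AbundanceTable(S={len(self.species)}, units={len(self.units)}, N={self.N})"


@dataclass
class IncidenceTable:
    """Species incidence frequencies over T sampling units.

    ``Y`` maps each species to the number of distinct units in which it
    occurs (0 <= Y_i <= T); ``U`` is the total incidence count.
    """

    Y: pd.Series
    T: int

    def __post_init__(self) -> None:
        if ((self.Y < 0) | (self.Y > self.T)).any():
            raise ValueError("incidence frequencies must lie in [0, T]")

    @property
    def U(self) -> int:
        return int(self.Y.sum())

    def frequencies(self) -> np.ndarray:
        """Positive incidence frequencies Y_i as an array."""
        y = self.Y[self.Y > 0]
        return y.to_numpy()


def _belt_for(stand_code: str, row: object = None) -> str:
    try:
        return STAND_BELT[stand_code]
    except KeyError:
        where = f" (row {row})" if row is not None else ""
        raise ValueError(
            f"unknown stand_code {stand_code!r}{where}; valid codes: "
            + ", ".join(sorted(STAND_BELT))
        ) from None


def read_stems(
    path: str | Path,
    plots_path: str | Path | None = None,
) -> tuple[list[StemRecord], list[PlotInfo]]:
    """Read a stems CSV (and optionally a plots CSV) into validated records.

    The stems file must carry ``plot_id, stand_code, species, dbh_cm``
    columns (``belt, height_m, crown_m`` optional; belt is re-derived from
    the stand code and checked if present). Without a plots file, one
    900 m2 ``PlotInfo`` per distinct plot_id is synthesised.
    """
    df = pd.read_csv(path)
    required = {"plot_id", "stand_code", "species", "dbh_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stems file {path} missing columns: {sorted(missing)}")

    stems: list[StemRecord] = []
    for idx, rec in enumerate(df.itertuples(index=False)):
        code = str(rec.stand_code)
        belt = _belt_for(code, row=idx)
        if "belt" in df.columns and str(rec.belt) not in ("nan", belt):
            raise ValueError(
                f"row {idx}: belt {rec.belt!r} inconsistent with stand {code!r} ({belt})"
            )
        dbh = float(rec.dbh_cm)
        if not dbh > 0:
            raise ValueError(f"row {idx}: nonpositive DBH {dbh}")
        height = float(rec.height_m) if "height_m" in df.columns and not pd.isna(rec.height_m) else None
        crown = float(rec.crown_m) if "crown_m" in df.columns and not pd.isna(rec.crown_m) else None
        stems.append(
            StemRecord(str(rec.plot_id), code, belt, str(rec.species), dbh, height, crown)
        )

    if plots_path is not None:
        plots = read_plots(plots_path)
    else:
        seen: dict[str, str] = {}
        for s in stems:
            seen.setdefault(s.plot_id, s.stand_code)
        plots = [PlotInfo(pid, code) for pid, code in seen.items()]
    return stems, plots


def read_plots(path: str | Path) -> list[PlotInfo]:
    df = pd.read_csv(path)
    plots = []
    for idx, rec in enumerate(df.itertuples(index=False)):
        _belt_for(str(rec.stand_code), row=idx)
        elev = float(rec.elevation_m) if "elevation_m" in df.columns and not pd.isna(rec.elevation_m) else None
        plots.append(PlotInfo(str(rec.plot_id), str(rec.stand_code), float(rec.area_m2), elev))
    return plots


def write_stems(stems: Iterable[StemRecord], path: str | Path) -> None:
    rows = [
        {
            "plot_id": s.plot_id,
            "stand_code": s.stand_code,
            "belt": s.belt,
            "species": s.species,
            "dbh_cm": s.dbh,
            "height_m": s.height,
            "crown_m": s.crown,
        }
        for s in stems
    ]
    pd.DataFrame(rows, columns=_STEM_COLUMNS).to_csv(path, index=False)


def write_plots(plots: Iterable[PlotInfo], path: str | Path) -> None:
    rows = [
        {
            "plot_id": p.plot_id,
            "stand_code": p.stand_code,
            "area_m2": p.area_m2,
            "elevation_m": p.elevation_m,
        }
        for p in plots
    ]
    pd.DataFrame(rows, columns=_PLOT_COLUMNS).to_csv(path, index=False)


def filter_dbh(stems: Sequence[StemRecord], threshold_cm: float = 5.0) -> list[StemRecord]:
    """Keep stems with DBH >= threshold (inclusive), preserving order."""
    if threshold_cm < 0:
        raise ValueError("threshold must be nonnegative")
    return [s for s in stems if s.dbh >= threshold_cm]


def _unit_of(stem: StemRecord, group_by: str) -> str:
    if group_by == "plot":
        return stem.plot_id
    if group_by == "stand":
        return stem.stand_code
    if group_by == "belt":
        return stem.belt
    raise ValueError(f"group_by must be 'plot', 'stand' or 'belt', got {group_by!r}")


def abundance_table(stems: Sequence[StemRecord], group_by: str = "stand") -> AbundanceTable:
    """Cross-tabulate stems into a species x unit count matrix."""
    if not stems:
        raise ValueError("cannot build an abundance table from zero stems")
    df = pd.DataFrame(
        {"species": [s.species for s in stems], "unit": [_unit_of(s, group_by) for s in stems]}
    )
    counts = pd.crosstab(df["species"], df["unit"])
    counts.index.name = "species"
    counts = counts.sort_index()
    return AbundanceTable(counts)


def incidence_table(
    stems: Sequence[StemRecord],
    plots: Sequence[PlotInfo] | None = None,
    unit: str = "plot",
) -> IncidenceTable:
    """Incidence frequencies Y_i = number of units where species i occurs.

    ``plots`` fixes T (units with zero stems still count); otherwise T is
    the number of distinct units present among the stems.
    """
    pairs = {( _unit_of(s, unit), s.species) for s in stems}
    if plots is not None and unit == "plot":
        all_units = {p.plot_id for p in plots}
    elif plots is not None and unit == "stand":
        all_units = {p.stand_code for p in plots}
    else:
        all_units = {u for u, _ in pairs}
    species = sorted({s.species for s in stems})
    y = pd.Series(
        {sp: sum(1 for u, s2 in pairs if s2 == sp and u in all_units) for sp in species},
        name="Y",
    )
    return IncidenceTable(Y=y, T=len(all_units))


def basal_area(dbh_cm: float | np.ndarray) -> float | np.ndarray:
    """Cross-sectional stem area pi * (DBH/2)^2, in m2 for DBH in cm."""
    arr = np.asarray(dbh_cm, dtype=float)
    if (arr <= 0).any():
        raise ValueError("dbh must be positive")
    out = math.pi * (arr / 200.0) ** 2
    return float(out) if np.isscalar(dbh_cm) or arr.ndim == 0 else out


def load_taxonomy() -> pd.DataFrame:
    """Packaged species -> genus -> family lookup (indexed by species)."""
    with resources.files("forestdiv.data").joinpath("taxonomy.csv").open() as fh:
        return pd.read_csv(fh).set_index("species")


def _taxon_of(species: str, taxonomy: pd.DataFrame, rank: str) -> str:
    if species in taxonomy.index:
        return str(taxonomy.loc[species, rank])
    return "unknown"


def stand_summary(
    stems: Sequence[StemRecord],
    plots: Sequence[PlotInfo],
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-stand attributes: taxon counts, DBH stats, basal area and density.

    Density and basal area are scaled per hectare using the summed area of
    the stand's plots. Species absent from the taxonomy lookup fall into an
    'unknown' genus/family bucket (with a warning).
    """
    import warnings

    if taxonomy is None:
        taxonomy = load_taxonomy()
    missing = sorted({s.species for s in stems} - set(taxonomy.index))
    if missing:
        warnings.warn(f"species missing from taxonomy, bucketed as 'unknown': {missing}")

    by_stand: dict[str, list[StemRecord]] = {}
    for s in stems:
        by_stand.setdefault(s.stand_code, []).append(s)
    area_ha = {
        code: sum(p.area_m2 for p in plots if p.stand_code == code) / 1e4 for code in by_stand
    }

    rows = []
    for code, group in sorted(by_stand.items()):
        dbh = np.array([s.dbh for s in group])
        species = {s.species for s in group}
        genera = {_taxon_of(sp, taxonomy, "genus") for sp in species}
        families = {_taxon_of(sp, taxonomy, "family") for sp in species}
        ha = area_ha[code]
        rows.append(
            {
                "stand_code": code,
                "belt": STAND_BELT.get(code, "unknown"),
                "n_plots": sum(1 for p in plots if p.stand_code == code),
                "n_stems": len(group),
                "n_species": len(species),
                "n_genera": len(genera),
                "n_families": len(families),
                "dbh_min": dbh.min(),
                "dbh_max": dbh.max(),
                "dbh_mean": dbh.mean(),
                "basal_area_ha": float(np.sum(basal_area(dbh)) / ha),
                "density_ha": len(group) / ha,
            }
        )
    return pd.DataFrame(rows).set_index("stand_code")
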