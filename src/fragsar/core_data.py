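"""Domain types, CSV input/output and the rare/common species classification.

The system under study is an archipelago of habitat patches (land-bridge
islands) carrying a species x island presence/absence matrix.  Islands are
described by three pre-digested geometric scalars: surface area (ha), edge
perimeter (m) and shortest island-edge-to-mainland-edge distance (m).

Species are split into "rare" and "common" by patch occupancy: a species
recorded on at most 10% of the islands (floor rule) is rare, otherwise
common.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Island",
    "Archipelago",
    "SpeciesOccupancy",
    "ValidationError",
    "FormatError",
    "read_island_table",
    "write_island_table",
    "read_incidence",
    "write_incidence",
    "classify_species",
    "rare_cutoff",
    "subset_incidence",
]

#: relative tolerance on the isoperimetric lower bound for island perimeters
_PERIM_RTOL = 1e-9

HA_TO_M2 = 1.0e4

SpeciesClass = Literal["rare", "common"]


class ValidationError(ValueError):
    """A value violates a domain invariant (non-positive area, empty row, ...)."""


class FormatError(ValueError):
    """A file does not have the expected columns/layout."""


def circle_perimeter(area_ha: float) -> float:
    """Perimeter (m) of the circle whose area equals ``area_ha`` hectares."""
    return 2.0 * math.sqrt(math.pi * area_ha * HA_TO_M2)


@dataclass(frozen=True)
class Island:
    """One habitat patch.

    Attributes
    ----------
    id : str
        Opaque identifier.
    area : float
        Surface area in hectares; strictly positive.
    perimeter : float
        Edge length in meters; at least the perimeter of the equal-area
        circle (no closed curve encloses a given area with less edge).
    dist_mainland : float
        Shortest island-edge-to-mainland-edge distance in meters; >= 0.
    """

    id: str
    area: float
    perimeter: float
    dist_mainland: float

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValidationError(f"island {self.id!r}: area must be > 0, got {self.area}")
        if not self.perimeter > 0:
            raise ValidationError(
                f"island {self.id!r}: perimeter must be > 0, got {self.perimeter}"
            )
        if self.dist_mainland < 0:
            raise ValidationError(
                f"island {self.id!r}: dist_mainland must be >= 0, got {self.dist_mainland}"
            )
        min_perim = circle_perimeter(self.area)
        if self.perimeter < min_perim * (1.0 - _PERIM_RTOL):
            raise ValidationError(
                f"island {self.id!r}: perimeter {self.perimeter:g} m is below the "
                f"equal-area circle perimeter {min_perim:g} m"
            )


@dataclass
class Archipelago:
    """An island collection plus a species x island incidence matrix.

    ``incidence[j, i]`` is True when species ``species_ids[j]`` occurs on
    ``islands[i]``.  Every island hosts at least one species and every
    species occurs somewhere, unless ``allow_empty_islands`` is set (used
    for class-restricted views, where islands may legitimately carry none
    of the retained species).
    """

    islands: list[Island]
    species_ids: list[str]
    incidence: np.ndarray
    allow_empty_islands: bool = False
    #: island ids that lost all species under a class-restricted view
    empty_island_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=bool)
        if inc.shape != (len(self.species_ids), len(self.islands)):
            raise ValidationError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.islands)} islands"
            )
        self.incidence = inc
        row_sums = inc.sum(axis=1)
        if np.any(row_sums == 0):
            bad = [self.species_ids[j] for j in np.flatnonzero(row_sums == 0)]
            raise ValidationError(f"species with no occurrences: {bad[:5]}")
        col_sums = inc.sum(axis=0)
        empty = np.flatnonzero(col_sums == 0)
        if empty.size and not self.allow_empty_islands:
            bad = [self.islands[i].id for i in empty]
            raise ValidationError(f"islands with no species: {bad[:5]}")
        self.empty_island_ids = tuple(self.islands[i].id for i in empty)

    @property
    def n_islands(self) -> int:
        return len(self.islands)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def island_richness(self) -> np.ndarray:
        """Observed per-island species counts (column sums)."""
        return self.incidence.sum(axis=0)

    def occupancy(self) -> np.ndarray:
        """Per-species island counts (row sums)."""
        return self.incidence.sum(axis=1)


@dataclass(frozen=True)
class SpeciesOccupancy:
    species_id: str
    n_islands: int
    proportion: float
    species_class: SpeciesClass


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

ISLAND_COLUMNS = ("id", "area_ha", "perimeter_m", "dist_mainland_m")


def read_island_table(path: str | Path) -> list[Island]:
    """Read an island attribute table.

    The file is comma-separated UTF-8 with a mandatory header row and
    columns ``id, area_ha, perimeter_m, dist_mainland_m``.  Row order is
    preserved; duplicate ids are rejected.
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in ISLAND_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise FormatError(f"{path}: duplicate island ids {dups[:5]}")
    islands: list[Island] = []
    for row_number, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            islands.append(
                Island(
                    id=str(rec.id),
                    area=float(rec.area_ha),
                    perimeter=float(rec.perimeter_m),
                    dist_mainland=float(rec.dist_mainland_m),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {row_number}: {exc}") from exc
    return islands


def write_island_table(islands: Sequence[Island], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [isl.id for isl in islands],
            "area_ha": [isl.area for isl in islands],
            "perimeter_m": [isl.perimeter for isl in islands],
            "dist_mainland_m": [isl.dist_mainland for isl in islands],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_incidence(path: str | Path, islands: Sequence[Island]) -> Archipelago:
    """Read a 0/1 incidence table and align its columns to ``islands``.

    The first column holds species ids; each remaining column is named
    after an island id.  Column order in the file is irrelevant — the
    matrix is reindexed to the island-table order.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a species-id column plus island columns")
    sp_col = df.columns[0]
    species_ids = df[sp_col].astype(str).tolist()
    island_ids = [isl.id for isl in islands]
    file_cols = list(df.columns[1:])
    unknown = sorted(set(file_cols) - set(island_ids))
    if unknown:
        raise FormatError(f"{path}: unknown island columns {unknown[:5]}")
    missing = sorted(set(island_ids) - set(file_cols))
    if missing:
        raise FormatError(f"{path}: missing island columns {missing[:5]}")
    values = df[island_ids].to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError(f"{path}: incidence cells must be 0 or 1")
    return Archipelago(
        islands=list(islands), species_ids=species_ids, incidence=values.astype(bool)
    )


def write_incidence(arch: Archipelago, path: str | Path) -> None:
    df = pd.DataFrame(
        arch.incidence.astype(int),
        columns=[isl.id for isl in arch.islands],
    )
    df.insert(0, "species_id", arch.species_ids)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rare/common classification
# ---------------------------------------------------------------------------


def rare_cutoff(n_islands: int) -> int:
    """Largest occupancy count still classified as rare: floor(0.10 * N)."""
    return math.floor(0.10 * n_islands)


def classify_species(arch: Archipelago) -> list[SpeciesOccupancy]:
    """Classify every species as rare (occupancy <= 10% of islands) or common.

    The cutoff is ``floor(0.10 * N_islands)``, so in a 152-island system a
    species seen on 15 islands is rare and one seen on 16 is common.
    """
    n = arch.n_islands
    cutoff = rare_cutoff(n)
    out = []
    for sp, count in zip(arch.species_ids, arch.occupancy()):
        count = int(count)
        cls: SpeciesClass = "rare" if count <= cutoff else "common"
        out.append(SpeciesOccupancy(sp, count, count / n, cls))
    return out


def subset_incidence(arch: Archipelago, cls: str) -> Archipelago:
    """Restrict the incidence matrix to one species class.

    ``cls`` is one of ``rare``, ``common`` or ``all``.  Islands that lose
    every species under the restriction are retained (with an empty species
    set) so landscape geometry is unaffected by the species view; their ids
    are recorded on ``empty_island_ids``.
    """
    if cls == "all":
        return arch
    if cls not in ("rare", "common"):
        raise ValueError(f"unknown species class {cls!r}")
    keep = [
        j
        for j, occ in enumerate(classify_species(arch))
        if occ.species_class == cls
    ]
    if not keep:
        raise ValidationError(f"no species in class {cls!r}")
    return Archipelago(
        islands=arch.islands,
        species_ids=[arch.species_ids[j] for j in keep],
        incidence=arch.incidence[keep, :],
        allow_empty_islands=True,
    )
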