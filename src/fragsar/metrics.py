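"""Landscape attributes of a set of islands: Area, PN, PSV, LSI, MDM.

Area is total habitat amount.  The four remaining attributes quantify
fragmentation *per se* — the spatial configuration of the habitat
independent of its amount: patch number (PN), patch size variability
(PSV, the coefficient of variation of patch area), landscape shape index
(LSI, total edge over the perimeter of the single circle with the same
total area) and mean mainland distance (MDM, mean of the member islands'
shortest edge-to-mainland distances).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_data import Island, circle_perimeter

__all__ = ["LandscapeAttributes", "attributes", "attributes_arrays", "ATTRIBUTE_NAMES"]

ATTRIBUTE_NAMES = ("area_total", "pn", "psv", "lsi", "mdm")


@dataclass(frozen=True)
class LandscapeAttributes:
    """The five landscape attributes.

    area_total in ha, mdm in m; pn a count; psv and lsi dimensionless.
    LSI >= 1 always: each island's perimeter is at least its equal-area
    circle's, and one circle minimizes total edge for a given total area.
    """

    area_total: float
    pn: int
    psv: float
    lsi: float
    mdm: float


def attributes(islands: Sequence[Island]) -> LandscapeAttributes:
    """Compute the five attributes of a nonempty island collection.

    PSV uses the sample (n-1) standard deviation over the mean, reported
    as a plain ratio, and is defined as 0 for a single patch.
    """
    if len(islands) == 0:
        raise ValueError("landscape must contain at least one island")
    areas = np.array([isl.area for isl in islands])
    perims = np.array([isl.perimeter for isl in islands])
    dists = np.array([isl.dist_mainland for isl in islands])
    area_total = float(areas.sum())
    pn = len(islands)
    psv = float(areas.std(ddof=1) / areas.mean()) if pn > 1 else 0.0
    lsi = float(perims.sum() / circle_perimeter(area_total))
    return LandscapeAttributes(area_total, pn, psv, lsi, float(dists.mean()))


def attributes_arrays(
    areas: np.ndarray, perims: np.ndarray, dists: np.ndarray, idx: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized attributes for many equal-size landscapes.

    ``idx`` is an (n_landscapes, pn) array of island indices into the
    attribute vectors.  Returns one array per attribute name.
    """
    a = areas[idx]
    area_total = a.sum(axis=1)
    pn = idx.shape[1]
    if pn > 1:
        psv = a.std(axis=1, ddof=1) / a.mean(axis=1)
    else:
        psv = np.zeros(idx.shape[0])
    lsi = perims[idx].sum(axis=1) / (2.0 * np.sqrt(np.pi * area_total * 1.0e4))
    mdm = dists[idx].mean(axis=1)
    return {
        "area_total": area_total,
        "pn": np.full(idx.shape[0], pn),
        "psv": psv,
        "lsi": lsi,
        "mdm": mdm,
    }
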