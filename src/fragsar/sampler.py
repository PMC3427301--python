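"""Stratified ensemble of simulated fragmented landscapes.

A simulated landscape is a subset of islands drawn uniformly at random
without replacement.  For every patch number pn in [pn_min, pn_max] the
admissible total-area range [area_min, area_max] is split into
``n_sections`` equal-width sections, and ``n_reps`` landscapes are drawn
per (pn, section) cell, so that the ensemble's total areas are spread
evenly across the range at every patch number.  At defaults (2..50
patches, 5 sections, 200 replicates) the ensemble holds 49 x 5 x 200 =
49,000 landscapes.

The admissible range, when not given, is derived from the islands
themselves: area_min is the smallest possible total with pn_max patches
(the pn_max smallest islands) and area_max the largest possible total
with pn_min patches (the pn_min largest), which guarantees every
(pn, section) cell is geometrically attainable.

Sampling mechanism: batched uniform rejection (draw size-pn subsets
uniformly, keep those whose total area lands in a still-unfilled
section).  Cells whose qualifying subsets are too rare for rejection to
find within the try budget fall back to a uniform swap chain: starting
from a feasible subset, repeatedly propose swapping one member for one
non-member (both uniform) and accept iff the total stays in bounds.  The
proposal is symmetric, so the chain's stationary distribution is uniform
over qualifying subsets; draws are taken after burn-in with thinning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_data import Archipelago, Island
from .metrics import LandscapeAttributes, attributes_arrays

__all__ = [
    "SamplerConfig",
    "SimulatedLandscape",
    "SamplingInfeasibleError",
    "derive_area_range",
    "section_edges",
    "sample_landscape",
    "build_ensemble",
    "ensemble_to_frame",
]

logger = logging.getLogger(__name__)


class SamplingInfeasibleError(RuntimeError):
    """No qualifying subset could be found for a (pn, section) cell."""


@dataclass(frozen=True)
class SamplerConfig:
    pn_min: int = 2
    pn_max: int = 50
    n_sections: int = 5
    n_reps: int = 200
    area_min: float | None = None  # ha; None = derive from the islands
    area_max: float | None = None
    seed: int = 0
    max_tries: int = 100_000
    #: "error" aborts on an infeasible cell; "skip" logs and omits it
    on_infeasible: str = "error"

    def __post_init__(self) -> None:
        if self.pn_min < 2:
            raise ValueError("pn_min must be >= 2")
        if self.pn_max < self.pn_min:
            raise ValueError("pn_max must be >= pn_min")
        if self.n_sections < 1 or self.n_reps < 1:
            raise ValueError("n_sections and n_reps must be >= 1")
        if (
            self.area_min is not None
            and self.area_max is not None
            and not self.area_min < self.area_max
        ):
            raise ValueError("area_min must be < area_max")


@dataclass
class SimulatedLandscape:
    pn_level: int
    section: int  # 1-based
    rep: int  # 1-based
    island_ids: tuple[str, ...]
    island_idx: np.ndarray
    attrs: LandscapeAttributes
    #: pooled species count per incidence view, filled lazily
    richness: dict[str, int] = field(default_factory=dict)


def _island_list(islands: Sequence[Island] | Archipelago) -> list[Island]:
    if isinstance(islands, Archipelago):
        return islands.islands
    return list(islands)


def derive_area_range(
    islands: Sequence[Island] | Archipelago, cfg: SamplerConfig
) -> tuple[float, float]:
    """Admissible total-area range: (sum of pn_max smallest, sum of pn_min largest)."""
    isl = _island_list(islands)
    if cfg.pn_max > len(isl):
        raise ValueError(f"pn_max={cfg.pn_max} exceeds the {len(isl)} available islands")
    areas = np.sort(np.array([i.area for i in isl]))
    lo = float(areas[: cfg.pn_max].sum())
    hi = float(areas[-cfg.pn_min :].sum())
    if not lo < hi:
        raise ValueError(
            f"derived area range is degenerate: min total {lo:g} ha (with {cfg.pn_max} "
            f"patches) is not below max total {hi:g} ha (with {cfg.pn_min} patches)"
        )
    return lo, hi


def section_edges(area_min: float, area_max: float, n_sections: int) -> np.ndarray:
    """Equal-width section boundaries on the arithmetic scale."""
    return np.linspace(area_min, area_max, n_sections + 1)


def _assign_section(totals: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """0-based section index; boundaries belong to the lower section except the maximum."""
    k = np.searchsorted(edges, totals, side="left") - 1
    return np.clip(k, 0, len(edges) - 2)


def sample_landscape(
    islands: Sequence[Island],
    pn: int,
    section_bounds: tuple[float, float],
    rng: np.random.Generator,
    max_tries: int = 100_000,
) -> np.ndarray:
    """One uniform draw of a size-pn subset with total area in the bounds.

    Pure rejection sampling; raises SamplingInfeasibleError when the try
    budget is exhausted.  Returns island indices.
    """
    areas = np.array([i.area for i in islands])
    lo, hi = section_bounds
    n = len(islands)
    batch = 512
    tries = 0
    while tries < max_tries:
        m = min(batch, max_tries - tries)
        idx = np.argpartition(rng.random((m, n)), pn - 1, axis=1)[:, :pn]
        totals = areas[idx].sum(axis=1)
        ok = np.flatnonzero((totals >= lo) & (totals <= hi))
        if ok.size:
            return np.sort(idx[ok[0]])
        tries += m
    raise SamplingInfeasibleError(
        f"no subset of {pn} islands with total area in [{lo:g}, {hi:g}] ha "
        f"found in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# swap-chain fallback for rare cells
# ---------------------------------------------------------------------------


def _feasible_subset(
    areas: np.ndarray, pn: int, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray | None:
    """Find one size-pn subset with total in [lo, hi], or None.

    Randomized multi-start hill climb on the distance to the interval:
    from a uniform random subset, propose single member/non-member swaps
    and accept strict improvements.  Restarts guard against starts whose
    improvement landscape is trapped by an outlier island.  Returning
    None does not prove infeasibility, but the provable min/max bounds
    are checked first and 200 restarts make a false negative unlikely
    for any cell a practitioner would configure.
    """
    order = np.argsort(areas)
    n = len(areas)
    if areas[order[:pn]].sum() > hi or areas[order[-pn:]].sum() < lo:
        return None  # provably infeasible
    for _ in range(200):
        members = rng.choice(n, size=pn, replace=False)
        in_set = np.zeros(n, dtype=bool)
        in_set[members] = True
        out_set = np.flatnonzero(~in_set)
        members = list(members)
        out_list = list(out_set)
        total = areas[members].sum()
        dist = max(lo - total, 0.0) + max(total - hi, 0.0)
        if dist == 0.0:
            return np.sort(np.array(members))
        stalled = 0
        while stalled < 3000:
            mi = int(rng.integers(pn))
            oi = int(rng.integers(n - pn))
            a, b = members[mi], out_list[oi]
            new_total = total - areas[a] + areas[b]
            new_d = max(lo - new_total, 0.0) + max(new_total - hi, 0.0)
            if new_d < dist:
                members[mi], out_list[oi] = b, a
                total, dist = new_total, new_d
                stalled = 0
                if dist == 0.0:
                    return np.sort(np.array(members))
            else:
                stalled += 1
    return None


def _swap_chain_draws(
    areas: np.ndarray,
    pn: int,
    lo: float,
    hi: float,
    n_draws: int,
    rng: np.random.Generator,
    burn_in: int = 500,
    thin: int = 100,
) -> list[np.ndarray] | None:
    start = _feasible_subset(areas, pn, lo, hi, rng)
    if start is None:
        return None
    n = len(areas)
    if n == pn:  # single possible subset
        return [start.copy() for _ in range(n_draws)]
    in_set = np.zeros(n, dtype=bool)
    in_set[start] = True
    total = areas[start].sum()
    members = list(start)
    out = list(np.flatnonzero(~in_set))
    draws: list[np.ndarray] = []
    steps = burn_in + thin * n_draws
    mi = rng.integers(pn, size=steps)
    oi = rng.integers(n - pn, size=steps)
    for step in range(steps):
        a, b = members[mi[step]], out[oi[step]]
        new_total = total - areas[a] + areas[b]
        if lo <= new_total <= hi:
            members[mi[step]], out[oi[step]] = b, a
            total = new_total
        if step >= burn_in and (step - burn_in) % thin == thin - 1:
            draws.append(np.sort(np.array(members)))
    return draws


# ---------------------------------------------------------------------------
# ensemble construction
# ---------------------------------------------------------------------------


def build_ensemble(
    islands: Sequence[Island] | Archipelago, cfg: SamplerConfig
) -> list[SimulatedLandscape]:
    """Draw the full stratified ensemble.

    Returns (pn_max - pn_min + 1) * n_sections * n_reps landscapes (minus
    any provably infeasible cells when ``on_infeasible='skip'``), each
    with its attributes computed; richness is filled lazily per incidence
    view by :func:`fragsar.lsar.compute_richness`.
    """
    isl = _island_list(islands)
    areas = np.array([i.area for i in isl])
    perims = np.array([i.perimeter for i in isl])
    dists = np.array([i.dist_mainland for i in isl])
    ids = np.array([i.id for i in isl])
    n = len(isl)

    area_min, area_max = cfg.area_min, cfg.area_max
    if area_min is None or area_max is None:
        d_lo, d_hi = derive_area_range(isl, cfg)
        area_min = d_lo if area_min is None else area_min
        area_max = d_hi if area_max is None else area_max
    edges = section_edges(area_min, area_max, cfg.n_sections)

    out: list[SimulatedLandscape] = []
    for pn in range(cfg.pn_min, cfg.pn_max + 1):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, pn]))
        cell_draws: dict[int, list[np.ndarray]] = {k: [] for k in range(cfg.n_sections)}
        # batched rejection, shared across sections of this pn level
        tries = 0
        batch = 4096
        while tries < cfg.max_tries and any(
            len(v) < cfg.n_reps for v in cell_draws.values()
        ):
            m = min(batch, cfg.max_tries - tries)
            idx = np.argpartition(rng.random((m, n)), pn - 1, axis=1)[:, :pn]
            totals = areas[idx].sum(axis=1)
            ok = (totals >= area_min) & (totals <= area_max)
            sections = _assign_section(totals, edges)
            for row in np.flatnonzero(ok):
                k = sections[row]
                if len(cell_draws[k]) < cfg.n_reps:
                    cell_draws[k].append(np.sort(idx[row]))
            tries += m
        # swap-chain fallback for cells rejection could not fill
        for k in range(cfg.n_sections):
            need = cfg.n_reps - len(cell_draws[k])
            if need == 0:
                continue
            lo, hi = edges[k], edges[k + 1]
            draws = _swap_chain_draws(areas, pn, lo, hi, need, rng)
            if draws is None:
                msg = (
                    f"cell (pn={pn}, section={k + 1}, area [{lo:g}, {hi:g}] ha) "
                    f"is infeasible"
                )
                if cfg.on_infeasible == "skip":
                    logger.warning("skipping %s", msg)
                    continue
                raise SamplingInfeasibleError(msg)
            cell_draws[k].extend(draws)
        for k in range(cfg.n_sections):
            draws = cell_draws[k]
            if not draws:
                continue
            idx = np.vstack(draws)
            attrs = attributes_arrays(areas, perims, dists, idx)
            for r in range(idx.shape[0]):
                out.append(
                    SimulatedLandscape(
                        pn_level=pn,
                        section=k + 1,
                        rep=r + 1,
                        island_ids=tuple(ids[idx[r]]),
                        island_idx=idx[r],
                        attrs=LandscapeAttributes(
                            area_total=float(attrs["area_total"][r]),
                            pn=pn,
                            psv=float(attrs["psv"][r]),
                            lsi=float(attrs["lsi"][r]),
                            mdm=float(attrs["mdm"][r]),
                        ),
                    )
                )
    return out


def ensemble_to_frame(ensemble: Sequence[SimulatedLandscape]) -> "pd.DataFrame":
    """Flatten an ensemble to a table (one row per landscape)."""
    import pandas as pd

    rows = []
    for ls in ensemble:
        row = {
            "pn_level": ls.pn_level,
            "section": ls.section,
            "rep": ls.rep,
            "island_ids": ";".join(ls.island_ids),
            "area_total_ha": ls.attrs.area_total,
            "pn": ls.attrs.pn,
            "psv": ls.attrs.psv,
            "lsi": ls.attrs.lsi,
            "mdm_m": ls.attrs.mdm,
        }
        for view, val in ls.richness.items():
            row[f"richness_{view}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
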