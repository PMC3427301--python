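"""Rank correlations and adjusted-R2 variation partitioning.

Three analyses attribute variation in landscape richness and LSAR
z-values to landscape structure:

* pairwise Spearman rank correlations among the landscape attributes
  (midranks for ties, t-approximation p-values, Bonferroni over the
  matrix's pairs);
* partial Spearman correlations — rank-transform every column, regress
  x and y on the controls, correlate the residuals; df = n - 2 - k;
* two-set variation partitioning of z between total area and the
  fragmentation-per-se set {PN, PSV, LSI, MDM}.  With a univariate
  response, redundancy analysis reduces to linear regression, and the
  unique/shared/unexplained fractions are differences of Ezekiel
  adjusted R2 values; negative fractions are reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .breakpoint import BreakpointFit, split_phases
from .sampler import SimulatedLandscape

__all__ = [
    "CorrelationResult",
    "VarpartResult",
    "spearman_matrix",
    "partial_spearman",
    "adjusted_r2",
    "varpart2",
    "attach_z",
    "landscape_table",
    "run_phase_varpart",
    "FRAGMENTATION_SET",
]

FRAGMENTATION_SET = ("pn", "psv", "lsi", "mdm")


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    p_raw: float
    p_adj: float
    controls: tuple[str, ...]
    n: int


@dataclass(frozen=True)
class VarpartResult:
    """Adjusted-R2 fractions: a = unique to set 1, c = unique to set 2,
    b = shared, d = unexplained; a + b + c + d = 1 by construction."""

    frac_a: float
    frac_b: float
    frac_c: float
    frac_d: float


def _t_pvalue(rho: float, df: int) -> float:
    if df <= 0:
        return float("nan")
    r = min(max(rho, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def spearman_matrix(table: pd.DataFrame, columns: Sequence[str] | None = None
                    ) -> list[CorrelationResult]:
    """All pairwise Spearman correlations; one Bonferroni family per matrix."""
    cols = list(columns) if columns is not None else list(table.columns)
    n = len(table)
    if n < 4:
        raise ValueError("need >= 4 rows")
    ranks = {c: sps.rankdata(table[c].to_numpy()) for c in cols}
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    m = len(pairs)
    out = []
    for a, b in pairs:
        ra, rb = ranks[a], ranks[b]
        if np.ptp(ra) == 0 or np.ptp(rb) == 0:
            rho, p = float("nan"), float("nan")
        else:
            rho = float(np.corrcoef(ra, rb)[0, 1])
            p = _t_pvalue(rho, n - 2)
        out.append(
            CorrelationResult(a, b, rho, p, min(1.0, p * m) if np.isfinite(p) else p,
                              (), n)
        )
    return out


def partial_spearman(
    table: pd.DataFrame,
    x: str,
    y: str,
    controls: Sequence[str] = (),
    family_size: int = 1,
) -> CorrelationResult:
    """Partial Spearman correlation of x and y given the control columns.

    Midrank-transform all columns, regress the x- and y-ranks on the
    control ranks (with intercept), then Pearson-correlate the residuals.
    With no controls this equals the plain Spearman coefficient.
    """
    controls = tuple(controls)
    if x in controls or y in controls:
        raise ValueError("controls must be disjoint from {x, y}")
    n = len(table)
    k = len(controls)
    if n <= k + 3:
        raise ValueError(f"need n > |controls| + 3, got n={n}, k={k}")
    rx = sps.rankdata(table[x].to_numpy())
    ry = sps.rankdata(table[y].to_numpy())
    if k:
        design = np.column_stack(
            [np.ones(n)] + [sps.rankdata(table[c].to_numpy()) for c in controls]
        )
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"singular control design for controls={controls}")
        rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        rho = float("nan")
        p = float("nan")
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
        p = _t_pvalue(rho, n - 2 - k)
    p_adj = min(1.0, p * family_size) if np.isfinite(p) else p
    return CorrelationResult(x, y, rho, p, p_adj, controls, n)


def adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Ezekiel-adjusted R2 of an OLS fit with intercept."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear design matrix")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("constant response: R2 undefined")
    r2 = 1.0 - float(resid @ resid) / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def varpart2(y: np.ndarray, X1: np.ndarray, X2: np.ndarray) -> VarpartResult:
    """Partition variation in y between predictor sets X1 and X2.

    frac_a is unique to X1, frac_c unique to X2, frac_b shared and
    frac_d unexplained; the four sum to 1 algebraically.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float).T).T
    X2 = np.atleast_2d(np.asarray(X2, dtype=float).T).T
    n = len(y)
    if n <= X1.shape[1] + X2.shape[1] + 2:
        raise ValueError("too few rows for the full model")
    if np.ptp(np.asarray(y, dtype=float)) == 0:
        # constant response (e.g. z inherited within a single-level phase):
        # nothing to explain
        return VarpartResult(0.0, 0.0, 0.0, 1.0)
    r1 = adjusted_r2(y, X1)
    r2_ = adjusted_r2(y, X2)
    rf = adjusted_r2(y, np.column_stack([X1, X2]))
    frac_a = rf - r2_
    frac_c = rf - r1
    frac_b = r1 + r2_ - rf
    frac_d = 1.0 - rf
    return VarpartResult(frac_a, frac_b, frac_c, frac_d)


# ---------------------------------------------------------------------------
# per-landscape analysis tables
# ---------------------------------------------------------------------------


def landscape_table(
    ensemble: Sequence[SimulatedLandscape], view: str = "observed"
) -> pd.DataFrame:
    """One row per landscape: attributes + richness for ``view``."""
    return pd.DataFrame(
        {
            "area": [ls.attrs.area_total for ls in ensemble],
            "pn": [ls.attrs.pn for ls in ensemble],
            "psv": [ls.attrs.psv for ls in ensemble],
            "lsi": [ls.attrs.lsi for ls in ensemble],
            "mdm": [ls.attrs.mdm for ls in ensemble],
            "richness": [ls.richness[view] for ls in ensemble],
            "pn_level": [ls.pn_level for ls in ensemble],
        }
    )


def attach_z(table: pd.DataFrame, zseries: pd.DataFrame) -> pd.DataFrame:
    """Give every landscape the z of its patch-number level.

    z is estimated once per pn level (from all landscapes of that level),
    so per-landscape analyses against z inherit the level value.
    """
    zmap = dict(zip(zseries["pn_level"], zseries["z"]))
    out = table.copy()
    out["z"] = out["pn_level"].map(zmap)
    return out


def run_phase_varpart(
    ensemble: Sequence[SimulatedLandscape],
    zseries_by_view: dict[str, pd.DataFrame],
    fits_by_view: dict[str, BreakpointFit],
) -> dict[tuple[str, str], VarpartResult]:
    """Variation partitioning of z per (view, phase).

    For each view, landscapes inherit their pn level's z; within each
    phase (responsive: pn < psi, stable: pn >= psi) z is partitioned
    between total area and the fragmentation set {PN, PSV, LSI, MDM}.
    """
    results: dict[tuple[str, str], VarpartResult] = {}
    for view, fit in fits_by_view.items():
        responsive, stable = split_phases(fit, ensemble)
        for phase, group in (("responsive", responsive), ("stable", stable)):
            tab = attach_z(landscape_table(group, view), zseries_by_view[view])
            y = tab["z"].to_numpy()
            results[(view, phase)] = varpart2(
                y,
                tab[["area"]].to_numpy(),
                tab[list(FRAGMENTATION_SET)].to_numpy(),
            )
    return results
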