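"""Two-segment continuous piecewise linear regression on the z-series.

Fits y = b0 + b1*x + b2*(x - psi)*1[x > psi], continuous at the
breakpoint psi.  Profiling over psi: for each candidate the remaining
model is linear in (b0, b1, b2) and solved by OLS; psi is located by a
coarse grid over the interior x-range (step 0.1) followed by
golden-section refinement of the profiled sum of squared errors.

Applied to the z-vs-patch-number series, psi separates the "responsive
phase" (few patches, z changes rapidly) from the "stable phase" (many
patches, z nearly constant): levels with pn < psi are responsive, levels
with pn >= psi are stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TypeVar

import numpy as np
from scipy import stats

from .sampler import SimulatedLandscape

__all__ = ["BreakpointFit", "fit_piecewise", "split_phases"]

_GRID_STEP = 0.1
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class BreakpointFit:
    psi: float
    beta0: float
    beta1: float  # slope below psi
    beta2: float  # slope change above psi (slope above = beta1 + beta2)
    r2: float
    p: float
    #: True when the broken-stick fit improves SSE over a single line by < 1%,
    #: or when y is constant (psi is then not meaningful)
    no_threshold: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.beta0 + self.beta1 * x + self.beta2 * np.maximum(x - self.psi, 0.0)

    def phase_of(self, pn: float) -> str:
        # tolerance keeps an integer-valued psi assigning its own level stable
        return "responsive" if pn < self.psi - 1e-6 else "stable"


def _profiled_sse(x: np.ndarray, y: np.ndarray, psi: float) -> tuple[float, np.ndarray]:
    design = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid), beta


def fit_piecewise(x: Sequence[float], y: Sequence[float]) -> BreakpointFit:
    """Fit the broken-stick model; >= 5 points, x strictly increasing."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError(f"need >= 5 points, got {x.size}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:  # all-equal y: slope-0 fit, breakpoint undefined
        return BreakpointFit(
            psi=float("nan"), beta0=float(y[0]), beta1=0.0, beta2=0.0,
            r2=0.0, p=1.0, no_threshold=True,
        )
    # interior candidates: a breakpoint at/outside the data range is no model
    lo, hi = x[1], x[-2]
    grid = np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP)
    sses = np.array([_profiled_sse(x, y, g)[0] for g in grid])
    k = int(np.argmin(sses))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    # golden-section refinement inside the bracketing grid interval
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, _ = _profiled_sse(x, y, c)
    fd, _ = _profiled_sse(x, y, d)
    for _ in range(60):
        if b - a < 1e-8:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc, _ = _profiled_sse(x, y, c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd, _ = _profiled_sse(x, y, d)
    psi = 0.5 * (a + b)
    sse, beta = _profiled_sse(x, y, psi)
    if sses[k] < sse:  # keep the grid optimum if refinement did not help
        psi = grid[k]
        sse, beta = _profiled_sse(x, y, psi)
    r2 = 1.0 - sse / sst
    # single straight line for the no-threshold check
    line_sse, _ = _profiled_sse(x, y, x[-1] + 1.0)  # hinge inactive => plain line
    no_threshold = line_sse <= 1e-12 * sst or (line_sse - sse) / line_sse < 0.01
    # overall F-test vs the intercept-only model; psi counts as a parameter
    n = x.size
    df_model, df_resid = 3, n - 4
    if sse <= 0:
        p = 0.0
    else:
        f = ((sst - sse) / df_model) / (sse / df_resid)
        p = float(stats.f.sf(f, df_model, df_resid))
    return BreakpointFit(
        psi=float(psi), beta0=float(beta[0]), beta1=float(beta[1]),
        beta2=float(beta[2]), r2=float(r2), p=p, no_threshold=no_threshold,
    )


T = TypeVar("T")


def split_phases(
    fit: BreakpointFit, landscapes: Sequence[SimulatedLandscape]
) -> tuple[list[SimulatedLandscape], list[SimulatedLandscape]]:
    """Partition landscapes into (responsive, stable) by their pn level.

    pn < psi is responsive, pn >= psi stable; the breakpoint must sit
    strictly inside the pn range so both phases are nonempty.
    """
    if not np.isfinite(fit.psi):
        raise ValueError("breakpoint is undefined (degenerate fit)")
    responsive = [ls for ls in landscapes if fit.phase_of(ls.pn_level) == "responsive"]
    stable = [ls for ls in landscapes if fit.phase_of(ls.pn_level) == "stable"]
    if not responsive or not stable:
        raise ValueError(
            f"breakpoint psi={fit.psi:g} leaves an empty phase: it lies at the "
            f"edge of the patch-number range"
        )
    return responsive, stable
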