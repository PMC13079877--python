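"""Binary phase equilibria from a gE/(RT) surface.

The Gibbs energy of mixing, Delta g_mix/(RT) = gE/(RT) + x1 ln x1 +
x2 ln x2, determines liquid-liquid demixing: negative curvature anywhere is
the necessary (spinodal) condition for a split, and the lower convex
envelope of the discretized curve yields the coexisting compositions.  The
convex-envelope construction is realized as a monotone-chain lower convex
hull over a uniform composition grid (101 nodes by default); a hull edge
that skips at least two interior grid nodes is reported as a miscibility
gap.  An independent iterative equal-activity solver is provided for
cross-checks and for generating noise-free synthetic phase compositions.

Vapor-liquid equilibria use extended Raoult's law with Antoine vapor
pressures: p = sum_i p_i^sat x_i gamma_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from . import autodiff as ad
from .autodiff import Tensor
from .gemodels import BinaryGEProvider


@dataclass
class GmixCurve:
    """Discretized Delta g_mix/(RT) over a uniform x1 grid at fixed T."""

    T: float
    grid: np.ndarray
    values: np.ndarray


@dataclass
class PhaseSplit:
    """Compositions of two coexisting liquid phases, x1' < x1''."""

    x1_prime: float
    x1_doubleprime: float
    gap_index: int = 0

    def __post_init__(self):
        if not 0.0 <= self.x1_prime < self.x1_doubleprime <= 1.0:
            raise ValueError(
                f"phase compositions must satisfy 0 <= x1' < x1'' <= 1, got "
                f"({self.x1_prime}, {self.x1_doubleprime})"
            )


def gmix_curve(provider: BinaryGEProvider, T: float, n_grid: int = 101) -> GmixCurve:
    """Delta g_mix/(RT) on a uniform grid; endpoints exactly 0 (x ln x -> 0)."""
    grid = np.linspace(0.0, 1.0, n_grid)
    values = np.zeros(n_grid)
    interior = grid[1:-1]
    ge = np.asarray(provider.gE_RT_np(interior, T)).reshape(interior.shape)
    values[1:-1] = ge + interior * np.log(interior) + (1 - interior) * np.log(1 - interior)
    return GmixCurve(T=float(T), grid=grid, values=values)


def stability_values(provider: BinaryGEProvider, T: float, grid: np.ndarray) -> np.ndarray:
    """S(x) = d^2(Delta g_mix/RT)/dx^2 at interior grid nodes.

    The curvature of gE/(RT) comes from exact (automatic) differentiation of
    the provider; the ideal part contributes 1/x + 1/(1-x) analytically.
    """
    x = np.asarray(grid, dtype=np.float64)
    interior = x[(x > 0) & (x < 1)]
    leaf = Tensor(interior, requires_grad=True)
    g = provider.gE_RT(leaf, T)
    (d1,) = ad.grad(ad.tsum(g), [leaf])
    (d2,) = ad.grad(ad.tsum(d1), [leaf])
    return d2.data + 1.0 / interior + 1.0 / (1.0 - interior)


def stability_min(provider: BinaryGEProvider, T: float, grid: np.ndarray | None = None):
    """Minimum of S over interior grid nodes and its location."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=np.float64)
    interior = grid[(grid > 0) & (grid < 1)]
    s = stability_values(provider, T, grid)
    k = int(np.argmin(s))
    return float(s[k]), float(interior[k])


def cem_binary(curve: GmixCurve, min_skip: int = 2) -> list[PhaseSplit]:
    """Miscibility gaps from the lower convex hull of the discretized curve.

    Monotone-chain construction over the grid nodes; every hull edge that
    skips at least ``min_skip`` interior nodes is a miscibility gap with the
    edge's vertices as phase compositions.  An empty list means the curve is
    convex on the grid (fully miscible).
    """
    x, v = curve.grid, curve.values
    hull: list[int] = []
    for k in range(len(x)):
        while len(hull) >= 2:
            i, j = hull[-2], hull[-1]
            cross = (x[j] - x[i]) * (v[k] - v[i]) - (v[j] - v[i]) * (x[k] - x[i])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(k)
    splits = []
    for a, b in zip(hull[:-1], hull[1:]):
        if b - a - 1 >= min_skip:
            splits.append(
                PhaseSplit(x1_prime=float(x[a]), x1_doubleprime=float(x[b]), gap_index=len(splits))
            )
    return splits


def equal_activity_split(
    provider: BinaryGEProvider, T: float, n_scan: int = 1001
) -> PhaseSplit | None:
    """Iterative reference LLE solver: equal activities in both phases.

    Locates the spinodal region by a dense curvature scan, then solves the
    isoactivity conditions x1' gamma_1' = x1'' gamma_1'' and (1-x1')
    gamma_2' = (1-x1'') gamma_2'' with a damped Newton-type root search in
    logit coordinates.  Independent of the convex-envelope construction.
    Returns None when no demixing region exists.
    """
    grid = np.linspace(0.0, 1.0, n_scan)
    s = stability_values(provider, T, grid)
    neg = np.where(s < 0)[0]
    if neg.size == 0:
        return None
    interior = grid[1:-1]
    s1, s2 = interior[neg[0]], interior[neg[-1]]

    def residual(z):
        xp, xq = 1.0 / (1.0 + np.exp(-z))
        lg1p, lg2p = provider.ln_gamma(np.array([xp]), T)
        lg1q, lg2q = provider.ln_gamma(np.array([xq]), T)
        return np.array(
            [
                np.log(xp) + lg1p[0] - np.log(xq) - lg1q[0],
                np.log(1 - xp) + lg2p[0] - np.log(1 - xq) - lg2q[0],
            ]
        )

    x0 = np.clip([s1 * 0.5, 0.5 * (1.0 + s2)], 1e-6, 1 - 1e-6)
    sol = root(residual, np.log(x0 / (1 - x0)), method="hybr", tol=1e-12)
    xp, xq = 1.0 / (1.0 + np.exp(-sol.x))
    if not sol.success or abs(xp - xq) < 1e-6:
        return None
    lo, hi = sorted((float(xp), float(xq)))
    return PhaseSplit(x1_prime=lo, x1_doubleprime=hi)


def bubble_pressure(provider: BinaryGEProvider, x1: float, T: float, antoine: tuple):
    """Bubble pressure and vapor composition from extended Raoult's law.

    p = p1_sat x1 gamma_1 + p2_sat x2 gamma_2 (bar); y_i = p_i_sat x_i
    gamma_i / p.  ``antoine`` is the pair of AntoineCoefficients.
    """
    ln_g1, ln_g2 = provider.ln_gamma(np.array([x1]), T)
    ps1 = float(antoine[0].p_sat(T))
    ps2 = float(antoine[1].p_sat(T))
    partial1 = ps1 * x1 * np.exp(ln_g1[0])
    partial2 = ps2 * (1.0 - x1) * np.exp(ln_g2[0])
    p = partial1 + partial2
    return float(p), np.array([partial1 / p, partial2 / p])


def lle_temperature_scan(
    provider: BinaryGEProvider,
    T_range: tuple[float, float],
    step: float,
    n_grid: int = 101,
):
    """Binodal table over a temperature range plus critical-solution estimates.

    Returns ``(rows, critical_temperatures)`` where rows are
    (T, x1_prime, x1_doubleprime, gap_index) and each critical solution
    temperature is the midpoint of the bracketing step at which a gap
    appears or disappears.
    """
    temps = np.arange(T_range[0], T_range[1] + 0.5 * step, step)
    rows = []
    had_gap = None
    criticals = []
    for T in temps:
        splits = cem_binary(gmix_curve(provider, float(T), n_grid=n_grid))
        for sp in splits:
            rows.append((float(T), sp.x1_prime, sp.x1_doubleprime, sp.gap_index))
        has_gap = bool(splits)
        if had_gap is not None and has_gap != had_gap:
            criticals.append(float(T) - 0.5 * step)
        had_gap = has_gap
    return rows, criticals
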