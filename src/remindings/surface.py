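"""Osgood-style surfaces: kernel-smoothed memorability or interdependence
over the (cue relatedness x target relatedness) plane, with pointwise
permutation significance bounds.

The summary places every condition relative to the Control (z = 0) plane:
the NoChange condition is a point at the cue/target identity corner, the
DeltaTarget condition a fitted line along the cue-identity edge, the
DeltaCue condition a fitted line along the target-identity edge, and the
DeltaBoth condition a locally smoothed surface over both axes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Condition
from .stats import RegressionFit, relatedness_regression

__all__ = [
    "SurfaceGrid",
    "OsgoodSummary",
    "smooth_surface",
    "permutation_bounds",
    "assemble_osgood",
]

#: a cell is supported when total kernel weight reaches that of one point
#: sitting 1.5 bandwidths away
SUPPORT_FLOOR = math.exp(-1.5**2 / 2.0)


@dataclass
class SurfaceGrid:
    grid_cue: np.ndarray
    grid_target: np.ndarray
    z: np.ndarray                      # [cue, target]
    support_mask: np.ndarray
    bandwidth: float
    lower_bound: np.ndarray | None = None
    upper_bound: np.ndarray | None = None
    significant: np.ndarray | None = None
    alpha: float | None = None
    n_perm: int | None = None


@dataclass
class OsgoodSummary:
    no_change_point: tuple[float, float]        # mean, across-pair sd
    delta_target_line: RegressionFit
    delta_cue_line: RegressionFit
    both_surface: SurfaceGrid
    control_plane: float = 0.0


def _points(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.DataFrame(points)
    cols = {"cue_rel", "target_rel", "value"}
    if not cols.issubset(df.columns):
        raise ValueError(f"points need columns {sorted(cols)}")
    df = df.dropna(subset=sorted(cols))
    return (
        df["cue_rel"].to_numpy(float),
        df["target_rel"].to_numpy(float),
        df["value"].to_numpy(float),
    )


def _weights(
    cue: np.ndarray,
    target: np.ndarray,
    grid_cue: np.ndarray,
    grid_target: np.ndarray,
    bandwidth: float,
) -> np.ndarray:
    """Gaussian product-kernel weights, shape (n_grid_cells, n_points)."""
    gc, gt = np.meshgrid(grid_cue, grid_target, indexing="ij")
    d2 = (cue[None, :] - gc.ravel()[:, None]) ** 2 + (
        target[None, :] - gt.ravel()[:, None]
    ) ** 2
    return np.exp(-d2 / (2.0 * bandwidth**2))


def smooth_surface(
    points,
    grid_cue: np.ndarray | None = None,
    grid_target: np.ndarray | None = None,
    bandwidth: float | None = None,
    n_grid: int = 41,
    support_floor: float = SUPPORT_FLOOR,
) -> SurfaceGrid:
    """Nadaraya-Watson surface of per-pair values over the relatedness plane.

    ``z(g) = sum_i w_i v_i / sum_i w_i`` with Gaussian product-kernel
    weights ``w_i = exp(-[(c_i-g_c)^2 + (t_i-g_t)^2] / (2 h^2))``.  Cells
    whose total weight falls below ``support_floor`` are masked (NaN)
    rather than extrapolated.  Default bandwidth is 0.15 x the spanned
    relatedness range.
    """
    cue, target, value = _points(points)
    if len(value) < 1:
        raise ValueError("no points to smooth")
    span = max(np.ptp(cue), np.ptp(target))
    if bandwidth is None:
        bandwidth = 0.15 * span if span > 0 else 0.15
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_cue is None:
        grid_cue = np.linspace(cue.min(), cue.max(), n_grid)
    if grid_target is None:
        grid_target = np.linspace(target.min(), target.max(), n_grid)
    grid_cue = np.asarray(grid_cue, float)
    grid_target = np.asarray(grid_target, float)

    W = _weights(cue, target, grid_cue, grid_target, bandwidth)
    wsum = W.sum(axis=1)
    support = wsum >= support_floor
    if not support.any():
        raise ValueError("no grid cell reaches the support floor")
    z = np.full(W.shape[0], np.nan)
    z[support] = (W[support] @ value) / wsum[support]
    shape = (len(grid_cue), len(grid_target))
    return SurfaceGrid(
        grid_cue=grid_cue,
        grid_target=grid_target,
        z=z.reshape(shape),
        support_mask=support.reshape(shape),
        bandwidth=float(bandwidth),
    )


def permutation_bounds(
    points,
    grid_cue: np.ndarray | None = None,
    grid_target: np.ndarray | None = None,
    bandwidth: float | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    n_grid: int = 41,
    exact: bool = False,
    support_floor: float = SUPPORT_FLOOR,
) -> SurfaceGrid:
    """Pointwise permutation significance bounds for the smoothed surface.

    Values are shuffled against their (cue, target) coordinate pairs -
    exchangeable under "relatedness carries no information" - and the
    surface recomputed per shuffle; the bounds are the pointwise
    (alpha/2, 1-alpha/2) quantiles of the permuted surfaces, and cells
    where the observed surface escapes them are flagged significant.
    ``exact=True`` enumerates all permutations instead (small inputs only).
    """
    if n_perm < 100 and not exact:
        raise ValueError("n_perm must be >= 100 (or use exact=True)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cue, target, value = _points(points)
    n = len(value)
    n_distinct = math.factorial(n) if n <= 20 else None
    if not exact and n_distinct is not None and n_distinct < n_perm:
        raise ValueError(
            f"only {n_distinct} distinct permutations of {n} values exist; "
            "use exact=True to enumerate them all"
        )

    obs = smooth_surface(
        points, grid_cue, grid_target, bandwidth,
        n_grid=n_grid, support_floor=support_floor,
    )
    W = _weights(cue, target, obs.grid_cue, obs.grid_target, obs.bandwidth)
    wsum = W.sum(axis=1)
    support = obs.support_mask.ravel()
    Ws = W[support]
    ws = wsum[support]

    if exact:
        if n > 8:
            raise ValueError(f"exact enumeration is limited to 8 points, got {n}")
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    V = value[perms.T]                      # (n_points, n_perm_actual)
    surfaces = (Ws @ V) / ws[:, None]       # (n_support_cells, n_perm_actual)
    lo = np.quantile(surfaces, alpha / 2.0, axis=1)
    hi = np.quantile(surfaces, 1.0 - alpha / 2.0, axis=1)

    shape = obs.z.shape
    lower = np.full(shape, np.nan).ravel()
    upper = np.full(shape, np.nan).ravel()
    lower[support] = lo
    upper[support] = hi
    lower = lower.reshape(shape)
    upper = upper.reshape(shape)
    # tolerance guards against summation-order rounding when the observed
    # surface coincides with a permuted one (e.g. constant values)
    with np.errstate(invalid="ignore"):
        eps = 1e-9 * (1.0 + np.abs(obs.z))
        significant = (obs.z < lower - eps) | (obs.z > upper + eps)
    significant &= obs.support_mask
    return SurfaceGrid(
        grid_cue=obs.grid_cue,
        grid_target=obs.grid_target,
        z=obs.z,
        support_mask=obs.support_mask,
        bandwidth=obs.bandwidth,
        lower_bound=lower,
        upper_bound=upper,
        significant=significant,
        alpha=alpha,
        n_perm=len(perms),
    )


def assemble_osgood(
    tables: dict[str | Condition, pd.DataFrame],
    value_col: str = "memorability",
    stimuli: pd.DataFrame | None = None,
    metric: str | None = None,
    bandwidth: float | None = None,
    n_grid: int = 41,
    n_perm: int | None = None,
    alpha: float = 0.01,
    seed: int = 0,
) -> OsgoodSummary:
    """Assemble the full Osgood summary from the four experimental tables.

    ``tables`` maps each non-Control condition to its per-pair table (as
    produced by :func:`remindings.metrics.memorability` or the dependence
    table).  The DeltaBoth surface needs separate cue and target
    coordinates; they are taken from ``stimuli`` (falling back to the
    table's own columns if named ``cue_rel``/``target_rel``).
    """
    tables = {Condition(k).value: v for k, v in tables.items()}
    for cond in (Condition.NO_CHANGE, Condition.DELTA_TARGET,
                 Condition.DELTA_CUE, Condition.DELTA_BOTH):
        if cond.value not in tables:
            raise ValueError(f"missing table for condition {cond.value}")

    nc = tables[Condition.NO_CHANGE.value][value_col]
    no_change_point = (float(nc.mean()), float(nc.std(ddof=1)))

    dt_line = relatedness_regression(
        tables[Condition.DELTA_TARGET.value], value_col=value_col
    )
    dc_line = relatedness_regression(
        tables[Condition.DELTA_CUE.value], value_col=value_col
    )

    both = tables[Condition.DELTA_BOTH.value]
    if {"cue_rel", "target_rel"}.issubset(both.columns):
        pts = both.rename(columns={value_col: "value"})[
            ["cue_rel", "target_rel", "value"]
        ]
    else:
        if stimuli is None:
            raise ValueError(
                "DeltaBoth table lacks cue_rel/target_rel columns; "
                "pass the stimulus table"
            )
        m = metric or both.attrs.get("metric") or "AS"
        stim = stimuli.set_index("pair_id")
        pts = pd.DataFrame(
            {
                "cue_rel": stim.loc[both["pair_id"], f"cue_rel_{m}"].to_numpy(),
                "target_rel": stim.loc[both["pair_id"], f"target_rel_{m}"].to_numpy(),
                "value": both[value_col].to_numpy(),
            }
        )
    if n_perm:
        surf = permutation_bounds(
            pts, bandwidth=bandwidth, n_grid=n_grid,
            n_perm=n_perm, alpha=alpha, seed=seed,
        )
    else:
        surf = smooth_surface(pts, bandwidth=bandwidth, n_grid=n_grid)
    return OsgoodSummary(
        no_change_point=no_change_point,
        delta_target_line=dt_line,
        delta_cue_line=dc_line,
        both_surface=surf,
    )
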