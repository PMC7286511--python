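"""Forward predictions from fitted interaction parameters.

Once (mu, U_ff, U_mm, U_fm) are estimated, the canonical ensemble predicts
the occupancy statistics of ANY design (N pots, K_f females, K_m males) —
this is the model's main practical payoff: surfaces of expected outsiders
and linkage over candidate designs, the "equation of state" trade-off
between female-male linkage and outsiders as dens are made scarce, and the
dense many-animal limit where the per-den occupancy develops a Mott-like
staircase in mu/U at strong repulsion.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExperimentSetup
from .ensemble import ModelParams, partition
from .inference import observable_uncertainty

__all__ = [
    "DesignGrid",
    "DenseLimit",
    "observable_grid",
    "equation_of_state",
    "dense_limit",
    "mahalanobis",
]


@dataclass(frozen=True)
class DesignGrid:
    """Grid of candidate designs sharing one parameter set."""

    k: int
    n_values: tuple[int, ...]
    kf_values: tuple[int, ...]
    params: ModelParams
    m_ref: int = 7  # reference day count for the finite-M uncertainty term

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_values):
            raise ValueError("need N >= 1")
        if any(not 0 <= kf <= self.k for kf in self.kf_values):
            raise ValueError("need 0 <= K_f <= K")


def observable_grid(grid: DesignGrid) -> pd.DataFrame:
    """Expected outsiders, linkage and sharing for every (N, K_f) design,
    each cell by exact enumeration of the canonical ensemble."""
    rows = []
    for n in grid.n_values:
        for kf in grid.kf_values:
            setup = ExperimentSetup(n, kf, grid.k - kf)
            s = partition(setup, grid.params)
            rows.append(
                {
                    "n_pots": n,
                    "k_f": kf,
                    "mean_n0": float(s.moments[0]),
                    "sigma_ff": float(s.moments[1]),
                    "sigma_mm": float(s.moments[2]),
                    "sigma_fm": float(s.moments[3]),
                    "mean_sd": s.mean_sharing,
                }
            )
    return pd.DataFrame(rows)


def equation_of_state(
    grid: DesignGrid,
    cov: np.ndarray | None = None,
    active: Sequence[str] = (),
    k_f: int | None = None,
) -> pd.DataFrame:
    """Trade-off trajectory in the (mean outsiders, mean f-m linkage) plane
    as den availability N varies, with uncertainty ellipses.

    For every N the intrinsic (infinite-M) 2x2 covariance of (n0, sigma_fm)
    is reported, and — when a parameter covariance from a fit is supplied —
    the finite-M inflated matrix as well.  Ellipse half-axes at one standard
    deviation are the square roots of the matrix eigenvalues; a 10%-relative-
    error box (0.1 x the predicted means) is included for comparison with
    the convention of quoting 10% uncertainty per observable.
    """
    kf = grid.k // 2 if k_f is None else k_f
    rows = []
    for n in grid.n_values:
        setup = ExperimentSetup(n, kf, grid.k - kf)
        s = partition(setup, grid.params)
        sub = np.ix_([0, 3], [0, 3])
        intrinsic = s.cov[sub]
        row = {
            "n_pots": n,
            "mean_n0": float(s.moments[0]),
            "sigma_fm": float(s.moments[3]),
            "var_n0": float(intrinsic[0, 0]),
            "var_sigma_fm": float(intrinsic[1, 1]),
            "cov_n0_sigma_fm": float(intrinsic[0, 1]),
            "rel10_n0": 0.1 * float(s.moments[0]),
            "rel10_sigma_fm": 0.1 * float(s.moments[3]),
        }
        if cov is not None:
            full = observable_uncertainty(setup, grid.params, cov, active, grid.m_ref)
            infl = full[sub]
            row.update(
                {
                    "var_n0_inflated": float(infl[0, 0]),
                    "var_sigma_fm_inflated": float(infl[1, 1]),
                    "cov_n0_sigma_fm_inflated": float(infl[0, 1]),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def mahalanobis(
    point: tuple[float, float], mean: tuple[float, float], cov2: np.ndarray
) -> float:
    """Mahalanobis distance of an empirical (n0, sigma_fm) point from its
    predicted mean under a 2x2 error matrix."""
    d = np.asarray(point, dtype=float) - np.asarray(mean, dtype=float)
    return float(np.sqrt(d @ np.linalg.solve(cov2, d)))


@dataclass(frozen=True)
class DenseLimit:
    """Per-den statistics in the grand-canonical dense limit."""

    r: float    # mu / U
    u: float
    rho: float  # mean occupancy per den
    xi: float   # mean pair links per den


def dense_limit(r: float, u: float, tol: float = 1e-15) -> DenseLimit:
    """Dense-limit (1 << N << K) per-den occupancy and linkage.

    Each den is an independent grand-canonical site with occupation weight
    exp[U(r n - n(n-1)/2)], r = mu/U; the outsider reservoir plays the role
    of the particle bath.  The sum is truncated once terms fall below
    ``tol`` relative to the largest.  For weak repulsion the discrete saddle
    point gives rho ~ r + 1/2 and xi ~ r^2/2; at strong repulsion
    (U ~ 4 pi) rho(r) becomes a Mott-like staircase.
    """
    if u <= 0:
        raise ValueError("the dense-limit sum requires repulsion (U > 0)")
    mu = r * u
    n = np.arange(0, max(64, int(4 * (abs(r) + 4))))
    log_w = u * (r * n - n * (n - 1) / 2.0)
    log_w -= log_w.max()
    w = np.exp(log_w)
    keep = w >= tol
    w, n = w[keep], n[keep]
    z = w.sum()
    rho = float((w * n).sum() / z)
    xi = float((w * n * (n - 1) / 2.0).sum() / z)
    return DenseLimit(r=float(r), u=float(u), rho=rho, xi=xi)
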