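"""Exact canonical ensembles over den-occupancy configurations.

The model treats a tank of K animals and N pots as a small lattice gas: a
configuration is the vector of per-slot occupation numbers (slot 0 being the
open tank), its statistical weight is the number of labeled-animal
assignments g times the Boltzmann factor of the energy

    H = mu * n0  +  U_ff * sigma_ff  +  U_mm * sigma_mm  +  U_fm * sigma_fm

where n0 counts outsiders of both sexes and the sigmas count within-pot
pairs (the conventional 1/2 factors are absorbed into the pair counts).
Energies are dimensionless (k_B T = 1).  The chemical potential mu penalises
staying outside a den; positive U is social repulsion, negative U attraction;
U = 0 with outsiders excluded recovers neutral (non-interacting) animals.

Configuration spaces are small enough (a few thousand states) for the
partition function, all moments and the sharing distribution to be computed
by exhaustive enumeration; weights are accumulated in log space so that
interactions up to |U| ~ 30 are safe.  A parameter may be "traced out"
(sent to +infinity), which removes the configurations it penalises from the
space; this is how designs with no observed outsiders or no observed pairs
of a given kind are handled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial, prod
from typing import Iterator

import numpy as np
from scipy.special import gammaln, logsumexp

from .data import ExperimentSetup, OccupancyConfig

__all__ = [
    "PARAM_NAMES",
    "ModelParams",
    "EnsembleSummary",
    "enumerate_configs",
    "space_size",
    "multiplicity",
    "hamiltonian",
    "partition",
    "sharing_pmf",
    "config_table",
]

#: parameter order; the matching sufficient statistics are
#: (n0_f + n0_m, sigma_ff, sigma_mm, sigma_fm)
PARAM_NAMES = ("mu", "u_ff", "u_mm", "u_fm")


@dataclass(frozen=True)
class ModelParams:
    """Interaction parameters; names in ``traced`` are treated as +infinity."""

    mu: float = 0.0
    u_ff: float = 0.0
    u_mm: float = 0.0
    u_fm: float = 0.0
    traced: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = self.traced - set(PARAM_NAMES)
        if bad:
            raise ValueError(f"unknown traced parameters: {sorted(bad)}")
        for name in set(PARAM_NAMES) - self.traced:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite value for active parameter {name}")

    def vector(self) -> np.ndarray:
        """Active-parameter vector in :data:`PARAM_NAMES` order, traced -> 0
        (their statistics vanish identically on the restricted space)."""
        return np.array(
            [0.0 if n in self.traced else getattr(self, n) for n in PARAM_NAMES]
        )


class ExcludedConfigurationError(ValueError):
    """An observed configuration lies outside the model's configuration space."""


def _compositions(total: int, slots: int) -> Iterator[tuple[int, ...]]:
    # weak compositions of `total` into `slots` ordered cells
    if slots == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, slots - 1):
            yield (first, *rest)


def _sex_space(
    n_pots: int, k: int, exclude_outside: bool, exclude_pairs: bool
) -> np.ndarray:
    """All occupation vectors (slots 0..N) of one sex, as an int array."""
    rows = []
    for pots in _compositions(k, n_pots + 1):
        if exclude_outside and pots[0] > 0:
            continue
        if exclude_pairs and max(pots[1:]) > 1:
            continue
        rows.append(pots)
    if not rows:
        raise ValueError("empty configuration space (over-constrained tracing)")
    return np.array(rows, dtype=np.int64)


@dataclass(frozen=True)
class ConfigTable:
    """Enumerated configuration space with precomputed statistics."""

    n_f: np.ndarray      # (omega, N+1)
    n_m: np.ndarray
    stats: np.ndarray    # (omega, 4): n0, sigma_ff, sigma_mm, sigma_fm
    sharing: np.ndarray  # (omega,)
    log_g: np.ndarray    # (omega,)

    @property
    def omega(self) -> int:
        return self.stats.shape[0]


def _log_multinomial(counts: np.ndarray) -> np.ndarray:
    k = counts.sum(axis=1)
    return gammaln(k + 1) - gammaln(counts + 1).sum(axis=1)


@lru_cache(maxsize=256)
def config_table(setup: ExperimentSetup, traced: frozenset = frozenset()) -> ConfigTable:
    """Enumerate the configuration space of ``setup``.

    ``traced`` restricts the space: 'mu' removes all outsiders, 'u_ff'
    ('u_mm') removes same-sex pairs of that sex, 'u_fm' removes pots housing
    both sexes.  The setup's delta flags remove outsiders per sex.
    """
    f = _sex_space(
        setup.n_pots,
        setup.k_f,
        exclude_outside=bool(setup.delta_f) or "mu" in traced,
        exclude_pairs="u_ff" in traced,
    )
    m = _sex_space(
        setup.n_pots,
        setup.k_m,
        exclude_outside=bool(setup.delta_m) or "mu" in traced,
        exclude_pairs="u_mm" in traced,
    )
    idx_f = np.repeat(np.arange(len(f)), len(m))
    idx_m = np.tile(np.arange(len(m)), len(f))
    n_f, n_m = f[idx_f], m[idx_m]
    if "u_fm" in traced:
        keep = ~np.any((n_f[:, 1:] > 0) & (n_m[:, 1:] > 0), axis=1)
        if not keep.any():
            raise ValueError("empty configuration space (over-constrained tracing)")
        n_f, n_m = n_f[keep], n_m[keep]
    pots_f, pots_m = n_f[:, 1:], n_m[:, 1:]
    stats = np.column_stack(
        [
            n_f[:, 0] + n_m[:, 0],
            (pots_f * (pots_f - 1)).sum(axis=1) / 2,
            (pots_m * (pots_m - 1)).sum(axis=1) / 2,
            (pots_f * pots_m).sum(axis=1),
        ]
    ).astype(float)
    pooled = pots_f + pots_m
    sharing = np.where(pooled >= 2, pooled, 0).sum(axis=1)
    log_g = _log_multinomial(n_f) + _log_multinomial(n_m)
    return ConfigTable(n_f, n_m, stats, sharing, log_g)


def enumerate_configs(
    setup: ExperimentSetup, traced: frozenset = frozenset()
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All occupancy vectors (n_f, n_m) of the configuration space, each once."""
    t = config_table(setup, traced)
    return [(tuple(map(int, f)), tuple(map(int, m))) for f, m in zip(t.n_f, t.n_m)]


def space_size(setup: ExperimentSetup) -> int:
    """Closed-form count of configurations: the product over sexes of the
    number of weak compositions of K over N+1-delta slots."""
    from math import comb

    return comb(setup.n_pots + setup.k_f - setup.delta_f, setup.k_f) * comb(
        setup.n_pots + setup.k_m - setup.delta_m, setup.k_m
    )


def multiplicity(config: OccupancyConfig) -> int:
    """Number of labeled-animal assignments realising ``config`` (exact int):
    the multinomial coefficient per sex, multiplied."""
    out = 1
    for counts, k in ((config.n_f, config.k_f), (config.n_m, config.k_m)):
        out *= factorial(k) // prod(factorial(n) for n in counts)
    return out


def hamiltonian(config: OccupancyConfig, params: ModelParams) -> float:
    """Energy of a configuration; raises :class:`ExcludedConfigurationError`
    if the configuration is forbidden by a traced parameter."""
    from .data import linkage

    sff, smm, sfm = linkage(config)
    n0 = config.n_f[0] + config.n_m[0]
    values = dict(zip(PARAM_NAMES, (n0, sff, smm, sfm)))
    for name in params.traced:
        if values[name] > 0:
            raise ExcludedConfigurationError(
                f"configuration has {name} statistic {values[name]} > 0 but "
                f"{name} is traced out"
            )
    return float(
        sum(getattr(params, n) * values[n] for n in PARAM_NAMES if n not in params.traced)
    )


@dataclass(frozen=True)
class EnsembleSummary:
    """Partition function, moments and correlations of a canonical ensemble."""

    log_z: float
    mean_n0_f: float
    mean_n0_m: float
    moments: np.ndarray        # E of (n0, sigma_ff, sigma_mm, sigma_fm)
    cov: np.ndarray            # connected 2-point covariance, 4x4
    mean_sharing: float
    sharing_pmf: np.ndarray    # P(S_d = k), k = 0..K
    fourpoint: np.ndarray | None = None  # connected 4-point tensor, 4x4x4x4

    @property
    def z(self) -> float:
        return float(np.exp(self.log_z))

    @property
    def free_energy(self) -> float:
        return -self.log_z


def _connected_fourpoint(d: np.ndarray, p: np.ndarray, cov: np.ndarray) -> np.ndarray:
    # central 4th moments minus the three pair products (Gaussian part)
    m4 = np.einsum("w,wi,wj,wk,wl->ijkl", p, d, d, d, d, optimize=True)
    g = (
        np.einsum("ij,kl->ijkl", cov, cov)
        + np.einsum("ik,jl->ijkl", cov, cov)
        + np.einsum("il,jk->ijkl", cov, cov)
    )
    return m4 - g


def partition(
    setup: ExperimentSetup, params: ModelParams, fourpoint: bool = False
) -> EnsembleSummary:
    """Exact partition function and ensemble moments for one design.

    Z = sum over configurations of g * exp(-H), accumulated in log space;
    moments and connected 2-point (and optionally 4-point) correlations of
    the sufficient statistics are probability-weighted sums over the space.
    """
    t = config_table(setup, params.traced)
    log_w = t.log_g - t.stats @ params.vector()
    log_z = float(logsumexp(log_w))
    p = np.exp(log_w - log_z)
    mean = p @ t.stats
    d = t.stats - mean
    cov = np.einsum("w,wi,wj->ij", p, d, d)
    k = setup.k
    pmf = np.bincount(t.sharing, weights=p, minlength=k + 1)
    return EnsembleSummary(
        log_z=log_z,
        mean_n0_f=float(p @ t.n_f[:, 0]),
        mean_n0_m=float(p @ t.n_m[:, 0]),
        moments=mean,
        cov=cov,
        mean_sharing=float(p @ t.sharing),
        sharing_pmf=pmf,
        fourpoint=_connected_fourpoint(d, p, cov) if fourpoint else None,
    )


def sharing_pmf(setup: ExperimentSetup, params: ModelParams) -> tuple[np.ndarray, float]:
    """Distribution of the daily sharing level under the canonical ensemble.

    Returns (pmf over k = 0..K, mean).  k = 1 is impossible: a shared pot
    holds at least two animals.
    """
    s = partition(setup, params)
    return s.sharing_pmf, s.mean_sharing
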