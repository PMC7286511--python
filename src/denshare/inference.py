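"""Maximum-likelihood inference for the pairwise-interaction occupancy model.

The model is a discrete exponential family: the log-likelihood of M observed
configurations is W = sum_days [log g - H - log Z], so its gradient in the
parameters is the gap between ensemble and empirical moments of the
sufficient statistics (n0, sigma_ff, sigma_mm, sigma_fm), and its Hessian is
minus M times their ensemble covariance.  Fitting therefore reduces to
moment matching: Newton iterations drive the ensemble moments onto the
empirical means, and the inverse Fisher information (M times the covariance
of the statistics at the optimum) gives asymptotic standard errors.

A parameter whose sufficient statistic is identically zero in the data (no
outsiders ever seen, no male-male pair ever seen, ...) has its maximum at
+infinity; such parameters are traced out automatically: the configurations
they penalise are removed from the space and no finite estimate or error is
reported for them.

Replicates with different designs (different N or K) are combined by
summing their log-likelihoods with shared parameters, each design carrying
its own partition function — equivalently, by matching the day-weighted
average of ensemble moments to the pooled empirical means.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import ExperimentSetup, ReplicateSeries, linkage, pool_replicates
from .ensemble import (
    PARAM_NAMES,
    ConfigTable,
    EnsembleSummary,
    ModelParams,
    config_table,
    multiplicity,
    partition,
)

__all__ = [
    "FitResult",
    "ModelSpec",
    "log_likelihood",
    "fit",
    "fit_single_sex",
    "fit_mixed",
    "joint_fit",
    "param_contrast",
    "observable_uncertainty",
    "kl_profile",
    "model_selection",
]

_MAX_PARAM = 30.0
_TOL = 1e-10


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood estimate with Fisher-information errors."""

    params: ModelParams
    active: tuple[str, ...]
    cov: np.ndarray               # covariance of the active parameters
    loglik: float
    setups: tuple[ExperimentSetup, ...]
    m_days: int
    moment_residuals: np.ndarray  # per-day mean residual, active statistics

    @property
    def se(self) -> dict[str, float]:
        return {
            name: float(np.sqrt(self.cov[i, i])) for i, name in enumerate(self.active)
        }

    def estimate(self, name: str) -> tuple[float, float]:
        """(estimate, standard error) of one active parameter."""
        i = self.active.index(name)
        return float(getattr(self.params, name)), float(np.sqrt(self.cov[i, i]))


def _observed_stats(config) -> np.ndarray:
    sff, smm, sfm = linkage(config)
    return np.array([config.n_f[0] + config.n_m[0], sff, smm, sfm], dtype=float)


def _group_by_setup(
    replicates: Sequence[ReplicateSeries],
) -> list[tuple[ExperimentSetup, int, np.ndarray, list]]:
    groups: dict[ExperimentSetup, list] = {}
    for r in replicates:
        groups.setdefault(r.setup, []).extend(r.configs)
    out = []
    for setup, configs in groups.items():
        totals = np.sum([_observed_stats(c) for c in configs], axis=0)
        out.append((setup, len(configs), totals, configs))
    return out


def log_likelihood(
    replicates: Sequence[ReplicateSeries], params: ModelParams
) -> float:
    """W = sum over days of log P(config) = log g - H - log Z, with the
    partition function computed once per distinct design."""
    w = 0.0
    x = params.vector()
    for setup, m, totals, configs in _group_by_setup(replicates):
        table = config_table(setup, params.traced)
        for c in configs:
            stats = _observed_stats(c)
            for j, name in enumerate(PARAM_NAMES):
                if name in params.traced and stats[j] > 0:
                    raise ValueError(
                        f"day {c.day} ({c.experiment}/{c.tank}) has "
                        f"{name}-statistic {stats[j]:g} but {name} is traced out"
                    )
            w += float(np.log(multiplicity(c)) - stats @ x)
        w -= m * partition(setup, params).log_z
    return w


def _structural_support(setup: ExperimentSetup, traced: frozenset) -> np.ndarray:
    """Which of the four statistics can be non-zero on this design's space."""
    t = config_table(setup, traced)
    return t.stats.max(axis=0) > 0


def _auto_trace(groups) -> frozenset[str]:
    """Trace out every parameter whose statistic is present in some design's
    space but identically zero across all observed days."""
    traced = set()
    total = np.sum([g[2] for g in groups], axis=0)
    support = np.zeros(4, dtype=bool)
    for setup, _, _, _ in groups:
        support |= _structural_support(setup, frozenset())
    for j, name in enumerate(PARAM_NAMES):
        if support[j] and total[j] == 0:
            traced.add(name)
    return frozenset(traced)


def fit(
    replicates: Sequence[ReplicateSeries],
    trace: str | frozenset = "auto",
    max_iter: int = 200,
) -> FitResult:
    """Maximum-likelihood fit of (mu, U_ff, U_mm, U_fm) by moment matching.

    ``trace`` is either 'auto' (trace out every parameter with zero empirical
    support, the default) or an explicit frozenset of parameter names.
    Newton iterations start from all-zero parameters and stop when every
    active per-day moment residual is below 1e-10; estimates are confined to
    [-30, 30].
    """
    groups = _group_by_setup(replicates)
    traced = _auto_trace(groups) if trace == "auto" else frozenset(trace)

    support = np.zeros(4, dtype=bool)
    tables: list[tuple[ExperimentSetup, int, np.ndarray]] = []
    for setup, m, totals, _ in groups:
        support |= _structural_support(setup, traced)
        tables.append((setup, m, totals))
    active_idx = [
        j for j, name in enumerate(PARAM_NAMES) if support[j] and name not in traced
    ]
    active = tuple(PARAM_NAMES[j] for j in active_idx)
    m_total = sum(m for _, m, _ in tables)
    t_total = np.sum([tot for _, _, tot in tables], axis=0)

    # attainability: the pooled empirical mean must lie strictly inside the
    # convex hull of the statistics over the (weighted) spaces
    for j in active_idx:
        lo = sum(m * config_table(s, traced).stats[:, j].min() for s, m, _ in tables)
        hi = sum(m * config_table(s, traced).stats[:, j].max() for s, m, _ in tables)
        if not lo < t_total[j] < hi:
            raise ValueError(
                f"empirical mean of {PARAM_NAMES[j]}-statistic "
                f"({t_total[j] / m_total:g}/day) is not attainable by any finite "
                f"parameter value"
            )

    def ensembles(x_full: np.ndarray) -> list[EnsembleSummary]:
        p = _params_from_vector(x_full, traced)
        return [partition(s, p) for s, _, _ in tables]

    x = np.zeros(4)
    summ = ensembles(x)
    residual = _weighted_residual(summ, tables, t_total, active_idx)
    for _ in range(max_iter):
        if np.max(np.abs(residual)) / m_total <= _TOL:
            break
        fisher = _weighted_fisher(summ, tables, active_idx)
        step = np.linalg.solve(fisher, residual)
        scale = 1.0
        for _ in range(60):  # backtrack if the full Newton step overshoots
            x_new = x.copy()
            x_new[active_idx] = np.clip(x[active_idx] + scale * step, -_MAX_PARAM, _MAX_PARAM)
            summ_new = ensembles(x_new)
            residual_new = _weighted_residual(summ_new, tables, t_total, active_idx)
            if np.linalg.norm(residual_new) < np.linalg.norm(residual):
                break
            scale /= 2.0
        x, summ, residual = x_new, summ_new, residual_new
    else:
        raise RuntimeError("moment-matching Newton iteration did not converge")

    fisher = _weighted_fisher(summ, tables, active_idx)
    cov = np.linalg.inv(fisher)
    params = _params_from_vector(x, traced)
    return FitResult(
        params=params,
        active=active,
        cov=cov,
        loglik=log_likelihood(replicates, params),
        setups=tuple(s for s, _, _ in tables),
        m_days=m_total,
        moment_residuals=residual / m_total,
    )


def _params_from_vector(x: np.ndarray, traced: frozenset) -> ModelParams:
    kw = {name: float(x[j]) for j, name in enumerate(PARAM_NAMES)}
    return ModelParams(traced=traced, **kw)


def _weighted_residual(summaries, tables, t_total, active_idx) -> np.ndarray:
    pred = np.sum([m * s.moments for s, (_, m, _) in zip(summaries, tables)], axis=0)
    return (pred - t_total)[active_idx]


def _weighted_fisher(summaries, tables, active_idx) -> np.ndarray:
    f = np.sum([m * s.cov for s, (_, m, _) in zip(summaries, tables)], axis=0)
    return f[np.ix_(active_idx, active_idx)]


def fit_single_sex(replicates: Sequence[ReplicateSeries]) -> FitResult:
    """Fit the on-site interaction of a single-sex series (U_ff or U_mm).

    Replicates of unequal design are combined through the day-weighted
    free energy; with no outsiders ever observed, mu is traced out and the
    single condition is mean pair count = dF_eff/dU.
    """
    for r in replicates:
        if r.setup.k_f > 0 and r.setup.k_m > 0:
            raise ValueError("single-sex fit requires single-sex data")
    return fit(pool_replicates(list(replicates)))


def fit_mixed(
    replicates: Sequence[ReplicateSeries], trace: str | frozenset = "auto"
) -> FitResult:
    """Fit (mu, U_ff, U_mm, U_fm) to mixed-sex data; parameters with zero
    empirical support are traced out (``trace='auto'``)."""
    return fit(pool_replicates(list(replicates)), trace=trace)


@dataclass(frozen=True)
class JointFit:
    """Shared-parameter fit over heterogeneous designs, with the
    inverse-variance-weighted combination of per-design fits as cross-check."""

    joint: FitResult
    per_group: dict[str, FitResult]
    weighted_mean: dict[str, tuple[float, float]]


def joint_fit(groups: dict[str, Sequence[ReplicateSeries]]) -> JointFit:
    """Combine all experimental conditions into one set of parameters.

    The primary method maximises the summed log-likelihood over all days
    with shared (mu, U_ff, U_mm, U_fm) and design-specific partition
    functions; each treatment group keeps its own outsider-exclusion flags
    (pooled within the group), while interaction tracing is decided from the
    pooled statistics of the whole fit.  The alternative reported alongside
    is the inverse-variance-weighted mean of the per-group estimates.
    """
    if len(groups) < 2:
        raise ValueError("joint fit needs at least two experimental conditions")
    per_group = {name: fit(pool_replicates(list(reps))) for name, reps in groups.items()}
    all_reps = [r for reps in groups.values() for r in pool_replicates(list(reps))]
    joint = fit(all_reps)

    weighted: dict[str, tuple[float, float]] = {}
    for name in PARAM_NAMES:
        est, w = [], []
        for res in per_group.values():
            if name in res.active:
                e, s = res.estimate(name)
                est.append(e)
                w.append(1.0 / s**2)
        if est:
            w = np.asarray(w)
            weighted[name] = (
                float(np.dot(w, est) / w.sum()),
                float(1.0 / np.sqrt(w.sum())),
            )
    return JointFit(joint=joint, per_group=per_group, weighted_mean=weighted)


def param_contrast(
    a: tuple[float, float], b: tuple[float, float]
) -> tuple[float, float]:
    """t-statistic and one-sided normal p-value for the difference between
    two independent estimates given as (value, standard error)."""
    (ea, sa), (eb, sb) = a, b
    if sa <= 0 or sb <= 0:
        raise ValueError("standard errors must be positive")
    t = abs(ea - eb) / np.hypot(sa, sb)
    return float(t), float(norm.sf(t))


def observable_uncertainty(
    setup: ExperimentSetup,
    params: ModelParams,
    cov: np.ndarray,
    active: Sequence[str],
    m_days: int,
) -> np.ndarray:
    """Predicted 4x4 error matrix of the observables (n0, sigma_ff,
    sigma_mm, sigma_fm).

    Two contributions: the intrinsic day-to-day fluctuation (connected
    2-point covariance of the ensemble) plus the parameter-uncertainty term
    (1/2M) * sum_kl <dy_i dy_j dy_k dy_l>_c * cov(x_k, x_l), which vanishes
    as the number of observation days M grows.
    """
    active_idx = [PARAM_NAMES.index(n) for n in active]
    if cov.shape != (len(active_idx), len(active_idx)):
        raise ValueError("parameter covariance does not match the active set")
    s = partition(setup, params, fourpoint=True)
    cov_full = np.zeros((4, 4))
    cov_full[np.ix_(active_idx, active_idx)] = cov
    inflation = np.einsum("ijkl,kl->ij", s.fourpoint, cov_full) / (2.0 * m_days)
    return s.cov + inflation


def kl_profile(
    replicates: Sequence[ReplicateSeries],
    u_grid: np.ndarray,
    traced: frozenset = frozenset({"mu"}),
) -> tuple[pd.DataFrame, float]:
    """Kullback-Leibler divergence D(P_obs(S_d) || P_model(S_d | U)) over a
    grid of interaction values, and its argmin.

    The empirical sharing histogram pools all days; the model distribution
    of a random day is the day-weighted mixture of the per-design sharing
    pmfs (series that mix e.g. 5- and 6-pot replicates are handled this
    way).  Empirical bins with zero mass contribute nothing; a model bin
    with zero probability under positive empirical mass yields an infinite
    divergence.  For an interacting single-sex series the argmin agrees
    with the moment-matching MLE to within the grid resolution.
    """
    from .data import sharing_level

    groups = _group_by_setup(replicates)
    k_max = max(g[0].k for g in groups)
    m_total = sum(g[1] for g in groups)
    counts = np.zeros(k_max + 1)
    for r in replicates:
        for c in r.configs:
            counts[sharing_level(c)] += 1
    p_obs = counts / counts.sum()
    mask = p_obs > 0
    rows = []
    for u in np.asarray(u_grid, dtype=float):
        par = ModelParams(u_ff=u, u_mm=u, u_fm=u, traced=traced)
        pmf = np.zeros(k_max + 1)
        for setup, m, _, _ in groups:
            part = partition(setup, par).sharing_pmf
            pmf[: len(part)] += m * part
        pmf /= m_total
        with np.errstate(divide="ignore"):
            terms = p_obs[mask] * (np.log(p_obs[mask]) - np.log(pmf[mask]))
        d = float(np.sum(terms)) if np.all(pmf[mask] > 0) else np.inf
        rows.append({"u": float(u), "kl": d})
    df = pd.DataFrame(rows)
    return df, float(df.loc[df["kl"].idxmin(), "u"])


# ---------------------------------------------------------------------------
# model selection between one-site Hamiltonian families


@dataclass(frozen=True)
class ModelSpec:
    """A one-site Hamiltonian family for single-sex model comparison.

    H1 'hubbard': (U/2) sum_i n_i (n_i - 1), one parameter.
    H2 'linear': (V/2) sum_i n_i I[n_i >= nu], parameters (V, nu); nu is a
       discrete threshold profiled over 2..K.
    H3 'third': (1/2) sum_i W(n_i) with W(0) = 0 and free levels
       W(1), W(2), W(n >= 3) — three parameters.
    """

    name: str
    params: dict
    p: int


def _occupancy_level_counts(table: ConfigTable) -> np.ndarray:
    pots = table.n_f[:, 1:] + table.n_m[:, 1:]
    return np.column_stack(
        [(pots == 1).sum(axis=1), (pots == 2).sum(axis=1), (pots >= 3).sum(axis=1)]
    ).astype(float)


def _fit_family(
    table: ConfigTable, stat: np.ndarray, obs_total: np.ndarray, m: int
) -> tuple[np.ndarray, float, bool]:
    """Newton moment matching for an arbitrary sufficient-statistic matrix;
    returns (parameters, log Z at optimum, converged)."""
    from scipy.special import logsumexp

    x = np.zeros(stat.shape[1])
    ok = False
    last_obj = -np.inf
    for _ in range(300):
        log_w = table.log_g - stat @ x
        log_z = logsumexp(log_w)
        p = np.exp(log_w - log_z)
        mean = p @ stat
        r = m * mean - obs_total
        if np.max(np.abs(r)) / m <= 1e-9:
            ok = True
            break
        obj = -float(obs_total @ x) - m * log_z
        if obj - last_obj < 1e-12:
            break  # flat (non-identified) direction: likelihood has plateaued
        last_obj = obj
        d = stat - mean
        fisher = m * np.einsum("w,wi,wj->ij", p, d, d)
        # near-degenerate families: regularised solve
        step, *_ = np.linalg.lstsq(fisher + 1e-10 * np.eye(len(x)), r, rcond=None)
        ns = np.linalg.norm(r)
        scale = 1.0
        for _ in range(60):
            x_new = np.clip(x + scale * step, -_MAX_PARAM, _MAX_PARAM)
            log_w = table.log_g - stat @ x_new
            log_z_new = logsumexp(log_w)
            p_new = np.exp(log_w - log_z_new)
            if np.linalg.norm(m * (p_new @ stat) - obs_total) < ns:
                break
            scale /= 2.0
        x = x_new
    log_w = table.log_g - stat @ x
    return x, float(logsumexp(log_w)), ok


def model_selection(
    replicates: Sequence[ReplicateSeries], models: Sequence[str] = ("hubbard", "linear", "third")
) -> pd.DataFrame:
    """Fit competing one-site Hamiltonians to a single-design, single-sex
    series and compare them by small-sample AIC and BIC.

    AIC = -2 log L + 2p + 2p(p+1)/(M - p - 1) (second-order correction) and
    BIC = -2 log L + 2p log M as conventionally printed for this analysis;
    the standard BIC (-2 log L + p log M) is reported alongside.
    """
    reps = pool_replicates(list(replicates))
    setups = {r.setup for r in reps}
    if len(setups) != 1:
        raise ValueError("model selection requires a single design")
    setup = next(iter(setups))
    if setup.k_f and setup.k_m:
        raise ValueError("model selection families are single-sex")
    groups = _group_by_setup(reps)
    _, m, _, configs = groups[0]
    if setup.delta_f == 0 or setup.delta_m == 0:
        raise ValueError("model-selection families assume no outsiders")
    table = config_table(setup, frozenset())
    pots = table.n_f[:, 1:] + table.n_m[:, 1:]
    obs_pots = np.array([c.pooled[1:] for c in configs], dtype=float)
    log_g_obs = float(np.sum([np.log(multiplicity(c)) for c in configs]))

    rows = []
    for name in models:
        if name == "hubbard":
            stat = (pots * (pots - 1)).sum(axis=1, keepdims=True) / 2.0
            obs = np.array([(obs_pots * (obs_pots - 1)).sum() / 2.0])
            x, log_z, ok = _fit_family(table, stat, obs, m)
            p_n, params = 1, {"u": float(x[0])}
        elif name == "linear":
            best = None
            for nu in range(2, setup.k + 1):
                stat = np.where(pots >= nu, pots, 0).sum(axis=1, keepdims=True) / 2.0
                obs = np.array([np.where(obs_pots >= nu, obs_pots, 0).sum() / 2.0])
                if obs[0] == 0 or stat.max() == 0:
                    continue
                x, log_z, ok = _fit_family(table, stat, obs, m)
                ll = log_g_obs - float(obs @ x) - m * log_z
                if best is None or ll > best[0]:
                    best = (ll, x, log_z, ok, nu, obs)
            _, x, log_z, ok, nu, obs = best
            stat = np.where(pots >= nu, pots, 0).sum(axis=1, keepdims=True) / 2.0
            p_n, params = 2, {"v": float(x[0]), "nu": nu}
        elif name == "third":
            stat = _occupancy_level_counts(table) / 2.0
            lv = np.column_stack(
                [(obs_pots == 1).sum(axis=1), (obs_pots == 2).sum(axis=1), (obs_pots >= 3).sum(axis=1)]
            )
            obs = lv.sum(axis=0).astype(float) / 2.0
            x, log_z, ok = _fit_family(table, stat, obs, m)
            p_n = 3
            params = {"w1": float(x[0]), "w2": float(x[1]), "w3": float(x[2])}
        else:
            raise ValueError(f"unknown model family {name!r}")
        if m <= p_n + 1:
            raise ValueError(f"need M > p + 1 for the corrected AIC ({name})")
        loglik = log_g_obs - float(obs @ x) - m * log_z
        rows.append(
            {
                "model": name,
                "params": params,
                "p": p_n,
                "loglik": loglik,
                "aic": -2 * loglik + 2 * p_n + 2 * p_n * (p_n + 1) / (m - p_n - 1),
                "bic": -2 * loglik + 2 * p_n * np.log(m),
                "bic_standard": -2 * loglik + p_n * np.log(m),
                "converged": ok,
            }
        )
    return pd.DataFrame(rows)
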