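"""Classical hypothesis tests for den-sharing series.

This module holds the hypothesis-testing layer that brackets the
interaction-model analysis: one-sample t-tests of daily sharing levels
against the neutral reference, a one-way unbalanced ANOVA across treatment
groups with Welch pairwise post-hocs (Bonferroni-style x12 correction:
six contrasts, two-sided), a uniformity check of per-pot mean occupancy,
and the temporal autocovariance of the sharing level used to argue that
daily censuses are effectively independent.

Conventions, fixed by matching published p-values: location tests use the
sample (divisor M-1) standard deviation and are one-sided toward the
observed direction; pooled treatment groups concatenate replicate days for
location tests but never across replicate boundaries for autocorrelation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import ReplicateSeries, sharing_level

__all__ = [
    "SeriesByGroup",
    "AutocorrResult",
    "t_vs_neutral",
    "oneway_anova",
    "welch_pairwise",
    "pot_uniformity",
    "autocorr",
]


@dataclass(frozen=True)
class SeriesByGroup:
    """Daily sharing levels by treatment, replicate boundaries preserved."""

    groups: dict[str, list[np.ndarray]]

    def pooled(self, name: str) -> np.ndarray:
        return np.concatenate(self.groups[name])

    @classmethod
    def from_replicates(cls, replicates: Sequence[ReplicateSeries]) -> "SeriesByGroup":
        groups: dict[str, list[np.ndarray]] = {}
        for r in replicates:
            groups.setdefault(r.label, []).append(r.sharing_levels.astype(float))
        return cls(groups)


def t_vs_neutral(values: np.ndarray, s0: float) -> tuple[float, float]:
    """One-sample t-test of daily sharing levels against the neutral mean.

    One-sided toward the observed direction, df = M - 1, sample standard
    deviation.  Returns (t, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two days")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t-test undefined")
    t = (x.mean() - s0) / (sd / np.sqrt(x.size))
    p = float(sps.t.sf(abs(t), x.size - 1))
    return float(t), p


def oneway_anova(groups: SeriesByGroup) -> pd.DataFrame:
    """Unbalanced one-way ANOVA of daily sharing level on treatment.

    Returns the decomposition table (between / within / total sums of
    squares, degrees of freedom, F and p)."""
    series = [groups.pooled(name) for name in groups.groups]
    if len(series) < 2 or any(len(s) < 2 for s in series):
        raise ValueError("need >= 2 groups with >= 2 values each")
    allx = np.concatenate(series)
    grand = allx.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in series)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in series)
    df_b, df_w = len(series) - 1, len(allx) - len(series)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return pd.DataFrame(
        [
            {"source": "between", "ssq": ss_between, "dof": df_b, "msq": ss_between / df_b, "F": f, "p": p},
            {"source": "within", "ssq": ss_within, "dof": df_w, "msq": ss_within / df_w, "F": np.nan, "p": np.nan},
            {"source": "total", "ssq": ss_between + ss_within, "dof": df_b + df_w, "msq": np.nan, "F": np.nan, "p": np.nan},
        ]
    )


def welch_pairwise(groups: SeriesByGroup, correction: int = 12) -> pd.DataFrame:
    """Welch two-sample t-tests between every pair of treatments.

    One-sided p-values (Welch-Satterthwaite df) are reported raw and
    multiplied by ``correction`` (default 12 = 6 contrasts x 2 for
    sidedness), capped at 1."""
    names = list(groups.groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa, xb = groups.pooled(a), groups.pooled(b)
            if a == b or (xa.shape == xb.shape and np.allclose(xa, xb)):
                t, p = 0.0, 0.5
            else:
                t, p2 = sps.ttest_ind(xa, xb, equal_var=False)
                p = p2 / 2.0 if not np.isnan(t) else np.nan
                t = float(t)
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "t": t,
                    "p_raw": float(p),
                    "p_corrected": float(min(1.0, p * correction)),
                }
            )
    return pd.DataFrame(rows)


def pot_uniformity(replicates: Sequence[ReplicateSeries]) -> tuple[np.ndarray, float]:
    """Per-pot mean occupancy (sexes pooled) and a one-way ANOVA p-value for
    differences between pots.

    All replicates must share the same number of pots; an insignificant
    ANOVA supports treating the pots as statistically interchangeable."""
    n_pots = {r.setup.n_pots for r in replicates}
    if len(n_pots) != 1:
        raise ValueError("pot-uniformity check requires a common number of pots")
    occ = np.array(
        [c.pooled[1:] for r in replicates for c in r.configs], dtype=float
    )  # (days, N)
    means = occ.mean(axis=0)
    _, p = sps.f_oneway(*occ.T)
    return means, float(p)


@dataclass(frozen=True)
class AutocorrResult:
    """Pooled temporal autocovariance of the daily sharing level."""

    lags: np.ndarray
    c: np.ndarray              # autocovariance C(tau)
    c_normalized: np.ndarray   # C(tau) / C(0)
    tau0: float                # relaxation time, days: 2 * main-lobe area of C/C(0)
    tau0_unnormalized: float   # same integral of the raw C, days * animals^2
    lobe_ratio_db: float       # main-to-strongest-side-lobe power ratio, dB


def _main_lobe_area(cn: np.ndarray) -> float:
    """Trapezoidal area under a normalized correlation function from lag 0
    to its first (interpolated) zero crossing."""
    area = 0.0
    for tau in range(1, len(cn)):
        a, b = cn[tau - 1], cn[tau]
        if b >= 0:
            area += (a + b) / 2.0
        else:  # crosses zero inside [tau-1, tau]
            area += a * (a / (a - b)) / 2.0
            return area
    return area


def autocorr(replicates: Sequence[ReplicateSeries], max_lag: int | None = None) -> AutocorrResult:
    """Autocovariance of daily sharing within replicates, pooled across them.

    Each replicate is demeaned separately and lagged products never straddle
    replicate boundaries.  The relaxation time tau0 is twice the area of the
    main lobe of C(tau)/C(0) — the trapezoidal integral from tau = 0 up to
    the first (linearly interpolated) zero crossing; side lobes of the
    short, demeaned series are finite-sample noise and are excluded.  A
    white-noise series gives tau0 close to 1 day (only the tau = 0 term
    contributes).
    """
    series = [r.sharing_levels.astype(float) for r in replicates]
    series = [s - s.mean() for s in series]
    longest = max(len(s) for s in series)
    if max_lag is None:
        max_lag = longest - 1
    c = np.zeros(max_lag + 1)
    for tau in range(max_lag + 1):
        prods = [s[tau:] * s[: len(s) - tau] for s in series if len(s) > tau]
        flat = np.concatenate(prods) if prods else np.array([])
        c[tau] = flat.mean() if flat.size else 0.0
    if c[0] <= 0:
        raise ValueError("zero variance: autocorrelation undefined")
    cn = c / c[0]
    lags = np.arange(max_lag + 1)
    tau0 = 2.0 * _main_lobe_area(cn)
    tau0_un = 2.0 * _main_lobe_area(cn) * c[0]
    side = np.abs(c[1:]).max() if max_lag >= 1 else np.nan
    lobe = 10.0 * np.log10(c[0] ** 2 / side**2) if side and side > 0 else np.inf
    return AutocorrResult(lags, c, cn, tau0, tau0_un, float(lobe))
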