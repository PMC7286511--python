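"""Den-occupancy data model, I/O and summary statistics.

The experimental unit is a tank-day census: for each of ``N`` interchangeable
pots (slots ``1..N``) and the open tank (slot ``0``), the number of females
and males found there.  A replicate is an ordered series of such censuses for
one tank.  The canonical interchange format is a long TSV with one row per
(experiment, tank, day, slot); the study's own 45 tank-days across four
treatments (all-female FF, all-male MM, mixed FM, and pots-limited PL) ship
as a packaged fixture in this format.

Slot 0 is always present in the data model.  When a replicate never has
outsiders the corresponding ``delta`` flag of its :class:`ExperimentSetup` is
set, which downstream modules interpret as "outsiders excluded from the
configuration space".
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentSetup",
    "OccupancyConfig",
    "ReplicateSeries",
    "SummaryStats",
    "sharing_level",
    "linkage",
    "summarize",
    "load_occupancy",
    "load_paper_tables",
    "pool_replicates",
    "summary_table",
]

TREATMENTS = ("FF", "MM", "FM", "PL")


@dataclass(frozen=True)
class ExperimentSetup:
    """Design of one occupancy experiment.

    Parameters
    ----------
    n_pots
        Number of pots N.
    k_f, k_m
        Number of females / males in the tank.
    delta_f, delta_m
        1 if outsiders of that sex are excluded from the configuration
        space (every census of the series found none), else 0.
    """

    n_pots: int
    k_f: int
    k_m: int
    delta_f: int = 0
    delta_m: int = 0

    def __post_init__(self) -> None:
        if self.n_pots < 1:
            raise ValueError("need at least one pot")
        if self.k_f + self.k_m < 1:
            raise ValueError("need at least one animal")
        if self.delta_f not in (0, 1) or self.delta_m not in (0, 1):
            raise ValueError("delta flags must be 0 or 1")

    @property
    def k(self) -> int:
        """Total number of animals."""
        return self.k_f + self.k_m


@dataclass(frozen=True)
class OccupancyConfig:
    """One tank-day: per-slot female and male counts, slot 0 = outside."""

    n_f: tuple[int, ...]
    n_m: tuple[int, ...]
    tank: str = ""
    day: int = 0
    experiment: str = ""

    def __post_init__(self) -> None:
        if len(self.n_f) != len(self.n_m):
            raise ValueError("female and male slot vectors differ in length")
        if any(n < 0 for n in self.n_f + self.n_m):
            raise ValueError("negative occupancy count")

    @property
    def n_pots(self) -> int:
        return len(self.n_f) - 1

    @property
    def k_f(self) -> int:
        return sum(self.n_f)

    @property
    def k_m(self) -> int:
        return sum(self.n_m)

    @property
    def pooled(self) -> tuple[int, ...]:
        """Per-slot counts with sexes pooled."""
        return tuple(f + m for f, m in zip(self.n_f, self.n_m))


@dataclass(frozen=True)
class ReplicateSeries:
    """Ordered daily censuses of one tank under a fixed design."""

    setup: ExperimentSetup
    configs: tuple[OccupancyConfig, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.configs:
            raise ValueError("a replicate needs at least one day")
        for c in self.configs:
            if c.n_pots != self.setup.n_pots:
                raise ValueError("inconsistent number of pots within replicate")
            if c.k_f != self.setup.k_f or c.k_m != self.setup.k_m:
                raise ValueError(
                    f"day {c.day}: animal counts ({c.k_f}f, {c.k_m}m) do not "
                    f"match the setup ({self.setup.k_f}f, {self.setup.k_m}m)"
                )

    @property
    def m_days(self) -> int:
        return len(self.configs)

    @property
    def sharing_levels(self) -> np.ndarray:
        return np.array([sharing_level(c) for c in self.configs])


@dataclass(frozen=True)
class SummaryStats:
    """Per-day averages of the sufficient statistics of a replicate."""

    mean_n0_f: float
    mean_n0_m: float
    mean_sigma_ff: float
    mean_sigma_mm: float
    mean_sigma_fm: float
    mean_sd: float
    sd_sd_population: float  # divisor M
    sd_sd_sample: float      # divisor M - 1


def sharing_level(config: OccupancyConfig) -> int:
    """Daily sharing level: total occupants of pots holding >= 2 animals.

    Sexes are pooled and outsiders (slot 0) never contribute, so the value
    lies in {0, 2, 3, ..., K}.
    """
    return sum(n for n in config.pooled[1:] if n >= 2)


def linkage(config: OccupancyConfig) -> tuple[int, int, int]:
    """Within-pot pair counts (sigma_ff, sigma_mm, sigma_fm).

    sigma_ff = sum_i nf_i (nf_i - 1) / 2 over pots, likewise for males, and
    sigma_fm = sum_i nf_i * nm_i; outsiders form no pairs.
    """
    sff = sum(f * (f - 1) // 2 for f in config.n_f[1:])
    smm = sum(m * (m - 1) // 2 for m in config.n_m[1:])
    sfm = sum(f * m for f, m in zip(config.n_f[1:], config.n_m[1:]))
    return sff, smm, sfm


def summarize(replicate: ReplicateSeries | Sequence[ReplicateSeries]) -> SummaryStats:
    """Arithmetic per-day means of outsiders, linkage and sharing level.

    Accepts a single replicate or a list (pooled day-by-day).  Both the
    population (divisor M) and sample (divisor M-1) standard deviations of
    the sharing level are reported, since published summary tables use the
    two conventions inconsistently.
    """
    reps = [replicate] if isinstance(replicate, ReplicateSeries) else list(replicate)
    configs = [c for r in reps for c in r.configs]
    m = len(configs)
    sd = np.array([sharing_level(c) for c in configs], dtype=float)
    sig = np.array([linkage(c) for c in configs], dtype=float)
    return SummaryStats(
        mean_n0_f=float(np.mean([c.n_f[0] for c in configs])),
        mean_n0_m=float(np.mean([c.n_m[0] for c in configs])),
        mean_sigma_ff=float(sig[:, 0].mean()),
        mean_sigma_mm=float(sig[:, 1].mean()),
        mean_sigma_fm=float(sig[:, 2].mean()),
        mean_sd=float(sd.mean()),
        sd_sd_population=float(sd.std(ddof=0)),
        sd_sd_sample=float(sd.std(ddof=1)) if m > 1 else 0.0,
    )


def _infer_label(setup: ExperimentSetup) -> str:
    if setup.k_m == 0:
        return "FF"
    if setup.k_f == 0:
        return "MM"
    return "PL" if setup.n_pots < setup.k else "FM"


def load_occupancy(source) -> list[ReplicateSeries]:
    """Read a long-format occupancy TSV into replicate series.

    ``source`` is anything :func:`pandas.read_csv` accepts.  Required columns:
    experiment, tank, day, slot, n_female, n_male.  Slots absent from the
    table are read as 0.  Rows are grouped into replicates by
    (experiment, tank); a day whose animal counts disagree with the rest of
    its replicate is rejected with an error naming the day.
    """
    df = pd.read_csv(source, sep="\t")
    required = {"experiment", "tank", "day", "slot", "n_female", "n_male"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df.empty:
        return []
    if (df[["n_female", "n_male", "slot"]] < 0).any().any():
        raise ValueError("negative counts or slots in input table")

    series: list[ReplicateSeries] = []
    for (exp, tank), grp in df.groupby(["experiment", "tank"], sort=True):
        n_pots = int(grp["slot"].max())
        configs = []
        for day, sub in grp.groupby("day", sort=True):
            n_f = [0] * (n_pots + 1)
            n_m = [0] * (n_pots + 1)
            for _, row in sub.iterrows():
                n_f[int(row["slot"])] += int(row["n_female"])
                n_m[int(row["slot"])] += int(row["n_male"])
            configs.append(
                OccupancyConfig(tuple(n_f), tuple(n_m), str(tank), int(day), str(exp))
            )
        k_f, k_m = configs[0].k_f, configs[0].k_m
        for c in configs:
            if (c.k_f, c.k_m) != (k_f, k_m):
                raise ValueError(
                    f"replicate ({exp}, {tank}): day {c.day} has "
                    f"{c.k_f} females / {c.k_m} males, expected {k_f}/{k_m}"
                )
        setup = ExperimentSetup(
            n_pots=n_pots,
            k_f=k_f,
            k_m=k_m,
            delta_f=int(all(c.n_f[0] == 0 for c in configs)),
            delta_m=int(all(c.n_m[0] == 0 for c in configs)),
        )
        series.append(ReplicateSeries(setup, tuple(configs), _infer_label(setup)))
    return series


def load_paper_tables() -> dict[str, ReplicateSeries]:
    """The study's eight replicates, keyed '1a'..'4b'.

    1a/1b: mixed sexes, N=6, 3 females + 3 males (Pots Equal);
    2a/2b: Pots Limited, N=2, six animals; 3a/3b: all-female N=K=6;
    4a/4b: all-male, N=K=5 and N=K=6.
    """
    with resources.files("denshare").joinpath("data/occupancy.tsv").open() as fh:
        reps = load_occupancy(fh)
    out = {}
    for r in reps:
        out[r.configs[0].experiment] = r
    return out


def pool_replicates(replicates: Sequence[ReplicateSeries]) -> list[ReplicateSeries]:
    """Prepare replicates for a combined fit: recompute the outsider-exclusion
    flags from the POOLED days, so that e.g. a single outsider day in one
    replicate opens slot 0 for the whole combined series.

    Replicates are never concatenated into one series (their boundaries
    matter for autocorrelation and for per-setup partition functions); only
    their delta flags are harmonised per (N, k_f, k_m) design.
    """
    delta_f = int(all(c.n_f[0] == 0 for r in replicates for c in r.configs))
    delta_m = int(all(c.n_m[0] == 0 for r in replicates for c in r.configs))
    out = []
    for r in replicates:
        setup = replace(r.setup, delta_f=delta_f, delta_m=delta_m)
        out.append(ReplicateSeries(setup, r.configs, r.label))
    return out


def summary_table(groups: dict[str, Sequence[ReplicateSeries]]) -> pd.DataFrame:
    """Measurement summary (one row per replicate group): day counts, design,
    mean outsiders by sex and mean linkage by pair type."""
    rows = []
    for name, reps in groups.items():
        s = summarize(list(reps))
        setups = {r.setup for r in reps}
        rows.append(
            {
                "group": name,
                "m_days": sum(r.m_days for r in reps),
                "n_pots": ",".join(str(x) for x in sorted({t.n_pots for t in setups})),
                "k_f": ",".join(str(x) for x in sorted({t.k_f for t in setups})),
                "k_m": ",".join(str(x) for x in sorted({t.k_m for t in setups})),
                "mean_n0_f": s.mean_n0_f,
                "mean_n0_m": s.mean_n0_m,
                "sigma_ff": s.mean_sigma_ff,
                "sigma_mm": s.mean_sigma_mm,
                "sigma_fm": s.mean_sigma_fm,
                "mean_sd": s.mean_sd,
            }
        )
    return pd.DataFrame(rows)
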