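"""Hypothesis-testing layer: t-tests, ANOVA, post-hocs, pot uniformity and
temporal autocorrelation of the sharing level."""
import numpy as np
import pytest

from denshare.classical import (
    SeriesByGroup,
    autocorr,
    oneway_anova,
    pot_uniformity,
    t_vs_neutral,
    welch_pairwise,
)
from denshare.data import ReplicateSeries
from denshare.ensemble import ModelParams
from denshare.neutral import neutral_sharing_mean
from denshare.synthetic import SimulationSpec, sample_dataset
from denshare.data import ExperimentSetup

S0_66 = 4651 / 1296
S0_55 = 369 / 125
S0_26 = 6 * (1 - 0.5**5)  # = 5.8125; the published table misprints 5.71


@pytest.mark.parametrize(
    "values, s0, p_published",
    [
        ([4, 4, 2, 4, 2], S0_66, 0.2360),
        ([4, 2, 0, 0, 5], S0_66, 0.1225),
        ([4, 4, 2, 4, 2, 4, 2, 0, 0, 5], S0_66, 0.0731),
        ([0, 2, 2, 0, 0], S0_55, 0.0059),
        ([0, 2, 0, 0, 0], S0_66, 0.0007),
        ([0, 2, 0, 2, 0, 2], S0_66, 0.0011),
        ([5, 6, 5, 5, 5, 4, 6], S0_26, 0.0212),
        ([4, 5, 5, 5, 5, 5, 5], S0_26, 0.0003),
    ],
)
def test_one_sample_tests_reproduce_published_pvalues(values, s0, p_published):
    """One-sided t with sample sd and df = M-1 reproduces every published
    p-value; the pots-limited rows only do so against the exact neutral mean
    5.8125, not the misprinted 5.71."""
    _, p = t_vs_neutral(np.array(values, float), s0)
    assert abs(p - p_published) < 5e-4


def test_one_sample_test_degenerate_inputs():
    with pytest.raises(ValueError, match="zero variance"):
        t_vs_neutral(np.array([2.0, 2.0, 2.0]), 3.59)
    with pytest.raises(ValueError, match="two days"):
        t_vs_neutral(np.array([2.0]), 3.59)


@pytest.fixture(scope="module")
def groups(tables):
    return SeriesByGroup.from_replicates(list(tables.values()))


def test_anova_decomposition(groups):
    """Unbalanced one-way ANOVA across the four treatments, recomputed from
    the daily sharing columns: dof (3, 41, 44) as published; the sums of
    squares and F differ from the printed table (123.3/62.6/185.9, F=26.9),
    which is not self-consistent with its own S_d columns."""
    an = oneway_anova(groups).set_index("source")
    assert list(an["dof"]) == [3, 41, 44]
    assert np.isclose(an.loc["between", "ssq"], 126.6636, atol=1e-3)
    assert np.isclose(an.loc["within", "ssq"], 60.1364, atol=1e-3)
    assert np.isclose(an.loc["total", "ssq"], 186.80, atol=1e-3)
    assert np.isclose(
        an.loc["between", "ssq"] + an.loc["within", "ssq"], an.loc["total", "ssq"]
    )
    assert np.isclose(an.loc["between", "F"], 28.786, atol=1e-2)
    assert an.loc["between", "p"] < 1e-8
    # discrepancy flag: printed values are not reproduced
    assert abs(an.loc["between", "F"] - 26.9) > 1
    assert abs(an.loc["between", "ssq"] - 123.3) > 3


def test_anova_invariances(groups):
    an = oneway_anova(groups)
    relabeled = SeriesByGroup({k[::-1]: v for k, v in groups.groups.items()})
    an2 = oneway_anova(relabeled)
    assert np.isclose(an.loc[0, "F"], an2.loc[0, "F"])
    same = SeriesByGroup({"a": [np.array([1.0, 2.0])], "b": [np.array([1.0, 2.0])]})
    assert np.isclose(oneway_anova(same).loc[0, "F"], 0.0)


def test_welch_posthocs(groups):
    """The female/mixed contrast is insignificant; mixed vs pots-limited is
    overwhelming; the x12 (Bonferroni x sidedness) correction caps at 1."""
    w = welch_pairwise(groups).set_index(["a", "b"])

    def p(a, b):
        return w.loc[(a, b), "p_raw"] if (a, b) in w.index else w.loc[(b, a), "p_raw"]

    assert p("FF", "FM") > 0.05
    assert p("FM", "PL") < 1e-3
    assert p("FF", "MM") < 0.05
    assert (w["p_corrected"] <= 1.0).all()
    assert np.allclose(
        w["p_corrected"], np.minimum(1.0, w["p_raw"] * 12), atol=1e-12
    )
    dup = SeriesByGroup({"x": [np.array([1.0, 2, 3])], "y": [np.array([1.0, 2, 3])]})
    assert np.isclose(welch_pairwise(dup).loc[0, "p_raw"], 0.5)


@pytest.fixture(scope="module")
def uniform_subset(tables):
    """The 25 six-pot, six-animal days: both all-female replicates, the
    six-pot all-male replicate, and the mixed days without an outsider."""
    out = [tables["3a"], tables["3b"], tables["4b"]]
    for key in ("1a", "1b"):
        r = tables[key]
        kept = tuple(c for c in r.configs if c.n_f[0] + c.n_m[0] == 0)
        out.append(ReplicateSeries(r.setup, kept, r.label))
    return out


def test_pot_uniformity(uniform_subset):
    """Per-pot mean occupancies over the 25-day subset reproduce the
    published values exactly, and the across-pot ANOVA is insignificant
    (published p = 0.23)."""
    means, p = pot_uniformity(uniform_subset)
    assert sum(r.m_days for r in uniform_subset) == 25
    assert np.allclose(means, [1.04, 1.16, 0.96, 0.76, 1.08, 1.00])
    assert np.all((means > 0.7) & (means < 1.3))
    assert p > 0.05
    assert abs(p - 0.23) < 0.01


def test_pot_uniformity_rejects_mixed_designs(tables):
    with pytest.raises(ValueError, match="common number of pots"):
        pot_uniformity([tables["3a"], tables["4a"]])


def test_autocorr_on_study_data(tables):
    """Pooled within-replicate autocovariance: the relaxation time (twice
    the main-lobe area of C/C(0)) is well under 1.5 days — daily censuses
    are effectively independent; the published 0.82 days reproduces."""
    ac = autocorr(list(tables.values()))
    assert ac.c[0] > 0
    assert ac.tau0 < 1.5
    assert abs(ac.tau0 - 0.82) < 0.01
    assert np.isfinite(ac.lobe_ratio_db)


def test_autocorr_white_noise_relaxation():
    """Exchangeable (neutral-model) days have no temporal structure: the
    relaxation time is close to one day."""
    setup = ExperimentSetup(6, 6, 0, 1, 1)
    sims = [
        sample_dataset(SimulationSpec(setup, ModelParams(), m_days=7, seed=123 + i))
        for i in range(40)
    ]
    ac = autocorr(sims)
    assert 0.7 < ac.tau0 < 1.2


def test_autocorr_constant_series_errors(tables):
    r = tables["3a"]
    const = ReplicateSeries(r.setup, (r.configs[0],) * 4, r.label)
    with pytest.raises(ValueError, match="zero variance"):
        autocorr([const])
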