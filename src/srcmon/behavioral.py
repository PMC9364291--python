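"""Descriptive and inferential statistics for the metamemory analyses.

Implements the statistics used to analyze judgments of source (JOS) and
restudy choices in the two-group experiment: balanced 2x2 ANOVAs (mixed or
fully within-subjects) with partial eta squared, paired/independent t tests
with d_z / d effect sizes, Goodman-Kruskal gamma between JOSs and binary
restudy choices, Loftus-Masson within-subject confidence intervals,
per-cell relative restudy frequencies, and the a-priori power analysis for
a paired t test via the noncentral t distribution.

ANOVAs are computed by direct least-squares decomposition for the balanced
two-by-two designs this package supports; unbalanced designs are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class StatsDomainError(ValueError):
    """Input violates a statistical operation's contract."""


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    ss: float
    df1: int
    df2: int
    ms_error: float
    f: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaTable:
    design: Literal["mixed", "within"]
    effects: tuple[AnovaEffect, ...]

    def __getitem__(self, effect: str) -> AnovaEffect:
        for e in self.effects:
            if e.effect == effect:
                return e
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects])


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    effect_size: float
    n: int
    kind: Literal["paired", "independent", "one_sample"]
    sided: Literal["two", "greater", "less"] = "two"
    zero_variance: bool = False


@dataclass(frozen=True)
class GammaResult:
    gamma: float | None
    concordant: int
    discordant: int
    ties: int
    defined: bool


@dataclass(frozen=True)
class PowerResult:
    required_n: int
    achieved_power: float
    d_z: float
    alpha: float
    target_power: float
    sided: Literal["one", "two"]


@dataclass(frozen=True)
class WithinSubjectCI:
    means: dict[str, float]
    half_width: float
    critical_t: float
    error_df: int


def _check_balanced(sizes: Sequence[int]) -> None:
    if len(set(sizes)) != 1:
        raise StatsDomainError(
            f"balanced design required; got cell sizes {sorted(set(sizes))}"
        )


def anova_2x2(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str | None = None,
    within2: str | None = None,
) -> AnovaTable:
    """Balanced 2x2 ANOVA on per-participant cell means.

    Mixed design (``between`` given): the between factor is tested against
    the between-subjects error (subjects within groups); the within factor
    and the interaction against the subject-by-within error.  Fully
    within-subjects design (``within2`` given): each effect is tested
    against its own subject-by-effect interaction error term.

    Partial eta squared is SS_effect / (SS_effect + SS_error-of-that-effect).
    """
    if (between is None) == (within2 is None):
        raise StatsDomainError("provide exactly one of `between` or `within2`")
    factor_b = between if between is not None else within2
    design = "mixed" if between is not None else "within"

    if design == "mixed":
        piv = data.pivot_table(
            index=subject, columns=[between, within], values=dv, aggfunc="mean"
        )
        groups = data.drop_duplicates(subject).set_index(subject)[between]
        levels_b = sorted(groups.unique())
        levels_w = sorted(data[within].unique())
        if len(levels_b) != 2 or len(levels_w) != 2:
            raise StatsDomainError("anova_2x2 requires exactly two levels per factor")
        # Y[g]: (n_g, 2) matrix of cell means for group g
        Y = {
            gl: piv.loc[groups[groups == gl].index, gl][levels_w].to_numpy()
            for gl in levels_b
        }
        if any(np.isnan(Y[gl]).any() for gl in levels_b):
            raise StatsDomainError(
                "missing cells: every subject needs every within cell"
            )
        ns = [Y[gl].shape[0] for gl in levels_b]
        _check_balanced(ns)
        n = ns[0]
        if n < 2:
            raise StatsDomainError("need >= 2 participants per group")
        N = 2 * n
        k = 2
        allY = np.vstack([Y[gl] for gl in levels_b])  # (N, 2)
        grand = allY.mean()
        group_means = np.array([Y[gl].mean() for gl in levels_b])
        w_means = allY.mean(axis=0)
        cell_means = np.array([Y[gl].mean(axis=0) for gl in levels_b])  # (2, 2)
        subj_means = allY.mean(axis=1)  # (N,)
        subj_group = np.repeat(group_means, n)

        ss_group = k * n * np.sum((group_means - grand) ** 2)
        ss_subj_err = k * np.sum((subj_means - subj_group) ** 2)
        ss_within = N * np.sum((w_means - grand) ** 2)
        ss_inter = n * np.sum(
            (cell_means - group_means[:, None] - w_means[None, :] + grand) ** 2
        )
        cell_for_subj = np.vstack([np.tile(cell_means[i], (n, 1)) for i in range(2)])
        resid = allY - subj_means[:, None] - cell_for_subj + subj_group[:, None]
        ss_w_err = np.sum(resid**2)

        df_b_err, df_w_err = N - 2, N - 2
        effects = []
        for name, ss, ss_err, df_err in [
            (between, ss_group, ss_subj_err, df_b_err),
            (within, ss_within, ss_w_err, df_w_err),
            (f"{between} * {within}", ss_inter, ss_w_err, df_w_err),
        ]:
            ms_err = ss_err / df_err
            f = ss / ms_err if ms_err > 0 else 0.0
            p = float(stats.f.sf(f, 1, df_err)) if ms_err > 0 else 1.0
            pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
            effects.append(
                AnovaEffect(name, float(ss), 1, df_err, float(ms_err), float(f),
                            p, float(pes))
            )
        return AnovaTable("mixed", tuple(effects))

    # fully within-subjects 2x2, one observation per subject per cell
    levels_a = sorted(data[within].unique())
    levels_b2 = sorted(data[within2].unique())
    if len(levels_a) != 2 or len(levels_b2) != 2:
        raise StatsDomainError("anova_2x2 requires exactly two levels per factor")
    piv2 = data.pivot_table(
        index=subject, columns=[within, within2], values=dv, aggfunc="mean"
    )
    if piv2.isna().any().any():
        raise StatsDomainError("missing cells: every subject needs every cell")
    n = piv2.shape[0]
    if n < 2:
        raise StatsDomainError("need >= 2 participants")
    Y = np.stack(
        [[piv2[(a, b)].to_numpy() for b in levels_b2] for a in levels_a], axis=-1
    )  # shape (2_b, n, 2_a) -> rearrange
    Y = np.transpose(Y, (1, 2, 0))  # (n, a, b)
    grand = Y.mean()
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_ab = Y.mean(axis=0)  # (a, b)
    m_s = Y.mean(axis=(1, 2))  # (n,)
    m_sa = Y.mean(axis=2)  # (n, a)
    m_sb = Y.mean(axis=1)  # (n, b)

    ss_a = 2 * n * np.sum((m_a - grand) ** 2)
    ss_b = 2 * n * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = 2 * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = 2 * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = np.sum(resid**2)

    df_err = n - 1
    effects = []
    for name, ss, ss_err in [
        (within, ss_a, ss_sa),
        (within2, ss_b, ss_sb),
        (f"{within} * {within2}", ss_ab, ss_sab),
    ]:
        ms_err = ss_err / df_err
        f = ss / ms_err if ms_err > 0 else 0.0
        p = float(stats.f.sf(f, 1, df_err)) if ms_err > 0 else 1.0
        pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        effects.append(
            AnovaEffect(name, float(ss), 1, df_err, float(ms_err), float(f), p,
                        float(pes))
        )
    return AnovaTable("within", tuple(effects))


def _t_p(t: float, df: int, sided: str) -> float:
    if sided == "two":
        return float(2 * stats.t.sf(abs(t), df))
    if sided == "greater":
        return float(stats.t.sf(t, df))
    if sided == "less":
        return float(stats.t.cdf(t, df))
    raise StatsDomainError(f"unknown sidedness {sided!r}")


def paired_t(
    x: Sequence[float], y: Sequence[float], sided: Literal["two", "greater", "less"] = "two"
) -> TTestResult:
    """Paired-samples t test of x - y with effect size d_z = mean/SD of differences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise StatsDomainError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise StatsDomainError("need n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return TTestResult(0.0, n - 1, 1.0 if sided == "two" else 0.5, 0.0, n,
                               "paired", sided, zero_variance=True)
        t = float(np.inf) * np.sign(mean)
        return TTestResult(t, n - 1, 0.0, float(np.inf) * np.sign(mean), n,
                           "paired", sided, zero_variance=True)
    d_z = mean / sd
    t = d_z * np.sqrt(n)
    return TTestResult(float(t), n - 1, _t_p(t, n - 1, sided), float(d_z), n,
                       "paired", sided)


def one_sample_t(
    x: Sequence[float], mu: float = 0.0,
    sided: Literal["two", "greater", "less"] = "two",
) -> TTestResult:
    """One-sample t test against mu; effect size d = |mean - mu| / SD."""
    x = np.asarray(x, float)
    n = x.size
    if n < 2:
        raise StatsDomainError("need n >= 2")
    sd = x.std(ddof=1)
    mean = x.mean() - mu
    if sd == 0:
        t = 0.0 if mean == 0 else float(np.inf) * np.sign(mean)
        return TTestResult(t, n - 1, 1.0 if mean == 0 else 0.0,
                           0.0 if mean == 0 else float(np.inf), n,
                           "one_sample", sided, zero_variance=True)
    t = mean / (sd / np.sqrt(n))
    d = abs(mean) / sd
    return TTestResult(float(t), n - 1, _t_p(t, n - 1, sided), float(d), n,
                       "one_sample", sided)


def independent_t(
    a: Sequence[float], b: Sequence[float],
    sided: Literal["two", "greater", "less"] = "two",
) -> TTestResult:
    """Independent-samples t test with pooled variance; Cohen's d on pooled SD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise StatsDomainError("need n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        t = 0.0 if diff == 0 else float(np.inf) * np.sign(diff)
        return TTestResult(t, df, 1.0 if diff == 0 else 0.0,
                           0.0 if diff == 0 else float(np.inf),
                           na + nb, "independent", sided, zero_variance=True)
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    d = diff / np.sqrt(sp2)
    return TTestResult(float(t), df, _t_p(t, df, sided), float(d), na + nb,
                       "independent", sided)


def goodman_kruskal_gamma(
    scores: Sequence[float], choices: Sequence[int]
) -> GammaResult:
    """Goodman-Kruskal gamma between ordinal scores and binary choices.

    Over all pairs (i, j): concordant if the score and choice orderings
    agree, discordant if they disagree; pairs tied on either variable are
    dropped.  gamma = (C - D) / (C + D); undefined (``defined=False``) when
    C + D = 0, e.g. when all choices are identical.
    """
    s = np.asarray(scores, float)
    c = np.asarray(choices, float)
    if s.shape != c.shape:
        raise StatsDomainError("scores and choices must have equal length")
    if s.size < 2:
        raise StatsDomainError("need >= 2 observations")
    ds = np.sign(s[:, None] - s[None, :])
    dc = np.sign(c[:, None] - c[None, :])
    prod = ds * dc
    iu = np.triu_indices(s.size, k=1)
    prod = prod[iu]
    concordant = int(np.sum(prod > 0))
    discordant = int(np.sum(prod < 0))
    ties = int(np.sum(prod == 0))
    if concordant + discordant == 0:
        return GammaResult(None, concordant, discordant, ties, defined=False)
    gamma = (concordant - discordant) / (concordant + discordant)
    return GammaResult(float(gamma), concordant, discordant, ties, defined=True)


def gamma_group_test(gammas: Sequence[GammaResult | float | None]) -> TTestResult:
    """One-sample t test of the defined per-participant gammas against zero.

    Raw (untransformed) gammas are tested; participants with an undefined
    gamma are excluded listwise, which reduces the degrees of freedom.
    """
    values = []
    for g in gammas:
        if isinstance(g, GammaResult):
            if g.defined:
                values.append(g.gamma)
        elif g is not None and np.isfinite(g):
            values.append(float(g))
    if len(values) < 2:
        raise StatsDomainError("need >= 2 defined gammas")
    return one_sample_t(values, 0.0, sided="two")


def loftus_masson_ci(
    cell_matrix: np.ndarray | pd.DataFrame, confidence: float = 0.95
) -> WithinSubjectCI:
    """95% within-subject confidence intervals for condition means.

    After removing participant means, the shared interval half-width is
    ``t_{(1+conf)/2, (n-1)(k-1)} * sqrt(MS_{subject x condition} / n)``.
    """
    if isinstance(cell_matrix, pd.DataFrame):
        names = [str(c) for c in cell_matrix.columns]
        Y = cell_matrix.to_numpy(dtype=float)
    else:
        Y = np.asarray(cell_matrix, float)
        names = [f"condition_{i}" for i in range(Y.shape[1])]
    if Y.ndim != 2:
        raise StatsDomainError("cell_matrix must be 2-D (participants x conditions)")
    if np.isnan(Y).any():
        raise StatsDomainError("missing cells are not allowed")
    n, k = Y.shape
    if n < 2 or k < 2:
        raise StatsDomainError("need >= 2 participants and >= 2 conditions")
    grand = Y.mean()
    subj = Y.mean(axis=1, keepdims=True)
    cond = Y.mean(axis=0, keepdims=True)
    resid = Y - subj - cond + grand
    df_err = (n - 1) * (k - 1)
    ms_err = np.sum(resid**2) / df_err
    tcrit = float(stats.t.ppf(0.5 + confidence / 2, df_err))
    half = tcrit * np.sqrt(ms_err / n)
    return WithinSubjectCI(
        means={name: float(m) for name, m in zip(names, Y.mean(axis=0))},
        half_width=float(half),
        critical_t=tcrit,
        error_df=df_err,
    )


def paired_t_power(n: int, d_z: float, alpha: float, sided: str = "one") -> float:
    """Power of a paired t test at sample size n via the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = d_z * np.sqrt(n)
    if sided == "one":
        tcrit = stats.t.ppf(1 - alpha, df)
        return float(stats.nct.sf(tcrit, df, nc))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_n_paired_t(
    d_z: float,
    alpha: float = 0.05,
    power: float = 0.90,
    sided: Literal["one", "two"] = "one",
    n_max: int = 100_000,
) -> PowerResult:
    """Smallest n at which a paired t test reaches the target power.

    Searches n upward from 2, computing power as P(T' > t_crit(n-1, alpha))
    with noncentrality d_z * sqrt(n).
    """
    if not (d_z > 0):
        raise StatsDomainError("d_z must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise StatsDomainError("alpha and power must lie in (0, 1)")
    for n in range(2, n_max + 1):
        p = paired_t_power(n, d_z, alpha, sided)
        if p >= power:
            return PowerResult(n, p, d_z, alpha, power, sided)
    raise StatsDomainError(f"target power not reached by n={n_max}")


def restudy_rates_by_cell(
    trials: pd.DataFrame,
    cell_keys: Sequence[str],
    participant: str = "participant",
    choice: str = "restudy_choice",
) -> pd.DataFrame:
    """Relative restudy-choice frequency per participant per cell.

    Returns a long DataFrame with columns ``participant``, the cell keys,
    ``n_trials``, ``n_chosen`` and ``rate`` (chosen / total).  Cells that a
    participant never contributes to are simply absent, which downstream
    balanced analyses treat as listwise exclusion.
    """
    cols = [participant, *cell_keys]
    grouped = trials.groupby(cols, observed=True)[choice].agg(["size", "sum"])
    out = grouped.reset_index().rename(columns={"size": "n_trials", "sum": "n_chosen"})
    out["rate"] = out["n_chosen"] / out["n_trials"]
    return out
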