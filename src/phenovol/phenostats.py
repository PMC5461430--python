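"""Treatment-comparison statistics for the phenotyping experiment.

Group summaries (mean +- SE), one- and two-way ANOVA, Bonferroni-adjusted
pairwise post tests rendered as a compact letter display, percent change
versus control, and the conventional Fv/Fm stress classification.

Pairwise comparisons default to Welch (unequal-variance) t tests; the family
is all pairwise comparisons within one response at one time point, matching
per-panel letter displays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UnsupportedDesignError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "PosthocLetters",
    "group_summary",
    "one_way_anova",
    "two_way_anova",
    "pairwise_bonferroni",
    "bonferroni_letters",
    "percent_change",
    "classify_stress",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    timepoint: float
    n: int
    mean: float
    se: float


@dataclass(frozen=True)
class AnovaResult:
    """ANOVA table: per-factor F, degrees of freedom and p values."""

    factors: tuple
    f: Mapping[str, float]
    df: Mapping[str, float]
    p: Mapping[str, float]
    residual_df: float


@dataclass(frozen=True)
class PosthocLetters:
    """Compact letter display: groups sharing a letter do not differ at alpha."""

    letters: Mapping[str, str]
    alpha: float
    adjusted_p: Mapping[tuple, float]


def _as_groups(values_by_group) -> dict:
    if isinstance(values_by_group, pd.DataFrame):
        raise InvalidInputError("pass a mapping {group: values}, not a DataFrame")
    return {str(g): np.asarray(v, dtype=float)
            for g, v in values_by_group.items()}


def group_summary(values_by_group: Mapping, timepoint: float = 0.0) -> list:
    """Mean and standard error per group."""
    out = []
    for g, v in _as_groups(values_by_group).items():
        if v.size < 1:
            raise InvalidInputError(f"group '{g}' is empty")
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        out.append(GroupSummary(g, timepoint, int(v.size), float(v.mean()), se))
    return out


def one_way_anova(values_by_group: Mapping) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Between/within sums-of-squares decomposition with p from the F
    distribution. A design with zero residual variance but non-zero
    between-group variance yields p = 0 with a warning.
    """
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise InvalidInputError("one-way ANOVA needs >= 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise InvalidInputError(f"group '{g}' needs n >= 2")
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    ms_b = ss_between / df_b
    if ss_within == 0:
        if ss_between == 0:
            f, p = 0.0, 1.0
        else:
            warnings.warn("zero residual variance; p set to 0", stacklevel=2)
            f, p = np.inf, 0.0
    else:
        f = ms_b / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(("group",), {"group": float(f)}, {"group": float(df_b)},
                       {"group": float(p)}, float(df_w))


def two_way_anova(data: pd.DataFrame, response: str, factor_a: str,
                  factor_b: str) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction (balanced designs only).

    Type-I sums of squares via statsmodels OLS; unbalanced or incomplete
    factorials raise :class:`UnsupportedDesignError`.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    counts = data.groupby([factor_a, factor_b], observed=True)[response].count()
    n_a = data[factor_a].nunique()
    n_b = data[factor_b].nunique()
    if len(counts) != n_a * n_b or counts.nunique() != 1:
        raise UnsupportedDesignError(
            "two-way ANOVA requires a complete balanced factorial")
    if counts.iloc[0] < 2:
        raise UnsupportedDesignError("two-way ANOVA requires replication")
    df = data.rename(columns={response: "_y", factor_a: "_fa", factor_b: "_fb"})
    fit = smf.ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    table = anova_lm(fit, typ=1)
    key = {f"C(_fa)": factor_a, f"C(_fb)": factor_b,
           "C(_fa):C(_fb)": f"{factor_a}:{factor_b}"}
    f, dfs, p = {}, {}, {}
    for row, name in key.items():
        f[name] = float(table.loc[row, "F"])
        dfs[name] = float(table.loc[row, "df"])
        p[name] = float(table.loc[row, "PR(>F)"])
    return AnovaResult(tuple(key.values()), f, dfs, p,
                       float(table.loc["Residual", "df"]))


def pairwise_bonferroni(values_by_group: Mapping, equal_var: bool = False) -> dict:
    """Bonferroni-adjusted pairwise t-test p values (Welch by default).

    Returns {(group_i, group_j): adjusted p}, p multiplied by the number of
    comparisons and capped at 1.
    """
    groups = _as_groups(values_by_group)
    pairs = list(combinations(groups, 2))
    m = len(pairs)
    out = {}
    for a, b in pairs:
        if groups[a].size < 2 or groups[b].size < 2:
            raise InvalidInputError("pairwise tests need n >= 2 per group")
        res = stats.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        out[(a, b)] = min(float(res.pvalue) * m, 1.0)
    return out


def bonferroni_letters(values_by_group: Mapping, alpha: float = 0.05,
                       equal_var: bool = False) -> PosthocLetters:
    """Compact letter display from Bonferroni-adjusted pairwise tests.

    Letters are assigned by insert-and-absorb over groups sorted by mean:
    groups sharing a letter are not significantly different at ``alpha``.
    """
    groups = _as_groups(values_by_group)
    if len(groups) == 1:
        g = next(iter(groups))
        return PosthocLetters({g: "a"}, alpha, {})
    adj = pairwise_bonferroni(values_by_group, equal_var=equal_var)

    def differs(a: str, b: str) -> bool:
        return adj.get((a, b), adj.get((b, a), 1.0)) < alpha

    order = sorted(groups, key=lambda g: groups[g].mean())
    # Letter classes are the maximal cliques of the "not significantly
    # different" graph (insert-and-absorb endpoint): every non-different
    # pair shares a letter, no different pair ever does.
    classes: list[set] = []

    def extend(clique: set, candidates: list) -> None:
        grown = False
        for i, g in enumerate(candidates):
            if not any(differs(g, member) for member in clique):
                extend(clique | {g}, candidates[i + 1:])
                grown = True
        if not grown and not any(clique <= c for c in classes):
            classes.append(clique)

    extend(set(), order)
    classes.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, cls in zip(alphabet, classes):
        for g in cls:
            letters[g] += letter
    letters = {g: "".join(sorted(s)) for g, s in letters.items()}
    return PosthocLetters(letters, alpha, adj)


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Percent change of a treated mean relative to the control mean."""
    if control_mean <= 0:
        raise InvalidInputError("control mean must be > 0")
    return 100.0 * (treated_mean - control_mean) / control_mean


def classify_stress(record, threshold: float = 0.83) -> str:
    """Classify leaf tissue by Fv/Fm: unstressed iff strictly above threshold."""
    fvfm = record.fvfm if hasattr(record, "fvfm") else float(record)
    if not 0.0 <= fvfm <= 1.0:
        raise InvalidInputError("Fv/Fm must lie in [0, 1]")
    return "unstressed" if fvfm > threshold else "stressed"
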