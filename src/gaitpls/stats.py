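"""Group-level statistics framing the prediction analysis.

Severity matching (trimming the larger group's mildest subjects on
MDS-UPDRS-III so the two groups are the same size), the independent
t-test on improvement, the two-factor mixed-design ANOVA (between-subject
group, within-subject time or network, subject nested in group as the
error stratum), per-covariate ANCOVA, and Tukey-adjusted post hoc
comparisons on an ANOVA error term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gait import SubjectRecord

__all__ = [
    "MatchResult",
    "TTestResult",
    "match_on_severity",
    "independent_t",
    "mixed_anova",
    "ancova_group_effect",
    "tukey_posthoc",
    "baseline_network_anova",
]


@dataclass(frozen=True)
class MatchResult:
    """Result of trimming the larger group on a matching variable."""

    kept_ids: dict[str, list[str]]
    removed_ids: list[str]
    n_removed: int
    post_match_p: float

    @property
    def kept(self) -> list[str]:
        return [i for ids in self.kept_ids.values() for i in ids]


def match_on_severity(
    cohort: list[SubjectRecord], variable: str = "updrs_iii"
) -> MatchResult:
    """Equalize group sizes by removing the larger group's lowest scorers.

    The excess subjects with the lowest values of ``variable`` (mildest
    motor severity for MDS-UPDRS-III) are removed from the larger group;
    ties are broken by subject id order. The post-match two-sided pooled
    t-test p on the matching variable is reported.
    """
    by_group: dict[str, list[SubjectRecord]] = {}
    for rec in cohort:
        if getattr(rec, variable) is None:
            raise ValueError(f"subject {rec.id!r} is missing {variable!r}")
        by_group.setdefault(rec.group, []).append(rec)
    if len(by_group) != 2:
        raise ValueError(f"need exactly 2 groups, got {sorted(by_group)}")
    (g_small, small), (g_large, large) = sorted(
        by_group.items(), key=lambda kv: len(kv[1])
    )
    n_remove = len(large) - len(small)
    if n_remove == 0:
        import warnings

        warnings.warn("groups already equal in size; matching is a no-op")
    ranked = sorted(large, key=lambda r: (getattr(r, variable), r.id))
    removed = ranked[:n_remove]
    kept_large = [r for r in large if r not in removed]
    removed_ids = [r.id for r in removed]
    a = [getattr(r, variable) for r in small]
    b = [getattr(r, variable) for r in kept_large]
    post_p = independent_t(a, b).p
    return MatchResult(
        kept_ids={g_small: [r.id for r in small], g_large: [r.id for r in kept_large]},
        removed_ids=removed_ids,
        n_removed=n_remove,
        post_match_p=post_p,
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_difference: float


def independent_t(a, b, welch: bool = False) -> TTestResult:
    """Two-sided independent-samples t-test; pooled variance by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not welch:
        pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        if pooled == 0:
            raise ValueError("zero pooled variance; t undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TTestResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        mean_difference=float(a.mean() - b.mean()),
    )


def _anova_row(ss, df1, ms_error, df2):
    if ss == 0:
        return {"F": 0.0, "df1": df1, "df2": df2, "p": 1.0, "ss": ss}
    if ms_error == 0:
        return {"F": float("inf"), "df1": df1, "df2": df2, "p": 0.0, "ss": ss}
    F = (ss / df1) / ms_error
    return {
        "F": float(F),
        "df1": df1,
        "df2": df2,
        "p": float(sps.f.sf(F, df1, df2)),
        "ss": float(ss),
    }


def mixed_anova(values, group, within_name: str = "time") -> pd.DataFrame:
    """Two-factor mixed-design ANOVA by explicit sums of squares.

    Parameters
    ----------
    values : (n_subjects, n_levels) array or DataFrame — one row per
        subject, one column per level of the within-subject factor; each
        subject must be observed at every level (listwise-complete).
    group : length-n labels of the between-subject factor.
    within_name : label for the within factor in the output ("time" for the
        gait analysis, "network" for the baseline-thickness analysis).

    Returns
    -------
    DataFrame indexed by effect (group, within, interaction) with F, df1,
    df2, p and the effect sum of squares. The between-subject error stratum
    is subject-within-group; no sphericity correction is applied (with two
    within levels sphericity holds trivially).
    """
    vals = np.asarray(
        values.to_numpy() if isinstance(values, pd.DataFrame) else values, dtype=float
    )
    if vals.ndim != 2:
        raise ValueError("values must be a 2-d subject x level table")
    if not np.all(np.isfinite(vals)):
        raise ValueError(
            "missing cells in the within-subject table; apply listwise deletion first"
        )
    group = np.asarray(group)
    n, b = vals.shape
    if len(group) != n:
        raise ValueError("group labels do not match the number of subjects")
    levels = np.unique(group)
    a = len(levels)
    if a < 2 or b < 2:
        raise ValueError("need at least 2 groups and 2 within-factor levels")

    grand = vals.mean()
    subj_means = vals.mean(axis=1)
    col_means = vals.mean(axis=0)
    group_sizes = {g: int(np.sum(group == g)) for g in levels}
    group_means = {g: vals[group == g].mean() for g in levels}
    cell_means = {g: vals[group == g].mean(axis=0) for g in levels}

    ss_total = float(((vals - grand) ** 2).sum())
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    ss_group = float(
        b * sum(group_sizes[g] * (group_means[g] - grand) ** 2 for g in levels)
    )
    ss_subj_within = ss_between_subj - ss_group
    ss_within_subj = ss_total - ss_between_subj
    ss_within_factor = float(n * ((col_means - grand) ** 2).sum())
    ss_inter = float(
        sum(
            group_sizes[g]
            * ((cell_means[g] - group_means[g] - col_means + grand) ** 2).sum()
            for g in levels
        )
    )
    ss_error_within = ss_within_subj - ss_within_factor - ss_inter

    df_group, df_subj = a - 1, n - a
    df_within, df_err_w = b - 1, (n - a) * (b - 1)
    ms_subj = ss_subj_within / df_subj if df_subj > 0 else 0.0
    ms_err_w = ss_error_within / df_err_w if df_err_w > 0 else 0.0

    rows = {
        "group": _anova_row(ss_group, df_group, ms_subj, df_subj),
        within_name: _anova_row(ss_within_factor, df_within, ms_err_w, df_err_w),
        f"group x {within_name}": _anova_row(
            ss_inter, df_group * df_within, ms_err_w, df_err_w
        ),
    }
    return pd.DataFrame(rows).T


def ancova_group_effect(outcome, group, covariate) -> dict:
    """F-test for the group effect adjusted for one covariate.

    Fits ``outcome ~ group + covariate`` by OLS and reports the Type-III
    test for group (with a single covariate and no interaction this
    coincides with Type II). Covariates are controlled one at a time —
    five separate ANCOVAs in the gait analysis — not in one joint model.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    outcome = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    cov = np.asarray(covariate, dtype=float)
    if not (len(outcome) == len(group) == len(cov)):
        raise ValueError("outcome, group and covariate lengths differ")
    if len(outcome) < 4:
        raise ValueError("need at least 4 observations")
    data = pd.DataFrame({"y": outcome, "g": group.astype(str), "x": cov})
    # collinearity guard: covariate constant within the whole sample or
    # perfectly determined by group makes the adjusted group test singular
    if np.std(cov) == 0:
        raise ValueError("covariate is constant")
    resid_within = cov - data.groupby("g")["x"].transform("mean").to_numpy()
    if np.allclose(resid_within, 0):
        raise ValueError("covariate is collinear with group")
    model = ols("y ~ C(g) + x", data=data).fit()
    table = anova_lm(model, typ=2)
    row = table.loc["C(g)"]
    return {
        "F": float(row["F"]),
        "df1": float(row["df"]),
        "df2": float(table.loc["Residual", "df"]),
        "p": float(row["PR(>F)"]),
    }


def tukey_posthoc(cell_means, ms_error, df_error, ns) -> pd.DataFrame:
    """Tukey-adjusted pairwise comparisons on an ANOVA error term.

    For each pair of cells, the studentized range statistic
    ``q = |m_i - m_j| / sqrt(ms_error/2 * (1/n_i + 1/n_j))`` is referred to
    the studentized range distribution with k cells and ``df_error``
    degrees of freedom (the Tukey-Kramer form for unequal cell sizes).
    """
    means = np.asarray(cell_means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least 2 cells")
    if ns.size != k:
        raise ValueError("cell means and sizes differ in length")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if ms_error < 0:
        raise ValueError("ms_error must be >= 0")
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(ms_error / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            q = 0.0 if diff == 0 else float("inf")
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_error)) if np.isfinite(q) else 0.0
        rows.append(
            {"cell_i": i, "cell_j": j, "mean_diff": float(diff), "q": float(q),
             "p_adj": min(max(p, 0.0), 1.0)}
        )
    return pd.DataFrame(rows)


def baseline_network_anova(network_means, group) -> pd.DataFrame:
    """Mixed ANOVA of baseline thickness: networks (within) x group (between).

    ``network_means`` is the subjects x networks table of per-network mean
    thickness (mm); the same mixed-design engine as :func:`mixed_anova` is
    used with networks as the repeated factor.
    """
    return mixed_anova(network_means, group, within_name="network")
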