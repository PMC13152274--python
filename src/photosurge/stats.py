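"""Group comparisons for per-animal summaries (within-subject designs).

The test-selection policy mirrors standard practice for small repeated-
measures designs: Shapiro-Wilk normality per group plus a variance-
homogeneity check (F-test for two groups, Bartlett for more) choose
between the parametric branch (paired t for two groups; repeated-measures
ANOVA with Greenhouse-Geisser correction followed by Tukey on the
within-subject error term for three or more) and the non-parametric
branch (Wilcoxon signed-rank; Friedman followed by Dunn's multiple
comparisons).  Borderline cases fall to the non-parametric branch.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p: float
    posthoc: list = field(default_factory=list)  # (group_a, group_b, stat, p_adj)
    branch: str = ""
    normality_p: dict = field(default_factory=dict)
    variance_p: float = float("nan")

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _to_matrix(summaries: pd.DataFrame, value: str, group: str, subject: str):
    wide = summaries.pivot(index=subject, columns=group, values=value)
    if wide.isna().any().any():
        raise ValueError("unbalanced pairing: every subject needs every group")
    return wide


def dunn_posthoc(wide: pd.DataFrame) -> list[tuple]:
    """Dunn's multiple comparisons after Friedman (Bonferroni-adjusted).

    Ranks within each subject across groups; the z statistic for a pair is
    the mean-rank difference over its null SE sqrt(k(k+1)/(6n)).
    """
    ranks = wide.rank(axis=1)
    n, k = wide.shape
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(wide.columns, 2))
    out = []
    for a, b in pairs:
        zstat = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(zstat)) * len(pairs)  # Bonferroni
        out.append((a, b, float(zstat), float(min(1.0, p))))
    return out


def tukey_rm_posthoc(wide: pd.DataFrame) -> list[tuple]:
    """Tukey HSD on the within-subject error mean square.

    q = |mean_i - mean_j| / sqrt(MS_error / n) with MS_error from the
    subject-by-group residual of the RM decomposition; p from the
    studentized range with (n-1)(k-1) error df.
    """
    X = wide.to_numpy(float)
    n, k = X.shape
    grand = X.mean()
    row = X.mean(axis=1, keepdims=True)
    col = X.mean(axis=0, keepdims=True)
    resid = X - row - col + grand
    df_err = (n - 1) * (k - 1)
    ms_err = float((resid**2).sum() / df_err)
    out = []
    for a, b in itertools.combinations(range(k), 2):
        q = abs(X[:, a].mean() - X[:, b].mean()) / np.sqrt(ms_err / n)
        p = float(sps.studentized_range.sf(q, k, df_err))
        out.append((wide.columns[a], wide.columns[b], float(q), p))
    return out


def rm_anova_gg(wide: pd.DataFrame) -> tuple[float, float]:
    """Repeated-measures one-way ANOVA with Greenhouse-Geisser correction."""
    import pingouin as pg

    long = wide.reset_index().melt(
        id_vars=wide.index.name or "index", var_name="group", value_name="value"
    )
    long.columns = ["subject", "group", "value"]
    res = pg.rm_anova(
        data=long, dv="value", within="group", subject="subject", correction=True
    )
    row = res.iloc[0]
    p = row["p_unc"]
    if "p_GG_corr" in res.columns and np.isfinite(row["p_GG_corr"]):
        p = row["p_GG_corr"]
    return float(row["F"]), float(p)


def compare_groups(
    summaries: pd.DataFrame,
    value: str,
    group: str = "stage",
    subject: str = "animal_id",
    policy: str = "auto",
) -> GroupComparison:
    """Compare a summary metric across conditions, paired by animal.

    ``policy`` is ``"auto"`` (Shapiro-Wilk + variance homogeneity select
    the branch), ``"parametric"`` or ``"nonparametric"``.
    """
    wide = _to_matrix(summaries, value, group, subject)
    n, k = wide.shape
    if k < 2:
        raise ValueError("need at least two groups")
    groups = [wide[c].to_numpy(float) for c in wide.columns]

    normality_p = {}
    var_p = float("nan")
    if policy == "auto":
        for c, g in zip(wide.columns, groups):
            normality_p[c] = float(sps.shapiro(g).pvalue) if len(g) >= 3 else 1.0
        if k == 2:
            f = np.var(groups[0], ddof=1) / max(np.var(groups[1], ddof=1), 1e-300)
            d1 = d2 = n - 1
            var_p = float(2 * min(sps.f.sf(f, d1, d2), sps.f.cdf(f, d1, d2)))
        else:
            try:
                var_p = float(sps.bartlett(*groups).pvalue)
            except Exception:
                var_p = 0.0
        parametric = all(p > ALPHA for p in normality_p.values()) and var_p > ALPHA
        branch = "parametric" if parametric else "nonparametric"
        if not parametric:
            logger.info("non-parametric branch selected (normality/variance)")
    else:
        branch = policy

    if k == 2:
        d = groups[0] - groups[1]
        if branch == "parametric":
            res = sps.ttest_rel(groups[0], groups[1])
            return GroupComparison("paired-t", float(res.statistic), float(res.pvalue),
                                   [], branch, normality_p, var_p)
        res = sps.wilcoxon(groups[0], groups[1]) if np.any(d != 0) else None
        stat, p = (float(res.statistic), float(res.pvalue)) if res else (0.0, 1.0)
        return GroupComparison("wilcoxon", stat, p, [], branch, normality_p, var_p)

    if branch == "parametric":
        F, p = rm_anova_gg(wide)
        posthoc = tukey_rm_posthoc(wide) if p < ALPHA else []
        return GroupComparison("RM-ANOVA", F, p, posthoc, branch, normality_p, var_p)

    stat, p = sps.friedmanchisquare(*groups)
    posthoc = dunn_posthoc(wide) if p < ALPHA else []
    return GroupComparison("Friedman", float(stat), float(p), posthoc, branch,
                           normality_p, var_p)
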