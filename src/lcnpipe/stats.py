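"""Group comparison of quantified parameters.

Workflow used for every quantified parameter: Shapiro-Wilk normality per
group, one-way ANOVA across groups, and Tukey's honestly-significant-
difference test for pairwise comparisons at alpha = 0.05.  Non-normal
groups are flagged but ANOVA is still run (no nonparametric fallback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GroupStatsResult:
    """Descriptives, normality, ANOVA and Tukey HSD for one parameter."""

    group_summary: pd.DataFrame  # n, mean, median, sd, shapiro_p, normal
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, significant
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        rows = self.tukey[self.tukey["significant"]]
        return list(zip(rows["group_a"], rows["group_b"]))

    def summary(self) -> str:
        lines = [
            "Group summary:",
            self.group_summary.to_string(),
            f"One-way ANOVA: F = {self.anova_f:.4g}, p = {self.anova_p:.4g}",
            f"Tukey HSD (alpha = {self.alpha}):",
            self.tukey.to_string(index=False),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "groups": self.group_summary.reset_index().to_dict(orient="records"),
            "anova_F": self.anova_f,
            "anova_p": self.anova_p,
            "tukey": self.tukey.to_dict(orient="records"),
            "alpha": self.alpha,
        }


def compare_groups(
    values: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "value",
    alpha: float = 0.05,
) -> GroupStatsResult:
    """Compare a numeric parameter across groups.

    Requires at least two groups with at least two observations each; raises
    ``ValueError`` naming any offending group.
    """
    df = values[[group_col, value_col]].dropna()
    groups = {str(g): sub[value_col].to_numpy(float) for g, sub in df.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups, got {len(groups)}")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has {len(vals)} observation(s); need >= 2")

    rows = {}
    for name, vals in sorted(groups.items()):
        if np.ptp(vals) == 0:
            sw_p = np.nan  # Shapiro-Wilk undefined for constant data
        else:
            sw_p = float(sps.shapiro(vals).pvalue)
        rows[name] = {
            "n": len(vals),
            "mean": float(vals.mean()),
            "median": float(np.median(vals)),
            "sd": float(vals.std(ddof=1)),
            "shapiro_p": sw_p,
            "normal": bool(sw_p >= alpha) if np.isfinite(sw_p) else True,
        }
    summary = pd.DataFrame(rows).T
    summary.index.name = group_col

    f_stat, p_val = sps.f_oneway(*[groups[k] for k in sorted(groups)])
    if not np.isfinite(f_stat):  # identical groups: zero between- and within-variance
        f_stat, p_val = 0.0, 1.0

    tk = pairwise_tukeyhsd(
        df[value_col].to_numpy(float), df[group_col].astype(str).to_numpy(), alpha=alpha
    )
    pairs = _pairs(tk)
    tukey = pd.DataFrame(
        {
            "group_a": [p[0] for p in pairs],
            "group_b": [p[1] for p in pairs],
            "mean_diff": tk.meandiffs,
            "p_adj": tk.pvalues,
            "significant": tk.pvalues < alpha,
        }
    )
    return GroupStatsResult(
        group_summary=summary,
        anova_f=float(f_stat),
        anova_p=float(p_val),
        tukey=tukey,
        alpha=alpha,
    )


def _pairs(tk) -> list[tuple[str, str]]:
    names = tk.groupsunique
    return [(str(names[i]), str(names[j])) for i, j in zip(*tk._multicomp.pairindices)]


def annotate(p_value: float, alpha: float = 0.05) -> str:
    """Boxplot-style significance annotation: '*' if p < alpha else 'ns'."""
    return "*" if p_value < alpha else "ns"


def plot_groups(values: pd.DataFrame, group_col: str = "group", value_col: str = "value", ax=None):
    """Boxplot of per-group values (matplotlib); returns the axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = sorted(values[group_col].astype(str).unique())
    data = [values.loc[values[group_col].astype(str) == n, value_col] for n in names]
    ax.boxplot(data, tick_labels=names, showmeans=True)
    ax.set_ylabel(value_col)
    return ax
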