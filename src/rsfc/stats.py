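"""Group-level inference.

Mixed between/within ANOVA interaction, Bonferroni-corrected paired
t-tests with Cohen's d, the dependent-correlation z test for two
correlations sharing one variable, and one-way ANOVA with partial
eta-squared.  All p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sst

__all__ = [
    "StatResult",
    "mixed_anova_interaction",
    "paired_ttest_cohend",
    "bonferroni_adjust",
    "pearson_filon_z",
    "oneway_anova_eta",
]


@dataclass
class StatResult:
    """One group-level test: statistic, dof, p, effect size, correction."""

    name: str
    statistic: float
    dof: tuple[float, ...]  # one dof for t/z (z: empty), two for F
    p: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    correction: str = "none"
    m_comparisons: int = 1
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")
        if any(d <= 0 for d in self.dof):
            raise ValueError("degrees of freedom must be positive")
        if self.correction not in ("none", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")


def mixed_anova_interaction(
    values: np.ndarray,
    groups: Sequence,
    name: str = "group_x_condition",
) -> StatResult:
    """Group-by-condition interaction F for a two-level within factor.

    ``values`` is subjects x 2 (each subject measured in both within-factor
    cells); ``groups`` assigns each subject to a between-subject group.
    The interaction is tested through the within-subject part of the
    mixed-design decomposition: with difference scores ``d_i = y_i2 -
    y_i1``,

        SS_interaction = sum_g n_g (dbar_g - dbar)^2 / 2
        SS_error       = sum_g sum_i (d_i - dbar_g)^2 / 2
        F = (SS_interaction / (g - 1)) / (SS_error / (N - g))

    For two groups this equals the squared pooled two-sample t on the
    difference scores.  Subjects with a missing cell are dropped with a
    warning.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("values must be subjects x 2 (two within-factor cells)")
    if g.shape[0] != y.shape[0]:
        raise ValueError("groups length differs from number of subjects")
    complete = np.all(np.isfinite(y), axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} subject(s) with a missing cell")
        y, g = y[complete], g[complete]
    labels = np.unique(g)
    if labels.size < 2:
        raise ValueError("need at least 2 between-subject groups")
    counts = np.array([(g == lab).sum() for lab in labels])
    if np.any(counts < 2):
        small = [str(lab) for lab, c in zip(labels, counts) if c < 2]
        raise ValueError(f"group(s) with fewer than 2 subjects: {small}")

    d = y[:, 1] - y[:, 0]
    n_total = d.size
    dbar = d.mean()
    group_means = np.array([d[g == lab].mean() for lab in labels])
    ss_inter = float(np.sum(counts * (group_means - dbar) ** 2) / 2.0)
    ss_err = float(
        sum(np.sum((d[g == lab] - mu) ** 2) for lab, mu in zip(labels, group_means)) / 2.0
    )
    df1, df2 = labels.size - 1, n_total - labels.size
    if ss_err == 0.0:
        raise ValueError("zero within-group variance of difference scores")
    f = (ss_inter / df1) / (ss_err / df2)
    p = float(sst.f.sf(f, df1, df2))
    eta = ss_inter / (ss_inter + ss_err)
    return StatResult(
        name=name, statistic=float(f), dof=(float(df1), float(df2)), p=p,
        effect_size=float(eta), effect_size_name="partial_eta2",
    )


def paired_ttest_cohend(
    values_a: np.ndarray, values_b: np.ndarray, name: str = "paired_t"
) -> StatResult:
    """Two-sided paired t-test with Cohen's d for paired samples.

    ``t = mean(d) / (sd(d) / sqrt(n))`` and ``d_effect = mean(d) / sd(d)``
    with the n-1 sample SD, where ``d = a - b``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be 1-D and equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2.0 * sst.t.sf(abs(t), n - 1))
    return StatResult(
        name=name, statistic=float(t), dof=(float(n - 1),), p=p,
        effect_size=float(d.mean() / sd), effect_size_name="cohen_d",
    )


def bonferroni_adjust(p_values: Sequence[float] | float, m: int | None = None):
    """``p_adj = min(1, m * p)``; ``m`` defaults to the family size."""
    scalar = np.isscalar(p_values)
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = int(m) if m is not None else p.size
    if m_eff < 1:
        raise ValueError("m must be >= 1")
    adjusted = np.minimum(1.0, m_eff * p)
    return float(adjusted[0]) if scalar else adjusted


def pearson_filon_z(
    r_jk: float, r_hk: float, r_jh: float, n: int, name: str = "pearson_filon_z"
) -> StatResult:
    """z test for two dependent correlations sharing variable k.

    With ``k_term = r_jh (1 - r_jk^2 - r_hk^2) - r_jk r_hk
    (1 - r_jk^2 - r_hk^2 - r_jh^2) / 2``,

        z = sqrt(n) (r_jk - r_hk)
            / sqrt((1 - r_jk^2)^2 + (1 - r_hk^2)^2 - 2 k_term)

    with a two-sided p from the standard normal.
    """
    for label, r in (("r_jk", r_jk), ("r_hk", r_hk), ("r_jh", r_jh)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{label}={r} must lie strictly in (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    k_term = r_jh * (1 - r_jk**2 - r_hk**2) - 0.5 * r_jk * r_hk * (
        1 - r_jk**2 - r_hk**2 - r_jh**2
    )
    disc = (1 - r_jk**2) ** 2 + (1 - r_hk**2) ** 2 - 2 * k_term
    if disc <= 0.0:
        raise ValueError(f"non-positive variance term ({disc:.3g}); correlations inconsistent")
    z = np.sqrt(n) * (r_jk - r_hk) / np.sqrt(disc)
    p = float(2.0 * sst.norm.sf(abs(z)))
    return StatResult(name=name, statistic=float(z), dof=(), p=p)


def oneway_anova_eta(groups: Sequence[np.ndarray], name: str = "oneway_anova") -> StatResult:
    """One-way ANOVA F with partial eta-squared.

    ``partial eta^2 = SS_between / (SS_between + SS_within)``, which for a
    one-way design equals plain eta-squared.
    """
    arrays = [np.asarray(x, dtype=float).ravel() for x in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(np.sum((a - a.mean()) ** 2) for a in arrays))
    df1 = len(arrays) - 1
    df2 = all_values.size - len(arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return StatResult(name=name, statistic=0.0, dof=(float(df1), float(df2)),
                              p=1.0, effect_size=0.0, effect_size_name="partial_eta2")
        raise ValueError("zero within-group variance with nonzero between-group variance")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sst.f.sf(f, df1, df2))
    eta = ss_between / (ss_between + ss_within)
    return StatResult(
        name=name, statistic=float(f), dof=(float(df1), float(df2)), p=p,
        effect_size=float(eta), effect_size_name="partial_eta2",
    )
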