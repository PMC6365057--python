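"""Group-comparison decision procedure.

The decision tree mirrors common practice in quantitative embryology
figure legends: per-group normality is assessed with the D'Agostino–Pearson
omnibus test; two normal groups are compared with an unpaired two-sided
t-test, two non-normal groups with a Mann-Whitney test; more than two
normal groups with one-way ANOVA followed by Tukey's multiple-comparison
test, otherwise Kruskal-Wallis followed by Dunn's multiple-comparison test.

The chosen test is a pure function of (group count, per-group normality
verdicts, paired flag). The omnibus normality test is undefined below 8
observations; such groups get verdict ``None`` and the comparison falls back
to the nonparametric branch, with the reason recorded in ``notes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "dunn_posthoc"]

MIN_N_NORMALITY = 8  # D'Agostino-Pearson needs >= 8 observations


@dataclass
class GroupComparison:
    groups: list
    test_name: str
    statistic: float
    p_value: float
    normality: dict  # label -> bool | None (None: not testable)
    posthoc: pd.DataFrame | None = None
    alpha: float = 0.05
    notes: list = field(default_factory=list)


def _normality(values: np.ndarray, alpha: float):
    """D'Agostino-Pearson verdict: True/False, or None when n < 8."""
    if len(values) < MIN_N_NORMALITY:
        return None
    _, p = sps.normaltest(values)
    return bool(p >= alpha)


def dunn_posthoc(samples: dict, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise rank-sum comparisons after Kruskal-Wallis.

    Pooled ranks (mid-ranks on ties, with tie correction); pairwise z
    statistics; two-sided normal p-values adjusted by Bonferroni (default),
    Holm, or left unadjusted.
    """
    labels = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in labels])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    offsets = np.cumsum([0] + [len(samples[g]) for g in labels])
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(labels)
    }
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            na, nb = len(samples[a]), len(samples[b])
            se = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
            )
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append((a, b, z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw"])
    m = len(df)
    if adjust == "bonferroni":
        df["p_adj"] = np.minimum(df["p_raw"] * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(df["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_adj"] = adj
    elif adjust == "none":
        df["p_adj"] = df["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def compare_groups(
    samples: dict,
    alpha: float = 0.05,
    paired: bool = False,
    dunn_adjust: str = "bonferroni",
) -> GroupComparison:
    """Compare ≥ 2 groups following the normality-gated decision tree.

    ``samples`` maps group label → 1D values (each n ≥ 3). Two groups:
    unpaired two-sided t-test when every group passes the omnibus normality
    test at ``alpha``, otherwise Mann-Whitney (paired=True switches these to
    paired t-test / Wilcoxon signed-rank). More than two groups: one-way
    ANOVA + Tukey HSD, or Kruskal-Wallis + Dunn. Groups too small for the
    normality test (n < 8) force the nonparametric branch.
    """
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(samples[g], dtype=float) for g in labels}
    for g, v in arrays.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has n={len(v)} < 3")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {g!r} contains non-finite values")

    notes = []
    normality = {g: _normality(v, alpha) for g, v in arrays.items()}
    untestable = [g for g, verdict in normality.items() if verdict is None]
    if untestable:
        notes.append(
            f"groups {untestable} have n < {MIN_N_NORMALITY}: normality not "
            "testable, using the nonparametric branch"
        )
    all_normal = all(v is True for v in normality.values())

    values = [arrays[g] for g in labels]
    posthoc = None
    if len(labels) == 2:
        if all_normal:
            if paired:
                stat, p = sps.ttest_rel(*values)
                name = "paired t-test"
            else:
                stat, p = sps.ttest_ind(*values, equal_var=True)
                name = "unpaired t-test"
        else:
            if paired:
                stat, p = sps.wilcoxon(*values)
                name = "Wilcoxon signed-rank"
            else:
                stat, p = sps.mannwhitneyu(*values, alternative="two-sided")
                name = "Mann-Whitney"
    else:
        if paired:
            notes.append("paired flag ignored for > 2 groups")
        if all_normal:
            stat, p = sps.f_oneway(*values)
            name = "one-way ANOVA + Tukey"
            res = sps.tukey_hsd(*values)
            rows = []
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    rows.append(
                        (labels[i], labels[j], res.statistic[i, j], res.pvalue[i, j])
                    )
            posthoc = pd.DataFrame(
                rows, columns=["group_a", "group_b", "statistic", "p_adj"]
            )
        else:
            stat, p = sps.kruskal(*values)
            name = "Kruskal-Wallis + Dunn"
            posthoc = dunn_posthoc(arrays, adjust=dunn_adjust)

    return GroupComparison(
        groups=labels,
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        normality=normality,
        posthoc=posthoc,
        alpha=alpha,
        notes=notes,
    )
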