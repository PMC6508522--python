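"""Metabolite contrast statistics and F1 heterosis analysis.

The input is a long-format table of relative concentrations
(metabolite, compound class, experiment, genotype, replicate, value)
covering two experiments: experiment 1 measures the SH and YK parents,
experiment 2 additionally measures the SH x YK F1 hybrid.

Per metabolite the module provides: two-tailed parent t tests within
each experiment (pooled-variance default, Welch switch), Tukey's
studentized range test across the three genotypes, an additive
two-factor ANOVA over both experiments (experiment + genotype, no
interaction), a one-sample t test of the F1 against the mid-parent
value using the F1 variance only, transgressive classification against
the extreme parent with the F1/high-parent (or low-parent/F1) ratio,
an exact binomial test for the direction of transgression, a 2x2
chi-squared association between parental difference and heterosis, the
pooled maltose+glucose starch proxy, and the below-mid-parent summary
fraction.

No multiple-testing correction is applied across metabolites (matching
the star convention of the source analysis); a supplementary BH column
is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

ALPHA = 0.05


@dataclass(frozen=True)
class TTestResult:
    metabolite: str
    experiment: int
    mean_sh: float
    mean_yk: float
    statistic: float
    pvalue: float
    testable: bool


@dataclass(frozen=True)
class HeterosisCall:
    metabolite: str
    compound_class: str
    mid_parent: float
    f1_mean: float
    below_mid_parent: bool
    p_mid_parent: float
    transgressive: str        # "none" | "high" | "low"
    p_transgressive: float
    ratio: float              # F1/high-parent (high) or low-parent/F1 (low)
    parent_detected: str      # "both" | "one"


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray         # 2x2: parental difference yes/no x heterosis yes/no
    statistic: float
    pvalue: float
    test_used: str            # "chi-squared" | "binomial-exact"


def _values(records: pd.DataFrame, metabolite: str, experiment: int, genotype: str):
    mask = (
        (records["metabolite"] == metabolite)
        & (records["experiment"] == experiment)
        & (records["genotype"] == genotype)
    )
    return records.loc[mask, "value"].to_numpy(dtype=float)


def two_sample_ttest(x, y, welch: bool = False, axis: int = -1):
    """Two-tailed two-sample t test (pooled variance unless welch)."""
    res = stats.ttest_ind(x, y, axis=axis, equal_var=not welch)
    return res.statistic, res.pvalue


def one_sample_ttest(x, popmean, axis: int = -1):
    """Two-tailed one-sample t test against a constant."""
    res = stats.ttest_1samp(x, popmean, axis=axis)
    return res.statistic, res.pvalue


def per_experiment_ttest(
    records: pd.DataFrame, metabolite: str, experiment: int, welch: bool = False
) -> TTestResult:
    """SH-vs-YK two-tailed t test within one experiment.

    Metabolites absent in one genotype (all-zero) are still tested when
    some variance remains; a completely variance-free contrast with
    equal means is p = 1, and with unequal means it is flagged
    untestable rather than assigned p = 0.
    """
    sh = _values(records, metabolite, experiment, "SH")
    yk = _values(records, metabolite, experiment, "YK")
    if len(sh) < 2 or len(yk) < 2:
        raise ValueError(f"need >=2 replicates per genotype for {metabolite}")
    mean_sh, mean_yk = float(np.mean(sh)), float(np.mean(yk))
    if np.var(sh) == 0 and np.var(yk) == 0:
        if mean_sh == mean_yk:
            return TTestResult(metabolite, experiment, mean_sh, mean_yk, 0.0, 1.0, True)
        return TTestResult(
            metabolite, experiment, mean_sh, mean_yk, float("nan"), float("nan"), False
        )
    t, p = two_sample_ttest(sh, yk, welch=welch)
    return TTestResult(metabolite, experiment, mean_sh, mean_yk, float(t), float(p), True)


def tukey_hsd_genotypes(
    records: pd.DataFrame, metabolite: str, experiment: int = 2
) -> dict[tuple[str, str], float]:
    """Tukey studentized-range pairwise p-values for SH/YK/F1."""
    groups = [_values(records, metabolite, experiment, g) for g in ("SH", "YK", "F1")]
    names = ("SH", "YK", "F1")
    if any(len(g) < 2 for g in groups):
        raise ValueError("all three genotypes must be present with >=2 replicates")
    if all(np.var(g) == 0 for g in groups):
        # degenerate MSE: identical means -> no evidence; any difference is exact
        out = {}
        for i in range(3):
            for j in range(i + 1, 3):
                out[(names[i], names[j])] = 1.0 if np.mean(groups[i]) == np.mean(groups[j]) else 0.0
        return out
    res = stats.tukey_hsd(*groups)
    return {
        (names[i], names[j]): float(res.pvalue[i, j])
        for i in range(3)
        for j in range(i + 1, 3)
    }


def anova_additive(y, factor_a, factor_b):
    """Additive two-factor fixed-effects ANOVA (no interaction).

    ``y`` may be 1-D (one table) or 2-D with replicate tables in rows;
    factors are integer codes of length n.  Returns type-II F-test
    p-values ``(p_a, p_b)`` computed from residual sums of squares of
    nested least-squares fits, so unbalanced layouts are handled.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    n = y.shape[-1]
    if len(a) != n or len(b) != n:
        raise ValueError("factor length must match the number of observations")

    def dummies(codes):
        levels = np.unique(codes)
        return (codes[:, None] == levels[1:][None, :]).astype(float)

    X_full = np.column_stack([np.ones(n), dummies(a), dummies(b)])
    X_no_a = np.column_stack([np.ones(n), dummies(b)])
    X_no_b = np.column_stack([np.ones(n), dummies(a)])

    def rss(X):
        Q, _ = np.linalg.qr(X)
        resid = y - (y @ Q) @ Q.T
        return (resid**2).sum(axis=-1), X.shape[1]

    rss_full, k_full = rss(X_full)
    df_res = n - k_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    out = []
    for X_red, k_red in ((X_no_a, X_no_a.shape[1]), (X_no_b, X_no_b.shape[1])):
        rss_red, _ = rss(X_red)
        df_num = k_full - k_red
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (rss_red - rss_full) / df_num / (rss_full / df_res)
        p = stats.f.sf(F, df_num, df_res)
        out.append(p if p.ndim else float(p))
    p_a, p_b = out
    if y.shape[0] == 1:
        return float(np.squeeze(p_a)), float(np.squeeze(p_b))
    return p_a, p_b


def nested_anova(records: pd.DataFrame, metabolite: str, nested: bool = False):
    """Genotype and experiment p-values from the combined two-experiment model.

    The default is the additive two-factor model (experiment + genotype,
    no interaction) applied to the parents measured in both experiments.
    ``nested=True`` instead codes genotype within experiment
    (genotype-within-experiment nested variant).
    """
    mask = (records["metabolite"] == metabolite) & records["genotype"].isin(("SH", "YK"))
    sub = records.loc[mask]
    if sub["experiment"].nunique() < 2:
        raise ValueError(f"{metabolite}: both experiments required")
    y = sub["value"].to_numpy(dtype=float)
    g = pd.factorize(sub["genotype"])[0]
    e = pd.factorize(sub["experiment"])[0]
    if nested:
        g = pd.factorize(list(zip(sub["experiment"], sub["genotype"])))[0]
    p_g, p_e = anova_additive(y, g, e)
    return p_g, p_e


def mid_parent_test(records: pd.DataFrame, metabolite: str, experiment: int = 2):
    """One-sample t of the F1 replicates against the constant mid-parent mean.

    The mid-parent value is the average of the two parental means in
    the same experiment; only the F1 variance enters the test
    (df = n_F1 - 1).  Returns (mid_parent, f1_mean, below, t, p).
    """
    f1 = _values(records, metabolite, experiment, "F1")
    if len(f1) < 2:
        raise ValueError(f"{metabolite}: need >=2 F1 replicates")
    sh = _values(records, metabolite, experiment, "SH")
    yk = _values(records, metabolite, experiment, "YK")
    mid = (float(np.mean(sh)) + float(np.mean(yk))) / 2.0
    f1_mean = float(np.mean(f1))
    if np.var(f1) == 0:
        t = 0.0 if f1_mean == mid else float("inf") * np.sign(f1_mean - mid)
        p = 1.0 if f1_mean == mid else 0.0
    else:
        t, p = one_sample_ttest(f1, mid)
    return mid, f1_mean, bool(f1_mean < mid), float(t), float(p)


def transgressive_classify(
    records: pd.DataFrame, metabolite: str, experiment: int = 2, alpha: float = ALPHA
):
    """Transgression label and ratio against the extreme parent.

    The F1 is compared by two-tailed two-sample t test with the high
    parent (upward) or the low parent (downward); the label applies
    only when the F1 mean lies beyond that parent and p <= alpha.  The
    ratio is F1/high-parent for upward and low-parent/F1 for downward
    transgression.  Returns (label, p, ratio, parent_detected).
    """
    sh = _values(records, metabolite, experiment, "SH")
    yk = _values(records, metabolite, experiment, "YK")
    f1 = _values(records, metabolite, experiment, "F1")
    if len(f1) < 2:
        raise ValueError(f"{metabolite}: need >=2 F1 replicates")
    mean_sh, mean_yk, f1_mean = np.mean(sh), np.mean(yk), np.mean(f1)
    parent_detected = "both" if mean_sh > 0 and mean_yk > 0 else "one"
    hi_vals, lo_vals = (sh, yk) if mean_sh >= mean_yk else (yk, sh)
    hi_mean, lo_mean = np.mean(hi_vals), np.mean(lo_vals)

    label, p, ratio = "none", float("nan"), float("nan")
    if f1_mean > hi_mean:
        _, p = two_sample_ttest(f1, hi_vals)
        if p <= alpha:
            label = "high"
            ratio = float(f1_mean / hi_mean) if hi_mean > 0 else float("inf")
    elif f1_mean < lo_mean:
        _, p = two_sample_ttest(f1, lo_vals)
        if p <= alpha:
            label = "low"
            ratio = float(lo_mean / f1_mean) if f1_mean > 0 else float("inf")
    return label, float(p), ratio, parent_detected


def heterosis_calls(
    records: pd.DataFrame, experiment: int = 2, alpha: float = ALPHA
) -> list[HeterosisCall]:
    """Mid-parent and transgression analysis for every F1-measured metabolite."""
    sub = records[records["experiment"] == experiment]
    classes = records.drop_duplicates("metabolite").set_index("metabolite")["class"]
    calls = []
    for met in sub["metabolite"].unique():
        genos = set(sub.loc[sub["metabolite"] == met, "genotype"])
        if not {"SH", "YK", "F1"} <= genos:
            continue
        mid, f1_mean, below, _, p_mid = mid_parent_test(records, met, experiment)
        label, p_tr, ratio, parent_detected = transgressive_classify(
            records, met, experiment, alpha
        )
        calls.append(
            HeterosisCall(
                metabolite=met,
                compound_class=str(classes.get(met, "other")),
                mid_parent=mid,
                f1_mean=f1_mean,
                below_mid_parent=below,
                p_mid_parent=p_mid,
                transgressive=label,
                p_transgressive=p_tr,
                ratio=ratio,
                parent_detected=parent_detected,
            )
        )
    return calls


def classify_heterosis_modes(
    records: pd.DataFrame, experiment: int = 2, alpha: float = ALPHA
) -> dict[str, str]:
    """Additive / dominant / transgressive mode for each metabolite.

    Transgressive metabolites are those flagged by the extreme-parent
    test (beyond the extreme parent at p <= alpha).  The remaining
    calls are split by proximity of the F1 mean to the mid-parent value
    versus the nearer parent: a significance-only dominance rule would
    be hopelessly underpowered at n=3 (df=2), whereas the proximity
    rule separates the two hypotheses at the quarter-span boundary.
    """
    sub = records[records["experiment"] == experiment]
    modes: dict[str, str] = {}
    for met in sub["metabolite"].unique():
        genos = set(sub.loc[sub["metabolite"] == met, "genotype"])
        if not {"SH", "YK", "F1"} <= genos:
            continue
        label, _, _, _ = transgressive_classify(records, met, experiment, alpha)
        if label == "high":
            modes[met] = "transgressive_up"
            continue
        if label == "low":
            modes[met] = "transgressive_down"
            continue
        sh = np.mean(_values(records, met, experiment, "SH"))
        yk = np.mean(_values(records, met, experiment, "YK"))
        f1 = np.mean(_values(records, met, experiment, "F1"))
        mid = (sh + yk) / 2.0
        nearer_parent = sh if abs(f1 - sh) <= abs(f1 - yk) else yk
        modes[met] = "additive" if abs(f1 - mid) <= abs(f1 - nearer_parent) else "dominant"
    return modes


def direction_binomial(calls: list[HeterosisCall]) -> tuple[int, int, float]:
    """Exact two-sided binomial test of low- vs high-transgression counts.

    Only metabolites detected in both parents enter.  Returns
    (n_low, n_high, p).
    """
    trans = [c for c in calls if c.transgressive != "none" and c.parent_detected == "both"]
    if not trans:
        raise ValueError("no transgressive calls among both-parent metabolites")
    n_low = sum(1 for c in trans if c.transgressive == "low")
    n_high = len(trans) - n_low
    p = stats.binomtest(n_low, len(trans), 0.5, alternative="two-sided").pvalue
    return n_low, n_high, float(p)


def chi2_independence(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction: sum (O-E)^2/E."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("a 2x2 table of non-negative counts is required")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    expected = row @ col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0).sum()
    return float(stat), float(stats.chi2.sf(stat, df=1))


def heterosis_contingency(
    calls: list[HeterosisCall],
    parental_p: dict[str, float],
    alpha: float = ALPHA,
    heterosis_def: str = "transgressive",
    exact: bool = False,
) -> ContingencyResult:
    """2x2 association of parental difference with heterosis.

    Rows: parental SH-vs-YK difference significant yes/no (p <= alpha
    in the F1-bearing experiment); columns: heterosis yes/no, where
    heterosis is transgression (default) or significant mid-parent
    deviation (``heterosis_def="mid_parent"``).  ``exact=True`` switches
    to Fisher's exact test for sparse tables.
    """
    table = np.zeros((2, 2))
    for call in calls:
        p_par = parental_p.get(call.metabolite)
        if p_par is None or not np.isfinite(p_par):
            continue
        diff = p_par <= alpha
        if heterosis_def == "transgressive":
            het = call.transgressive != "none"
        elif heterosis_def == "mid_parent":
            het = call.p_mid_parent <= alpha
        else:
            raise ValueError("heterosis_def must be 'transgressive' or 'mid_parent'")
        table[0 if diff else 1, 0 if het else 1] += 1
    if exact:
        p = float(stats.fisher_exact(table.astype(int))[1])
        return ContingencyResult(table, float("nan"), p, "binomial-exact")
    stat, p = chi2_independence(table)
    return ContingencyResult(table, stat, p, "chi-squared")


def starch_proxy_from_means(means: pd.DataFrame) -> float:
    """SH/YK ratio of maltose+glucose pooled over both experiments.

    ``means`` is long-format with columns metabolite, experiment,
    genotype, mean; maltose and glucose must be present for both
    genotypes in both experiments.
    """
    sub = means[means["metabolite"].str.lower().isin(("maltose", "glucose"))]
    sums = sub.groupby("genotype")["mean"].sum()
    for genotype in ("SH", "YK"):
        if genotype not in sums.index:
            raise ValueError(f"missing {genotype} maltose/glucose means")
    n_cells = sub.groupby(["metabolite", "genotype"])["experiment"].nunique()
    if (n_cells < 2).any():
        raise ValueError("maltose and glucose must be present in both experiments")
    return float(sums["SH"] / sums["YK"])


def starch_proxy(records: pd.DataFrame) -> float:
    """Starch proxy computed from replicate-level records."""
    sub = records[records["metabolite"].str.lower().isin(("maltose", "glucose"))]
    means = (
        sub[sub["genotype"].isin(("SH", "YK"))]
        .groupby(["metabolite", "experiment", "genotype"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "mean"})
    )
    return starch_proxy_from_means(means)


def summarize_mid_parent_fraction(calls: list[HeterosisCall]) -> dict:
    """Fraction of metabolites whose F1 mean falls below the mid-parent value.

    Reports both the mean-comparison count and the count restricted to
    significant mid-parent deviations, plus a per-compound-class
    breakdown.
    """
    if not calls:
        raise ValueError("no heterosis calls")
    n = len(calls)
    below = [c for c in calls if c.below_mid_parent]
    sig_below = [c for c in below if c.p_mid_parent <= ALPHA]
    per_class: dict[str, float] = {}
    for cls in sorted({c.compound_class for c in calls}):
        cls_calls = [c for c in calls if c.compound_class == cls]
        per_class[cls] = sum(c.below_mid_parent for c in cls_calls) / len(cls_calls)
    return {
        "n_metabolites": n,
        "fraction_below_mid_parent": len(below) / n,
        "fraction_significantly_below": len(sig_below) / n,
        "per_class_below": per_class,
    }


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    for cutoff, mark in _STAR_LEVELS:
        if p < cutoff:
            return mark
    return "n.s."


def metabolite_table(records: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Per-metabolite parent means and significance summary.

    One row per metabolite: per-experiment SH/YK means, per-experiment t
    p-values, the combined additive-ANOVA genotype p-value, their star
    codes, and a supplementary BH-adjusted column per test family.
    """
    rows = []
    for met in records["metabolite"].unique():
        cls = records.loc[records["metabolite"] == met, "class"].iloc[0]
        row: dict = {"metabolite": met, "class": cls}
        experiments = sorted(
            records.loc[
                (records["metabolite"] == met) & records["genotype"].isin(("SH", "YK")),
                "experiment",
            ].unique()
        )
        for e in experiments:
            try:
                res = per_experiment_ttest(records, met, e, welch=welch)
            except ValueError:
                continue
            row[f"mean_sh_e{e}"] = res.mean_sh
            row[f"mean_yk_e{e}"] = res.mean_yk
            row[f"p_e{e}"] = res.pvalue if res.testable else float("nan")
        if len(experiments) == 2:
            try:
                row["p_nested"], row["p_experiment"] = nested_anova(records, met)
            except ValueError:
                pass
        rows.append(row)
    table = pd.DataFrame(rows)
    for col in ("p_e1", "p_e2", "p_nested"):
        if col in table:
            table[f"stars_{col[2:]}"] = table[col].map(stars)
            finite = table[col].notna()
            adj = np.full(len(table), np.nan)
            if finite.any():
                adj[finite.to_numpy()] = bh_adjust(table.loc[finite, col].to_numpy())
            table[f"padj_{col[2:]}"] = adj
    return table
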