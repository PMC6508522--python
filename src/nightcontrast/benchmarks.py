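"""End-to-end benchmark measurements on synthetic and printed data.

Each function regenerates its inputs, runs the relevant pipeline stage,
and measures recovery of the planted (or printed) truth.  They back
both the validation test suite and the reproduction script; every
quantity is recomputed at call time.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from . import enrichment, expression, metabolites, qpcr, reference_data, variants
from .simulate import SimConfig, simulate_counts, simulate_metabolome, simulate_pileups


def fold_display_check() -> dict:
    """Reproduce every printed DEG fold / absence label from raw counts."""
    bench = reference_data.deg_benchmark()
    numeric = matched_numeric = absence = matched_absence = 0
    for row in bench.itertuples():
        computed = expression.fold_change(row.count_sh, row.count_yk)
        if isinstance(row.printed_fold, str):
            absence += 1
            matched_absence += int(computed == row.printed_fold)
        else:
            numeric += 1
            matched_numeric += int(
                expression.display_fold(computed) == row.printed_fold
            )
    return {
        "n_numeric": numeric,
        "matched_numeric": matched_numeric,
        "n_absence": absence,
        "matched_absence": matched_absence,
    }


def qrt_concordance_check() -> dict:
    """Directional agreement of qRT-PCR verdicts with the RNA-seq folds."""
    bench = reference_data.deg_benchmark()
    rnaseq = dict(zip(bench["gene"], bench["printed_fold"]))
    qrt = dict(zip(bench["gene"], bench["qrt_fold"]))
    _, summary = qpcr.concordance_with_rnaseq(qrt, rnaseq)
    return summary


def starch_ratio_printed() -> float:
    """Starch proxy from the printed maltose/glucose means, 1-dp display."""
    ratio = metabolites.starch_proxy_from_means(reference_data.sugar_means())
    return round(ratio, 1)


def snp_cascade_benchmark(seed: int = 0, n_genes: int = 1000) -> dict:
    """PASS recall/precision and per-class artifact capture at default config.

    A planted SNP counts as clean when both simulated depths reach the
    calling minimum and it does not fall inside a planted cluster
    window (where removal is the desired behavior).
    """
    cfg = SimConfig(seed=seed, n_genes=n_genes)
    fcfg = variants.FilterConfig()
    _, pile_sh, pile_yk, truth = simulate_pileups(cfg)
    calls = variants.call_snps(pile_sh, pile_yk, fcfg)
    call_map = {(c.seq_id, c.pos): c for c in calls}
    passed = {(c.seq_id, c.pos) for c in calls if c.passed}

    cluster_sites = {
        (s, p) for s, p, cls, _, _ in truth.artifact_sites if cls == "cluster"
    }
    depth = {
        (s, p): (d1, d2)
        for s, p, d1, d2 in zip(
            pile_sh["seq_id"], pile_sh["pos"], pile_sh["depth"], pile_yk["depth"]
        )
    }

    def near_cluster(site):
        s, p = site
        return any(
            cs == s and abs(cp - p) < fcfg.cluster_window_bp for cs, cp in cluster_sites
        )

    clean = [
        (s, p)
        for s, p, _, _ in truth.true_snps
        if min(depth[(s, p)]) >= fcfg.min_depth and not near_cluster((s, p))
    ]
    recall = sum(site in passed for site in clean) / len(clean) if clean else float("nan")
    true_sites = {(s, p) for s, p, _, _ in truth.true_snps}
    precision = (
        sum(site in true_sites for site in passed) / len(passed)
        if passed
        else float("nan")
    )

    flag_for = {
        "heterozygous": ("het_within_accession",),
        "cluster": ("snp_cluster",),
        "reference_discordant": ("ref_discordant",),
        "low_fraction": ("low_alt_reads", "low_alt_fraction"),
    }
    capture: dict[str, float] = {}
    removed: dict[str, float] = {}
    class_counts: dict[str, int] = {}
    for cls, labels in flag_for.items():
        sites = [(s, p) for s, p, c, _, _ in truth.artifact_sites if c == cls]
        class_counts[cls] = len(sites)
        if not sites:
            capture[cls] = removed[cls] = float("nan")
            continue
        hit = sum(
            1
            for site in sites
            if site in call_map and set(labels) & call_map[site].filters
        )
        not_passed = sum(1 for site in sites if site not in passed)
        capture[cls] = hit / len(sites)
        removed[cls] = not_passed / len(sites)
    return {
        "n_true_snps": len(true_sites),
        "n_clean": len(clean),
        "n_pass": len(passed),
        "recall_clean": recall,
        "precision": precision,
        "artifact_capture": capture,
        "artifact_removed": removed,
        "artifact_counts": class_counts,
    }


def brute_force_cluster_flags(positions, window: int = 100, max_snps: int = 4):
    """Exhaustive all-windows oracle for the cluster filter."""
    positions = sorted(positions)
    flagged = set()
    for start in range(1, max(positions) + 1):
        inside = [p for p in positions if start <= p <= start + window - 1]
        if len(inside) > max_snps:
            flagged.update(inside)
    return flagged


def cluster_oracle_agreement(seed: int = 0, n_instances: int = 100) -> float:
    """Fraction of random instances where the sliding-window filter equals
    the exhaustive-window enumeration."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, 40))
        positions = sorted(rng.choice(np.arange(1, 1200), size=n, replace=False))
        calls = [
            variants.VariantCall(
                seq_id="t", pos=int(p), ref_allele="A", alt_allele="G",
                depth_a1=12, depth_a2=9, alt_fraction=0.43, quality=100.0,
                counts_a1=(12, 0, 0, 0), counts_a2=(0, 0, 9, 0),
            )
            for p in positions
        ]
        flagged = {
            c.pos
            for c in variants.cluster_filter(calls)
            if variants.CLUSTER_FILTER in c.filters
        }
        agree += int(flagged == brute_force_cluster_flags(positions))
    return agree / n_instances


def de_recall_benchmark(seed: int = 0, n_seeds: int = 50, n_genes: int = 800) -> dict:
    """Recovery of planted 16-fold DEGs (baseline mean 1000) at FDR 0.2."""
    found = planted_total = null_called = null_total = 0
    for i in range(n_seeds):
        cfg = SimConfig(
            seed=seed * 1000 + i, n_genes=n_genes, mean_expression=1000,
            de_fraction=16 / n_genes, fold_range=(4.0, 4.0), pav_fraction=0.0,
        )
        table, truth = simulate_counts(cfg)
        t = table.set_index("gene_id").rename(
            columns={"count_SH": "SH", "count_YK": "YK"}
        )
        res = expression.de_test_noreplicates(t)
        called = set(res.index[res["de_call"]])
        planted = set(truth.true_fold)
        found += len(called & planted)
        planted_total += len(planted)
        null_called += len(called - planted)
        null_total += n_genes - len(planted)
    return {
        "recall": found / planted_total,
        "null_call_rate": null_called / null_total,
        "n_seeds": n_seeds,
        "n_planted": planted_total,
        "n_null": null_total,
    }


def identical_column_pvalues(seed: int = 0, n_genes: int = 400) -> float:
    """Minimum p-value when the YK column is a copy of SH (should be 1)."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, pav_fraction=0.0, de_fraction=0.0)
    table, _ = simulate_counts(cfg)
    t = table.set_index("gene_id")
    dup = t[["count_SH"]].copy()
    dup.columns = ["SH"]
    dup["YK"] = dup["SH"]
    dup = dup[dup.sum(axis=1) > 0]
    res = expression.de_test_noreplicates(dup)
    return float(res["pvalue"].min())


def bh_oracle_max_error(seed: int = 0, n_draws: int = 50, n: int = 300) -> float:
    """Worst deviation of the BH implementation from a literal step-up."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        p = rng.random(n) ** rng.uniform(0.5, 3)
        ours = expression.bh_adjust(p)
        order = np.argsort(p)
        adj = p[order] * n / np.arange(1, n + 1)
        for i in range(n - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        literal = np.empty(n)
        literal[order] = np.minimum(adj, 1.0)
        worst = max(worst, float(np.abs(ours - literal).max()))
    return worst


def type_one_error_rates(seed: int = 0, reps: int = 10000) -> dict:
    """Empirical size at alpha = .05 for the three metabolite tests.

    Nulls mirror the study design: parent t test with n=4 per genotype,
    mid-parent one-sample t with n=3 F1 replicates, and the additive
    two-factor ANOVA on the 4+4 / 3+3 two-experiment layout with a
    strong experiment shift but no genotype effect.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(reps, 4))
    y = rng.normal(size=(reps, 4))
    _, p_t = metabolites.two_sample_ttest(x, y, axis=1)

    f1 = rng.normal(size=(reps, 3))
    _, p_mid = metabolites.one_sample_ttest(f1, 0.0, axis=1)

    g = np.array([0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 1, 1, 1])
    e = np.array([0] * 8 + [1] * 6)
    yv = rng.normal(size=(reps, 14)) + 5.0 * e
    p_anova, _ = metabolites.anova_additive(yv, g, e)

    return {
        "ttest": float((p_t <= 0.05).mean()),
        "mid_parent": float((p_mid <= 0.05).mean()),
        "anova_genotype": float((np.asarray(p_anova) <= 0.05).mean()),
        "reps": reps,
    }


def heterosis_confusion(seed: int = 0, n_seeds: int = 6) -> dict:
    """Planted-mode recovery of the heterosis classifier at default noise."""
    modes = ("additive", "dominant", "transgressive_up", "transgressive_down")
    counts = {m: {"n": 0, "hit": 0} for m in modes}
    for i in range(n_seeds):
        cfg = SimConfig(seed=seed * 100 + i)
        rec, truth = simulate_metabolome(cfg)
        predicted = metabolites.classify_heterosis_modes(rec)
        for met, (mode, *_rest) in truth.metab_class.items():
            if met in truth.metab_parent_absent:
                continue
            counts[mode]["n"] += 1
            counts[mode]["hit"] += int(predicted[met] == mode)
    diag = {m: c["hit"] / c["n"] if c["n"] else float("nan") for m, c in counts.items()}
    return {
        "per_class": diag,
        "min_diagonal": min(v for v in diag.values() if np.isfinite(v)),
        "n_scored": sum(c["n"] for c in counts.values()),
    }


def heterosis_summary_benchmark(seed: int = 0) -> dict:
    """Below-mid-parent fraction, transgressive counts, and direction test
    on one default-condition metabolome."""
    rec, _ = simulate_metabolome(SimConfig(seed=seed))
    calls = metabolites.heterosis_calls(rec)
    summary = metabolites.summarize_mid_parent_fraction(calls)
    trans = [c for c in calls if c.transgressive != "none"]
    out = {
        "fraction_below_mid_parent": summary["fraction_below_mid_parent"],
        "n_metabolites": summary["n_metabolites"],
        "n_transgressive": len(trans),
    }
    try:
        n_low, n_high, p = metabolites.direction_binomial(calls)
        out.update({"n_low": n_low, "n_high": n_high, "direction_p": p})
    except ValueError:
        out.update({"n_low": 0, "n_high": 0, "direction_p": float("nan")})
    return out


def direction_binomial_closed_form_error() -> float:
    """|p - 2*0.5^24| for an all-negative 24-call transgression set."""
    calls = [
        metabolites.HeterosisCall(
            metabolite=f"m{i}", compound_class="other", mid_parent=10.0, f1_mean=4.0,
            below_mid_parent=True, p_mid_parent=0.01, transgressive="low",
            p_transgressive=0.01, ratio=2.0, parent_detected="both",
        )
        for i in range(24)
    ]
    _, _, p = metabolites.direction_binomial(calls)
    return abs(p - 2 * 0.5**24)


def chi2_hand_formula_max_error(seed: int = 0, n_tables: int = 50) -> float:
    """Worst deviation of the chi-squared statistic from sum (O-E)^2/E."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        table = rng.integers(1, 40, size=(2, 2)).astype(float)
        stat, _ = metabolites.chi2_independence(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = ((table - expected) ** 2 / expected).sum()
        worst = max(worst, abs(stat - hand))
    return worst


def signed_rank_exact_vs_bruteforce(seed: int = 0, max_n: int = 12) -> float:
    """Worst |p_exact - p_enumeration| over random categories of size 3..max_n."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for n in range(3, max_n + 1):
        for _ in range(5):
            vals = np.round(rng.normal(size=n), 2)
            vals[vals == 0] = 0.25
            _, p, method = enrichment.signed_rank_test(vals)
            assert method == "exact"
            ranks = stats.rankdata(np.abs(vals))
            w_obs = ranks[vals > 0].sum()
            dist = np.array(
                [
                    sum(r for s, r in zip(signs, ranks) if s > 0)
                    for signs in itertools.product([1, -1], repeat=n)
                ]
            )
            lower = np.mean(dist <= w_obs + 1e-9)
            upper = np.mean(dist >= w_obs - 1e-9)
            p_brute = min(1.0, 2.0 * min(lower, upper))
            worst = max(worst, abs(p - p_brute))
    return worst


def qpcr_efficiency_benchmark() -> dict:
    """Noiseless standard curves at canonical slopes."""
    out = {}
    for slope in (-3.3219, -3.45):
        conc = [1 / 5**i for i in range(5)]
        cts = [[20.0 + slope * np.log10(c)] for c in conc]
        fit = qpcr.fit_efficiency(qpcr.DilutionSeries(conc, cts))
        out[slope] = fit.efficiency
    return out
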