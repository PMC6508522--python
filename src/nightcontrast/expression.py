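"""Replicate-free differential expression and presence-absence calling.

The input is a two-column table of reads uniquely aligned to each gene
in the SH-like and YK-like accessions.  With no biological replicates,
per-gene overdispersion cannot be estimated within condition; instead
the two columns are pooled as if they were replicates of a single
condition ("blind" estimation) and a parametric mean-dispersion trend
alpha(mu) = a0 + a1/mu is fit by gamma-family iteratively reweighted
least squares, falling back to a kernel smoother when the parametric
fit diverges.  Only the fitted trend is used per gene (fit-only
sharing) with a floor of 1e-8.  This is deliberately conservative:
genuine expression differences inflate the blind dispersions, so only
large fold changes can reach significance.

Each gene is then tested with the exact conditional negative-binomial
test: conditional on the two-column sum, the p-value is the total
probability of splits as or less likely than the observed one under
equal-mean NB laws with the fitted dispersion and the estimated size
factors.  P-values are Benjamini-Hochberg adjusted and genes are called
differentially expressed at FDR 0.2.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

DISPERSION_FLOOR = 1e-8
DEFAULT_FDR = 0.2

ABSENT_SH = "Absent in SH"
ABSENT_YK = "Absent in YK"


class NormalizationError(ValueError):
    """No gene has positive counts in every column."""


def _validate_counts(table: pd.DataFrame) -> np.ndarray:
    counts = table.to_numpy()
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("count table must have at least two columns")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if table.index.has_duplicates:
        raise ValueError("gene ids must be unique")
    return counts


def size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per column.

    Each gene with all-positive counts contributes its ratio to the
    geometric-mean pseudo-reference; the column factor is the median of
    those ratios.
    """
    counts = _validate_counts(table)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError("no gene has positive counts in every column")
    logc = np.log(counts[positive].astype(float))
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geomean, axis=0))
    return pd.Series(factors, index=table.columns, name="size_factor")


def _blind_dispersions(counts: np.ndarray, sf: np.ndarray):
    """Per-gene method-of-moments dispersions treating all columns as one condition."""
    norm = counts / sf
    mu = norm.mean(axis=1)
    w = norm.var(axis=1, ddof=1)
    z = mu * np.mean(1.0 / sf)  # shot-noise term on the normalized scale
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (w - z) / mu**2
    raw[~np.isfinite(raw)] = np.nan
    return mu, raw


def _parametric_fit(mu: np.ndarray, disp: np.ndarray):
    """Gamma-family IRLS fit of disp ~ a0 + a1/mu on usable genes.

    Returns (a0, a1) or None when the fit diverges (negative
    coefficients or no convergence), mirroring the documented fallback
    behavior of the no-replicate analysis contract.
    """
    use = np.isfinite(disp) & (disp > 1e-7) & (mu > 0)
    if use.sum() < 10:
        return None
    x, y = mu[use], disp[use]
    X = np.column_stack([np.ones_like(x), 1.0 / x])
    coef = np.array([np.median(y), 0.0])
    for _ in range(25):
        fitted = X @ coef
        if (fitted <= 0).any():
            fitted = np.clip(fitted, 1e-10, None)
        W = 1.0 / fitted**2  # gamma variance function
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X, XtW @ y)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(new)):
            return None
        if np.allclose(new, coef, rtol=1e-6, atol=1e-12):
            coef = new
            break
        coef = new
    a0, a1 = coef
    if a0 < 0 or a1 < 0 or (a0 == 0 and a1 == 0):
        return None
    return float(a0), float(a1)


def _local_fit(mu: np.ndarray, disp: np.ndarray):
    """Gaussian-kernel regression of log dispersion on log mean (fallback)."""
    use = np.isfinite(disp) & (disp > 1e-7) & (mu > 0)
    if not use.any():
        return lambda m: np.full_like(np.asarray(m, dtype=float), DISPERSION_FLOOR)
    lx, ly = np.log(mu[use]), np.log(disp[use])
    bw = max(0.5, 0.5 * np.std(lx))

    def predict(m):
        m = np.atleast_1d(np.asarray(m, dtype=float))
        out = np.empty(len(m))
        for i, mi in enumerate(m):
            if mi <= 0:
                out[i] = np.exp(np.median(ly))
                continue
            w = np.exp(-0.5 * ((np.log(mi) - lx) / bw) ** 2)
            out[i] = np.exp(np.sum(w * ly) / np.sum(w)) if w.sum() > 1e-12 else np.exp(
                np.median(ly)
            )
        return out

    return predict


def fitted_dispersions(counts: np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Fitted mean-dispersion trend evaluated at each gene's mean."""
    mu, raw = _blind_dispersions(counts, sf)
    params = _parametric_fit(mu, raw)
    if params is not None:
        a0, a1 = params
        with np.errstate(divide="ignore"):
            fitted = a0 + a1 / mu
        fitted[mu <= 0] = a0
    else:
        fitted = _local_fit(mu, raw)(mu)
    return np.maximum(fitted, DISPERSION_FLOOR)


def exact_nb_pvalue(k1: int, k2: int, s1: float, s2: float, alpha: float) -> float:
    """Exact conditional NB test of equal means for one gene.

    Conditional on S = k1 + k2, sums the probabilities of all splits
    (a, S-a) no more likely than the observed split under independent
    NB(q*s_j, alpha) laws with q = S/(s1+s2).
    """
    S = k1 + k2
    if S == 0:
        return 1.0
    q = S / (s1 + s2)
    m1, m2 = q * s1, q * s2
    alpha = max(alpha, DISPERSION_FLOOR)
    r = 1.0 / alpha
    ks = np.arange(S + 1)
    logp = stats.nbinom.logpmf(ks, r, r / (r + m1)) + stats.nbinom.logpmf(
        S - ks, r, r / (r + m2)
    )
    obs = logp[k1]
    num = logsumexp(logp[logp <= obs + 1e-8])
    den = logsumexp(logp)
    return float(min(1.0, np.exp(num - den)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def fold_change(sh_count: int, yk_count: int):
    """log2(YK/SH) on raw counts, or an absence label.

    Returns a float when both counts are positive, ``"Absent in SH"`` /
    ``"Absent in YK"`` when exactly one is zero, and ``None`` when both
    are zero (undefined).
    """
    if sh_count < 0 or yk_count < 0:
        raise ValueError("counts must be non-negative")
    if sh_count == 0 and yk_count == 0:
        return None
    if sh_count == 0:
        return ABSENT_SH
    if yk_count == 0:
        return ABSENT_YK
    return float(np.log2(yk_count / sh_count))


def display_fold(value, decimals: int = 1):
    """One-decimal display rounding, half away from zero (as printed)."""
    if not isinstance(value, (int, float)):
        return value
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(abs(value))).quantize(q, rounding=ROUND_HALF_UP)) * (
        -1.0 if value < 0 else 1.0
    )


def pav_classify(table: pd.DataFrame, sh_col: str = "SH", yk_col: str = "YK"):
    """Per-gene presence-absence call plus the single-accession fraction.

    A gene is single-accession when zero reads aligned in exactly one
    column; the summary fraction is taken over detected genes (nonzero
    somewhere).
    """
    sh = table[sh_col].to_numpy()
    yk = table[yk_col].to_numpy()
    calls = np.where(
        (sh == 0) & (yk == 0),
        "neither",
        np.where(yk == 0, "yk_only", np.where(sh == 0, "sh_only", "both")),
    )
    detected = calls != "neither"
    single = np.isin(calls, ("sh_only", "yk_only"))
    summary = {
        "n_detected": int(detected.sum()),
        "n_sh_only": int((calls == "sh_only").sum()),
        "n_yk_only": int((calls == "yk_only").sum()),
        "pav_fraction": float(single.sum() / detected.sum()) if detected.any() else float("nan"),
    }
    return pd.Series(calls, index=table.index, name="pav_call"), summary


def de_test_noreplicates(
    table: pd.DataFrame,
    fdr: float = DEFAULT_FDR,
    sh_col: str = "SH",
    yk_col: str = "YK",
) -> pd.DataFrame:
    """Exact-test differential expression for a two-column count table.

    Returns one row per gene with normalized means, raw and normalized
    log2(YK/SH) folds, the display fold (with absence labels), p-value,
    BH-adjusted p-value, the DE call at the given FDR, and the
    presence-absence call.
    """
    if list(table.columns) != [sh_col, yk_col]:
        missing = [c for c in (sh_col, yk_col) if c not in table.columns]
        if missing:
            raise ValueError(f"count table is missing column(s) {missing}")
        table = table[[sh_col, yk_col]]
    counts = _validate_counts(table)
    if counts.shape[1] != 2:
        raise ValueError("exactly two columns (SH, YK) are required")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("a column is all zero; nothing to test")

    sf = size_factors(table).to_numpy()
    alpha = fitted_dispersions(counts, sf)
    norm = counts / sf

    pvals = np.array(
        [
            exact_nb_pvalue(int(k1), int(k2), sf[0], sf[1], a)
            for (k1, k2), a in zip(counts, alpha)
        ]
    )
    padj = bh_adjust(pvals)

    sh, yk = counts[:, 0], counts[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_fold = np.where((sh > 0) & (yk > 0), np.log2(yk / np.where(sh > 0, sh, 1)), np.nan)
        norm_fold = np.where(
            (norm[:, 0] > 0) & (norm[:, 1] > 0),
            np.log2(norm[:, 1] / np.where(norm[:, 0] > 0, norm[:, 0], 1)),
            np.nan,
        )
    pav_calls, _ = pav_classify(table, sh_col, yk_col)
    display = [
        display_fold(fc) if isinstance(fc := fold_change(int(a), int(b)), float) else fc
        for a, b in zip(sh, yk)
    ]
    return pd.DataFrame(
        {
            "base_mean_sh": norm[:, 0],
            "base_mean_yk": norm[:, 1],
            "log2_fold_raw": raw_fold,
            "log2_fold_norm": norm_fold,
            "fold_display": display,
            "pvalue": pvals,
            "padj": padj,
            "de_call": padj <= fdr,
            "pav_call": pav_calls.to_numpy(),
            "dispersion": alpha,
        },
        index=table.index,
    )
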