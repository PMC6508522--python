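"""Primer efficiency and efficiency-corrected relative expression.

A dilution series of five fivefold steps is regressed as CT on log10
template concentration; the per-cycle amplification gain (primer
efficiency) is E = 10^(-1/slope) - 1, so a perfect doubling per cycle
gives slope -3.3219 and E = 1.  Primers pass when E lies in [0.80,
1.10] (inclusive).  Relative expression follows the delta-CT method
against a reference gene (the Actin2 role):

    relative expression = (1 + E)^-(CT,target - CT,reference)

Missing CT values encode "no amplification"; they are never written as
CT = 0.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EFFICIENCY_PASS_RANGE = (0.80, 1.10)


@dataclass(frozen=True)
class DilutionSeries:
    """A fivefold-gradient standard curve for one primer pair.

    ``ct_values[i]`` holds the technical-replicate CTs measured at
    ``concentrations[i]``; concentrations must be strictly positive and
    strictly decreasing by a constant factor, with at least 3 points.
    """

    concentrations: Sequence[float]
    ct_values: Sequence[Sequence[float]]

    def validate(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if len(conc) < 3:
            raise ValueError("at least 3 dilution points are required")
        if len(conc) != len(self.ct_values):
            raise ValueError("concentrations and ct_values differ in length")
        if (conc <= 0).any():
            raise ValueError("concentrations must be strictly positive")
        ratios = conc[:-1] / conc[1:]
        if (ratios <= 1).any():
            raise ValueError("concentrations must be strictly decreasing")
        if not np.allclose(ratios, ratios[0], rtol=1e-3):
            raise ValueError("dilution steps must use a constant factor")
        if any(len(c) == 0 for c in self.ct_values):
            raise ValueError("every dilution point needs at least one CT")


@dataclass(frozen=True)
class PrimerEfficiency:
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    passes: bool


def fit_efficiency(series: DilutionSeries) -> PrimerEfficiency:
    """OLS of mean CT on log10(concentration); E = 10^(-1/slope) - 1.

    Technical replicates are averaged per dilution point before the
    regression so a single outlier well cannot dominate the slope.
    """
    series.validate()
    x = np.log10(np.asarray(series.concentrations, dtype=float))
    y = np.array([float(np.mean(c)) for c in series.ct_values])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in concentration")
    fit = stats.linregress(x, y)
    if fit.slope == 0:
        raise ValueError("flat standard curve; efficiency undefined")
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    lo, hi = EFFICIENCY_PASS_RANGE
    return PrimerEfficiency(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(eff),
        r_squared=float(fit.rvalue**2),
        passes=bool(fit.slope < 0 and lo <= eff <= hi),
    )


def fit_efficiencies(dilutions: pd.DataFrame) -> pd.DataFrame:
    """Fit one standard curve per primer from a long-format dilution table."""
    rows = []
    for primer, grp in dilutions.groupby("primer", sort=True):
        pts = grp.groupby("concentration", sort=False)["ct"].apply(list)
        pts = pts.sort_index(ascending=False)
        series = DilutionSeries(list(pts.index), list(pts.values))
        fit = fit_efficiency(series)
        rows.append(
            (primer, fit.slope, fit.intercept, fit.efficiency, fit.r_squared, fit.passes)
        )
    return pd.DataFrame(
        rows, columns=["primer", "slope", "intercept", "efficiency", "r_squared", "passes"]
    )


def relative_expression(ct_target: float, ct_reference: float, efficiency: float) -> float:
    """Delta-CT quantification: (1+E)^-(CT,target - CT,reference)."""
    if efficiency <= -1:
        raise ValueError("efficiency must exceed -1")
    if math.isnan(ct_target) or math.isnan(ct_reference):
        return float("nan")
    return float((1.0 + efficiency) ** (-(ct_target - ct_reference)))


def quantify_samples(samples: pd.DataFrame, efficiencies: pd.DataFrame) -> pd.DataFrame:
    """Per-well relative expression for a sample CT table.

    ``samples`` columns: gene, accession, replicate, ct_target,
    ct_reference.  Missing ct_target marks no amplification and yields
    NaN relative expression.
    """
    eff = efficiencies.set_index("primer")["efficiency"]
    out = samples.copy()
    out["relative_expression"] = [
        relative_expression(row.ct_target, row.ct_reference, eff[row.gene])
        if row.gene in eff.index
        else float("nan")
        for row in samples.itertuples()
    ]
    return out


_ABSENT_RE = re.compile(r"(absent|not detected)\s+in\s+(SH|YK)", re.IGNORECASE)


def _absence_side(label: str) -> str | None:
    m = _ABSENT_RE.search(label)
    return m.group(2).upper() if m else None


def agreement(qpcr_fold, rnaseq_fold) -> bool | None:
    """Directional agreement of one gene's qPCR and RNA-seq verdicts.

    Numeric values agree when their signs match (qPCR folds are signed
    linear ratios; RNA-seq folds are log2, so both are >0 iff YK-high).
    An RNA-seq absence label agrees with a no-amplification flag on the
    same side, or with a numeric qPCR fold in the consistent direction.
    A qPCR "n.s." verdict is a disagreement with a called DEG.  Returns
    None when either value carries no direction (e.g. not tested).
    """
    if rnaseq_fold is None or qpcr_fold is None:
        return None
    if isinstance(qpcr_fold, str) and qpcr_fold.strip().lower() in ("not tested", ""):
        return None
    if isinstance(qpcr_fold, str) and qpcr_fold.strip().lower() in ("n.s.", "ns"):
        return False

    r_side = _absence_side(rnaseq_fold) if isinstance(rnaseq_fold, str) else None
    q_side = _absence_side(qpcr_fold) if isinstance(qpcr_fold, str) else None
    if r_side is not None:
        if q_side is not None:
            return q_side == r_side
        # absent in SH => higher in YK => positive qPCR fold
        return (float(qpcr_fold) > 0) == (r_side == "SH")
    if q_side is not None:
        return (float(rnaseq_fold) > 0) == (q_side == "SH")
    return (float(qpcr_fold) > 0) == (float(rnaseq_fold) > 0)


def concordance_with_rnaseq(
    qpcr_folds: Mapping[str, object], rnaseq_folds: Mapping[str, object]
) -> tuple[pd.DataFrame, dict]:
    """Gene-by-gene agreement table plus the confirmed/testable summary."""
    rows = []
    for gene in rnaseq_folds:
        if gene not in qpcr_folds:
            continue
        agree = agreement(qpcr_folds[gene], rnaseq_folds[gene])
        rows.append((gene, qpcr_folds[gene], rnaseq_folds[gene], agree))
    table = pd.DataFrame(rows, columns=["gene", "qpcr_fold", "rnaseq_fold", "agree"])
    tested = table[table["agree"].notna()]
    summary = {
        "n_tested": int(len(tested)),
        "n_agree": int(tested["agree"].sum()),
    }
    return table, summary
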