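"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q tests heterogeneity of the per-SNP Wald ratios around the
pooled IVW estimate; the MR-Egger intercept tests directional horizontal
pleiotropy; leave-one-out re-estimation flags single influential
instruments.  The per-SNP forest and funnel tables are the data matrices
behind the conventional plots; rendering is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrEstimate, egger, ivw, to_odds_ratio, wald_ratios
from .harmonize import HarmonizedDataset

__all__ = [
    "HeterogeneityResult",
    "EggerInterceptResult",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "single_snp_forest",
    "funnel_data",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its df, p-value and the derived I² statistic."""

    q: float
    df: int
    pvalue: float
    i2: float


@dataclass(frozen=True)
class EggerInterceptResult:
    """The MR-Egger intercept as a standalone directional-pleiotropy test."""

    intercept: float
    se: float
    pvalue: float
    df: int


def cochran_q(
    data: HarmonizedDataset, around: MrEstimate | None = None
) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios around the pooled estimate.

    Q = Σ wⱼ(bⱼ − β̂)² with wⱼ = sⱼ⁻²; β̂ defaults to the fixed-effect
    IVW estimate (which minimizes Q); p from χ² on J−1 df.  I² is
    reported as max(0, (Q − df)/Q).
    """
    J = len(data)
    if J < 2:
        raise ValueError("Cochran's Q needs ≥ 2 SNPs")
    ratios = wald_ratios(data)
    beta = around.beta if around is not None else ivw(data, random_effects=False).beta
    q = float(np.sum(ratios.w * (ratios.b - beta) ** 2))
    df = J - 1
    pvalue = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pvalue=pvalue, i2=i2)


def egger_intercept_test(data: HarmonizedDataset) -> EggerInterceptResult:
    """Re-expose the MR-Egger intercept block as a pleiotropy test.

    Intercept ≈ 0 or p > 0.05 is read as no evidence of directional
    horizontal pleiotropy.
    """
    fit = egger(data)
    ex = fit.extras
    return EggerInterceptResult(
        intercept=float(ex["intercept"]),
        se=float(ex["intercept_se"]),
        pvalue=float(ex["intercept_pvalue"]),
        df=int(ex["df"]),
    )


def leave_one_out(data: HarmonizedDataset, random_effects: bool = True) -> pd.DataFrame:
    """IVW re-estimated J times, each omitting one SNP, plus the all-SNP row.

    Columns: omitted, beta, se, pvalue, or, ci_low, ci_high; the final
    row has omitted = "(none)".  Row count is always J + 1.
    """
    J = len(data)
    if J < 3:
        raise ValueError("leave-one-out needs ≥ 3 SNPs")
    rows = []
    for i, rsid in enumerate(data.rsids):
        sub = HarmonizedDataset(
            pairs=[p for j, p in enumerate(data.pairs) if j != i], drop_log={}
        )
        est = ivw(sub, random_effects=random_effects)
        rows.append(
            {
                "omitted": rsid,
                "beta": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    full = ivw(data, random_effects=random_effects)
    rows.append(
        {
            "omitted": "(none)",
            "beta": full.beta,
            "se": full.se,
            "pvalue": full.pvalue,
            "or": full.or_,
            "ci_low": full.ci_low,
            "ci_high": full.ci_high,
        }
    )
    return pd.DataFrame(rows)


def single_snp_forest(data: HarmonizedDataset, random_effects: bool = True) -> pd.DataFrame:
    """Per-SNP Wald-ratio estimates plus the pooled IVW row (forest-plot data).

    Columns: rsid, beta, se, or, ci_low, ci_high; the pooled row has
    rsid = "All (IVW)" and equals :func:`tsmr.estimators.ivw` exactly.
    """
    ratios = wald_ratios(data)
    rows = []
    for rsid, b, s in zip(ratios.rsids, ratios.b, ratios.s):
        or_, lo, hi = to_odds_ratio(float(b), float(s))
        rows.append(
            {"rsid": rsid, "beta": float(b), "se": float(s), "or": or_,
             "ci_low": lo, "ci_high": hi}
        )
    if len(data) >= 2:
        pooled = ivw(data, random_effects=random_effects)
    else:
        b, s = float(ratios.b[0]), float(ratios.s[0])
        or_, lo, hi = to_odds_ratio(b, s)
        pooled = None
        rows.append({"rsid": "All (IVW)", "beta": b, "se": s, "or": or_,
                     "ci_low": lo, "ci_high": hi})
    if pooled is not None:
        rows.append(
            {"rsid": "All (IVW)", "beta": pooled.beta, "se": pooled.se, "or": pooled.or_,
             "ci_low": pooled.ci_low, "ci_high": pooled.ci_high}
        )
    return pd.DataFrame(rows)


def funnel_data(data: HarmonizedDataset) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-SNP (ratio, precision) pairs and the vertical reference lines.

    Returns a DataFrame (rsid, ratio, precision = 1/sⱼ) and a dict of
    reference estimates {"IVW": β̂_IVW, "MR-Egger": β̂_Egger}; the Egger
    line is omitted when J < 3.
    """
    ratios = wald_ratios(data)
    df = pd.DataFrame(
        {
            "rsid": list(ratios.rsids),
            "ratio": ratios.b,
            "precision": 1.0 / ratios.s,
        }
    )
    refs: dict[str, float] = {}
    if len(data) >= 2:
        refs["IVW"] = ivw(data).beta
    if len(data) >= 3:
        refs["MR-Egger"] = egger(data).beta
    return df, refs
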