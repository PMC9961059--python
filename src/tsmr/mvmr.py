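"""Multivariable Mendelian randomization (MVMR).

Regresses the outcome effects on a J×K matrix of exposure effects with
no intercept, weighted by inverse outcome variance.  Coefficient k is
exposure k's direct effect on the outcome, holding the other modelled
exposures fixed — here used to adjust an air-pollution exposure effect
for adiposity and smoking, but the exposure set is arbitrary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MrEstimate, to_odds_ratio
from .harmonize import harmonize_pair
from .instruments import SelectionConfig, clump, select_by_pvalue
from .summary_io import LdTable, SummaryDataset

__all__ = ["MvmrInput", "mvmr_ivw", "assemble_mvmr_input"]


@dataclass
class MvmrInput:
    """Per-SNP effects for K ≥ 2 exposures and one outcome, no missing cells.

    exposure_beta and exposure_se are (J, K); outcome_beta/se are (J,).
    """

    rsids: list[str]
    exposure_names: list[str]
    exposure_beta: np.ndarray
    exposure_se: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    drop_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.exposure_beta = np.asarray(self.exposure_beta, dtype=float)
        self.exposure_se = np.asarray(self.exposure_se, dtype=float)
        self.outcome_beta = np.asarray(self.outcome_beta, dtype=float)
        self.outcome_se = np.asarray(self.outcome_se, dtype=float)
        J, K = self.exposure_beta.shape
        if len(self.exposure_names) != K:
            raise ValueError("exposure_names length must match exposure_beta columns")
        if len(self.rsids) != J or self.outcome_beta.shape != (J,):
            raise ValueError("inconsistent row counts in MVMR input")
        if not np.all(np.isfinite(self.exposure_beta)) or not np.all(
            np.isfinite(self.outcome_beta)
        ):
            raise ValueError("missing/non-finite cells in MVMR input")
        if not np.all(self.outcome_se > 0):
            raise ValueError("outcome SEs must be positive")

    @property
    def J(self) -> int:
        return self.exposure_beta.shape[0]

    @property
    def K(self) -> int:
        return self.exposure_beta.shape[1]


def mvmr_ivw(input: MvmrInput, level: float = 0.95) -> list[MrEstimate]:
    """MVMR-IVW: weighted no-intercept regression of Γ on the exposure matrix.

    Weights are 1/se_Γ²; SEs are scaled by max(1, σ̂) with σ̂² the
    weighted residual mean square on J−K df; p-values from t(J−K).
    With K = 1 this reduces exactly to univariable IVW.  A rank-deficient
    exposure matrix (collinear exposures) is a hard error.
    """
    J, K = input.J, input.K
    if J <= K:
        raise ValueError(f"need more SNPs than exposures (J={J}, K={K})")
    X = input.exposure_beta
    y = input.outcome_beta
    w = 1.0 / input.outcome_se**2
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    rank = np.linalg.matrix_rank(Xw)
    if rank < K:
        # name the offending columns: those whose removal restores full rank
        collinear = [
            name
            for k, name in enumerate(input.exposure_names)
            if np.linalg.matrix_rank(np.delete(Xw, k, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient exposure matrix; collinear exposures: {collinear}")
    xtx = Xw.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ coef
    sigma2 = float(resid @ resid) / (J - K)
    scale = max(1.0, math.sqrt(sigma2))
    cov = np.linalg.inv(xtx)
    ses = np.sqrt(np.diag(cov)) * scale
    out: list[MrEstimate] = []
    for k, name in enumerate(input.exposure_names):
        beta, se = float(coef[k]), float(ses[k])
        p = 2.0 * stats.t.sf(abs(beta / se), df=J - K)
        or_, lo, hi = to_odds_ratio(beta, se, level)
        out.append(
            MrEstimate(
                method=f"MVMR-IVW ({name})",
                n_snp=J,
                beta=beta,
                se=se,
                pvalue=float(p),
                or_=or_,
                ci_low=lo,
                ci_high=hi,
                level=level,
                extras={"exposure": name, "df": J - K, "sigma": math.sqrt(sigma2)},
            )
        )
    return out


def assemble_mvmr_input(
    exposures: list[SummaryDataset],
    outcome: SummaryDataset,
    ld: LdTable | None = None,
    config: SelectionConfig | None = None,
    maf_threshold: float = 0.3,
) -> MvmrInput:
    """Build the joint instrument matrix for MVMR.

    Instruments are selected per exposure at ``config.p_threshold``,
    pooled, and clumped jointly on the minimum p-value across exposures;
    every surviving SNP must carry a beta in *all* exposure datasets and
    the outcome, and is aligned to the first exposure's allele
    orientation (allele mismatches and ambiguous palindromes drop as in
    univariable harmonization).  An empty joint set is a hard error.
    """
    if len(exposures) < 2:
        raise ValueError("MVMR needs ≥ 2 exposure datasets")
    cfg = config or SelectionConfig()
    ld = ld or LdTable()

    lookups = [ds.by_rsid() for ds in exposures]
    outcome_lookup = outcome.by_rsid()

    selected: set[str] = set()
    for ds in exposures:
        selected |= {r.rsid for r in select_by_pvalue(ds, cfg.p_threshold).records}
    if not selected:
        raise ValueError("no SNP passes the selection threshold in any exposure")

    # joint clump: rank by min p across exposures; reuse the univariable
    # clumping on records rebuilt with that min p
    import dataclasses

    union_records = []
    for rsid in selected:
        base = next(lk[rsid] for lk in lookups if rsid in lk)
        min_p = min(lk[rsid].pvalue for lk in lookups if rsid in lk)
        union_records.append(dataclasses.replace(base, pvalue=min_p))
    union = SummaryDataset(
        trait_name="mvmr_union", trait_type="continuous", records=union_records
    )
    clumped = clump(union, ld, cfg)

    rsids: list[str] = []
    eb_rows, es_rows, ob, os_ = [], [], [], []
    drop_log: dict[str, str] = {}
    for rec in clumped.records:
        rsid = rec.rsid
        if any(rsid not in lk for lk in lookups):
            missing = [
                name
                for lk, name in zip(lookups, [d.trait_name for d in exposures])
                if rsid not in lk
            ]
            drop_log[rsid] = f"missing from exposure(s): {missing}"
            continue
        if rsid not in outcome_lookup:
            drop_log[rsid] = "absent from outcome"
            continue
        ref = lookups[0][rsid]
        betas, ses = [ref.beta], [ref.se]
        ok = True
        for lk in lookups[1:]:
            res = harmonize_pair(ref, lk[rsid], maf_threshold=maf_threshold)
            if isinstance(res, str):
                drop_log[rsid] = f"exposure alignment failed: {res}"
                ok = False
                break
            betas.append(res.Gamma)  # lk's beta re-expressed on ref's effect allele
            ses.append(res.se_Gamma)
        if not ok:
            continue
        res = harmonize_pair(ref, outcome_lookup[rsid], maf_threshold=maf_threshold)
        if isinstance(res, str):
            drop_log[rsid] = res
            continue
        rsids.append(rsid)
        eb_rows.append(betas)
        es_rows.append(ses)
        ob.append(res.Gamma)
        os_.append(res.se_Gamma)

    if not rsids:
        raise ValueError("empty joint instrument set after assembly")
    return MvmrInput(
        rsids=rsids,
        exposure_names=[d.trait_name for d in exposures],
        exposure_beta=np.array(eb_rows),
        exposure_se=np.array(es_rows),
        outcome_beta=np.array(ob),
        outcome_se=np.array(os_),
        drop_log=drop_log,
    )
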