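"""Synthetic two-sample GWAS summary data with known ground truth.

Summary statistics are simulated directly at the summary level (no
individual-level genotypes): per SNP j with minor-allele frequency
mafⱼ and true per-allele effect γⱼ on the standardized exposure,

    se(γ̂ⱼ) = 1 / √(2·mafⱼ(1−mafⱼ)·n_exposure),      γ̂ⱼ ~ N(γⱼ, se²)

with the γⱼ rescaled so the instruments jointly explain ``total_r2`` of
the exposure variance.  The outcome is binary: the true per-SNP
log-odds effect is Γⱼ = β·γⱼ + αⱼ (β the causal effect, αⱼ a
horizontal-pleiotropy term drawn for an ``invalid_fraction`` of SNPs),
observed with se(Γ̂ⱼ) = 1/√(2·mafⱼ(1−mafⱼ)·n_eff) where
n_eff = 4/(1/cases + 1/controls) is the harmonic effective size.  The
two samples are independent by construction.

Allele bookkeeping is planted to exercise harmonization: a configurable
fraction of SNPs is palindromic (A/T or C/G) and a fraction has the
allele coding swapped in the outcome file (beta negated, frequency
mirrored).  Defaults emulate an 85-instrument analysis of a continuous
exposure on a 6,033-case / 123,000-control outcome with total
R² = 5.85% and causal log-OR 0.551.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_io import LdTable, SummaryDataset, SummaryStatRecord

__all__ = [
    "SimulationConfig",
    "MvmrSimulationConfig",
    "SimulationTruth",
    "MvmrSimulationTruth",
    "simulate_two_sample",
    "simulate_mvmr",
]

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))

_P_FLOOR = 1e-300  # keep simulated p-values inside (0, 1]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one two-sample dataset pair.

    Defaults are the study conditions this package's simulations target:
    85 instruments, a 423,796-sample continuous-exposure GWAS, a binary
    outcome with 6,033 cases / 123,000 controls, causal log-OR 0.551 and
    total instrument R² 5.85%; no pleiotropy unless requested.
    """

    n_snps: int = 85
    n_exposure: int = 423_796
    n_outcome_cases: int = 6_033
    n_outcome_controls: int = 123_000
    true_beta: float = 0.551
    total_r2: float = 0.0585
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.1
    swap_fraction: float = 0.2
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    ld_blocks: tuple[tuple[int, float], ...] = ()  # (block size, within-block r²)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be ≥ 1")
        if not (0.0 < self.total_r2 < 1.0):
            raise ValueError("total_r2 must be in (0, 1)")
        for name in ("palindromic_fraction", "swap_fraction", "invalid_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo ≤ hi ≤ 0.5")
        if sum(size for size, _ in self.ld_blocks) > self.n_snps:
            raise ValueError("ld_blocks exceed n_snps")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth paired with one simulated dataset pair."""

    config: SimulationConfig
    true_beta: float
    maf: np.ndarray
    gamma_true: np.ndarray
    alpha: np.ndarray            # per-SNP pleiotropic effect on the outcome
    per_snp_r2: np.ndarray
    palindromic: np.ndarray      # bool mask
    swapped: np.ndarray          # bool mask: outcome allele coding swapped
    effect_allele: tuple[str, ...]
    other_allele: tuple[str, ...]


def _layout_positions(config: SimulationConfig) -> tuple[list[str], list[int], list[list[int]]]:
    """Chromosome/position layout: LD blocks are tight runs on one
    chromosome; remaining SNPs are isolated (> clumping window apart)."""
    chroms: list[str] = []
    positions: list[int] = []
    blocks: list[list[int]] = []
    idx = 0
    chrom_cursor = 0
    for size, _ in config.ld_blocks:
        members = []
        chrom = str(chrom_cursor % 22 + 1)
        base = 1_000_000 + (chrom_cursor // 22) * 200_000_000
        for k in range(size):
            chroms.append(chrom)
            positions.append(base + k * 50_000)  # 50 kb spacing inside a block
            members.append(idx)
            idx += 1
        blocks.append(members)
        chrom_cursor += 1
    while idx < config.n_snps:
        chrom = str(chrom_cursor % 22 + 1)
        base = 1_000_000 + (chrom_cursor // 22) * 200_000_000
        chroms.append(chrom)
        positions.append(base)
        idx += 1
        chrom_cursor += 1
    return chroms, positions, blocks


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[SummaryDataset, SummaryDataset, LdTable, SimulationTruth]:
    """Generate (exposure dataset, outcome dataset, LD table, truth).

    Deterministic given ``config.seed``; the truth object fully
    determines the generated datasets.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps

    maf = rng.uniform(*config.maf_range, size=J)
    var_geno = 2.0 * maf * (1.0 - maf)

    # emulate *post-screen* instruments: every SNP carries a comparable,
    # genuinely strong share of the total R² (share ~ U(0.5, 1.5), sign
    # random); the discovery screen and its winner's curse are not modelled
    share = rng.uniform(0.5, 1.5, size=J)
    share = share / share.sum()
    per_snp_r2 = config.total_r2 * share
    if np.any(per_snp_r2 >= 1.0):
        raise ValueError("total_r2 infeasible for n_snps/maf_range")
    sign = rng.choice([-1.0, 1.0], size=J)
    gamma_true = sign * np.sqrt(per_snp_r2 / var_geno)

    se_gamma = 1.0 / np.sqrt(var_geno * config.n_exposure)
    beta_exp = rng.normal(gamma_true, se_gamma)

    invalid = rng.random(J) < config.invalid_fraction
    alpha = np.where(
        invalid, rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=J), 0.0
    )
    # pleiotropy is directional with respect to the exposure-increasing
    # allele, the orientation under which directional pleiotropy is defined
    Gamma_true = config.true_beta * gamma_true + np.sign(gamma_true) * alpha

    n_eff = 4.0 / (1.0 / config.n_outcome_cases + 1.0 / config.n_outcome_controls)
    se_Gamma = 1.0 / np.sqrt(var_geno * n_eff)
    beta_out = rng.normal(Gamma_true, se_Gamma)

    palindromic = rng.random(J) < config.palindromic_fraction
    swapped = rng.random(J) < config.swap_fraction
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=J)
    nonpal_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=J)
    effect_allele = tuple(
        _PALINDROMIC_PAIRS[pal_choice[j]][0] if palindromic[j]
        else _NONPALINDROMIC_PAIRS[nonpal_choice[j]][0]
        for j in range(J)
    )
    other_allele = tuple(
        _PALINDROMIC_PAIRS[pal_choice[j]][1] if palindromic[j]
        else _NONPALINDROMIC_PAIRS[nonpal_choice[j]][1]
        for j in range(J)
    )

    chroms, positions, blocks = _layout_positions(config)
    rsids = [f"rs{j + 1:06d}" for j in range(J)]

    p_exp = np.maximum(2.0 * stats.norm.sf(np.abs(beta_exp / se_gamma)), _P_FLOOR)
    p_out = np.maximum(2.0 * stats.norm.sf(np.abs(beta_out / se_Gamma)), _P_FLOOR)

    exp_records = [
        SummaryStatRecord(
            rsid=rsids[j], chrom=chroms[j], pos=positions[j],
            effect_allele=effect_allele[j], other_allele=other_allele[j],
            eaf=float(maf[j]), beta=float(beta_exp[j]), se=float(se_gamma[j]),
            pvalue=float(p_exp[j]), n=float(config.n_exposure),
        )
        for j in range(J)
    ]

    out_records = []
    n_out_total = config.n_outcome_cases + config.n_outcome_controls
    for j in range(J):
        ea, oa, b, eaf = effect_allele[j], other_allele[j], beta_out[j], maf[j]
        if swapped[j]:
            ea, oa, b, eaf = oa, ea, -b, 1.0 - eaf
        out_records.append(
            SummaryStatRecord(
                rsid=rsids[j], chrom=chroms[j], pos=positions[j],
                effect_allele=ea, other_allele=oa,
                eaf=float(eaf), beta=float(b), se=float(se_Gamma[j]),
                pvalue=float(p_out[j]), n=float(n_out_total),
            )
        )

    ld = LdTable()
    for members, (_, r2) in zip(blocks, config.ld_blocks):
        for a in range(len(members)):
            for b_ in range(a + 1, len(members)):
                ld.set(rsids[members[a]], rsids[members[b_]], r2)

    exposure = SummaryDataset(
        trait_name="simulated_exposure", trait_type="continuous", records=exp_records
    )
    outcome = SummaryDataset(
        trait_name="simulated_outcome", trait_type="binary", records=out_records,
        n_cases=config.n_outcome_cases, n_controls=config.n_outcome_controls,
    )
    truth = SimulationTruth(
        config=config, true_beta=config.true_beta, maf=maf, gamma_true=gamma_true,
        alpha=alpha, per_snp_r2=per_snp_r2, palindromic=palindromic, swapped=swapped,
        effect_allele=effect_allele, other_allele=other_allele,
    )
    return exposure, outcome, ld, truth


@dataclass(frozen=True)
class MvmrSimulationConfig(SimulationConfig):
    """Extension with K exposures and a direct-effect vector.

    ``exposure_corr`` is the correlation between the per-SNP true
    effects of consecutive exposures (shared genetic architecture);
    ``disjoint_instruments`` instead gives each exposure its own block
    of instruments with zero true effect on the others.
    """

    direct_effects: tuple[float, ...] = (0.55, 0.2)
    exposure_corr: float = 0.0
    disjoint_instruments: bool = False
    palindromic_fraction: float = 0.0
    swap_fraction: float = 0.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.direct_effects) < 2:
            raise ValueError("MVMR simulation needs K ≥ 2 direct effects")
        if not (-1.0 < self.exposure_corr < 1.0):
            raise ValueError("exposure_corr must be in (-1, 1)")


@dataclass(frozen=True)
class MvmrSimulationTruth:
    config: MvmrSimulationConfig
    direct_effects: np.ndarray
    maf: np.ndarray
    gamma_true: np.ndarray  # (J, K)
    alpha: np.ndarray


def simulate_mvmr(
    config: MvmrSimulationConfig,
) -> tuple[list[SummaryDataset], SummaryDataset, LdTable, MvmrSimulationTruth]:
    """Generate K exposure datasets and one outcome with known direct effects.

    Γⱼ = Σₖ betaₖ·γⱼₖ + αⱼ + noise; the per-exposure effect columns are
    correlated (``exposure_corr``) or block-disjoint, and each column is
    scaled to explain ``total_r2`` of its exposure.
    """
    rng = np.random.default_rng(config.seed)
    J, K = config.n_snps, len(config.direct_effects)

    maf = rng.uniform(*config.maf_range, size=J)
    var_geno = 2.0 * maf * (1.0 - maf)

    def signed_magnitudes(size: int) -> np.ndarray:
        # post-screen-strength effects: share ~ U(0.5, 1.5), sign random
        return rng.choice([-1.0, 1.0], size=size) * np.sqrt(rng.uniform(0.5, 1.5, size=size))

    if config.disjoint_instruments:
        gamma = np.zeros((J, K))
        bounds = np.linspace(0, J, K + 1).astype(int)
        for k in range(K):
            block = slice(bounds[k], bounds[k + 1])
            gamma[block, k] = signed_magnitudes(bounds[k + 1] - bounds[k])
    else:
        # correlated effect columns: γ₂ = ρ·γ₁ + √(1−ρ²)·e, both terms
        # drawn from the strong-instrument marginal
        rho = config.exposure_corr
        gamma = np.empty((J, K))
        gamma[:, 0] = signed_magnitudes(J)
        for k in range(1, K):
            gamma[:, k] = rho * gamma[:, 0] + np.sqrt(1 - rho**2) * signed_magnitudes(J)
    # scale each column so its (nonzero) instruments explain total_r2
    for k in range(K):
        mask = gamma[:, k] != 0
        denom = float(np.sum(var_geno[mask] * gamma[mask, k] ** 2))
        gamma[:, k] *= np.sqrt(config.total_r2 / denom)

    se_gamma = 1.0 / np.sqrt(var_geno * config.n_exposure)
    invalid = rng.random(J) < config.invalid_fraction
    alpha = np.where(
        invalid, rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=J), 0.0
    )
    Gamma_true = gamma @ np.asarray(config.direct_effects) + alpha
    n_eff = 4.0 / (1.0 / config.n_outcome_cases + 1.0 / config.n_outcome_controls)
    se_Gamma = 1.0 / np.sqrt(var_geno * n_eff)

    chroms, positions, _ = _layout_positions(config)
    rsids = [f"rs{j + 1:06d}" for j in range(J)]
    nonpal = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=J)
    ea = [_NONPALINDROMIC_PAIRS[c][0] for c in nonpal]
    oa = [_NONPALINDROMIC_PAIRS[c][1] for c in nonpal]

    exposures: list[SummaryDataset] = []
    for k in range(K):
        beta_hat = rng.normal(gamma[:, k], se_gamma)
        pvals = np.maximum(2.0 * stats.norm.sf(np.abs(beta_hat / se_gamma)), _P_FLOOR)
        records = [
            SummaryStatRecord(
                rsid=rsids[j], chrom=chroms[j], pos=positions[j],
                effect_allele=ea[j], other_allele=oa[j], eaf=float(maf[j]),
                beta=float(beta_hat[j]), se=float(se_gamma[j]),
                pvalue=float(pvals[j]), n=float(config.n_exposure),
            )
            for j in range(J)
        ]
        exposures.append(
            SummaryDataset(
                trait_name=f"exposure_{k + 1}", trait_type="continuous", records=records
            )
        )

    beta_out = rng.normal(Gamma_true, se_Gamma)
    p_out = np.maximum(2.0 * stats.norm.sf(np.abs(beta_out / se_Gamma)), _P_FLOOR)
    out_records = [
        SummaryStatRecord(
            rsid=rsids[j], chrom=chroms[j], pos=positions[j],
            effect_allele=ea[j], other_allele=oa[j], eaf=float(maf[j]),
            beta=float(beta_out[j]), se=float(se_Gamma[j]),
            pvalue=float(p_out[j]),
            n=float(config.n_outcome_cases + config.n_outcome_controls),
        )
        for j in range(J)
    ]
    outcome = SummaryDataset(
        trait_name="simulated_outcome", trait_type="binary", records=out_records,
        n_cases=config.n_outcome_cases, n_controls=config.n_outcome_controls,
    )
    truth = MvmrSimulationTruth(
        config=config,
        direct_effects=np.asarray(config.direct_effects, dtype=float),
        maf=maf, gamma_true=gamma, alpha=alpha,
    )
    return exposures, outcome, LdTable(), truth
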