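"""Causal estimators for summary-data Mendelian randomization.

Five estimators over the harmonized per-SNP pairs (γⱼ, Γⱼ):

* **IVW** — weighted regression of Γ on γ through the origin, weights
  1/se_Γ²; equivalently inverse-variance pooling of the per-SNP Wald
  ratios.  Multiplicative random effects by default: the SE is scaled by
  max(1, σ̂) with σ̂² the weighted residual mean square on J−1 df, so it
  never falls below the fixed-effect SE.
* **MR-Egger** — the same regression with a free intercept (after
  orienting γⱼ ≥ 0); a nonzero intercept estimates directional
  horizontal pleiotropy.  Inference uses t on J−2 df.
* **Weighted median** — the 50th weighted percentile of the Wald ratios
  (mid-cumulative convention, linear interpolation); consistent when
  valid instruments carry > 50% of the weight.  SE by parametric
  bootstrap.
* **Weighted / simple mode** — argmax of a Gaussian-kernel density over
  the Wald ratios with a Silverman-type bandwidth; consistent when the
  largest cluster of instruments is valid.  SE by parametric bootstrap.

All causal effects are log odds ratios per SD of exposure;
:func:`to_odds_ratio` attaches the OR scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedDataset

__all__ = [
    "MrEstimate",
    "RatioEstimates",
    "EstimatorConfig",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "to_odds_ratio",
    "run_all_methods",
    "METHOD_ORDER",
]

METHOD_ORDER = ("IVW", "MR-Egger", "Weighted median", "Weighted mode", "Simple mode")


@dataclass(frozen=True)
class MrEstimate:
    """One causal estimate: log-OR per SD exposure with OR-scale CI."""

    method: str
    n_snp: int
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RatioEstimates:
    """Per-SNP Wald ratios bⱼ = Γⱼ/γⱼ with first-order SEs sⱼ = se_Γⱼ/|γⱼ|."""

    rsids: tuple[str, ...]
    b: np.ndarray
    s: np.ndarray

    @property
    def w(self) -> np.ndarray:
        """Inverse-variance weights sⱼ⁻²."""
        return 1.0 / self.s**2


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings shared by the bootstrap/mode estimators.

    n_boot: parametric-bootstrap draws for median/mode SEs.
    phi: mode bandwidth multiplier on the Silverman-type rule.
    grid_points: mode argmax grid resolution.
    random_effects: multiplicative-random-effects IVW (σ̂ floored at 1);
    False gives fixed-effect IVW.
    """

    n_boot: int = 1000
    phi: float = 1.0
    grid_points: int = 10_000
    seed: int = 0
    random_effects: bool = True


def wald_ratios(data: HarmonizedDataset) -> RatioEstimates:
    """Per-SNP ratio estimates; any γⱼ = 0 is a hard error naming the SNP."""
    gamma = data.gamma
    zero = np.flatnonzero(gamma == 0.0)
    if zero.size:
        raise ValueError(f"zero exposure effect for SNP(s): {[data.rsids[i] for i in zero]}")
    b = data.Gamma / gamma
    s = data.se_Gamma / np.abs(gamma)
    return RatioEstimates(rsids=tuple(data.rsids), b=b, s=s)


def _safe_exp(x: float) -> float:
    # exp saturating to inf/0 instead of raising (huge ratio SEs from
    # near-zero exposure effects would otherwise overflow)
    if x > 709.0:
        return math.inf
    if x < -745.0:
        return 0.0
    return math.exp(x)


def to_odds_ratio(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """(OR, ci_low, ci_high) = exp(beta ∓ z·se) at the given confidence level."""
    if se < 0:
        raise ValueError("se must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return _safe_exp(beta), _safe_exp(beta - z * se), _safe_exp(beta + z * se)


def _finalize(
    method: str, n_snp: int, beta: float, se: float, pvalue: float, level: float, extras: dict
) -> MrEstimate:
    or_, lo, hi = to_odds_ratio(beta, se, level)
    return MrEstimate(
        method=method,
        n_snp=n_snp,
        beta=float(beta),
        se=float(se),
        pvalue=float(pvalue),
        or_=or_,
        ci_low=lo,
        ci_high=hi,
        level=level,
        extras=extras,
    )


def ivw(data: HarmonizedDataset, random_effects: bool = True, level: float = 0.95) -> MrEstimate:
    """Inverse-variance-weighted estimate.

    Weighted least squares of Γ on γ through the origin with weights
    1/se_Γ²; with ``random_effects`` the SE is inflated by max(1, σ̂)
    where σ̂² is the weighted residual mean square on J−1 df.  p-value
    from the standard normal.
    """
    J = len(data)
    if J < 2:
        raise ValueError("IVW needs ≥ 2 SNPs; use wald_ratios for a single instrument")
    gamma, Gamma, se_G = data.gamma, data.Gamma, data.se_Gamma
    w = 1.0 / se_G**2
    sxx = float(np.sum(w * gamma**2))
    beta = float(np.sum(w * gamma * Gamma)) / sxx
    se_fixed = sxx**-0.5
    resid = Gamma - beta * gamma
    sigma2 = float(np.sum(w * resid**2)) / (J - 1)
    scale = max(1.0, math.sqrt(sigma2)) if random_effects else 1.0
    se = se_fixed * scale
    pvalue = 2.0 * stats.norm.sf(abs(beta / se))
    extras = {"sigma": math.sqrt(sigma2), "model": "mre" if random_effects else "fe"}
    return _finalize("IVW", J, beta, se, pvalue, level, extras)


def egger(data: HarmonizedDataset, level: float = 0.95) -> MrEstimate:
    """MR-Egger regression: weighted fit of Γ on γ with a free intercept.

    Pairs are oriented so γⱼ ≥ 0 (both effects negated where needed).
    The intercept block — the directional-pleiotropy test — is returned
    in ``extras`` as intercept/intercept_se/intercept_pvalue; slope and
    intercept p-values use t on J−2 df, with SEs scaled by max(1, σ̂).
    """
    J = len(data)
    if J < 3:
        raise ValueError("MR-Egger needs ≥ 3 SNPs")
    gamma, Gamma, se_G = data.gamma, data.Gamma, data.se_Gamma
    sign = np.where(gamma < 0, -1.0, 1.0)
    x, y = sign * gamma, sign * Gamma
    w = 1.0 / se_G**2

    sw = float(np.sum(w))
    sx = float(np.sum(w * x))
    sy = float(np.sum(w * y))
    sxx = float(np.sum(w * x * x))
    sxy = float(np.sum(w * x * y))
    det = sw * sxx - sx * sx
    if det <= 0:
        raise ValueError("degenerate design: exposure effects have no spread")
    slope = (sw * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    resid = y - intercept - slope * x
    sigma2 = float(np.sum(w * resid**2)) / (J - 2)
    scale = max(1.0, math.sqrt(sigma2))
    se_slope = math.sqrt(sw / det) * scale
    se_intercept = math.sqrt(sxx / det) * scale
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), df=J - 2)
    p_intercept = 2.0 * stats.t.sf(abs(intercept / se_intercept), df=J - 2)
    extras = {
        "intercept": intercept,
        "intercept_se": se_intercept,
        "intercept_pvalue": p_intercept,
        "sigma": math.sqrt(sigma2),
        "df": J - 2,
    }
    return _finalize("MR-Egger", J, slope, se_slope, p_slope, level, extras)


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by the mid-cumulative convention with interpolation."""
    order = np.argsort(b, kind="stable")
    b_s, w_s = b[order], w[order]
    w_s = w_s / w_s.sum()
    p = np.cumsum(w_s) - 0.5 * w_s
    return float(np.interp(0.5, p, b_s))


def weighted_median(
    data: HarmonizedDataset,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> MrEstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    The estimate interpolates the inverse-variance-weighted cumulative
    distribution of Wald ratios at 0.5; the SE is the standard deviation
    of the estimate over ``n_boot`` draws bⱼ* ~ N(bⱼ, sⱼ²); p-value from
    the normal approximation.
    """
    J = len(data)
    if J < 3:
        raise ValueError("weighted median needs ≥ 3 SNPs")
    ratios = wald_ratios(data)
    beta = _weighted_median_point(ratios.b, ratios.w)
    se = _bootstrap_se(
        ratios.b, ratios.s, ratios.w, n_boot, seed, lambda bs, w: _wmedian_rows(bs, w)
    )
    pvalue = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta != 0 else 1.0)
    return _finalize(
        "Weighted median", J, beta, se, pvalue, level, {"n_boot": n_boot, "seed": seed}
    )


def _wmedian_rows(b_draws: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted median of each row of ``b_draws`` (B, J) with fixed weights."""
    B, J = b_draws.shape
    order = np.argsort(b_draws, axis=1, kind="stable")
    b_s = np.take_along_axis(b_draws, order, axis=1)
    w_s = w[order]
    w_s = w_s / w_s.sum(axis=1, keepdims=True)
    p = np.cumsum(w_s, axis=1) - 0.5 * w_s
    out = np.empty(B)
    for i in range(B):
        out[i] = np.interp(0.5, p[i], b_s[i])
    return out


def _bootstrap_se(b, s, w, n_boot, seed, row_estimator) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=b, scale=s, size=(n_boot, b.size))
    est = row_estimator(draws, w)
    return float(np.std(est, ddof=1))


def _mode_bandwidth(b: np.ndarray, phi: float) -> float:
    """Silverman-type bandwidth h = φ·0.9·min(sd, mad/0.6745)·J^(−1/5).

    A zero component (ties collapsing sd or mad) falls back to the other;
    both zero means all ratios coincide (degenerate, handled by caller).
    """
    J = b.size
    sd = float(np.std(b, ddof=1)) if J > 1 else 0.0
    mad = float(np.median(np.abs(b - np.median(b)))) / 0.6745
    scales = [x for x in (sd, mad) if x > 0]
    if not scales:
        return 0.0
    return phi * 0.9 * min(scales) * J ** (-1 / 5)


def _mode_rows(
    b_draws: np.ndarray, u: np.ndarray, phi: float, grid_points: int
) -> np.ndarray:
    """Kernel-density argmax for each row of ``b_draws`` (B, J).

    ``u`` are the (fixed) normalized point masses.  The bandwidth is
    recomputed per row; the grid spans [min−2h, max+2h]; ties take the
    lowest grid value (np.argmax picks the first maximum).
    """
    B, J = b_draws.shape
    out = np.empty(B)
    sd = np.std(b_draws, axis=1, ddof=1)
    med = np.median(b_draws, axis=1)
    mad = np.median(np.abs(b_draws - med[:, None]), axis=1) / 0.6745
    lo_scale = np.where(
        (sd > 0) & (mad > 0), np.minimum(sd, mad), np.maximum(sd, mad)
    )
    h = phi * 0.9 * lo_scale * J ** (-1 / 5)

    degenerate = h <= 0
    out[degenerate] = b_draws[degenerate, 0] if degenerate.any() else 0.0

    idx = np.flatnonzero(~degenerate)
    # per-row grid over [min−2h, max+2h]; rows chunked to bound the
    # (B, grid, J) kernel tensor at ~2e7 elements
    chunk = max(1, int(2e7 / (grid_points * J)))
    steps = np.arange(grid_points)
    for start in range(0, idx.size, chunk):
        rows = idx[start : start + chunk]
        bd = b_draws[rows]
        hh = h[rows][:, None]
        lo = bd.min(axis=1, keepdims=True) - 2 * hh
        hi = bd.max(axis=1, keepdims=True) + 2 * hh
        grid = lo + (hi - lo) * steps[None, :] / (grid_points - 1)
        z = (grid[:, :, None] - bd[:, None, :]) / hh[:, :, None]
        dens = np.exp(-0.5 * z**2) @ u
        best = np.argmax(dens, axis=1)
        out[rows] = np.take_along_axis(grid, best[:, None], axis=1)[:, 0]
    return out


def mode_estimate(
    data: HarmonizedDataset,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    grid_points: int = 10_000,
    level: float = 0.95,
) -> MrEstimate:
    """Mode-based estimate (weighted or simple) with parametric-bootstrap SE.

    The estimate is the argmax on a ``grid_points`` grid of a Gaussian
    kernel density over the Wald ratios, each ratio carrying mass
    wⱼ/Σw (weighted) or 1/J (simple); bandwidth per :func:`_mode_bandwidth`.
    All ratios identical ⇒ that common ratio with SE 0.
    """
    J = len(data)
    if J < 3:
        raise ValueError("mode estimate needs ≥ 3 SNPs")
    ratios = wald_ratios(data)
    name = "Weighted mode" if weighted else "Simple mode"
    u = ratios.w / ratios.w.sum() if weighted else np.full(J, 1.0 / J)

    if np.all(ratios.b == ratios.b[0]):
        beta = float(ratios.b[0])
        return _finalize(name, J, beta, 0.0, 0.0 if beta != 0 else 1.0, level,
                         {"phi": phi, "n_boot": n_boot, "seed": seed, "bandwidth": 0.0})

    h = _mode_bandwidth(ratios.b, phi)
    beta = float(_mode_rows(ratios.b[None, :], u, phi, grid_points)[0])
    se = _bootstrap_se(
        ratios.b,
        ratios.s,
        u,
        n_boot,
        seed,
        lambda bs, uu: _mode_rows(bs, uu, phi, grid_points),
    )
    pvalue = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta != 0 else 1.0)
    return _finalize(
        name, J, beta, se, pvalue, level,
        {"phi": phi, "n_boot": n_boot, "seed": seed, "bandwidth": h},
    )


def run_all_methods(
    data: HarmonizedDataset, config: EstimatorConfig | None = None, level: float = 0.95
) -> list[MrEstimate]:
    """All five estimators in conventional reporting order.

    IVW, MR-Egger, weighted median, weighted mode, simple mode — each
    with the instrument count recorded; bootstrap methods use
    ``config.seed`` (offset per method so draws are independent but
    reproducible).
    """
    cfg = config or EstimatorConfig()
    return [
        ivw(data, random_effects=cfg.random_effects, level=level),
        egger(data, level=level),
        weighted_median(data, n_boot=cfg.n_boot, seed=cfg.seed, level=level),
        mode_estimate(
            data, weighted=True, phi=cfg.phi, n_boot=cfg.n_boot,
            seed=cfg.seed + 1, grid_points=cfg.grid_points, level=level,
        ),
        mode_estimate(
            data, weighted=False, phi=cfg.phi, n_boot=cfg.n_boot,
            seed=cfg.seed + 2, grid_points=cfg.grid_points, level=level,
        ),
    ]
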