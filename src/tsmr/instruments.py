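"""Instrument selection and strength.

Selection follows the conventional summary-data workflow: a p-value
screen (default 1e-5), greedy LD clumping (r² 0.001 within a 10,000 kb
window), an offline exclusion list standing in for phenome-wide
screening of pleiotropic candidates, and optional proxy lookup
(r² ≥ 0.8) for instruments absent from the outcome dataset.

Instrument strength uses the single-SNP variance-explained form
r² = β² / (β² + n·se²) with F = r²(n−2)/(1−r²), falling back to the
large-sample approximation F ≈ (β/se)² when the per-SNP sample size is
unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .summary_io import LdTable, SummaryDataset, SummaryStatRecord

__all__ = [
    "SelectionConfig",
    "InstrumentStrength",
    "select_by_pvalue",
    "clump",
    "find_proxy",
    "exclude_snps",
    "instrument_strength",
    "total_variance_explained",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection.

    Defaults mirror the conventional lenient two-sample workflow when too
    few variants reach genome-wide significance: screen at p < 1e-5,
    clump at r² = 0.001 within 10,000 kb, accept proxies at r² ≥ 0.8.
    """

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    proxy_min_r2: float = 0.8
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ValueError("clump_r2 must be in [0, 1]")
        if not (0.0 <= self.proxy_min_r2 <= 1.0):
            raise ValueError("proxy_min_r2 must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        object.__setattr__(self, "exclusion_list", frozenset(self.exclusion_list))


@dataclass(frozen=True)
class InstrumentStrength:
    """Per-instrument strength: F statistic and exposure variance explained.

    ``approximate`` flags the (β/se)² fallback used when n is unknown; in
    that case ``r2`` is None.
    """

    rsid: str
    f_stat: float
    r2: float | None
    approximate: bool = False


def select_by_pvalue(dataset: SummaryDataset, threshold: float) -> SummaryDataset:
    """Keep records with p-value strictly below ``threshold``; order preserved."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    kept = [r for r in dataset.records if r.pvalue < threshold]
    if not kept:
        warnings.warn(
            f"no SNP passes p < {threshold:g} in {dataset.trait_name!r}", stacklevel=2
        )
    return replace(dataset, records=kept)


def _p_rank_key(rec: SummaryStatRecord):
    # ties: smaller position, then lexicographic rsid, for determinism
    return (rec.pvalue, rec.pos, rec.rsid)


def clump(dataset: SummaryDataset, ld: LdTable, config: SelectionConfig) -> SummaryDataset:
    """Greedy LD clumping by ascending p-value.

    A SNP is discarded iff some already-kept SNP lies on the same
    chromosome within ``clump_window_kb`` and has r² > ``clump_r2`` with
    it; pairs outside the window are independent regardless of the LD
    table, and a missing LD entry counts as r² = 0.  Output is
    deterministic and invariant to input record order.
    """
    window_bp = config.clump_window_kb * 1000.0
    kept: list[SummaryStatRecord] = []
    for rec in sorted(dataset.records, key=_p_rank_key):
        pruned = any(
            k.chrom == rec.chrom
            and abs(k.pos - rec.pos) <= window_bp
            and ld.r2(k.rsid, rec.rsid) > config.clump_r2
            for k in kept
        )
        if not pruned:
            kept.append(rec)
    return replace(dataset, records=kept)


def find_proxy(
    rsid: str,
    outcome: SummaryDataset,
    ld: LdTable,
    min_r2: float = 0.8,
    target_chrom: str | None = None,
    target_pos: int | None = None,
) -> str | None:
    """Best outcome-present proxy for ``rsid``: maximal r² among r² ≥ min_r2.

    Ties break by smaller base-pair distance to the target (when its
    coordinates are supplied), then lexicographic rsid.  Returns None if
    no candidate reaches ``min_r2``.
    """
    best: tuple[float, float, str] | None = None  # (-r2, distance, rsid)
    for rec in outcome.records:
        if rec.rsid == rsid:
            continue
        r2 = ld.r2(rsid, rec.rsid)
        if r2 < min_r2:
            continue
        if target_pos is not None and target_chrom is not None and rec.chrom == target_chrom:
            dist = float(abs(rec.pos - target_pos))
        else:
            dist = float("inf")
        key = (-r2, dist, rec.rsid)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def exclude_snps(
    dataset: SummaryDataset, exclusion_list: Iterable[str]
) -> tuple[SummaryDataset, int]:
    """Remove listed rsids (e.g. variants flagged as pleiotropic by an
    offline phenome screen); returns the filtered dataset and the count
    removed."""
    excl = set(exclusion_list)
    kept = [r for r in dataset.records if r.rsid not in excl]
    return replace(dataset, records=kept), len(dataset.records) - len(kept)


def instrument_strength(rec: SummaryStatRecord, n: float | None = None) -> InstrumentStrength:
    """F statistic and variance explained for one instrument.

    With n known: r² = β²/(β² + n·se²), F = r²(n−2)/(1−r²).  Without n:
    F ≈ (β/se)², flagged approximate, r² unreported.
    """
    if n is None:
        n = rec.n
    if n is None:
        return InstrumentStrength(
            rsid=rec.rsid, f_stat=(rec.beta / rec.se) ** 2, r2=None, approximate=True
        )
    if n <= 2:
        raise ValueError("n must exceed 2 for the variance-explained form")
    r2 = rec.beta**2 / (rec.beta**2 + n * rec.se**2)
    f_stat = r2 * (n - 2) / (1.0 - r2)
    return InstrumentStrength(rsid=rec.rsid, f_stat=f_stat, r2=r2, approximate=False)


def total_variance_explained(strengths: Sequence[InstrumentStrength]) -> float:
    """Summed per-SNP r² (instruments assumed independent after clumping)."""
    if not strengths:
        raise ValueError("no instrument strengths supplied")
    if any(s.r2 is None for s in strengths):
        raise ValueError("r2 unavailable for some instruments (n unknown)")
    return float(sum(s.r2 for s in strengths))
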