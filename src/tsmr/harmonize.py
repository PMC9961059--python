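"""Allele harmonization between exposure and outcome summary statistics.

Both effects for each SNP are expressed on the exposure file's effect
allele.  Non-palindromic variants are aligned by direct allele match,
swap, or strand complement; palindromic (A/T, C/G) variants cannot be
resolved from alleles and are aligned by effect-allele frequency instead,
and only when the minor-allele frequency is below the ambiguity threshold
(default 0.3) in both datasets — an intermediate-frequency palindrome is
dropped.  The exposure orientation is never flipped, so the exposure
effect keeps its original units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .instruments import SelectionConfig, find_proxy
from .summary_io import LdTable, SummaryDataset, SummaryStatRecord

__all__ = [
    "HarmonizedPair",
    "HarmonizedDataset",
    "is_palindromic",
    "harmonize_pair",
    "harmonize_datasets",
    "DROP_ALLELE_MISMATCH",
    "DROP_AMBIGUOUS_PALINDROME",
    "DROP_ABSENT",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DROP_ALLELE_MISMATCH = "allele mismatch"
DROP_AMBIGUOUS_PALINDROME = "ambiguous palindrome"
DROP_ABSENT = "absent from outcome"


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return _COMPLEMENT[effect_allele.upper()] == other_allele.upper()


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a common effect allele.

    gamma/se_gamma: exposure effect and SE; Gamma/se_Gamma: outcome
    effect and SE.  ``flipped`` records that the outcome effect was
    negated to match the exposure orientation.
    """

    rsid: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    palindromic: bool = False
    flipped: bool = False
    proxy_used: str | None = None

    def __post_init__(self) -> None:
        if self.se_gamma <= 0 or self.se_Gamma <= 0:
            raise ValueError(f"{self.rsid}: standard errors must be positive")


@dataclass
class HarmonizedDataset:
    """Harmonized SNP pairs plus a drop log accounting for every input SNP."""

    pairs: list[HarmonizedPair]
    drop_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rsids = [p.rsid for p in self.pairs]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in harmonized dataset")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[HarmonizedPair]:
        return iter(self.pairs)

    @property
    def rsids(self) -> list[str]:
        return [p.rsid for p in self.pairs]

    @property
    def gamma(self) -> np.ndarray:
        return np.array([p.gamma for p in self.pairs])

    @property
    def se_gamma(self) -> np.ndarray:
        return np.array([p.se_gamma for p in self.pairs])

    @property
    def Gamma(self) -> np.ndarray:
        return np.array([p.Gamma for p in self.pairs])

    @property
    def se_Gamma(self) -> np.ndarray:
        return np.array([p.se_Gamma for p in self.pairs])

    @classmethod
    def from_arrays(
        cls,
        gamma: Sequence[float],
        se_gamma: Sequence[float],
        Gamma: Sequence[float],
        se_Gamma: Sequence[float],
        rsids: Sequence[str] | None = None,
    ) -> "HarmonizedDataset":
        """Build directly from effect arrays (synthetic / testing entry point)."""
        if rsids is None:
            rsids = [f"snp{i + 1}" for i in range(len(gamma))]
        pairs = [
            HarmonizedPair(
                rsid=r, gamma=float(g), se_gamma=float(sg), Gamma=float(G), se_Gamma=float(sG)
            )
            for r, g, sg, G, sG in zip(rsids, gamma, se_gamma, Gamma, se_Gamma, strict=True)
        ]
        return cls(pairs=pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": p.rsid,
                    "gamma": p.gamma,
                    "se_gamma": p.se_gamma,
                    "Gamma": p.Gamma,
                    "se_Gamma": p.se_Gamma,
                    "eaf_exposure": p.eaf_exposure,
                    "eaf_outcome": p.eaf_outcome,
                    "palindromic": p.palindromic,
                    "flipped": p.flipped,
                    "proxy_used": p.proxy_used,
                }
                for p in self.pairs
            ],
            columns=[
                "rsid",
                "gamma",
                "se_gamma",
                "Gamma",
                "se_Gamma",
                "eaf_exposure",
                "eaf_outcome",
                "palindromic",
                "flipped",
                "proxy_used",
            ],
        )


def _pair(
    exposure: SummaryStatRecord,
    outcome: SummaryStatRecord,
    *,
    flipped: bool,
    palindromic: bool,
    proxy_used: str | None,
) -> HarmonizedPair:
    sign = -1.0 if flipped else 1.0
    eaf_out = outcome.eaf
    if flipped and eaf_out is not None:
        eaf_out = 1.0 - eaf_out
    return HarmonizedPair(
        rsid=exposure.rsid,
        gamma=exposure.beta,
        se_gamma=exposure.se,
        Gamma=sign * outcome.beta,
        se_Gamma=outcome.se,
        eaf_exposure=exposure.eaf,
        eaf_outcome=eaf_out,
        palindromic=palindromic,
        flipped=flipped,
        proxy_used=proxy_used,
    )


def harmonize_pair(
    exposure: SummaryStatRecord,
    outcome: SummaryStatRecord,
    maf_threshold: float = 0.3,
    proxy_used: str | None = None,
) -> HarmonizedPair | str:
    """Harmonize one SNP; returns a pair or a drop-reason string.

    Non-palindromic: direct match copies effects; swapped alleles negate
    the outcome effect and mirror its frequency; otherwise the outcome
    alleles are strand-complemented and re-tried; failing all three, the
    SNP is dropped as an allele mismatch.  Palindromic: aligned purely by
    allele frequency (opposite sides of 0.5 ⇒ flip), and only when
    MAF < ``maf_threshold`` in both datasets; an intermediate or missing
    frequency drops the SNP as an ambiguous palindrome.
    """
    if proxy_used is None and exposure.rsid != outcome.rsid:
        raise ValueError(
            f"rsid mismatch without proxy mapping: {exposure.rsid} vs {outcome.rsid}"
        )
    e_ea, e_oa = exposure.effect_allele, exposure.other_allele
    o_ea, o_oa = outcome.effect_allele, outcome.other_allele

    if is_palindromic(e_ea, e_oa):
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return DROP_ALLELE_MISMATCH
        eaf_e, eaf_o = exposure.eaf, outcome.eaf
        if eaf_e is None or eaf_o is None:
            return DROP_AMBIGUOUS_PALINDROME
        if min(eaf_e, 1 - eaf_e) >= maf_threshold or min(eaf_o, 1 - eaf_o) >= maf_threshold:
            return DROP_AMBIGUOUS_PALINDROME
        flipped = (eaf_e - 0.5) * (eaf_o - 0.5) < 0
        return _pair(exposure, outcome, flipped=flipped, palindromic=True, proxy_used=proxy_used)

    for o_ea_try, o_oa_try, complemented in (
        (o_ea, o_oa, False),
        (_COMPLEMENT[o_ea], _COMPLEMENT[o_oa], True),
    ):
        if (o_ea_try, o_oa_try) == (e_ea, e_oa):
            return _pair(
                exposure, outcome, flipped=False, palindromic=False, proxy_used=proxy_used
            )
        if (o_ea_try, o_oa_try) == (e_oa, e_ea):
            return _pair(
                exposure, outcome, flipped=True, palindromic=False, proxy_used=proxy_used
            )
    return DROP_ALLELE_MISMATCH


def harmonize_datasets(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LdTable | None = None,
    config: SelectionConfig | None = None,
    maf_threshold: float = 0.3,
    use_proxies: bool = False,
) -> HarmonizedDataset:
    """Harmonize every (instrument-selected) exposure SNP against the outcome.

    Outcome lookup is by rsid; when ``use_proxies`` and an LD table is
    supplied, a proxy (r² ≥ config.proxy_min_r2) substitutes for an
    absent SNP.  Every input SNP appears exactly once in the output,
    either as a kept pair or in the drop log.  Zero kept pairs is a hard
    error — no analysis is possible.
    """
    config = config or SelectionConfig()
    outcome_by_rsid = outcome.by_rsid()
    pairs: list[HarmonizedPair] = []
    drop_log: dict[str, str] = {}
    for rec in exposure.records:
        out_rec = outcome_by_rsid.get(rec.rsid)
        proxy: str | None = None
        if out_rec is None and use_proxies and ld is not None:
            proxy = find_proxy(
                rec.rsid,
                outcome,
                ld,
                min_r2=config.proxy_min_r2,
                target_chrom=rec.chrom,
                target_pos=rec.pos,
            )
            if proxy is not None:
                out_rec = outcome_by_rsid[proxy]
        if out_rec is None:
            drop_log[rec.rsid] = DROP_ABSENT
            continue
        result = harmonize_pair(rec, out_rec, maf_threshold=maf_threshold, proxy_used=proxy)
        if isinstance(result, str):
            drop_log[rec.rsid] = result
        else:
            pairs.append(result)
    if not pairs:
        raise ValueError("no SNP survived harmonization; nothing to analyse")
    return HarmonizedDataset(pairs=pairs, drop_log=drop_log)
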