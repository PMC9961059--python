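"""GWAS summary-statistic data model and tabular I/O.

The central container is :class:`SummaryDataset`, an ordered collection of
per-SNP association records for one trait.  On-disk format is plain TSV
with a canonical header; an LD table is a 3-column TSV of pairwise r²
values, and an exclusion list is one rsid per line.  Coordinates are
1-based and treated as opaque but internally consistent between files
(no genome-build arithmetic is performed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "SummaryDataset",
    "LdTable",
    "ValidationReport",
    "ReadReport",
    "record_violations",
    "read_summary_table",
    "write_summary_table",
    "validate_dataset",
    "read_ld_table",
    "write_ld_table",
    "read_exclusion_list",
    "CANONICAL_COLUMNS",
]

_BASES = {"A", "C", "G", "T"}

#: canonical on-disk column order
CANONICAL_COLUMNS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is per copy of ``effect_allele``: SD units for a continuous
    trait, log-odds for a binary one.  ``eaf`` and ``n`` may be missing
    (``None``).  Alleles are normalized to upper case; range invariants
    are checked by :func:`record_violations` rather than the constructor,
    so that invalid rows can be represented, reported and dropped.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", str(self.effect_allele).upper())
        object.__setattr__(self, "other_allele", str(self.other_allele).upper())
        object.__setattr__(self, "chrom", str(self.chrom))
        object.__setattr__(self, "pos", int(self.pos))

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


def record_violations(rec: SummaryStatRecord) -> list[str]:
    """Return the list of invariant violations for one record (empty if valid).

    Checked: alleles are single distinct upper-case bases (biallelic SNPs
    only — indels / multi-base alleles are rejected), se > 0, pvalue in
    (0, 1], eaf (if present) strictly inside (0, 1), finite beta.
    """
    out: list[str] = []
    if rec.effect_allele not in _BASES or rec.other_allele not in _BASES:
        out.append("allele not a single A/C/G/T base")
    elif rec.effect_allele == rec.other_allele:
        out.append("effect and other allele identical")
    if not (rec.se > 0 and math.isfinite(rec.se)):
        out.append("se not strictly positive")
    if not (0.0 < rec.pvalue <= 1.0):
        out.append("pvalue outside (0, 1]")
    if rec.eaf is not None and not (0.0 < rec.eaf < 1.0):
        out.append("eaf outside (0, 1)")
    if not math.isfinite(rec.beta):
        out.append("beta not finite")
    if rec.pos < 1:
        out.append("position not 1-based positive")
    return out


def _chrom_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (10**9, chrom)


@dataclass
class SummaryDataset:
    """Ordered, validated collection of summary-statistic records for a trait."""

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    records: list[SummaryStatRecord]
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        # duplicates are representable (validate_dataset reports them);
        # read_summary_table never produces them
        self.records = sorted(self.records, key=lambda r: (_chrom_key(r.chrom), r.pos))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_rsid(self) -> dict[str, SummaryStatRecord]:
        return {r.rsid: r for r in self.records}

    def subset(self, rsids: Iterable[str]) -> "SummaryDataset":
        """New dataset restricted to ``rsids``, metadata preserved."""
        keep = set(rsids)
        return replace(self, records=[r for r in self.records if r.rsid in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rsid": r.rsid,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": r.eaf,
                    "beta": r.beta,
                    "se": r.se,
                    "pvalue": r.pvalue,
                    "n": r.n,
                }
                for r in self.records
            ],
            columns=list(CANONICAL_COLUMNS),
        )


class LdTable:
    """Pairwise r² between SNPs, keyed by unordered rsid pairs.

    A missing pair is treated as r² = 0; a self-pair is 1 by definition.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset[str], float] = {}
        if entries:
            for (a, b), r2 in entries.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2} for ({a}, {b})")
        if a == b and r2 != 1.0:
            raise ValueError(f"self-pair r2 must be 1, got {r2} for {a}")
        self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def neighbors(self, rsid: str) -> dict[str, float]:
        """All SNPs with a recorded r² entry against ``rsid``."""
        out: dict[str, float] = {}
        for key, r2 in self._r2.items():
            if rsid in key:
                others = key - {rsid}
                other = next(iter(others)) if others else rsid
                out[other] = r2
        return out

    def __len__(self) -> int:
        return len(self._r2)

    def items(self):
        for key, r2 in self._r2.items():
            pair = sorted(key)
            if len(pair) == 1:
                pair = [pair[0], pair[0]]
            yield (pair[0], pair[1]), r2


@dataclass
class ReadReport:
    """Accounting of one read: rows seen, kept, and dropped with reasons."""

    n_input: int = 0
    n_kept: int = 0
    dropped: dict[str, str] = field(default_factory=dict)  # row label -> reason

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


@dataclass
class ValidationReport:
    duplicate_rsids: list[str]
    violations: dict[str, list[str]]  # rsid -> violation messages
    missing_eaf_fraction: float
    missing_n_fraction: float

    @property
    def ok(self) -> bool:
        return not self.duplicate_rsids and not self.violations


_DEFAULT_COLUMN_MAP = {c: c for c in CANONICAL_COLUMNS}


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_meta: Mapping[str, object] | None = None,
    sep: str = "\t",
) -> tuple[SummaryDataset, ReadReport]:
    """Read a delimited summary-statistic table into a validated dataset.

    ``column_map`` maps record fields to source column names (defaults to
    the canonical header).  Rows failing record invariants, or with
    unparseable numeric cells, are dropped and accounted for in the
    returned :class:`ReadReport`.  Missing mandatory columns (rsid,
    alleles, beta, se) are a hard error.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    meta = dict(trait_meta or {})

    df = pd.read_csv(path, sep=sep, dtype=str)
    mandatory = ("rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue")
    missing_cols = [f for f in mandatory if cmap[f] not in df.columns]
    if missing_cols:
        raise ValueError(f"missing mandatory columns in {path}: {missing_cols}")

    report = ReadReport(n_input=len(df))
    records: list[SummaryStatRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        label = str(row[cmap["rsid"]])
        try:
            eaf_raw = row[cmap["eaf"]] if cmap["eaf"] in df.columns else None
            n_raw = row[cmap["n"]] if cmap["n"] in df.columns else None
            rec = SummaryStatRecord(
                rsid=label,
                chrom=str(row[cmap["chrom"]]),
                pos=int(float(row[cmap["pos"]])),
                effect_allele=str(row[cmap["effect_allele"]]),
                other_allele=str(row[cmap["other_allele"]]),
                eaf=None if _is_na(eaf_raw) else float(eaf_raw),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pvalue=float(row[cmap["pvalue"]]),
                n=None if _is_na(n_raw) else float(n_raw),
            )
        except (TypeError, ValueError) as exc:
            report.dropped[f"row {i} ({label})"] = f"unparseable cell: {exc}"
            continue
        problems = record_violations(rec)
        if problems:
            report.dropped[f"row {i} ({label})"] = "; ".join(problems)
            continue
        if rec.rsid in seen:
            report.dropped[f"row {i} ({label})"] = "duplicate rsid"
            continue
        seen.add(rec.rsid)
        records.append(rec)
    report.n_kept = len(records)

    dataset = SummaryDataset(
        trait_name=str(meta.get("trait_name", Path(path).stem)),
        trait_type=str(meta.get("trait_type", "continuous")),
        records=records,
        n_cases=meta.get("n_cases"),
        n_controls=meta.get("n_controls"),
    )
    return dataset, report


def _is_na(value) -> bool:
    if value is None:
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def write_summary_table(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset as canonical TSV.

    Floats are written with Python's shortest round-trip repr, so
    :func:`read_summary_table` reproduces the dataset bit-for-bit.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in dataset.records:
            fields = [
                r.rsid,
                r.chrom,
                str(r.pos),
                r.effect_allele,
                r.other_allele,
                "" if r.eaf is None else repr(float(r.eaf)),
                repr(float(r.beta)),
                repr(float(r.se)),
                repr(float(r.pvalue)),
                "" if r.n is None else repr(float(r.n)),
            ]
            fh.write("\t".join(fields) + "\n")


def validate_dataset(dataset: SummaryDataset) -> ValidationReport:
    """Report duplicate rsids, invariant violations and missingness.

    Purely a reporting operation: never mutates the dataset.
    """
    rsids = [r.rsid for r in dataset.records]
    dupes = sorted({r for r in rsids if rsids.count(r) > 1})
    violations: dict[str, list[str]] = {}
    for r in dataset.records:
        problems = record_violations(r)
        if problems:
            violations[r.rsid] = problems
    n = max(len(dataset.records), 1)
    missing_eaf = sum(1 for r in dataset.records if r.eaf is None) / n
    missing_n = sum(1 for r in dataset.records if r.n is None) / n
    return ValidationReport(
        duplicate_rsids=dupes,
        violations=violations,
        missing_eaf_fraction=missing_eaf,
        missing_n_fraction=missing_n,
    )


def read_ld_table(path: str | Path) -> LdTable:
    """Read a 3-column TSV (snp_a, snp_b, r2) into an :class:`LdTable`."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str, "r2": float})
    table = LdTable()
    for _, row in df.iterrows():
        table.set(row["snp_a"], row["snp_b"], float(row["r2"]))
    return table


def write_ld_table(table: LdTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("snp_a\tsnp_b\tr2\n")
        for (a, b), r2 in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{repr(float(r2))}\n")


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read one rsid per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
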