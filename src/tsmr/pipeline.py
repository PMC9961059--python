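"""End-to-end two-sample MR workflow over summary-statistic files.

``run_pipeline`` chains selection → exclusion → clumping → harmonization
→ the five estimators → sensitivity diagnostics (→ power when the
outcome's case/control sizes are known), writing every result table as
TSV plus a JSON manifest that records all parameters, seeds and
per-stage counts.  A rerun from the same config and seed is
byte-identical, and ``make_report`` renders a one-page narrative summary
from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .estimators import EstimatorConfig, MrEstimate, run_all_methods
from .harmonize import HarmonizedDataset, harmonize_datasets
from .instruments import (
    SelectionConfig,
    clump,
    exclude_snps,
    instrument_strength,
    select_by_pvalue,
    total_variance_explained,
)
from .power import PowerInput, mr_power_binary
from .sensitivity import cochran_q, egger_intercept_test, funnel_data, leave_one_out, single_snp_forest
from .summary_io import (
    LdTable,
    read_exclusion_list,
    read_ld_table,
    read_summary_table,
    write_summary_table,
)

__all__ = ["PipelineConfig", "PipelineBundle", "run_pipeline", "make_report"]


@dataclass
class PipelineConfig:
    """Everything one run needs: input paths, thresholds, estimator settings."""

    exposure_path: str
    outcome_path: str
    out_dir: str
    ld_path: str | None = None
    exclusion_path: str | None = None
    exposure_meta: dict = field(default_factory=dict)
    outcome_meta: dict = field(default_factory=dict)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    maf_threshold: float = 0.3
    use_proxies: bool = False

    def to_manifest_dict(self) -> dict:
        d = asdict(self)
        d["selection"]["exclusion_list"] = sorted(d["selection"]["exclusion_list"])
        return d


@dataclass
class PipelineBundle:
    """In-memory results of one pipeline run."""

    config: PipelineConfig
    harmonized: HarmonizedDataset
    estimates: list[MrEstimate]
    estimates_table: pd.DataFrame
    heterogeneity: pd.DataFrame
    pleiotropy: pd.DataFrame
    loo: pd.DataFrame
    forest: pd.DataFrame
    funnel: pd.DataFrame
    manifest: dict


def _estimates_frame(estimates: list[MrEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": e.method,
                "n_snp": e.n_snp,
                "beta": e.beta,
                "se": e.se,
                "or": e.or_,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pvalue": e.pvalue,
            }
            for e in estimates
        ]
    )


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Execute the full workflow and write all outputs under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    exposure, exp_report = read_summary_table(
        config.exposure_path, trait_meta=config.exposure_meta
    )
    outcome, out_report = read_summary_table(
        config.outcome_path, trait_meta=config.outcome_meta
    )
    ld = read_ld_table(config.ld_path) if config.ld_path else LdTable()
    exclusions = set(config.selection.exclusion_list)
    if config.exclusion_path:
        exclusions |= read_exclusion_list(config.exclusion_path)

    counts: dict[str, int] = {
        "exposure_rows_read": exp_report.n_input,
        "exposure_rows_kept": exp_report.n_kept,
        "outcome_rows_read": out_report.n_input,
        "outcome_rows_kept": out_report.n_kept,
    }

    selected = select_by_pvalue(exposure, config.selection.p_threshold)
    counts["after_p_threshold"] = len(selected)
    clumped = clump(selected, ld, config.selection)
    counts["after_clumping"] = len(clumped)
    kept, n_excluded = exclude_snps(clumped, exclusions)
    counts["excluded_by_list"] = n_excluded
    counts["after_exclusion"] = len(kept)

    harmonized = harmonize_datasets(
        kept,
        outcome,
        ld=ld,
        config=config.selection,
        maf_threshold=config.maf_threshold,
        use_proxies=config.use_proxies,
    )
    counts["harmonized"] = len(harmonized)
    counts["dropped_in_harmonization"] = len(harmonized.drop_log)

    estimates = run_all_methods(harmonized, config.estimator)
    est_df = _estimates_frame(estimates)

    het = cochran_q(harmonized)
    het_df = pd.DataFrame(
        [{"q": het.q, "df": het.df, "pvalue": het.pvalue, "i2": het.i2}]
    )
    plei = egger_intercept_test(harmonized)
    plei_df = pd.DataFrame(
        [{"intercept": plei.intercept, "se": plei.se, "pvalue": plei.pvalue, "df": plei.df}]
    )
    loo_df = leave_one_out(harmonized)
    forest_df = single_snp_forest(harmonized)
    funnel_df, funnel_refs = funnel_data(harmonized)

    kept_rsids = set(harmonized.rsids)
    strengths = [instrument_strength(r) for r in kept.records if r.rsid in kept_rsids]
    f_stats = [s.f_stat for s in strengths]
    strength_block: dict = {
        "f_min": min(f_stats),
        "f_max": max(f_stats),
        "n_weak": sum(1 for f in f_stats if f <= 10),
    }
    if all(not s.approximate for s in strengths):
        strength_block["total_r2"] = total_variance_explained(strengths)

    power_block: dict | None = None
    n_cases = outcome.n_cases or config.outcome_meta.get("n_cases")
    n_controls = outcome.n_controls or config.outcome_meta.get("n_controls")
    if n_cases and n_controls and "total_r2" in strength_block:
        ivw_est = estimates[0]
        n_total = float(n_cases + n_controls)
        p_in = PowerInput(
            n_total=n_total,
            prop_case=n_cases / n_total,
            r2_xz=strength_block["total_r2"],
            odds_ratio=ivw_est.or_,
        )
        prop, pct = mr_power_binary(p_in)
        power_block = {
            "n_total": n_total,
            "prop_case": p_in.prop_case,
            "r2_xz": p_in.r2_xz,
            "odds_ratio": p_in.odds_ratio,
            "alpha": p_in.alpha,
            "power": prop,
            "power_percent": pct,
        }

    manifest = {
        "tsmr_version": __version__,
        "config": config.to_manifest_dict(),
        "counts": counts,
        "drop_log": dict(sorted(harmonized.drop_log.items())),
        "estimates": est_df.to_dict(orient="records"),
        "heterogeneity": het_df.to_dict(orient="records")[0],
        "egger_intercept": plei_df.to_dict(orient="records")[0],
        "instrument_strength": strength_block,
        "funnel_references": funnel_refs,
        "power": power_block,
    }

    write_summary_table(kept, out / "instruments.tsv")
    harmonized.to_frame().to_csv(out / "harmonized.tsv", sep="\t", index=False)
    est_df.to_csv(out / "estimates.tsv", sep="\t", index=False)
    het_df.to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
    plei_df.to_csv(out / "pleiotropy.tsv", sep="\t", index=False)
    loo_df.to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
    forest_df.to_csv(out / "forest.tsv", sep="\t", index=False)
    funnel_df.to_csv(out / "funnel.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle = PipelineBundle(
        config=config,
        harmonized=harmonized,
        estimates=estimates,
        estimates_table=est_df,
        heterogeneity=het_df,
        pleiotropy=plei_df,
        loo=loo_df,
        forest=forest_df,
        funnel=funnel_df,
        manifest=manifest,
    )
    (out / "report.md").write_text(make_report(manifest))
    return bundle


def make_report(bundle: PipelineBundle | dict) -> str:
    """One-page markdown summary, reconstructible from the manifest alone."""
    manifest = bundle.manifest if isinstance(bundle, PipelineBundle) else bundle
    c = manifest["counts"]
    lines = [
        "# Two-sample MR report",
        "",
        f"tsmr version {manifest['tsmr_version']}",
        "",
        "## Instrument selection",
        "",
        f"- exposure rows read/kept: {c['exposure_rows_read']}/{c['exposure_rows_kept']}",
        f"- passing p-threshold: {c['after_p_threshold']}",
        f"- after LD clumping: {c['after_clumping']}",
        f"- removed by exclusion list: {c['excluded_by_list']}"
        f" (remaining {c['after_exclusion']})",
        f"- harmonized against outcome: {c['harmonized']}"
        f" (dropped {c['dropped_in_harmonization']})",
        "",
        "## Causal estimates",
        "",
        "| method | n SNPs | beta | SE | OR (95% CI) | p |",
        "|---|---|---|---|---|---|",
    ]
    for e in manifest["estimates"]:
        lines.append(
            f"| {e['method']} | {e['n_snp']} | {e['beta']:.3f} | {e['se']:.3f} | "
            f"{e['or']:.3f} ({e['ci_low']:.3f}–{e['ci_high']:.3f}) | {e['pvalue']:.3g} |"
        )
    het = manifest["heterogeneity"]
    plei = manifest["egger_intercept"]
    s = manifest["instrument_strength"]
    lines += [
        "",
        "## Diagnostics",
        "",
        f"- Cochran's Q = {het['q']:.3f} on {het['df']} df, p = {het['pvalue']:.3f}, "
        f"I² = {het['i2']:.1%}",
        f"- MR-Egger intercept = {plei['intercept']:.4f} "
        f"(SE {plei['se']:.4f}), p = {plei['pvalue']:.3f}",
        f"- per-SNP F statistics: {s['f_min']:.2f}–{s['f_max']:.2f}"
        f" ({s['n_weak']} below 10)",
    ]
    if "total_r2" in s:
        lines.append(f"- total exposure variance explained: {s['total_r2']:.2%}")
    power = manifest.get("power")
    if power:
        lines += [
            "",
            "## Power",
            "",
            f"- binary-outcome power at OR {power['odds_ratio']:.3f}, "
            f"R² {power['r2_xz']:.2%}, n {power['n_total']:.0f} "
            f"(case fraction {power['prop_case']:.3f}): "
            f"{power['power']:.4f} ({power['power_percent']}%)",
        ]
    lines.append("")
    return "\n".join(lines)
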