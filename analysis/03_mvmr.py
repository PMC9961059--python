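"""Multivariable MR: direct effect of the primary exposure adjusting for
a correlated secondary exposure.

Simulates two exposures sharing genetic architecture (effect correlation
0.6) with direct effects (0.55, 0.20) on the outcome, then contrasts
univariable IVW on exposure 1 (biased by the shared pathway) with
MVMR-IVW (adjusted).  Writes results/mvmr/mvmr_estimates.tsv.
"""

from pathlib import Path

import pandas as pd

from tsmr.estimators import ivw
from tsmr.harmonize import harmonize_datasets
from tsmr.instruments import SelectionConfig, select_by_pvalue
from tsmr.mvmr import assemble_mvmr_input, mvmr_ivw
from tsmr.synthdata import MvmrSimulationConfig, simulate_mvmr

OUT = Path(__file__).resolve().parent.parent / "results" / "mvmr"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = MvmrSimulationConfig(
        seed=SEED, direct_effects=(0.55, 0.20), exposure_corr=0.6
    )
    exposures, outcome, ld, truth = simulate_mvmr(config)

    uni = ivw(harmonize_datasets(select_by_pvalue(exposures[0], 1e-5), outcome))
    inp = assemble_mvmr_input(exposures, outcome, ld, SelectionConfig())
    estimates = mvmr_ivw(inp)

    rows = [
        {
            "method": "univariable IVW (exposure_1)",
            "n_snp": uni.n_snp,
            "beta": uni.beta, "se": uni.se, "or": uni.or_,
            "ci_low": uni.ci_low, "ci_high": uni.ci_high, "pvalue": uni.pvalue,
        }
    ] + [
        {
            "method": e.method, "n_snp": e.n_snp, "beta": e.beta, "se": e.se,
            "or": e.or_, "ci_low": e.ci_low, "ci_high": e.ci_high,
            "pvalue": e.pvalue,
        }
        for e in estimates
    ]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "mvmr_estimates.tsv", sep="\t", index=False)

    print(f"true direct effects: {config.direct_effects}, "
          f"effect correlation {config.exposure_corr}")
    print(df.to_string(index=False))
    print(
        f"univariable IVW on exposure 1 is inflated by the shared pathway "
        f"({uni.beta:.3f} vs true 0.55); MVMR adjusts it to "
        f"{estimates[0].beta:.3f} while attributing {estimates[1].beta:.3f} "
        f"to exposure 2 (true 0.20)"
    )


if __name__ == "__main__":
    main()
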