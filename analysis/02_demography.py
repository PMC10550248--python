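#!/usr/bin/env python
"""Demographic structure: composition, sex-ratio test, age-range trimming.

Reads results/data/specimens.csv (run 01_simulate.py first), summarises
the two populations, tests the sex-ratio difference, computes the
minimum generations since the fence became an effective barrier (1975)
and applies the common-age-range trimming rule used by all
between-population analyses.
"""

import json
from pathlib import Path

from crossfence.core_io import read_specimens
from crossfence.demography import (
    demographic_summary,
    generations_since,
    sex_ratio_test,
    trim_to_common_age_range,
    with_ages,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = with_ages(read_specimens(ROOT / "data" / "specimens.csv").records)

    summary = demographic_summary(records)
    summary.to_csv(ROOT / "demography_summary.tsv", sep="\t")
    print(summary.round(3))

    counts = [
        [int(summary.loc[p, "n_female"]), int(summary.loc[p, "n_male"])]
        for p in ("dingoes_rare", "dingoes_common")
    ]
    chi2 = sex_ratio_test(counts, yates=True)
    print(f"\nsex ratio: chi2({chi2.df}) = {chi2.statistic:.2f}, P = {chi2.p:.4g} "
          f"(continuity-corrected; uncorrected "
          f"{sex_ratio_test(counts, yates=False).statistic:.2f})")

    gens = generations_since(1975, 2018, months_per_generation=30.0)
    print(f"minimum generations since effective barrier (30 mo/gen): {gens}")

    trim = trim_to_common_age_range(records)
    print(f"\ntrimming dingoes-rare to the dingoes-common age range "
          f"[{trim.reference_range_years[0]:.2f}, {trim.reference_range_years[1]:.2f}] y: "
          f"excluded {trim.excluded_below} below + {trim.excluded_above} above, "
          f"{len(trim.kept)} specimens kept")
    trim.kept.to_csv(ROOT / "specimens_trimmed.csv", index=False)

    with open(ROOT / "demography.json", "w") as fh:
        json.dump(
            {
                "sex_ratio": {"counts": counts, "chi2": chi2.statistic, "p": chi2.p},
                "generations_since_fence": gens,
                "trim": {
                    "reference_range_years": trim.reference_range_years,
                    "excluded_below": trim.excluded_below,
                    "excluded_above": trim.excluded_above,
                    "n_kept": len(trim.kept),
                },
            },
            fh,
            indent=2,
        )


if __name__ == "__main__":
    main()
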