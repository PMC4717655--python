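"""Draw the study cohort and write it in the standard exchange formats.

Writes PED/MAP and HAPS/SAMPLE files (to scratch/, they are inputs for
manual experimentation, not results) and a small per-variant summary —
allele frequencies by class — to results/01_cohort_summary.tsv.  The
causal SNP and the SNPs of the causal window should show visibly
enriched allele/haplotype frequencies in cases.
"""

import numpy as np
import pandas as pd

from common import CAUSAL_SNP, CAUSAL_WINDOW, RESULTS, SCRATCH, study_cohort
from polyrisk.io import write_haps_sample, write_ped_map

haps, genos, phen, truth = study_cohort()
variants = truth["variants"]

SCRATCH.mkdir(exist_ok=True)
RESULTS.mkdir(exist_ok=True)
cohort_dir = SCRATCH / "cohort"
cohort_dir.mkdir(exist_ok=True)
write_ped_map(genos, variants, phen, cohort_dir / "cohort.ped", cohort_dir / "cohort.map")
write_haps_sample(haps, variants, phen,
                  cohort_dir / "cohort.haps", cohort_dir / "cohort.sample")

is_case = phen.status == 1
rows = []
for j in range(genos.n_variants):
    rows.append(
        {
            "snp": variants.ids[j],
            "freq_cases": genos.values[is_case, j].mean() / 2,
            "freq_controls": genos.values[~is_case, j].mean() / 2,
            "causal": "snp" if j == CAUSAL_SNP else (
                "window" if CAUSAL_WINDOW[0] <= j < CAUSAL_WINDOW[0] + CAUSAL_WINDOW[1]
                else ""
            ),
        }
    )
summary = pd.DataFrame(rows)
summary.to_csv(RESULTS / "01_cohort_summary.tsv", sep="\t", index=False,
               float_format="%.4f")

d = summary["freq_cases"] - summary["freq_controls"]
print(f"cohort: {phen.n_cases} cases / {phen.n_controls} controls, "
      f"{genos.n_variants} SNPs; files under {cohort_dir}")
print(f"causal SNP case-control allele-frequency gap: {d[CAUSAL_SNP]:+.3f} "
      f"(null median |gap| {np.median(np.abs(d.drop(CAUSAL_SNP))):.3f})")
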