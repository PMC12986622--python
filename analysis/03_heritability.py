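"""Genomic heritability of the seven lodging-related traits.

Builds the VanRaden genomic relationship matrix from the QC'd panel and
estimates variance components by AI-REML for every trait in each season,
using the accessions phenotyped in that season. Compares the estimates
with the simulation's realized heritabilities.

Writes results/heritability.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ricegs import compute_grm, read_dosage_tsv, reml_fit
from ricegs.sim import read_phenotype_tsv

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main():
    G = read_dosage_tsv(SCRATCH / "panel_qc_dosages.tsv")
    pheno = read_phenotype_tsv(SCRATCH / "synthetic" / "phenotypes.tsv")
    membership = json.loads((SCRATCH / "synthetic" / "membership.json")
                            .read_text())
    truth = json.loads((SCRATCH / "synthetic" / "truth.json").read_text())

    grm = compute_grm(G)
    print(f"GRM over {len(grm.sample_ids)} accessions "
          f"({grm.n_snps_used} polymorphic SNPs)")

    rows = []
    for (trait, season), sub in pheno.groupby(["trait", "season"]):
        ids = [s for s in membership[season]]
        y = sub.set_index("accession")["value"].loc[ids].to_numpy()
        vc = reml_fit(y, grm.subset(ids))
        realized = truth[f"{trait}/{season}"]["realized_h2"]
        rows.append({"trait": trait, "season": season,
                     "h2_estimate": round(vc.h2, 4),
                     "h2_realized": round(realized, 4),
                     "sigma_g2": round(vc.sigma_g2, 4),
                     "sigma_e2": round(vc.sigma_e2, 4),
                     "converged": vc.converged,
                     "n": len(y)})
    out = pd.DataFrame(rows).sort_values(["trait", "season"])
    out.to_csv(RESULTS / "heritability.tsv", sep="\t", index=False)
    err = np.abs(out["h2_estimate"] - out["h2_realized"])
    print(out.to_string(index=False))
    print(f"mean |h2_estimate - h2_realized| = {err.mean():.3f} "
          f"(max {err.max():.3f})")


if __name__ == "__main__":
    main()
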