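"""Independent validation: train on the 217-accession core set of each
season and predict the accessions unique to that season (98 early-season,
123 late-season), mirroring the generalization test of the study design.

Writes results/independent_validation.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from ricegs import independent_validation, read_dosage_tsv
from ricegs.sim import read_phenotype_tsv

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main():
    G = read_dosage_tsv(SCRATCH / "panel_qc_dosages.tsv")
    pheno = read_phenotype_tsv(SCRATCH / "synthetic" / "phenotypes.tsv")
    membership = json.loads((SCRATCH / "synthetic" / "membership.json")
                            .read_text())
    core = set(membership["core"])

    rows = []
    for (trait, season), sub in pheno.groupby(["trait", "season"]):
        by_id = sub.set_index("accession")["value"]
        train_ids = sorted(core)
        test_ids = [s for s in membership[season] if s not in core]
        r, _ = independent_validation(
            G.subset_samples(train_ids), by_id.loc[train_ids].to_numpy(),
            G.subset_samples(test_ids), by_id.loc[test_ids].to_numpy(),
            "gblup", trait=trait, season=season)
        rows.append({"trait": trait, "season": season, "model": "gblup",
                     "r": round(r, 4), "n_train": len(train_ids),
                     "n_test": len(test_ids)})
        print(f"{trait:7s} {season}: r = {r:.3f} "
              f"(train {len(train_ids)}, test {len(test_ids)})")
    pd.DataFrame(rows).to_csv(RESULTS / "independent_validation.tsv",
                              sep="\t", index=False)


if __name__ == "__main__":
    main()
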