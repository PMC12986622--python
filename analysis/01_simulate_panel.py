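"""Simulate the study population: a 438-accession rice diversity panel
genotyped at 2,000 SNPs, seven lodging-related traits expressed in two
seasons, a core set phenotyped in both seasons plus season-unique
accessions, and a 2,000-candidate germplasm bank with ordinal lodging
scores.

Writes genotypes (VCF + dosage TSV), phenotypes (tidy TSV), season
memberships, the candidate score table and the simulation ground truth
under scratch/synthetic/ (bulky, regenerated on demand).
"""

import json
from pathlib import Path

from ricegs import (SimulationConfig, simulate_candidate_population,
                    simulate_genotypes, simulate_membership,
                    simulate_phenotypes, write_dosage_tsv, write_vcf)
from ricegs.sim import default_trait_panel, write_phenotype_tsv

OUT = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"
MASTER_SEED = 20240901

config = SimulationConfig(
    n_accessions=438, n_snps=2000, n_founder_haplotypes=16,
    maf_min=0.05, recomb_rate=0.02, traits=default_trait_panel(),
    season_genetic_correlation=0.7, seed=MASTER_SEED)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    G = simulate_genotypes(config)
    print(f"panel: {G.n_samples} accessions x {G.n_variants} SNPs, "
          f"min MAF {G.maf().min():.3f}")
    write_vcf(G, OUT / "panel.vcf")
    write_dosage_tsv(G, OUT / "panel_dosages.tsv")

    table, truth = simulate_phenotypes(G, config)
    write_phenotype_tsv(table, OUT / "phenotypes.tsv")
    truth.to_json(OUT / "truth.json")
    realized = {f"{t}/{s}": round(truth.realized_h2(t, s), 4)
                for (t, s) in truth.per_trait}
    print("realized h2 per trait/season:", realized)

    early, late = simulate_membership(G.sample_ids, n_core=217,
                                      n_unique_a=98, n_unique_b=123,
                                      seed=MASTER_SEED + 1)
    core = sorted(set(early) & set(late))
    print(f"membership: |ES|={len(early)} |LS|={len(late)} core={len(core)}")
    with open(OUT / "membership.json", "w") as fh:
        json.dump({"ES": early, "LS": late, "core": core}, fh)

    G_cand, scores = simulate_candidate_population(
        config, config.trait("BR3"), n_candidates=2000, score_noise_sd=0.5,
        seed=MASTER_SEED + 2)
    write_dosage_tsv(G_cand, OUT / "candidates_dosages.tsv")
    scores.to_csv(OUT / "candidate_scores.tsv", sep="\t", index=False)
    print(f"candidates: {G_cand.n_samples} with scores "
          f"{scores['score'].min()}..{scores['score'].max()} "
          f"(bin rule {scores.attrs['bin_rule']})")


if __name__ == "__main__":
    main()
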