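"""Synthetic genotype-phenotype simulator for the genomic-selection pipeline.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without any external download: a diversity panel
of a few hundred accessions × a few thousand biallelic SNPs with blockwise
LD (founder-haplotype mosaic), seven quantitative traits expressed in two
genetically correlated growing seasons with per-trait target heritabilities,
partially overlapping season membership (a core set plus season-unique
accessions), and a large candidate population whose 9-level ordinal lodging
score is driven by latent breeding values.

The LD model is a copying process: each accession carries two haplotypes,
each a mosaic of a small founder pool with a per-SNP probability of
switching to a uniformly redrawn founder. Neighbouring SNPs are therefore
usually copied from the same founder, which induces local correlation that
decays with distance and weakens as the switch rate grows. Genetic values
are strictly additive; noise is Gaussian and independent across traits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ricegs.genio import GenotypeMatrix, VARIANT_COLUMNS

__all__ = ["TraitSpec", "SimulationConfig", "TraitTruth", "TruthRecord",
           "GenerationError", "simulate_genotypes", "simulate_phenotypes",
           "simulate_membership", "simulate_candidate_population",
           "write_phenotype_tsv", "read_phenotype_tsv", "SEASONS"]

SEASONS = ("ES", "LS")  # early and late growing season

# fixed stage offsets deriving stream seeds from the master seed
_OFF_GENOTYPES = 104729
_OFF_TRAIT = 224737
_OFF_NOISE = 350377
_OFF_CANDIDATE = 479909
_MOD = 2 ** 31

# default liability loadings of the ordinal lodging score: weaker culms
# lodge more (negative on strength), taller plants lodge more (positive)
DEFAULT_STRENGTH_LOADING = -1.0
DEFAULT_HEIGHT_LOADING = 0.5

# cumulative shares of the nine ordinal levels on the standardized liability,
# chosen so the four resistance categories (levels <=2 / 3-4 / 5-6 / >=7)
# have roughly the 31/42/14/12% base mix seen in large rice diversity panels
_LEVEL_CUMPROBS = (0.157, 0.314, 0.526, 0.738, 0.8065, 0.875, 0.9165, 0.958)


class GenerationError(RuntimeError):
    """A simulation draw failed its constraints after bounded retries."""


@dataclass
class TraitSpec:
    """One quantitative trait: its target genomic heritability and genetic
    architecture (number of additive QTL), plus which direction of the
    breeding value is favourable for lodging resistance (e.g. lower
    internode length, higher bending resistance)."""

    name: str
    target_h2: float
    n_qtl: int
    direction_favorable: str = "higher"

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError(f"target_h2 must be in [0, 1], got {self.target_h2}")
        if self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1")
        if self.direction_favorable not in ("lower", "higher"):
            raise ValueError("direction_favorable must be 'lower' or 'higher'")


@dataclass
class SimulationConfig:
    n_accessions: int = 438
    n_snps: int = 3000
    n_founder_haplotypes: int = 16
    maf_min: float = 0.05
    recomb_rate: float = 0.02
    traits: list[TraitSpec] = field(default_factory=list)
    season_genetic_correlation: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")
        if not 0.0 < self.maf_min <= 0.5:
            raise ValueError("maf_min must be in (0, 0.5]")
        if not 0.0 <= self.recomb_rate <= 1.0:
            raise ValueError("recomb_rate must be in [0, 1]")
        if not -1.0 <= self.season_genetic_correlation <= 1.0:
            raise ValueError("season_genetic_correlation must be in [-1, 1]")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("trait names must be unique")
        for t in self.traits:
            if t.n_qtl > self.n_snps:
                raise ValueError(f"trait {t.name}: n_qtl exceeds n_snps")

    def trait(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(f"trait {name!r} not in config")


def default_trait_panel() -> list[TraitSpec]:
    """The seven lodging-related traits with heritability targets spanning
    the range observed in rice diversity panels (~0.23–0.77)."""
    return [
        TraitSpec("IL3", 0.5054, 300, "lower"),
        TraitSpec("BR3", 0.3477, 300, "higher"),
        TraitSpec("IL4", 0.6257, 300, "lower"),
        TraitSpec("BR4", 0.2297, 300, "higher"),
        TraitSpec("IL3_PH", 0.2462, 300, "lower"),
        TraitSpec("IL4_PH", 0.3724, 300, "lower"),
        TraitSpec("PH", 0.7687, 300, "lower"),
    ]


@dataclass
class TraitTruth:
    """Ground truth for one trait in one season."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: pd.Series  # indexed by accession
    realized_h2: float

    def __post_init__(self) -> None:
        if len(self.qtl_indices) != len(self.qtl_effects):
            raise ValueError("qtl_indices and qtl_effects lengths differ")
        if not 0.0 <= self.realized_h2 <= 1.0:
            raise ValueError("realized_h2 outside [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth for every (trait, season) pair of one simulation."""

    per_trait: dict[tuple[str, str], TraitTruth] = field(default_factory=dict)

    def breeding_values(self, trait: str, season: str) -> pd.Series:
        return self.per_trait[(trait, season)].true_breeding_values

    def realized_h2(self, trait: str, season: str) -> float:
        return self.per_trait[(trait, season)].realized_h2

    def to_json(self, path=None) -> str:
        out = {}
        for (trait, season), tt in self.per_trait.items():
            out[f"{trait}/{season}"] = {
                "qtl_indices": tt.qtl_indices.tolist(),
                "qtl_effects": tt.qtl_effects.tolist(),
                "true_breeding_values": tt.true_breeding_values.to_dict(),
                "realized_h2": tt.realized_h2,
            }
        text = json.dumps(out)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


# ---------------------------------------------------------------------------
# genotypes


def _mosaic_haplotypes(rng: np.random.Generator, founders: np.ndarray,
                       n_haplotypes: int, recomb_rate: float) -> np.ndarray:
    """Copy haplotypes from a founder pool with per-SNP switch probability.

    Each switch redraws the donor uniformly over all founders (so the
    chance of changing donor is recomb_rate × (K−1)/K). recomb_rate = 0
    yields unbroken founder copies.
    """
    n_founders, m = founders.shape
    donors = rng.integers(n_founders, size=(n_haplotypes, m))
    switch = rng.random((n_haplotypes, m)) < recomb_rate
    switch[:, 0] = True
    last = np.maximum.accumulate(
        np.where(switch, np.arange(m)[None, :], -1), axis=1)
    path = donors[np.arange(n_haplotypes)[:, None], last]
    return founders[path, np.arange(m)[None, :]]


def _simulate_panel(config: SimulationConfig, n_samples: int, id_prefix: str,
                    rng: np.random.Generator, founders: np.ndarray,
                    enforce_maf: bool, max_rounds: int = 100):
    """Draw a sample panel from a founder pool; optionally enforce MAF by
    redrawing founder alleles at failing SNPs (panel and founders co-evolve)."""
    m = config.n_snps
    hap = _mosaic_haplotypes(rng, founders, 2 * n_samples,
                             config.recomb_rate)
    dosages = (hap[0::2].astype(float) + hap[1::2].astype(float))
    if enforce_maf:
        for _ in range(max_rounds):
            p = dosages.mean(axis=0) / 2.0
            bad = np.flatnonzero(np.minimum(p, 1 - p) < config.maf_min)
            if bad.size == 0:
                break
            pnew = rng.uniform(config.maf_min, 1 - config.maf_min, bad.size)
            founders[:, bad] = rng.random((founders.shape[0], bad.size)) < pnew
            # re-copy the failing columns through fresh mosaics
            hap_bad = _mosaic_haplotypes(rng, founders[:, bad],
                                         2 * n_samples, config.recomb_rate)
            dosages[:, bad] = (hap_bad[0::2].astype(float)
                               + hap_bad[1::2].astype(float))
        else:
            raise GenerationError(
                f"could not reach maf_min={config.maf_min} at every SNP "
                f"after {max_rounds} resampling rounds")
    ids = [f"{id_prefix}{i + 1:04d}" for i in range(n_samples)]
    variants = pd.DataFrame({
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 100,
        "id": [f"snp{j + 1}" for j in range(m)],
        "ref": "A",
        "alt": "C",
    })[VARIANT_COLUMNS]
    return GenotypeMatrix(ids, variants, dosages), founders


def _founder_pool(config: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    p = rng.uniform(config.maf_min, 1 - config.maf_min, config.n_snps)
    return rng.random((config.n_founder_haplotypes, config.n_snps)) < p


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate the accession panel: {0,1,2} dosages, no missing calls,
    every SNP at minor allele frequency >= ``config.maf_min``, blockwise LD
    from the founder-mosaic process. Deterministic given ``config.seed``."""
    G, _ = _panel_and_founders(config)
    return G


def _panel_and_founders(config: SimulationConfig):
    rng = np.random.default_rng((config.seed + _OFF_GENOTYPES) % _MOD)
    founders = _founder_pool(config, rng)
    return _simulate_panel(config, config.n_accessions, "acc", rng, founders,
                           enforce_maf=True)


# ---------------------------------------------------------------------------
# phenotypes


def _trait_rng(config: SimulationConfig, trait_name: str) -> np.random.Generator:
    """Per-trait effect stream, shared between the accession panel's
    phenotypes and the candidate population's breeding values."""
    names = [t.name for t in config.traits]
    i = names.index(trait_name)
    return np.random.default_rng((config.seed + _OFF_TRAIT + 7919 * i) % _MOD)


def _draw_trait_effects(config: SimulationConfig, trait: TraitSpec):
    """QTL positions and per-season effect vectors with the configured
    genetic correlation imposed in effect space (exact at rho = ±1)."""
    rng = _trait_rng(config, trait.name)
    qtl = np.sort(rng.choice(config.n_snps, size=trait.n_qtl, replace=False))
    b_es = rng.normal(size=trait.n_qtl)
    b_ind = rng.normal(size=trait.n_qtl)
    rho = config.season_genetic_correlation
    b_ls = rho * b_es + np.sqrt(max(0.0, 1.0 - rho ** 2)) * b_ind
    return qtl, {"ES": b_es, "LS": b_ls}


def _breeding_values(G: GenotypeMatrix, qtl: np.ndarray,
                     effects: np.ndarray) -> np.ndarray:
    Z = G.dosages[:, qtl]
    Zc = Z - Z.mean(axis=0)
    return Zc @ effects


def simulate_phenotypes(G: GenotypeMatrix, config: SimulationConfig
                        ) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate every configured trait in both seasons over the panel.

    For each (trait, season): genetic values u = Z·effects over the sampled
    QTL, plus Gaussian noise residualized against u and scaled so that
    var(u)/var(y) equals the target heritability exactly on the realized
    sample (target 1 means no noise; target 0 means pure noise). Returns a
    tidy table with columns ``accession, season, trait, value`` and the
    :class:`TruthRecord` (QTL, effects, per-season breeding values,
    realized h²). Deterministic given ``config.seed``.
    """
    if not config.traits:
        raise ValueError("config.traits is empty")
    rows = []
    truth = TruthRecord()
    for ti, trait in enumerate(config.traits):
        qtl, per_season = _draw_trait_effects(config, trait)
        for si, season in enumerate(SEASONS):
            rng = np.random.default_rng(
                (config.seed + _OFF_NOISE + 7919 * ti + si) % _MOD)
            u = None
            for _ in range(20):
                u = _breeding_values(G, qtl, per_season[season])
                if np.var(u) > 0:
                    break
                # degenerate draw (all QTL monomorphic): redraw effects
                per_season[season] = rng.normal(size=trait.n_qtl)
            else:
                raise GenerationError(
                    f"var(u)=0 for trait {trait.name}/{season} after retries")
            h2 = trait.target_h2
            if h2 >= 1.0:
                y = u.copy()
                realized = 1.0
            elif h2 <= 0.0:
                e = rng.normal(size=len(u))
                y = e - e.mean()
                realized = 0.0
            else:
                e = rng.normal(size=len(u))
                e = e - e.mean()
                uc = u - u.mean()
                e = e - (e @ uc) / (uc @ uc) * uc  # exact orthogonality
                e *= np.sqrt(np.var(uc) * (1 - h2) / h2 / np.var(e))
                y = u + e
                realized = float(np.var(uc) / np.var(y - y.mean()))
            truth.per_trait[(trait.name, season)] = TraitTruth(
                qtl_indices=qtl,
                qtl_effects=per_season[season].copy(),
                true_breeding_values=pd.Series(u, index=G.sample_ids),
                realized_h2=realized)
            rows.extend(zip(G.sample_ids, [season] * len(y),
                            [trait.name] * len(y), y))
    table = pd.DataFrame(rows, columns=["accession", "season", "trait",
                                        "value"])
    return table, truth


def simulate_membership(ids: list[str], n_core: int, n_unique_a: int,
                        n_unique_b: int, seed: int
                        ) -> tuple[list[str], list[str]]:
    """Split accessions into two season memberships sharing a core set.

    Season A gets ``n_core + n_unique_a`` members, season B gets
    ``n_core + n_unique_b``; the intersection is exactly the core set.
    """
    need = n_core + n_unique_a + n_unique_b
    if need > len(ids):
        raise ValueError(f"need {need} ids, only {len(ids)} available")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    core = perm[:n_core]
    uniq_a = perm[n_core:n_core + n_unique_a]
    uniq_b = perm[n_core + n_unique_a:need]
    return core + uniq_a, core + uniq_b


# ---------------------------------------------------------------------------
# candidate population and ordinal lodging score


def _discretize_liability(liab: np.ndarray, bin_rule: str) -> np.ndarray:
    sd = liab.std()
    z = (liab - liab.mean()) / sd if sd > 0 else liab - liab.mean()
    if bin_rule == "fixed_cuts":
        cuts = stats.norm.ppf(_LEVEL_CUMPROBS)
    elif bin_rule == "equal_frequency":
        cuts = np.quantile(z, np.arange(1, 9) / 9.0)
    else:
        raise ValueError(f"unknown bin rule {bin_rule!r}")
    return (np.searchsorted(cuts, z, side="left") + 1).astype(int)


def simulate_candidate_population(config: SimulationConfig, trait: TraitSpec,
                                  n_candidates: int, score_noise_sd: float,
                                  seed: int, bin_rule: str = "fixed_cuts",
                                  strength_loading: float = DEFAULT_STRENGTH_LOADING,
                                  height_loading: float = DEFAULT_HEIGHT_LOADING,
                                  height_trait: str = "PH",
                                  ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a germplasm-bank candidate population with ordinal scores.

    Candidates are drawn from the same founder-haplotype pool as the
    accession panel of ``config`` (so marker effects transfer). ``trait``
    names the culm-strength trait; its early-season effect vector, re-derived
    deterministically from the config, gives each candidate a strength
    breeding value (and likewise for the height trait when present). The
    latent lodging liability loads negatively on strength and positively on
    height, gets N(0, score_noise_sd²) noise, and is discretized into the
    nine ordinal levels (1 = no lodging … 9 = all plants lodged flat) by
    ``bin_rule``: fixed Gaussian cut points (default) or equal-frequency
    bins. The returned score table records the rule in ``.attrs['bin_rule']``
    together with the latent truth columns for validation.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    config.trait(trait.name)  # must be present
    _, founders = _panel_and_founders(config)
    rng = np.random.default_rng((seed + _OFF_CANDIDATE) % _MOD)
    G_cand, _ = _simulate_panel(config, n_candidates, "cand", rng,
                                founders.copy(), enforce_maf=False)

    qtl_s, eff_s = _draw_trait_effects(config, config.trait(trait.name))
    bv_strength = _breeding_values(G_cand, qtl_s, eff_s["ES"])
    has_height = any(t.name == height_trait for t in config.traits) \
        and height_trait != trait.name
    if has_height:
        qtl_h, eff_h = _draw_trait_effects(config, config.trait(height_trait))
        bv_height = _breeding_values(G_cand, qtl_h, eff_h["ES"])
    else:
        bv_height = np.zeros(n_candidates)

    def z(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else v - v.mean()

    liab = strength_loading * z(bv_strength)
    if has_height:
        liab = liab + height_loading * z(bv_height)
    liab = liab + rng.normal(scale=score_noise_sd, size=n_candidates) \
        if score_noise_sd > 0 else liab
    scores = _discretize_liability(liab, bin_rule)
    table = pd.DataFrame({
        "accession": G_cand.sample_ids,
        "score": scores,
        "liability": liab,
        "bv_strength": bv_strength,
        "bv_height": bv_height,
    })
    table.attrs["bin_rule"] = bin_rule
    return G_cand, table


# ---------------------------------------------------------------------------
# plain-text round trips


def write_phenotype_tsv(table: pd.DataFrame, path: str) -> None:
    table[["accession", "season", "trait", "value"]].to_csv(
        path, sep="\t", index=False)


def read_phenotype_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"accession": str, "season": str, "trait": str})
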