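"""End-to-end benchmark computations exercising the whole pipeline.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage(s) at a fixed desk-scale problem size, and returns the measured
quantity. They back both the reproducibility script and the acceptance test
suite, so every number they report is recomputed from scratch on each call.

Independent slow-path references (a dense REML likelihood maximized
numerically, an exhaustive LD-pruning re-scan) live here as validation
oracles; the pipeline never calls them for its own results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ricegs.evaluate import CvScheme, repeated_kfold_cv
from ricegs.genio import GenotypeMatrix, ld_prune
from ricegs.kinship import compute_grm, reml_fit
from ricegs.models import McmcConfig, fit_bayes_lasso, fit_gblup, predict_gebv
from ricegs.reference import SEASONAL_TRAIT_MEANS, percent_change
from ricegs.screen import enrichment_report, rank_and_select
from ricegs.sim import (SimulationConfig, TraitSpec, simulate_candidate_population,
                        simulate_genotypes, simulate_membership,
                        simulate_phenotypes)

_MOD = 2 ** 31


def _seed(base: int, offset: int) -> int:
    return (base + offset) % _MOD


def _single_trait_panel(n, m, h2, n_qtl, seed, **kw):
    cfg = SimulationConfig(n_accessions=n, n_snps=m,
                           traits=[TraitSpec("T", h2, n_qtl)], seed=seed,
                           **kw)
    G = simulate_genotypes(cfg)
    table, truth = simulate_phenotypes(G, cfg)
    y = (table.query("season == 'ES'").set_index("accession")["value"]
         .loc[G.sample_ids].to_numpy())
    return cfg, G, y, truth


# ---------------------------------------------------------------------------
# sampler and CV bookkeeping


def mcmc_retention(seed: int) -> dict:
    """Run the Bayesian LASSO under the standard 15,000/5,000/5 schedule
    on a small simulated panel and count the retained posterior draws."""
    _, G, y, _ = _single_trait_panel(60, 30, 0.6, 10, _seed(seed, 11))
    cfg = McmcConfig(seed=_seed(seed, 12))  # default full schedule
    fit = fit_bayes_lasso(G, y, cfg)
    return {"n_retained": fit.posterior["n_retained"], "n": G.n_samples,
            "schedule": (cfg.n_iter, cfg.burn_in, cfg.thin)}


def cv_bookkeeping(seed: int, n: int = 300, m: int = 2000) -> dict:
    """5-fold x 20-repeat GBLUP cross-validation on a simulated panel;
    reports the number of fold-level accuracies and their mean."""
    _, G, y, _ = _single_trait_panel(n, m, 0.5, 300, _seed(seed, 21))
    res = repeated_kfold_cv(G, y, "gblup",
                            CvScheme(k=5, n_repeats=20, seed=_seed(seed, 22)))
    return {"n_folds": len(res.per_fold_r), "mean_r": res.mean_r,
            "sd_r": res.sd_r, "n": n}


# ---------------------------------------------------------------------------
# reported-table derived statistics


def seasonal_mean_changes() -> dict:
    """Percent change of the bending-resistance means from the early to the
    late season, recomputed from the reported core-set trait means."""
    out = {}
    for trait in ("BR3", "BR4"):
        es, ls = SEASONAL_TRAIT_MEANS[trait]
        out[trait] = percent_change(es, ls)
    return out


def membership_sizes(seed: int) -> dict:
    """Reconstruct the core/season-unique membership structure: 217 core
    accessions of a 438-accession panel, season totals 315 and 340."""
    ids = [f"acc{i:04d}" for i in range(438)]
    core, total_a, total_b = 217, 315, 340
    a, b = simulate_membership(ids, core, total_a - core, total_b - core,
                               _seed(seed, 31))
    inter = set(a) & set(b)
    return {"early_total": len(a), "late_total": len(b),
            "core": len(inter),
            "early_unique": len(a) - len(inter),
            "late_unique": len(b) - len(inter), "n": len(ids)}


# ---------------------------------------------------------------------------
# oracle equivalences


def gblup_duality_gap(seed: int, n: int = 50, m: int = 200) -> dict:
    """Max |difference| between marker-space ridge predictions and the
    kinship-space BLUP identity, on held-out samples."""
    _, G, y, _ = _single_trait_panel(n + 20, m, 0.6, 50, _seed(seed, 41))
    train, test = np.arange(n), np.arange(n, n + 20)
    G_train, G_test = G.take_samples(train), G.take_samples(test)
    fit = fit_gblup(G_train, y[train])
    marker_pred = predict_gebv(fit, G_test).gebv

    Xc_tr = G_train.dosages - G_train.dosages.mean(0)
    Xc_te = G_test.dosages - G_train.dosages.mean(0)
    p = G_train.dosages.mean(0) / 2
    c = 2 * np.sum(p * (1 - p))
    vc = fit.variance_components
    lam = vc.sigma_e2 / vc.sigma_g2
    K_tr = Xc_tr @ Xc_tr.T / c
    K_te = Xc_te @ Xc_tr.T / c
    kin_pred = y[train].mean() + K_te @ np.linalg.solve(
        K_tr + lam * np.eye(n), y[train] - y[train].mean())
    scale = max(1.0, float(np.abs(kin_pred).max()))
    return {"max_abs_gap": float(np.abs(marker_pred - kin_pred).max() / scale),
            "n": n}


def dense_reml_loglik(y, K, sg2, se2) -> float:
    """Dense-matrix REML log-likelihood — the slow oracle path."""
    n = len(y)
    V = sg2 * K + se2 * np.eye(n)
    X = np.ones((n, 1))
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    beta = np.linalg.solve(XVX, X.T @ Vi @ y)
    r = y - X @ beta
    return float(-0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1]
                         + r @ Vi @ r))


def aireml_oracle_gap(seed: int, n: int = 30) -> dict:
    """|h2| difference between the AI-REML fit and a grid search plus
    Nelder-Mead refinement of the dense REML likelihood."""
    cfg = SimulationConfig(n_accessions=n, n_snps=150,
                           n_founder_haplotypes=4, recomb_rate=0.05,
                           seed=_seed(seed, 51))
    grm = compute_grm(simulate_genotypes(cfg))
    rng = np.random.default_rng(_seed(seed, 52))
    L = np.linalg.cholesky(grm.values + 1e-6 * np.eye(n))
    u = L @ rng.normal(size=n)
    y = u + rng.normal(scale=0.6 * np.sqrt(np.var(u)), size=n)

    vc = reml_fit(y, grm)
    vary = np.var(y, ddof=1)
    grid = np.linspace(0.02, 2.5, 50) * vary
    lls = np.array([[dense_reml_loglik(y, grm.values, a, b) for b in grid]
                    for a in grid])
    i, j = np.unravel_index(np.argmax(lls), lls.shape)
    res = minimize(lambda t: -dense_reml_loglik(y, grm.values, np.exp(t[0]),
                                                np.exp(t[1])),
                   x0=np.log([grid[i], grid[j]]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    sg, se = np.exp(res.x)
    return {"h2_gap": abs(vc.h2 - sg / (sg + se)), "h2": vc.h2, "n": n}


def _exhaustive_ld_prune(G: GenotypeMatrix, window: int, step: int,
                         thr: float) -> list[int]:
    """Reference pruner: rescan every window placement until no surviving
    pair violates the threshold, same removal rule as the fast path."""
    removed: set[int] = set()
    maf = G.maf()
    pos = G.variants["pos"].to_numpy()
    chrom = G.variants["chrom"].to_numpy()

    def r2(a, b):
        x, yv = G.dosages[:, a], G.dosages[:, b]
        if np.var(x) == 0 or np.var(yv) == 0:
            return 0.0
        return float(np.corrcoef(x, yv)[0, 1] ** 2)

    changed = True
    while changed:
        changed = False
        for c in pd.unique(chrom):
            idx = [int(i) for i in np.flatnonzero(chrom == c)]
            for start in range(0, len(idx), step):
                active = [i for i in idx[start:start + window]
                          if i not in removed]
                best, best_r2 = None, thr
                for ii in range(len(active)):
                    for jj in range(ii + 1, len(active)):
                        v = r2(active[ii], active[jj])
                        if v > best_r2:
                            best, best_r2 = (active[ii], active[jj]), v
                if best is not None:
                    a, b = best
                    removed.add(a if (maf[a], -pos[a]) < (maf[b], -pos[b])
                                else b)
                    changed = True
                    break
            if changed:
                break
    return [i for i in range(G.n_variants) if i not in removed]


def ld_prune_oracle_mismatches(seed: int, n_snps: int = 200) -> dict:
    """Symmetric difference between the windowed pruner's kept set and the
    exhaustive re-scan reference on a simulated chromosome."""
    cfg = SimulationConfig(n_accessions=80, n_snps=n_snps,
                           n_founder_haplotypes=6, recomb_rate=0.02,
                           seed=_seed(seed, 61))
    G = simulate_genotypes(cfg)
    kept, _ = ld_prune(G, window_snps=10, step_snps=5, r2_threshold=0.5)
    ref = _exhaustive_ld_prune(G, 10, 5, 0.5)
    return {"mismatches": len(set(kept.tolist()) ^ set(ref)),
            "n_kept": len(kept), "n": n_snps}


# ---------------------------------------------------------------------------
# parameter recovery and accuracy-heritability coupling


def h2_recovery(seed: int, h2_targets=(0.2297, 0.5054, 0.7687),
                n: int = 500, m: int = 2000, n_seeds: int = 10) -> dict:
    """Mean absolute error of REML heritability estimates at simulation
    truths spanning the published heritability range."""
    out = {}
    for h2 in h2_targets:
        errs = []
        for s in range(n_seeds):
            _, G, y, _ = _single_trait_panel(
                n, m, h2, 300, _seed(seed, 71 + 137 * s + int(h2 * 1000)))
            vc = reml_fit(y, compute_grm(G))
            errs.append(abs(vc.h2 - h2))
        out[h2] = float(np.mean(errs))
    return {"mae": out, "n": n, "n_seeds": n_seeds}


def cv_accuracy_by_h2(seed: int, h2_levels=(0.2, 0.5, 0.8), n: int = 400,
                      m: int = 2000, n_seeds: int = 5) -> dict:
    """Mean 5-fold GBLUP cross-validation accuracy at increasing simulated
    heritability (one repeat per seed, averaged over seeds)."""
    means = {}
    for h2 in h2_levels:
        vals = []
        for s in range(n_seeds):
            sub_seed = _seed(seed, 81 + 251 * s + int(h2 * 1000))
            _, G, y, _ = _single_trait_panel(n, m, h2, 300, sub_seed)
            res = repeated_kfold_cv(G, y, "gblup",
                                    CvScheme(k=5, n_repeats=1, seed=sub_seed))
            vals.append(res.mean_r)
        means[h2] = float(np.mean(vals))
    ordered = [means[h] for h in h2_levels]
    return {"mean_r": means, "monotone": all(a < b for a, b in
                                             zip(ordered, ordered[1:])),
            "n": n, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# germplasm screening


def enrichment_direction(seed: int, n_seeds: int = 5, n_panel: int = 300,
                         m: int = 1500, n_candidates: int = 2000,
                         top_n: int = 200) -> dict:
    """Screen synthetic candidate populations by culm-strength GEBV and
    check that the resistant (HLR+MLR) share rises above the base share."""
    successes = 0
    base_frac = sel_frac = None
    for s in range(n_seeds):
        sub_seed = _seed(seed, 91 + 409 * s)
        cfg = SimulationConfig(
            n_accessions=n_panel, n_snps=m,
            traits=[TraitSpec("BR3", 0.45, 300, "higher"),
                    TraitSpec("PH", 0.77, 300, "lower")],
            seed=sub_seed)
        G = simulate_genotypes(cfg)
        table, _ = simulate_phenotypes(G, cfg)
        y = (table.query("trait == 'BR3' and season == 'ES'")
             .set_index("accession")["value"].loc[G.sample_ids].to_numpy())
        G_cand, scores = simulate_candidate_population(
            cfg, cfg.trait("BR3"), n_candidates, score_noise_sd=0.5,
            seed=sub_seed)
        fit = fit_gblup(G, y)
        pred = predict_gebv(fit, G_cand, trait="BR3")
        selected = rank_and_select(pred, "higher", top_n)
        rep = enrichment_report(scores, selected, trait="BR3",
                                direction="higher")
        if rep.selected_resistant_fraction > rep.base_resistant_fraction:
            successes += 1
        if s == 0:
            base_frac = rep.base_resistant_fraction
            sel_frac = rep.selected_resistant_fraction
    return {"successes": successes, "n_seeds": n_seeds,
            "base_resistant_fraction": base_frac,
            "selected_resistant_fraction": sel_frac, "n": n_candidates}
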