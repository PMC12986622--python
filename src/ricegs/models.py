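"""Whole-genome regression models producing genomic estimated breeding values.

All models share the additive marker model ``y = mu + X g + e`` with X the
{0,1,2} dosage matrix column-centered on training means:

* **GBLUP** — marker effects i.i.d. normal. The default fit is the exact
  ridge solution with the shrinkage parameter taken from an AI-REML fit of
  the marker-based kinship (deterministic); an MCMC mode runs a Gibbs
  sampler over the same model for posterior summaries.
* **Bayesian LASSO** — double-exponential (Laplace) prior on marker
  effects, fit by the Park–Casella normal scale-mixture Gibbs sampler with
  a Gamma hyperprior on the regularization parameter lambda².
* **PC regressor** — principal-component features of the dosage matrix
  (training statistics only) feeding a pluggable fit/predict backend, e.g.
  gradient boosting; the backend itself is outside the correctness surface.

Prediction for new genotypes applies the stored training column means and
marker effects (or the stored PCA projection and backend).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ricegs.genio import GenotypeMatrix
from ricegs.kinship import VarianceComponents, compute_grm, reml_fit

__all__ = ["ModelFit", "McmcConfig", "PredictionResult", "PcProjection",
           "fit_gblup", "fit_bayes_lasso", "pc_features", "fit_pc_regressor",
           "predict_gebv", "register_backend"]


@dataclass
class McmcConfig:
    """Gibbs-sampler schedule and hyperpriors.

    Defaults follow common practice for rice-panel genomic prediction:
    15,000 iterations with 5,000 discarded as burn-in and a thinning
    interval of 5 (2,000 retained draws); Gamma(1.1, rate 1.12e-7)
    hyperprior on lambda²; scaled-inverse-chi²(5, scale 3.5) prior on the
    residual variance, with the scale parameterized so the density is
    proportional to (s²)^-(df/2+1) · exp(-scale/(2 s²)).
    """

    n_iter: int = 15000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    lambda2_shape: float = 1.1
    lambda2_rate: float = 1.12e-7
    resid_df: float = 5.0
    resid_scale: float = 3.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PcProjection:
    """Training-set PCA projection: loadings plus standardization constants."""

    mean: np.ndarray          # training column means of the dosages
    components: np.ndarray    # (k, m) principal axes
    score_sd: np.ndarray      # training SD of each score, used to standardize
    variance_target: float
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, dosages: np.ndarray) -> np.ndarray:
        if np.isnan(dosages).any():
            raise ValueError("projection requires complete dosages")
        return ((dosages - self.mean) @ self.components.T) / self.score_sd


@dataclass
class ModelFit:
    model_name: str                       # GBLUP | BayesLASSO | PCRegressor
    mu: float
    marker_effects: np.ndarray | None
    training_column_means: np.ndarray | None
    snp_keys: list[tuple]
    variance_components: VarianceComponents | None = None
    posterior: dict | None = None
    projection: PcProjection | None = None
    backend: object = None
    backend_name: str | None = None

    def __post_init__(self) -> None:
        if self.marker_effects is not None:
            if not (len(self.marker_effects) == len(self.snp_keys)
                    == len(self.training_column_means)):
                raise ValueError("marker_effects, training_column_means and "
                                 "snp_keys must have equal lengths")


@dataclass
class PredictionResult:
    sample_ids: list[str]
    gebv: np.ndarray
    trait: str = ""
    season_tag: str = ""
    model_name: str = ""

    def __post_init__(self) -> None:
        self.gebv = np.asarray(self.gebv, dtype=float)
        if len(self.gebv) != len(self.sample_ids):
            raise ValueError("gebv length does not match sample_ids")
        if not np.all(np.isfinite(self.gebv)):
            raise ValueError("non-finite GEBVs")


def _complete_dosages(G: GenotypeMatrix) -> np.ndarray:
    X = G.dosages
    if np.isnan(X).any():
        raise ValueError("model requires complete dosages; impute first")
    return X


# ---------------------------------------------------------------------------
# GBLUP


def fit_gblup(G_train: GenotypeMatrix, y: np.ndarray, mode: str = "reml_blup",
              mcmc: McmcConfig | None = None) -> ModelFit:
    """Fit the normal-prior marker model (GBLUP).

    ``reml_blup`` (default): variance components from AI-REML on the
    VanRaden kinship, then the exact ridge solution
    ``g = Xcᵀ (Xc Xcᵀ + (σe²/σm²) I)⁻¹ (y − ȳ)`` with σm² the marker-effect
    variance implied by the kinship-scale genetic variance. ``mcmc``: Gibbs
    sampling of the same model (normal marker prior, scaled-inverse-chi²
    priors on both variances); effects are posterior means.
    """
    X = _complete_dosages(G_train)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n < 10:
        raise ValueError("need at least 10 training samples")
    if len(y) != n:
        raise ValueError("phenotype length does not match samples")
    col_means = X.mean(axis=0)
    Xc = X - col_means
    mu = float(y.mean())

    if np.ptp(y) == 0.0:  # constant target: nothing to shrink
        return ModelFit("GBLUP", mu, np.zeros(m), col_means,
                        G_train.variant_keys())

    if mode == "reml_blup":
        grm = compute_grm(G_train)
        vc = reml_fit(y, grm)
        c = 2.0 * float(np.sum(grm.allele_freqs * (1 - grm.allele_freqs)))
        lam = c * vc.sigma_e2 / vc.sigma_g2  # ridge parameter in kernel space
        A = Xc @ Xc.T + lam * np.eye(n)
        try:
            alpha = np.linalg.solve(A, y - mu)
        except np.linalg.LinAlgError:
            warnings.warn("singular GBLUP system; adding 1e-8 jitter",
                          RuntimeWarning, stacklevel=2)
            alpha = np.linalg.solve(A + 1e-8 * np.eye(n), y - mu)
        effects = Xc.T @ alpha
        return ModelFit("GBLUP", mu, effects, col_means,
                        G_train.variant_keys(), variance_components=vc)
    elif mode == "mcmc":
        cfg = mcmc if mcmc is not None else McmcConfig()
        effects, mu_hat, summary = _gibbs_brr(Xc, y, cfg)
        return ModelFit("GBLUP", mu_hat, effects, col_means,
                        G_train.variant_keys(), posterior=summary)
    raise ValueError(f"unknown GBLUP mode {mode!r}")


def _scaled_inv_chi2(rng, df: float, scale: float) -> float:
    """Draw from density ∝ (s²)^-(df/2+1) exp(-scale/(2 s²))."""
    return scale / 2.0 / rng.gamma(df / 2.0)


def _gibbs_coordinates(rng, XT, xtx, r, g, inv_prior_var, sigma_e2):
    """One sweep of single-site updates of all marker effects (in place).

    ``r`` is the current residual y − mu − X g; ``inv_prior_var`` is a
    scalar or per-marker array of 1/prior-variance of each effect.
    """
    inv = np.broadcast_to(np.asarray(inv_prior_var, float), g.shape)
    for j in range(len(g)):
        xj = XT[j]
        rhs = xj @ r + xtx[j] * g[j]
        prec = xtx[j] + sigma_e2 * inv[j]
        mean = rhs / prec
        new = rng.normal(mean, np.sqrt(sigma_e2 / prec))
        r += xj * (g[j] - new)
        g[j] = new


def _gibbs_brr(Xc, y, cfg: McmcConfig):
    """Gibbs sampler for Bayesian ridge regression (the MCMC GBLUP)."""
    rng = np.random.default_rng(cfg.seed)
    n, m = Xc.shape
    XT = np.ascontiguousarray(Xc.T)
    xtx = np.einsum("ij,ij->i", XT, XT)
    g = np.zeros(m)
    mu = float(y.mean())
    sigma_e2 = max(float(np.var(y)) / 2.0, 1e-8)
    sigma_m2 = max(sigma_e2 / m, 1e-10)
    r = y - mu  # residual; Xg = 0 initially
    sum_g = np.zeros(m)
    sum_g2 = np.zeros(m)
    mus, se2s, sm2s = [], [], []
    for it in range(1, cfg.n_iter + 1):
        _gibbs_coordinates(rng, XT, xtx, r, g, 1.0 / sigma_m2, sigma_e2)
        # intercept (flat prior)
        r += mu
        mu = rng.normal(r.mean(), np.sqrt(sigma_e2 / n))
        r -= mu
        sigma_m2 = _scaled_inv_chi2(rng, cfg.resid_df + m,
                                    cfg.resid_scale + float(g @ g))
        sigma_e2 = _scaled_inv_chi2(rng, cfg.resid_df + n,
                                    cfg.resid_scale + float(r @ r))
        if not np.isfinite(sigma_e2) or not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite draw at iteration {it}")
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            sum_g += g
            sum_g2 += g ** 2
            mus.append(mu); se2s.append(sigma_e2); sm2s.append(sigma_m2)
    k = len(mus)
    assert k == cfg.n_retained
    eff = sum_g / k
    summary = {
        "n_retained": k,
        "mu": {"mean": float(np.mean(mus)), "sd": float(np.std(mus, ddof=1))},
        "sigma_e2": {"mean": float(np.mean(se2s)),
                     "sd": float(np.std(se2s, ddof=1))},
        "sigma_m2": {"mean": float(np.mean(sm2s)),
                     "sd": float(np.std(sm2s, ddof=1))},
        "effect_sd": np.sqrt(np.maximum(sum_g2 / k - eff ** 2, 0.0)),
    }
    return eff, float(np.mean(mus)), summary


# ---------------------------------------------------------------------------
# Bayesian LASSO (Park & Casella scale-mixture Gibbs)


def fit_bayes_lasso(G_train: GenotypeMatrix, y: np.ndarray,
                    cfg: McmcConfig | None = None,
                    lambda2_fixed: float | None = None) -> ModelFit:
    """Fit the Laplace-prior marker model by Gibbs sampling.

    Hierarchy: ``g_j | tau_j², s² ~ N(0, tau_j² s²)``;
    ``1/tau_j² | · ~ Inverse-Gaussian(sqrt(lambda² s² / g_j²), lambda²)``;
    ``lambda² ~ Gamma(shape, rate)`` updated through its conjugate full
    conditional ``Gamma(shape + m, rate + Σ tau_j²/2)``; the residual
    variance s² carries a scaled-inverse-chi² prior and a conjugate update
    that includes the marker-effect contribution. ``lambda2_fixed`` disables
    the hyperprior (used to probe the shrinkage limit). Marker effects are
    posterior means over the retained draws; deterministic given the seed.
    """
    cfg = cfg if cfg is not None else McmcConfig()
    X = _complete_dosages(G_train)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match samples")
    col_means = X.mean(axis=0)
    Xc = X - col_means
    rng = np.random.default_rng(cfg.seed)
    XT = np.ascontiguousarray(Xc.T)
    xtx = np.einsum("ij,ij->i", XT, XT)

    g = np.zeros(m)
    tau2 = np.ones(m)
    mu = float(y.mean())
    sigma2 = max(float(np.var(y)) / 2.0, 1e-8)
    lam2 = lambda2_fixed if lambda2_fixed is not None else 1.0
    r = y - mu
    sum_g = np.zeros(m)
    sum_g2 = np.zeros(m)
    mus, s2s, l2s = [], [], []
    for it in range(1, cfg.n_iter + 1):
        # prior var of g_j is tau_j^2 * sigma^2, so the effective ridge
        # penalty in the coordinate update is 1/tau_j^2
        _gibbs_coordinates(rng, XT, xtx, r, g, 1.0 / (tau2 * sigma2), sigma2)
        # tau_j^2 | g_j, lambda^2, sigma^2  (inverse-Gaussian on 1/tau_j^2)
        g_safe = np.where(np.abs(g) < 1e-12, 1e-12, g)
        inv_tau2 = rng.wald(np.sqrt(lam2 * sigma2 / g_safe ** 2), lam2)
        inv_tau2 = np.maximum(inv_tau2, 1e-12)
        tau2 = 1.0 / inv_tau2
        if lambda2_fixed is None:
            lam2 = rng.gamma(cfg.lambda2_shape + m,
                             1.0 / (cfg.lambda2_rate + tau2.sum() / 2.0))
        r += mu
        mu = rng.normal(r.mean(), np.sqrt(sigma2 / n))
        r -= mu
        ss = float(r @ r) + float(np.sum(g ** 2 / tau2))
        sigma2 = _scaled_inv_chi2(rng, cfg.resid_df + n + m,
                                  cfg.resid_scale + ss)
        if not (np.isfinite(sigma2) and np.isfinite(lam2)
                and np.all(np.isfinite(g))):
            raise FloatingPointError(f"non-finite draw at iteration {it}")
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            sum_g += g
            sum_g2 += g ** 2
            mus.append(mu); s2s.append(sigma2); l2s.append(lam2)
    k = len(mus)
    assert k == cfg.n_retained
    eff = sum_g / k
    summary = {
        "n_retained": k,
        "mu": {"mean": float(np.mean(mus)), "sd": float(np.std(mus, ddof=1))},
        "sigma2": {"mean": float(np.mean(s2s)),
                   "sd": float(np.std(s2s, ddof=1))},
        "lambda2": {"mean": float(np.mean(l2s)),
                    "sd": float(np.std(l2s, ddof=1))},
        "effect_sd": np.sqrt(np.maximum(sum_g2 / k - eff ** 2, 0.0)),
    }
    return ModelFit("BayesLASSO", float(np.mean(mus)), eff, col_means,
                    G_train.variant_keys(), posterior=summary)


# ---------------------------------------------------------------------------
# PCA features + pluggable regressor


def pc_features(G_train: GenotypeMatrix, variance_target: float = 0.95
                ) -> tuple[np.ndarray, PcProjection]:
    """Principal-component features of the centered dosage matrix.

    Keeps the smallest k whose cumulative explained variance reaches
    ``variance_target`` and standardizes the scores to unit training
    variance. The returned projection record applies the same loadings and
    standardization to new samples (never refit).
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    from sklearn.decomposition import PCA

    X = _complete_dosages(G_train)
    # centered rank is at most min(n - 1, m)
    pca = PCA(n_components=max(1, min(X.shape[0] - 1, X.shape[1])))
    scores = pca.fit_transform(X)
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    k = int(np.searchsorted(cum, variance_target - 1e-9) + 1)
    k = min(k, len(ratio))
    sd = np.sqrt(pca.explained_variance_[:k])
    sd = np.where(sd > 0, sd, 1.0)
    proj = PcProjection(mean=pca.mean_, components=pca.components_[:k],
                        score_sd=sd, variance_target=variance_target,
                        explained_variance_ratio=ratio[:k])
    return scores[:, :k] / sd, proj


class _OlsBackend:
    def fit(self, F, y):
        from sklearn.linear_model import LinearRegression
        self._m = LinearRegression().fit(F, y)
        return self

    def predict(self, F):
        return self._m.predict(F)


class _MeanBackend:
    def fit(self, F, y):
        self._mean = float(np.mean(y))
        return self

    def predict(self, F):
        return np.full(len(F), self._mean)


def _lightgbm_backend(**kwargs):
    from lightgbm import LGBMRegressor
    params = {"n_estimators": 200, "verbosity": -1, "random_state": 0}
    params.update(kwargs)
    return LGBMRegressor(**params)


_BACKENDS: dict = {
    "ols": lambda **kw: _OlsBackend(),
    "mean": lambda **kw: _MeanBackend(),
    "lightgbm": _lightgbm_backend,
}


def register_backend(name: str, factory) -> None:
    """Register a regressor backend: ``factory(**kwargs)`` must return an
    object with sklearn-style ``fit(F, y)`` / ``predict(F)``."""
    _BACKENDS[name] = factory


def fit_pc_regressor(features: np.ndarray, y: np.ndarray,
                     backend: str = "ols", projection: PcProjection = None,
                     snp_keys: list[tuple] | None = None,
                     **backend_kwargs) -> ModelFit:
    """Fit a registered backend on PCA features.

    The projection record travels with the fit so new genotypes are pushed
    through the identical training-set transform before prediction.
    """
    if backend not in _BACKENDS:
        raise KeyError(f"unregistered backend {backend!r}; "
                       f"known: {sorted(_BACKENDS)}")
    model = _BACKENDS[backend](**backend_kwargs)
    model.fit(np.asarray(features, float), np.asarray(y, float))
    return ModelFit("PCRegressor", float(np.mean(y)), None, None,
                    snp_keys or [], projection=projection, backend=model,
                    backend_name=backend)


# ---------------------------------------------------------------------------
# prediction


def _align(fit: ModelFit, G_new: GenotypeMatrix) -> np.ndarray:
    keys_new = {k: j for j, k in enumerate(G_new.variant_keys())}
    missing = [k for k in fit.snp_keys if k not in keys_new]
    if missing:
        raise KeyError(f"{len(missing)} fit variants absent from new "
                       f"genotypes, e.g. {missing[:3]}")
    idx = [keys_new[k] for k in fit.snp_keys]
    X = G_new.dosages[:, idx]
    if np.isnan(X).any():
        raise ValueError("new genotypes contain missing dosages; impute first")
    return X


def predict_gebv(fit: ModelFit, G_new: GenotypeMatrix, trait: str = "",
                 season_tag: str = "") -> PredictionResult:
    """Genomic estimated breeding values for new genotypes.

    Marker models: ``GEBV = mu + (X_new − training_column_means) · g``.
    PC-regressor fits route through the stored projection and backend.
    """
    if fit.model_name == "PCRegressor":
        if fit.projection is None:
            raise ValueError("PCRegressor fit lacks a projection record")
        if fit.snp_keys:
            X = _align(fit, G_new)
        else:
            X = _complete_dosages(G_new)
        gebv = np.asarray(fit.backend.predict(fit.projection.transform(X)),
                          dtype=float)
    else:
        X = _align(fit, G_new)
        gebv = fit.mu + (X - fit.training_column_means) @ fit.marker_effects
    return PredictionResult(list(G_new.sample_ids), gebv, trait=trait,
                            season_tag=season_tag,
                            model_name=fit.model_name)
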