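"""Prediction-accuracy evaluation: Pearson's r, repeated k-fold
cross-validation, and independent train/test validation.

Accuracy is the product-moment correlation between observed phenotypes and
predicted breeding values, computed per validation fold and averaged across
folds and repeats (never pooled over concatenated predictions). All
training-statistic computation — dosage centering, kinship, PCA — happens
inside each training fold only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ricegs.genio import GenotypeMatrix
from ricegs.models import (McmcConfig, PredictionResult, fit_bayes_lasso,
                           fit_gblup, fit_pc_regressor, pc_features,
                           predict_gebv)

__all__ = ["CvScheme", "CvResult", "pearson_r", "repeated_kfold_cv",
           "independent_validation", "make_model"]


@dataclass
class CvScheme:
    k: int = 5
    n_repeats: int = 20
    seed: int = 0
    stratified: bool = False  # kept off: partitions are uniform random

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def n_evaluations(self) -> int:
        return self.k * self.n_repeats


@dataclass
class CvResult:
    per_fold_r: np.ndarray   # length k × n_repeats; NaN marks a failed fold
    scheme: CvScheme
    trait: str = ""
    season: str = ""
    model_name: str = ""

    @property
    def mean_r(self) -> float:
        return float(np.nanmean(self.per_fold_r))

    @property
    def sd_r(self) -> float:
        valid = self.per_fold_r[~np.isnan(self.per_fold_r)]
        return float(np.std(valid, ddof=1)) if len(valid) > 1 else float("nan")

    def to_json(self, path=None) -> str:
        d = {"trait": self.trait, "season": self.season,
             "model_name": self.model_name, "k": self.scheme.k,
             "n_repeats": self.scheme.n_repeats, "mean_r": self.mean_r,
             "sd_r": self.sd_r,
             "per_fold_r": [None if np.isnan(v) else float(v)
                            for v in self.per_fold_r]}
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def pearson_r(y_obs, y_pred) -> float:
    """Product-moment correlation between observations and predictions.

    Raises on zero variance in either vector rather than returning a silent
    0 — an undefined correlation always signals an upstream problem here.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(y_obs) < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(y_obs) == 0 or np.var(y_pred) == 0:
        raise ValueError("undefined correlation: an input has zero variance")
    return float(stats.pearsonr(y_obs, y_pred)[0])


def make_model(spec):
    """Resolve a model spec into ``predict(G_train, y_train, G_test)``.

    Accepts a registered name ("gblup", "gblup_mcmc", "bayes_lasso",
    "pc_regressor"), a ``(name, kwargs)`` pair, or any callable with that
    signature (e.g. an oracle in tests).
    """
    if callable(spec):
        return spec
    name, kwargs = (spec, {}) if isinstance(spec, str) else spec
    kwargs = dict(kwargs)

    if name == "gblup":
        def predict(G_train, y_train, G_test):
            fit = fit_gblup(G_train, y_train, mode="reml_blup")
            return predict_gebv(fit, G_test).gebv
    elif name == "gblup_mcmc":
        cfg = kwargs.pop("mcmc", None) or McmcConfig(**kwargs)

        def predict(G_train, y_train, G_test):
            fit = fit_gblup(G_train, y_train, mode="mcmc", mcmc=cfg)
            return predict_gebv(fit, G_test).gebv
    elif name == "bayes_lasso":
        cfg = kwargs.pop("mcmc", None) or McmcConfig(**kwargs)

        def predict(G_train, y_train, G_test):
            fit = fit_bayes_lasso(G_train, y_train, cfg)
            return predict_gebv(fit, G_test).gebv
    elif name == "pc_regressor":
        backend = kwargs.pop("backend", "ols")
        target = kwargs.pop("variance_target", 0.95)

        def predict(G_train, y_train, G_test):
            feats, proj = pc_features(G_train, variance_target=target)
            fit = fit_pc_regressor(feats, y_train, backend=backend,
                                   projection=proj,
                                   snp_keys=G_train.variant_keys(), **kwargs)
            return predict_gebv(fit, G_test).gebv
    else:
        raise KeyError(f"unknown model spec {name!r}")
    return predict


def _partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random disjoint folds covering range(n), sizes differing by <= 1."""
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def repeated_kfold_cv(G: GenotypeMatrix, y, model, scheme: CvScheme,
                      trait: str = "", season: str = "") -> CvResult:
    """Repeated k-fold cross-validation scored by per-fold Pearson's r.

    Each repeat draws a fresh uniform-random partition into k near-equal
    folds; each fold is predicted by a model trained on the remaining
    folds, and its r is one entry of ``per_fold_r`` (length k × n_repeats).
    A model failure in a fold is recorded as NaN with a warning and
    excluded from the mean. Deterministic given ``scheme.seed``.
    """
    y = np.asarray(y, dtype=float)
    n = G.n_samples
    if len(y) != n:
        raise ValueError("phenotype length does not match samples")
    if n < 2 * scheme.k:
        raise ValueError(f"n={n} too small for {scheme.k}-fold CV")
    predictor = make_model(model)
    rng = np.random.default_rng(scheme.seed)
    per_fold = np.full(scheme.n_evaluations, np.nan)
    pos = 0
    for rep in range(scheme.n_repeats):
        folds = _partition(n, scheme.k, rng)
        assert sum(len(f) for f in folds) == n
        for fold in folds:
            if len(fold) < 3:
                raise ValueError("fold with fewer than 3 samples")
            train = np.setdiff1d(np.arange(n), fold)
            try:
                pred = predictor(G.take_samples(train), y[train],
                                 G.take_samples(fold))
                per_fold[pos] = pearson_r(y[fold], np.asarray(pred))
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                warnings.warn(f"model failed on repeat {rep} fold at "
                              f"position {pos}: {exc}", RuntimeWarning,
                              stacklevel=2)
            pos += 1
    return CvResult(per_fold, scheme, trait=trait, season=season,
                    model_name=model if isinstance(model, str) else
                    getattr(model, "__name__", "custom"))


def independent_validation(G_train: GenotypeMatrix, y_train,
                           G_test: GenotypeMatrix, y_test, model,
                           trait: str = "", season: str = ""
                           ) -> tuple[float, PredictionResult]:
    """Train once on the full training set, score on a disjoint test set."""
    overlap = set(G_train.sample_ids) & set(G_test.sample_ids)
    if overlap:
        raise ValueError(f"train/test sample ids overlap: "
                         f"{sorted(overlap)[:5]}")
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    predictor = make_model(model)
    pred = np.asarray(predictor(G_train, y_train, G_test), dtype=float)
    r = pearson_r(y_test, pred)
    result = PredictionResult(list(G_test.sample_ids), pred, trait=trait,
                              season_tag=season,
                              model_name=model if isinstance(model, str)
                              else "custom")
    return r, result
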