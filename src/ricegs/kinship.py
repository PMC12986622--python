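"""VanRaden genomic relationship matrix and AI-REML variance components.

The single-trait mixed model is ``y = 1·mu + g + e`` with
``g ~ N(0, K·sigma_g2)`` and ``e ~ N(0, I·sigma_e2)``, where K is the
marker-based genomic relationship matrix. Variance components are estimated
by restricted maximum likelihood using Average-Information updates with an
EM fallback; a one-time eigendecomposition of K makes every REML evaluation
O(n). Genomic heritability is sigma_g2 / (sigma_g2 + sigma_e2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ricegs.genio import GenotypeMatrix

__all__ = ["GRM", "VarianceComponents", "compute_grm", "reml_fit",
           "genomic_heritability", "reml_loglik"]


@dataclass
class GRM:
    """Symmetric genomic relationship matrix over accessions.

    ``allele_freqs`` holds the in-sample alternate-allele frequencies used
    for 2p centering (all input SNPs, monomorphic included);
    ``n_snps_used`` counts the polymorphic SNPs entering the denominator.
    """

    sample_ids: list[str]
    values: np.ndarray
    n_snps_used: int
    allele_freqs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")

    def subset(self, ids: list[str]) -> "GRM":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return GRM(list(ids), self.values[np.ix_(idx, idx)],
                   self.n_snps_used, self.allele_freqs)


@dataclass
class VarianceComponents:
    """REML estimates for one trait: sigma_g2, sigma_e2 and their ratio."""

    sigma_g2: float
    sigma_e2: float
    loglik: float
    n_iterations: int
    converged: bool
    algorithm_path: list[dict] = field(default_factory=list)

    @property
    def h2(self) -> float:
        total = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / total if total > 0 else 0.0

    def to_json(self, path=None) -> str:
        d = {"sigma_g2": self.sigma_g2, "sigma_e2": self.sigma_e2,
             "h2": self.h2, "loglik": self.loglik,
             "n_iterations": self.n_iterations, "converged": self.converged}
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def compute_grm(G: GenotypeMatrix) -> GRM:
    """VanRaden (method 1) genomic relationship matrix.

    With p_j the observed alternate-allele frequency, W = dosages − 2p
    column-wise and ``GRM = W Wᵀ / (2 Σ_j p_j (1 − p_j))``, the sum running
    over polymorphic SNPs only (monomorphic columns center to zero and are
    excluded from the denominator).
    """
    X = G.dosages
    if np.isnan(X).any():
        raise ValueError("GRM requires complete dosages; impute first")
    if G.n_samples < 2:
        raise ValueError("GRM requires at least 2 samples")
    p = X.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: GRM denominator is zero")
    W = X - 2.0 * p
    values = (W @ W.T) / denom
    values = (values + values.T) / 2.0  # exact numerical symmetry
    return GRM(list(G.sample_ids), values, int(poly.sum()), p)


def _as_kinship(K) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(K, GRM):
        return K.values, K.sample_ids
    K = np.asarray(K, dtype=float)
    return K, None


def reml_loglik(y: np.ndarray, K, sigma_g2: float, sigma_e2: float) -> float:
    """REML log-likelihood (up to an additive constant) of the GRM model."""
    Kv, _ = _as_kinship(K)
    d, U = np.linalg.eigh(Kv)
    return _rot_loglik(U.T @ np.asarray(y, float), U.T @ np.ones(len(y)),
                       d, sigma_g2, sigma_e2)


def _rot_loglik(y_rot, x_rot, d, sg2, se2) -> float:
    w = sg2 * d + se2
    if np.any(w <= 0):
        return -np.inf
    xtvx = np.sum(x_rot ** 2 / w)
    beta = np.sum(x_rot * y_rot / w) / xtvx
    r = y_rot - x_rot * beta
    ypy = np.sum(r ** 2 / w)
    return -0.5 * (np.sum(np.log(w)) + np.log(xtvx) + ypy)


def reml_fit(y: np.ndarray, K, max_iter: int = 100,
             tol: float = 1e-6) -> VarianceComponents:
    """AI-REML fit of ``y = 1·mu + g + e`` with ``g ~ N(0, K sigma_g2)``.

    The kinship is eigendecomposed once; each iteration proposes an
    Average-Information update of (sigma_g2, sigma_e2) and falls back to an
    EM step whenever the AI step leaves the parameter space or lowers the
    restricted likelihood. Components are clamped at a floor of
    ``1e-8 × var(y)`` so heritability stays inside (0, 1). Non-convergence
    within ``max_iter`` is reported via ``converged=False``, never raised.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype vector contains non-finite values")
    Kv, _ = _as_kinship(K)
    n = len(y)
    if Kv.shape != (n, n):
        raise ValueError(f"kinship shape {Kv.shape} does not match n={n}")
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")

    d, U = np.linalg.eigh(Kv)
    if d.max() - d.min() < 1e-8:
        warnings.warn("kinship is (nearly) a multiple of the identity: "
                      "sigma_g2 and sigma_e2 are not separately identifiable",
                      RuntimeWarning, stacklevel=2)
    y_rot = U.T @ y
    x_rot = U.T @ np.ones(n)
    floor = 1e-8 * vary

    def score_and_q(theta):
        sg2, se2 = theta
        w = sg2 * d + se2
        xtvx = np.sum(x_rot ** 2 / w)
        beta = np.sum(x_rot * y_rot / w) / xtvx
        r = y_rot - x_rot * beta
        q = r / w                      # rotated P·y
        scores = np.empty(2)
        for k, a in enumerate((d, np.ones(n))):
            tr_pa = np.sum(a / w) - np.sum(x_rot ** 2 * a / w ** 2) / xtvx
            scores[k] = -0.5 * (tr_pa - np.sum(a * q ** 2))
        return scores, q, w, xtvx

    def apply_p(v, w, xtvx):
        c = np.sum(x_rot * v / w) / xtvx
        return (v - x_rot * c) / w

    theta = np.array([vary / 2.0, vary / 2.0])
    path: list[dict] = []
    ll = _rot_loglik(y_rot, x_rot, d, *theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        scores, q, w, xtvx = score_and_q(theta)
        u_g, u_e = d * q, q
        ai = np.empty((2, 2))
        pu_g = apply_p(u_g, w, xtvx)
        pu_e = apply_p(u_e, w, xtvx)
        ai[0, 0] = 0.5 * u_g @ pu_g
        ai[0, 1] = ai[1, 0] = 0.5 * u_g @ pu_e
        ai[1, 1] = 0.5 * u_e @ pu_e

        step = "AI"
        try:
            delta = np.linalg.solve(ai, scores)
            # project onto the parameter space so boundary optima
            # (sigma_g2 -> 0) are reached instead of stalling in EM
            proposal = np.maximum(theta + delta, floor)
            new_ll = _rot_loglik(y_rot, x_rot, d, *proposal)
        except np.linalg.LinAlgError:
            proposal, new_ll = theta, -np.inf
        if new_ll < ll - 1e-10:
            # EM fallback: sigma_k^2 += sigma_k^4 (y'PA_kPy - tr(PA_k)) / n
            step = "EM"
            proposal = theta.copy()
            for k, a in enumerate((d, np.ones(n))):
                tr_pa = (np.sum(a / w)
                         - np.sum(x_rot ** 2 * a / w ** 2) / xtvx)
                proposal[k] += theta[k] ** 2 * (np.sum(a * q ** 2) - tr_pa) / n
            proposal = np.maximum(proposal, floor)
            new_ll = _rot_loglik(y_rot, x_rot, d, *proposal)
        change = float(np.max(np.abs(proposal - theta)))
        theta, ll = proposal, new_ll
        path.append({"iteration": it, "step": step,
                     "sigma_g2": float(theta[0]), "sigma_e2": float(theta[1]),
                     "loglik": float(ll)})
        if change < tol * vary:
            converged = True
            break

    return VarianceComponents(sigma_g2=float(theta[0]),
                              sigma_e2=float(theta[1]),
                              loglik=float(ll), n_iterations=it,
                              converged=converged, algorithm_path=path)


def genomic_heritability(vc: VarianceComponents) -> float:
    """Genomic heritability sigma_g2 / (sigma_g2 + sigma_e2)."""
    if not (np.isfinite(vc.sigma_g2) and np.isfinite(vc.sigma_e2)):
        raise ValueError("non-finite variance components")
    total = vc.sigma_g2 + vc.sigma_e2
    if total <= 0:
        warnings.warn("both variance components at the floor; returning 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return vc.sigma_g2 / total
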