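"""Population delineation: PCA and model-based ancestry estimation.

PCA follows the standard genotype convention: mean-impute missing
dosages per site, center, scale each site by sqrt(p(1-p)) where p is
its allele frequency, and eigendecompose. Ancestry estimation maximizes
the binomial admixture likelihood

    L(Q, F) = sum_il [ g_il ln(sum_k q_ik f_kl) + (2 - g_il) ln(1 - sum_k q_ik f_kl) ]

by EM over ancestry proportions Q (n x K, rows simplex) and cluster
allele frequencies F (K x L); missing genotypes drop out of the sums.
The number of clusters K is chosen by masked-genotype cross-validation:
a random share of called genotypes is hidden, the model fit, and hidden
dosages predicted as 2 sum_k q_ik f_kl; the K minimizing mean squared
prediction error wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

_F_EPS = 1e-6


@dataclass
class PcaResult:
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray | None = None


def pca(matrix: GenotypeMatrix, n_axes: int = 10) -> PcaResult:
    """Genotype PCA with mean imputation and p(1-p) scaling."""
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = matrix.dosage_float()
    p = matrix.allele_frequencies()
    poly = (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("no polymorphic sites: PCA undefined")
    X = X[:, poly]
    p = p[poly]
    mean = 2.0 * p
    scale = np.sqrt(p * (1.0 - p))
    X = np.where(np.isnan(X), mean[None, :], X)
    X = (X - mean[None, :]) / scale[None, :]
    U, s, Vt = np.linalg.svd(X - X.mean(axis=0, keepdims=True), full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if rank == 0:
        raise ValueError("no genotypic variance among samples: PCA undefined")
    if n_axes > rank:
        warnings.warn(f"n_axes={n_axes} exceeds rank {rank}; truncating")
        n_axes = rank
    var = s**2
    frac = var / var.sum()
    scores = U[:, :n_axes] * s[:n_axes]
    return PcaResult(scores, frac[:n_axes], loadings=Vt[:n_axes].T)


@dataclass
class AdmixtureResults:
    """Fitted ancestry model: Q (n x K), F (K x L), likelihood trace."""

    Q: np.ndarray
    F: np.ndarray
    loglik_trace: np.ndarray
    K: int
    converged: bool
    sample_ids: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def q_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=[f"Q{k+1}" for k in range(self.K)])
        df.insert(0, "sampleID", self.sample_ids or range(len(df)))
        return df

    def summary(self) -> str:
        lines = [
            "Admixture model (binomial likelihood, EM)",
            f"  K clusters:        {self.K}",
            f"  samples x sites:   {self.Q.shape[0]} x {self.F.shape[1]}",
            f"  log-likelihood:    {self.loglik:.3f}",
            f"  EM iterations:     {len(self.loglik_trace)}",
            f"  converged:         {self.converged}",
            f"  mean max ancestry: {self.Q.max(axis=1).mean():.3f}",
        ]
        return "\n".join(lines)


class AdmixtureModel:
    """Binomial admixture model for a biallelic dosage matrix.

    Parameters
    ----------
    matrix : GenotypeMatrix
    K : number of ancestral clusters (>= 1, <= n_samples).
    """

    def __init__(self, matrix: GenotypeMatrix, K: int):
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > matrix.n_samples:
            raise ValueError("K cannot exceed the number of samples")
        self.matrix = matrix
        self.K = K

    def fit(self, seed: int = 0, max_iter: int = 500, tol: float = 1e-6) -> AdmixtureResults:
        G = self.matrix.dosage_float()
        return self._fit_array(G, seed=seed, max_iter=max_iter, tol=tol)

    def _fit_array(self, G: np.ndarray, seed: int, max_iter: int, tol: float) -> AdmixtureResults:
        K = self.K
        called = ~np.isnan(G)
        Gz = np.where(called, G, 0.0)
        G2 = np.where(called, 2.0 - G, 0.0)
        n, L = G.shape
        rng = np.random.default_rng(seed)
        obs = np.clip(Gz.sum(axis=0) / np.maximum(2.0 * called.sum(axis=0), 1.0), 0.05, 0.95)
        F = np.clip(obs[None, :] + rng.normal(0, 0.05, size=(K, L)), _F_EPS, 1 - _F_EPS)
        Q = rng.dirichlet(np.ones(K), size=n)
        denom_q = 2.0 * called.sum(axis=1)  # called alleles per sample

        trace = []
        prev = -np.inf
        converged = False
        for _ in range(max_iter):
            P = np.clip(Q @ F, _F_EPS, 1 - _F_EPS)
            ll = float(np.sum(Gz * np.log(P) + G2 * np.log1p(-P)))
            trace.append(ll)
            if np.isfinite(prev) and abs(ll - prev) < tol * (abs(prev) + 1.0):
                converged = True
                break
            prev = ll
            R1 = Gz / P
            R2 = G2 / (1.0 - P)
            # E-step responsibilities folded into the M-step sufficient stats
            num_f = F * (Q.T @ R1)          # K x L: expected alt alleles from k
            den_f = (1.0 - F) * (Q.T @ R2)  # K x L: expected ref alleles from k
            Q = Q * (R1 @ F.T + R2 @ (1.0 - F).T) / denom_q[:, None]
            Q = Q / Q.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                F = num_f / (num_f + den_f)
            F = np.clip(np.nan_to_num(F, nan=0.5), _F_EPS, 1 - _F_EPS)
        return AdmixtureResults(
            Q=Q, F=F, loglik_trace=np.asarray(trace), K=K, converged=converged,
            sample_ids=list(self.matrix.sample_ids),
        )

    def fit_masked(self, mask: np.ndarray, seed: int = 0, max_iter: int = 500,
                   tol: float = 1e-6) -> AdmixtureResults:
        """Fit with an extra boolean mask of genotypes treated as missing."""
        G = self.matrix.dosage_float()
        G[mask] = np.nan
        return self._fit_array(G, seed=seed, max_iter=max_iter, tol=tol)


def admixture_em(matrix: GenotypeMatrix, K: int, seed: int = 0, max_iter: int = 500,
                 tol: float = 1e-6) -> AdmixtureResults:
    """Functional wrapper around AdmixtureModel(...).fit(...)."""
    return AdmixtureModel(matrix, K).fit(seed=seed, max_iter=max_iter, tol=tol)


def align_clusters(result: AdmixtureResults, reference_F: np.ndarray) -> AdmixtureResults:
    """Resolve label switching: greedily match columns to a reference F by
    correlation of cluster allele-frequency vectors, then permute Q and F."""
    K = result.K
    corr = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            c = np.corrcoef(reference_F[a], result.F[b])[0, 1]
            corr[a, b] = -np.inf if np.isnan(c) else c
    perm = np.full(K, -1, dtype=int)
    work = corr.copy()
    for _ in range(K):
        a, b = np.unravel_index(np.argmax(work), work.shape)
        perm[a] = b
        work[a, :] = -np.inf
        work[:, b] = -np.inf
    return AdmixtureResults(
        Q=result.Q[:, perm], F=result.F[perm], loglik_trace=result.loglik_trace,
        K=K, converged=result.converged, sample_ids=result.sample_ids,
    )


@dataclass
class KSelection:
    candidate_ks: list[int]
    mean_cv_error: np.ndarray
    cv_errors: pd.DataFrame  # long: K, replicate, fold, error
    best_k: int


def cv_choose_k(matrix: GenotypeMatrix, ks=range(1, 11), folds: int = 10,
                replicates: int = 10, seed: int = 0, max_iter: int = 300,
                tol: float = 1e-5) -> KSelection:
    """Choose K by masked-genotype cross-validation.

    Per replicate, called genotypes are randomly partitioned into
    ``folds`` groups; each fold is masked in turn, the model refit, and
    masked dosages predicted as 2 Q F. best_k minimizes the mean squared
    error across folds and replicates.
    """
    ks = list(ks)
    called = matrix.called()
    flat_idx = np.nonzero(called.ravel())[0]
    if flat_idx.size < folds:
        raise ValueError("not enough called genotypes to mask")
    G = matrix.dosage_float()
    rows = []
    ss = np.random.SeedSequence(seed)
    for rep, rep_ss in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(rep_ss)
        perm = rng.permutation(flat_idx)
        fold_of = np.array_split(perm, folds)
        for K in ks:
            model = AdmixtureModel(matrix, K)
            for f, fold_entries in enumerate(fold_of):
                mask = np.zeros(called.shape, dtype=bool)
                mask.ravel()[fold_entries] = True
                fit_seed = int(rng.integers(2**31 - 1))
                res = model.fit_masked(mask, seed=fit_seed, max_iter=max_iter, tol=tol)
                pred = 2.0 * (res.Q @ res.F)
                err = float(np.mean((pred[mask] - G[mask]) ** 2))
                rows.append((K, rep, f, err))
    df = pd.DataFrame(rows, columns=["K", "replicate", "fold", "error"])
    mean_err = df.groupby("K")["error"].mean().reindex(ks).to_numpy()
    best_k = ks[int(np.argmin(mean_err))]
    return KSelection(ks, mean_err, df, best_k)
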