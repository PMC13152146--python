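"""Isolation-by-distance vs discrete admixture diagnostics.

A Mantel permutation test correlates great-circle geographic distances
with Euclidean genetic distances between individual dosage vectors
(one-sided, greater: IBD predicts a positive association). The triangle
analysis plots each individual's hybrid index against its interclass
heterozygosity at ancestry-informative markers (AIMs; sites with allele
frequency difference >= 0.9 between two reference populations): recent
admixture produces elevated heterozygosity at intermediate hybrid
index, while IBD-like continuous variation does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .geodesy import pairwise_haversine_km


def geographic_distances(lons, lats) -> np.ndarray:
    """Symmetric haversine km matrix for coordinate arrays."""
    return pairwise_haversine_km(np.asarray(lons, float), np.asarray(lats, float))


def genetic_distances(matrix: GenotypeMatrix) -> np.ndarray:
    """Pairwise Euclidean distance between dosage vectors.

    Computed on pairwise-complete sites and rescaled by
    sqrt(n_sites_total / n_sites_used) so missingness does not shrink
    distances. Pairs sharing no called site get NaN.
    """
    G = matrix.dosage_float()
    n, L = G.shape
    called = ~np.isnan(G)
    Gz = np.where(called, G, 0.0)
    sq = Gz**2
    # sum over shared sites of (gi - gj)^2, via masked expansions
    shared = called.astype(float) @ called.T.astype(float)
    cross = Gz @ Gz.T
    si = sq @ called.T.astype(float)
    ss = si + si.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = ss * (L / shared)
    d = np.sqrt(np.clip(d2, 0.0, None))
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def mantel_test(geoD: np.ndarray, genD: np.ndarray, n_perm: int = 1000,
                seed: int = 0) -> tuple[float, float]:
    """One-sided (greater) Mantel permutation test.

    r is the Pearson correlation of the upper triangles;
    p = (#{permuted r >= observed} + 1) / (n_perm + 1), permuting rows
    and columns of one matrix jointly.
    """
    geoD = np.asarray(geoD, float)
    genD = np.asarray(genD, float)
    if geoD.shape != genD.shape or geoD.shape[0] != geoD.shape[1]:
        raise ValueError("distance matrices must be square and of equal shape")
    n = geoD.shape[0]
    iu = np.triu_indices(n, k=1)
    x = geoD[iu]
    y = genD[iu]
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("Mantel test requires complete distance matrices")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r_obs = float(np.mean(xc * yc))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = genD[np.ix_(perm, perm)][iu]
        ypc = (yp - yp.mean()) / yp.std()
        if float(np.mean(xc * ypc)) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p


@dataclass
class TriangleResult:
    aim_indices: np.ndarray
    orientation_alt_is_b: np.ndarray  # True where the ALT allele is the pop-B allele
    table: pd.DataFrame  # sampleID, hybrid_index, interclass_het, n_aims_called


def population_frequencies(matrix: GenotypeMatrix, sample_ids) -> np.ndarray:
    """Alternate-allele frequencies within a named subset of samples."""
    idx = [matrix.sample_ids.index(s) for s in sample_ids]
    if not idx:
        raise ValueError("reference population is empty")
    return matrix.take_samples(np.array(idx)).allele_frequencies()


def select_aims(freq_pop_a: np.ndarray, freq_pop_b: np.ndarray,
                afd_min: float = 0.9):
    """Ancestry-informative markers: |p_A - p_B| >= afd_min.

    Returns (indices, alt_is_b) where alt_is_b marks sites whose ALT
    allele is the one commoner in population B.
    """
    pa = np.asarray(freq_pop_a, float)
    pb = np.asarray(freq_pop_b, float)
    afd = np.abs(pa - pb)
    with np.errstate(invalid="ignore"):
        sel = afd >= afd_min
    sel &= ~np.isnan(afd)
    idx = np.nonzero(sel)[0]
    if idx.size == 0:
        warnings.warn("no AIMs at the requested allele-frequency difference")
    return idx, (pb >= pa)[idx]


def triangle_coordinates(matrix: GenotypeMatrix, aim_indices, alt_is_b) -> TriangleResult:
    """Per-individual hybrid index and interclass heterozygosity at AIMs.

    hybrid index h = (B-oriented allele count) / (2 * called AIMs);
    interclass heterozygosity = heterozygous AIMs / called AIMs.
    Individuals with zero called AIMs get NaN coordinates.
    """
    aim_indices = np.asarray(aim_indices, dtype=int)
    if aim_indices.size == 0:
        raise ValueError("need at least one AIM")
    g = matrix.dosage[:, aim_indices].astype(float)
    g[g == MISSING] = np.nan
    oriented = np.where(np.asarray(alt_is_b)[None, :], g, 2.0 - g)
    called = ~np.isnan(g)
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.nansum(oriented, axis=1) / (2.0 * n_called)
        het = (g == 1).sum(axis=1) / n_called
    h[n_called == 0] = np.nan
    het = np.where(n_called == 0, np.nan, het)
    table = pd.DataFrame(
        {
            "sampleID": matrix.sample_ids,
            "hybrid_index": h,
            "interclass_het": het,
            "n_aims_called": n_called,
        }
    )
    return TriangleResult(aim_indices, np.asarray(alt_is_b), table)
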