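"""Variant- and sample-level QC: hard filters, Tajima's D neutrality
partitioning, LD pruning and KING-robust duplicate removal.

The hard-filter defaults mirror standard practice for target-capture
variant callsets from degraded wildlife samples: drop indels and
multi-allelic sites, mean site depth below 8x or above a species-level
cap, site missingness above 30%, variant quality below Phred 20, and
minor allele count below 3. Individuals with more than 75% missing
genotypes are excluded. Sites whose locus-level Tajima's D falls
outside (-2, 2) are set aside as putatively non-neutral. LD pruning
follows the indep-pairwise convention (50-SNP window, 10-SNP step,
r^2 > 0.2), and duplicate/monozygotic pairs are flagged at KING-robust
kinship > 0.354.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix


@dataclass
class FilterConfig:
    min_mean_depth: float = 8.0
    max_mean_depth: float = 50.0  # species-specific, 35x-75x range
    max_site_missing: float = 0.30
    min_quality: float = 20.0
    min_mac: int = 3
    max_indiv_missing: float = 0.75
    tajima_bounds: tuple = (-2.0, 2.0)
    ld_window: int = 50
    ld_step: int = 10
    ld_r2: float = 0.2
    kinship_dup_threshold: float = 0.354
    biallelic_only: bool = True

    def validate(self) -> None:
        if self.min_mean_depth > self.max_mean_depth:
            raise ValueError("depth bounds out of order")
        if not 0 <= self.max_site_missing <= 1 or not 0 <= self.max_indiv_missing <= 1:
            raise ValueError("missingness thresholds outside [0, 1]")
        if self.tajima_bounds[0] >= self.tajima_bounds[1]:
            raise ValueError("tajima_bounds out of order")
        if self.ld_window < self.ld_step:
            raise ValueError("ld_window must be >= ld_step")


def build_site_table(matrix: GenotypeMatrix, mean_depth=None, variant_quality=None,
                     is_indel=None, n_alleles=None) -> pd.DataFrame:
    """Per-site annotation table; genotype-derived columns are recomputed
    from the matrix, sequencing-level columns default to passing values
    when the source VCF carries none (synthetic data)."""
    n = matrix.n_sites
    return pd.DataFrame(
        {
            "contig": matrix.contigs,
            "position": matrix.positions,
            "mean_depth": np.full(n, 30.0) if mean_depth is None else np.asarray(mean_depth, float),
            "variant_quality": np.full(n, 99.0) if variant_quality is None else np.asarray(variant_quality, float),
            "minor_allele_count": matrix.minor_allele_counts(),
            "missing_fraction": matrix.site_missingness(),
            "is_indel": np.zeros(n, bool) if is_indel is None else np.asarray(is_indel, bool),
            "n_alleles": np.full(n, 2) if n_alleles is None else np.asarray(n_alleles, int),
        }
    )


# rule order fixes first-failure attribution in the QC report
_SITE_RULES = (
    ("indel", lambda s, c: ~s["is_indel"].to_numpy()),
    ("biallelic", lambda s, c: (s["n_alleles"].to_numpy() == 2) | (not c.biallelic_only)),
    ("min_mean_depth", lambda s, c: s["mean_depth"].to_numpy() >= c.min_mean_depth),
    ("max_mean_depth", lambda s, c: s["mean_depth"].to_numpy() <= c.max_mean_depth),
    ("max_site_missing", lambda s, c: s["missing_fraction"].to_numpy() <= c.max_site_missing),
    ("min_quality", lambda s, c: s["variant_quality"].to_numpy() >= c.min_quality),
    ("min_mac", lambda s, c: s["minor_allele_count"].to_numpy() >= c.min_mac),
)


def filter_sites(matrix: GenotypeMatrix, sites: pd.DataFrame, config: FilterConfig):
    """Apply the hard site filters as a conjunction.

    Returns (filtered matrix, filtered site table, report). The report has
    one row per rule counting sites whose *first* failed rule it is, plus
    an ``any_rule`` row counting all removed sites.
    """
    config.validate()
    if len(sites) != matrix.n_sites:
        raise ValueError("matrix and site table are not aligned")
    passing = {name: rule(sites, config) for name, rule in _SITE_RULES}
    keep = np.logical_and.reduce(list(passing.values()))
    first_fail = np.full(len(sites), "", dtype=object)
    for name, _ in _SITE_RULES:
        newly = (first_fail == "") & ~passing[name]
        first_fail[newly] = name
    counts = [(name, int((first_fail == name).sum())) for name, _ in _SITE_RULES]
    counts.append(("any_rule", int((~keep).sum())))
    report = pd.DataFrame(counts, columns=["rule", "sites_removed"])
    if not keep.any():
        warnings.warn("all sites removed by filters")
    idx = np.nonzero(keep)[0]
    return matrix.take_sites(idx), sites.iloc[idx].reset_index(drop=True), report


def filter_individuals(matrix: GenotypeMatrix, max_missing: float = 0.75) -> GenotypeMatrix:
    """Drop samples with missing fraction strictly greater than the threshold."""
    keep = matrix.sample_missingness() <= max_missing
    return matrix.take_samples(np.nonzero(keep)[0])


def _tajima_constants(n_chrom: int):
    n = n_chrom
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, e1, e2


def tajimas_d(window: np.ndarray) -> float:
    """Tajima's D from a dosage window (samples x sites; -1 = missing).

    pi is the mean pairwise difference accumulated per site over that
    site's called chromosomes; the normalizing constants use the window's
    maximum called chromosome count. Returns NaN when no site segregates
    or fewer than 2 samples carry calls (no selection evidence).
    """
    g = np.asarray(window)
    called = g != MISSING
    m = 2 * called.sum(axis=0)  # called chromosomes per site
    alt = np.where(called, g, 0).sum(axis=0)
    seg = (alt > 0) & (alt < m) & (m >= 4)
    S = int(seg.sum())
    n_chrom = int(m.max(initial=0))
    if S == 0 or n_chrom < 4:
        return float("nan")
    mm, cc = m[seg].astype(float), alt[seg].astype(float)
    pi = np.sum(2.0 * cc * (mm - cc) / (mm * (mm - 1.0)))
    a1, e1, e2 = _tajima_constants(n_chrom)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((pi - S / a1) / np.sqrt(var))


def partition_neutral(matrix: GenotypeMatrix, sites: pd.DataFrame,
                      tajima_bounds=(-2.0, 2.0)):
    """Split sites into neutral vs non-neutral by locus-level Tajima's D.

    D is computed per contig (each capture locus is an independent
    reference sequence); sites on contigs with D > upper or D < lower are
    non-neutral, undefined D counts as neutral. Returns
    (neutral_idx, nonneutral_idx, site table with a tajima_d column).
    """
    lo, hi = tajima_bounds
    sites = sites.copy()
    d_per_contig = {}
    for ctg in pd.unique(matrix.contigs):
        cols = np.nonzero(matrix.contigs == ctg)[0]
        d_per_contig[ctg] = tajimas_d(matrix.dosage[:, cols])
    sites["tajima_d"] = [d_per_contig[c] for c in matrix.contigs]
    d = sites["tajima_d"].to_numpy()
    nonneutral = (d > hi) | (d < lo)  # NaN compares False -> neutral
    return np.nonzero(~nonneutral)[0], np.nonzero(nonneutral)[0], sites


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors on pairwise-complete samples."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(matrix: GenotypeMatrix, window: int = 50, step: int = 10,
             r2_max: float = 0.2) -> np.ndarray:
    """Sliding-window LD pruning; returns indices of retained sites.

    Within each window, ordered pairs (i, j), i < j, are scanned greedily;
    when r^2 exceeds the threshold the member with higher missingness is
    removed (tie: the later site). Windows advance by ``step`` sites.
    """
    if window < step:
        raise ValueError("window must be >= step")
    n = matrix.n_sites
    removed = np.zeros(n, dtype=bool)
    miss = matrix.site_missingness()
    dos = matrix.dosage
    for start in range(0, n, step):
        stop = min(start + window, n)
        idx = [j for j in range(start, stop) if not removed[j]]
        for a in range(len(idx)):
            i = idx[a]
            if removed[i]:
                continue
            for b in range(a + 1, len(idx)):
                j = idx[b]
                if removed[i]:
                    break
                if removed[j]:
                    continue
                if _pairwise_r2(dos[:, i], dos[:, j]) > r2_max:
                    if miss[i] > miss[j]:
                        removed[i] = True
                    else:
                        removed[j] = True
        if stop == n:
            break
    return np.nonzero(~removed)[0]


def king_kinship(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """KING-robust between-individual kinship estimate.

    phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j)) over sites called
    in both individuals; NaN when neither individual is heterozygous at
    any shared site (undefined).
    """
    gi, gj = np.asarray(dosage_i), np.asarray(dosage_j)
    ok = (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[ok], gj[ok]
    het_het = int(np.sum((gi == 1) & (gj == 1)))
    opp_hom = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    het_i = int(np.sum(gi == 1))
    het_j = int(np.sum(gj == 1))
    denom = het_i + het_j
    if denom == 0:
        return float("nan")
    return (het_het - 2.0 * opp_hom) / denom


def kinship_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """All pairwise KING-robust estimates (long format)."""
    rows = []
    for i in range(matrix.n_samples):
        for j in range(i + 1, matrix.n_samples):
            rows.append(
                (
                    matrix.sample_ids[i],
                    matrix.sample_ids[j],
                    king_kinship(matrix.dosage[i], matrix.dosage[j]),
                )
            )
    return pd.DataFrame(rows, columns=["id_i", "id_j", "phi"])


def deduplicate(matrix: GenotypeMatrix, threshold: float = 0.354):
    """Remove one member of every pair with kinship above the duplicate
    threshold (higher missingness removed; tie -> later sample), re-checking
    after each removal. Returns (pruned matrix, list of (kept, removed, phi))."""
    keep = list(range(matrix.n_samples))
    miss = matrix.sample_missingness()
    removed_pairs = []
    while True:
        worst = None
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                i, j = keep[a], keep[b]
                phi = king_kinship(matrix.dosage[i], matrix.dosage[j])
                if np.isnan(phi) or phi <= threshold:
                    continue
                if worst is None or phi > worst[2]:
                    worst = (i, j, phi)
        if worst is None:
            break
        i, j, phi = worst
        if miss[i] > miss[j]:
            drop, kept = i, j
        elif miss[j] > miss[i]:
            drop, kept = j, i
        else:  # tie: remove the later sample ID
            drop, kept = (j, i) if matrix.sample_ids[j] > matrix.sample_ids[i] else (i, j)
        keep.remove(drop)
        removed_pairs.append((matrix.sample_ids[kept], matrix.sample_ids[drop], phi))
    return matrix.take_samples(np.array(keep, dtype=int)), removed_pairs
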