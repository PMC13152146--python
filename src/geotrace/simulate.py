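"""Spatially structured genotype simulator with known ground truth.

Three generative regimes cover the structure a range-wide wildlife
genotyping study must discriminate:

* an isolation-by-distance (IBD) landscape — per-locus allele-frequency
  surfaces are logistic clines over standardized map coordinates, so
  genetic and geographic distance are positively correlated with a
  strength set by ``cline_strength``;
* discrete clusters — Balding–Nichols Beta-distributed cluster allele
  frequencies around a shared ancestral frequency, differentiation set
  by ``drift_f``;
* an admixture zone — a sigmoidal ancestry cline between two parental
  clusters along a transect.

Missingness is injected per genotype with a site-type-dependent rate
(emulating museum/trade sample degradation), and trade scenarios
displace query samples from their true origin by a configurable
great-circle distance so every downstream stage can be validated
against known truth.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io
from .containers import GenotypeMatrix, MISSING, make_sample_table
from .geodesy import destination_point, haversine_km

DEFAULT_MISSING_RATES = {
    "field_site": 0.05,
    "restricted_range_market": 0.05,
    "long_range_market": 0.15,
    "seizure": 0.20,
    "unknown": 0.30,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic landscape.

    ``landscape_bounds`` is (lon_min, lon_max, lat_min, lat_max) in
    decimal degrees; the default spans roughly 2000 x 2000 km near the
    equator. ``cline_strength`` is the logit-frequency slope per unit of
    standardized coordinate; ``drift_f`` is Balding–Nichols
    differentiation in [0, 1); ``admixture_zone_width`` is the km scale
    over which ancestry transitions between parental clusters.
    """

    landscape_bounds: tuple = (8.0, 26.0, -4.0, 14.0)
    n_loci: int = 1000
    n_clusters: int = 2
    drift_f: float = 0.1
    cline_strength: float = 2.0
    admixture_zone_width: float = 300.0
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    loci_per_contig: int = 10
    seed: int = 0

    def validate(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.landscape_bounds
        if not (lon_min < lon_max and lat_min < lat_max):
            raise ValueError("landscape has zero or negative area")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.drift_f < 1.0:
            raise ValueError("drift_f must be in [0, 1)")
        for st, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {st!r} outside [0, 1]")


@dataclass
class SyntheticDataset:
    """Genotypes plus sample metadata plus the immutable truth block."""

    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    truth: pd.DataFrame
    locus_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        lon = self.truth["true_lon"].to_numpy()
        lat = self.truth["true_lat"].to_numpy()
        q_cols = [c for c in self.truth.columns if c.startswith("q")]
        if q_cols:
            s = self.truth[q_cols].to_numpy().sum(axis=1)
            if not np.allclose(s, 1.0, atol=1e-8):
                raise ValueError("truth ancestry vectors must sum to 1")
        del lon, lat


@dataclass
class TradeScenario:
    """Known-truth trade scenario: who was moved where, from where."""

    query_ids: list[str]
    seizure_coords: pd.DataFrame  # sampleID, lon, lat, clipped
    true_source_coords: pd.DataFrame  # sampleID, lon, lat
    market_type: str = "long_range_market"


def _standardize_coords(lons, lats, bounds):
    lon_min, lon_max, lat_min, lat_max = bounds
    u = 2.0 * (lons - (lon_min + lon_max) / 2.0) / (lon_max - lon_min)
    v = 2.0 * (lats - (lat_min + lat_max) / 2.0) / (lat_max - lat_min)
    return u, v


def _contig_layout(n_loci: int, loci_per_contig: int, rng):
    """Assign loci to synthetic bait contigs with increasing positions."""
    contigs, positions = [], []
    for j in range(n_loci):
        contigs.append(f"locus{j // loci_per_contig:04d}")
    contigs = np.array(contigs)
    positions = np.empty(n_loci, dtype=int)
    for ctg in pd.unique(contigs):
        m = contigs == ctg
        positions[m] = 100 + np.cumsum(rng.integers(50, 500, size=m.sum()))
    return contigs, positions


def _sample_polymorphic(rng, draw_freqs, n_samples: int, n_loci: int, max_rounds=50):
    """Draw Binomial(2, p) genotype columns, keeping only polymorphic ones.

    ``draw_freqs(rng, m)`` must return an (n_samples, m) matrix of per-sample
    allele frequencies for m fresh loci.
    """
    cols, extras = [], []
    need = n_loci
    for _ in range(max_rounds):
        p = draw_freqs(rng, need)
        g = rng.binomial(2, p).astype(np.int8)
        poly = (g.min(axis=0) < 2) & (g.max(axis=0) > 0)
        for j in np.nonzero(poly)[0]:
            cols.append(g[:, j])
            extras.append(p[:, j])
            if len(cols) == n_loci:
                return np.column_stack(cols), np.column_stack(extras)
        need = n_loci - len(cols)
    raise RuntimeError("could not generate enough polymorphic loci")


def simulate_ibd_landscape(config: SimulationConfig, n_samples: int) -> SyntheticDataset:
    """Continuous IBD landscape: logistic allele-frequency clines.

    Per locus l the frequency surface is ``p_l(x, y) = expit(a_l + b_l*u
    + c_l*v)`` with (u, v) the standardized coordinates and slopes b, c
    drawn N(0, cline_strength^2). ``cline_strength = 0`` yields a
    spatially unstructured panmictic sample.
    """
    config.validate()
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lon_min, lon_max, lat_min, lat_max = config.landscape_bounds
    lons = rng.uniform(lon_min, lon_max, n_samples)
    lats = rng.uniform(lat_min, lat_max, n_samples)
    u, v = _standardize_coords(lons, lats, config.landscape_bounds)

    coeffs = []

    def draw_freqs(rng, m):
        # log-uniform base frequencies (1/x density, as under the neutral
        # site-frequency spectrum) with random allele-label orientation, so
        # rare variants are common and Tajima's D is centred near zero
        p0 = np.exp(rng.uniform(np.log(0.02), np.log(0.5), m))
        flip = rng.random(m) < 0.5
        a = np.where(flip, -logit(p0), logit(p0))
        b = rng.normal(0.0, 1.0, m) * config.cline_strength
        c = rng.normal(0.0, 1.0, m) * config.cline_strength
        coeffs.append(np.column_stack([a, b, c]))
        return expit(a[None, :] + b[None, :] * u[:, None] + c[None, :] * v[:, None])

    dosage, freqs = _sample_polymorphic(rng, draw_freqs, n_samples, config.n_loci)
    contigs, positions = _contig_layout(config.n_loci, config.loci_per_contig, rng)
    ids = [f"S{i:04d}" for i in range(n_samples)]
    gm = GenotypeMatrix(dosage, ids, contigs, positions)
    samples = make_sample_table(ids, lons, lats, ["field_site"] * n_samples)
    truth = pd.DataFrame(
        {"sampleID": ids, "true_lon": lons, "true_lat": lats, "cluster": 0, "q0": 1.0}
    )
    return SyntheticDataset(gm, samples, truth, {"freq_surface": freqs})


def _cluster_centers(bounds, k: int) -> np.ndarray:
    lon_min, lon_max, lat_min, lat_max = bounds
    lon_span, lat_span = lon_max - lon_min, lat_max - lat_min
    if k == 1:
        return np.array([[lon_min + lon_span / 2, lat_min + lat_span / 2]])
    lons = np.linspace(lon_min + 0.15 * lon_span, lon_max - 0.15 * lon_span, k)
    lats = np.where(
        np.arange(k) % 2 == 0, lat_min + 0.25 * lat_span, lat_max - 0.25 * lat_span
    )
    return np.column_stack([lons, lats])


def simulate_clusters(config: SimulationConfig, n_per_cluster) -> SyntheticDataset:
    """Discrete spatially separated clusters under the Balding–Nichols model."""
    config.validate()
    n_per_cluster = list(n_per_cluster)
    k = len(n_per_cluster)
    if k < 1 or any(n <= 0 for n in n_per_cluster):
        raise ValueError("every cluster must contain at least one sample")
    if config.drift_f == 0.0 and k > 1:
        warnings.warn("drift_f = 0 with K > 1: clusters are indistinguishable")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    centers = _cluster_centers(config.landscape_bounds, k)
    lon_min, lon_max, lat_min, lat_max = config.landscape_bounds
    sd_lon = 0.05 * (lon_max - lon_min)
    sd_lat = 0.05 * (lat_max - lat_min)

    labels = np.repeat(np.arange(k), n_per_cluster)
    n = labels.size
    lons = np.clip(centers[labels, 0] + rng.normal(0, sd_lon, n), lon_min, lon_max)
    lats = np.clip(centers[labels, 1] + rng.normal(0, sd_lat, n), lat_min, lat_max)

    F = config.drift_f
    cluster_freqs = []

    def draw_freqs(rng, m):
        p_anc = rng.uniform(0.1, 0.9, m)
        if F > 0:
            fk = rng.beta(
                p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F, size=(k, m)
            )
            fk = np.clip(fk, 1e-6, 1 - 1e-6)
        else:
            fk = np.tile(p_anc, (k, 1))
        cluster_freqs.append(fk)
        return fk[labels, :]

    dosage, _ = _sample_polymorphic(rng, draw_freqs, n, config.n_loci)
    contigs, positions = _contig_layout(config.n_loci, config.loci_per_contig, rng)
    ids = [f"S{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(dosage, ids, contigs, positions)
    samples = make_sample_table(ids, lons, lats, ["field_site"] * n)
    truth = pd.DataFrame({"sampleID": ids, "true_lon": lons, "true_lat": lats})
    truth["cluster"] = labels
    for kk in range(k):
        truth[f"q{kk}"] = (labels == kk).astype(float)
    return SyntheticDataset(gm, samples, truth, {"centers": centers})


def simulate_admixture_zone(config: SimulationConfig, transect_samples: int) -> SyntheticDataset:
    """Two parental clusters joined by a sigmoidal ancestry cline.

    Samples sit on a longitudinal transect; each allele copy picks its
    parental ancestry Bernoulli(q) where q rises from ~0 to ~1 across
    ``admixture_zone_width`` km around the landscape midline.
    """
    config.validate()
    if config.n_clusters != 2:
        raise ValueError("admixture zone requires exactly 2 parental clusters")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lon_min, lon_max, lat_min, lat_max = config.landscape_bounds
    lons = np.sort(rng.uniform(lon_min, lon_max, transect_samples))
    mid_lat = (lat_min + lat_max) / 2.0
    lats = np.clip(
        mid_lat + rng.normal(0, 0.02 * (lat_max - lat_min), transect_samples),
        lat_min,
        lat_max,
    )
    mid_lon = (lon_min + lon_max) / 2.0
    signed_km = np.where(lons >= mid_lon, 1.0, -1.0) * haversine_km(
        lons, lats, mid_lon, lats
    )
    q = expit(4.0 * signed_km / config.admixture_zone_width)

    F = max(config.drift_f, 1e-6)
    parent_freqs = []

    def draw_freqs(rng, m):
        p_anc = rng.uniform(0.1, 0.9, m)
        fk = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F, size=(2, m))
        fk = np.clip(fk, 1e-6, 1 - 1e-6)
        parent_freqs.append(fk)
        # per-allele mixture: P(alt) = q*f1 + (1-q)*f0, two independent copies
        return q[:, None] * fk[1][None, :] + (1 - q)[:, None] * fk[0][None, :]

    dosage, _ = _sample_polymorphic(rng, draw_freqs, transect_samples, config.n_loci)
    contigs, positions = _contig_layout(config.n_loci, config.loci_per_contig, rng)
    ids = [f"S{i:04d}" for i in range(transect_samples)]
    gm = GenotypeMatrix(dosage, ids, contigs, positions)
    samples = make_sample_table(ids, lons, lats, ["field_site"] * transect_samples)
    truth = pd.DataFrame(
        {
            "sampleID": ids,
            "true_lon": lons,
            "true_lat": lats,
            "cluster": (q > 0.5).astype(int),
            "q0": 1.0 - q,
            "q1": q,
        }
    )
    return SyntheticDataset(
        gm, samples, truth, {"parent_freqs": np.concatenate(parent_freqs, axis=1)[:, : config.n_loci]}
    )


def inject_missingness(dataset: SyntheticDataset, config: SimulationConfig) -> SyntheticDataset:
    """Set genotypes missing with each sample's site-type-specific rate."""
    for st, rate in config.missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {st!r} outside [0, 1]")
    present = set(dataset.samples["site_type"])
    lacking = present - set(config.missing_rates)
    if lacking:
        raise ValueError(f"missing_rates undefined for site types: {sorted(lacking)}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    gm = dataset.genotypes.copy()
    rates = dataset.samples["site_type"].map(config.missing_rates).to_numpy()
    mask = rng.random(gm.dosage.shape) < rates[:, None]
    gm.dosage[mask] = MISSING
    return SyntheticDataset(gm, dataset.samples.copy(), dataset.truth, dataset.locus_truth)


def make_trade_scenario(
    dataset: SyntheticDataset,
    n_queries: int,
    displacement_km_dist,
    seed: int,
    market_type: str = "long_range_market",
) -> TradeScenario:
    """Convert ``n_queries`` samples into traded queries with known true sources.

    ``displacement_km_dist`` may be a scalar (fixed km), a (low, high)
    tuple (uniform km), or a callable ``f(rng, n) -> km array``. Seizure
    points are the true origins displaced along a random bearing;
    displacements leaving the landscape are clipped to its bounds and
    flagged. The chosen samples' site_type becomes ``market_type`` and
    their table coordinates become the seizure point, so they drop out
    of the reference set; the truth block is left untouched.
    """
    n = dataset.genotypes.n_samples
    if n_queries > n:
        raise ValueError("more queries requested than samples available")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    qidx = np.sort(rng.choice(n, size=n_queries, replace=False))
    if callable(displacement_km_dist):
        disp = np.asarray(displacement_km_dist(rng, n_queries), dtype=float)
    elif np.isscalar(displacement_km_dist):
        disp = np.full(n_queries, float(displacement_km_dist))
    else:
        lo, hi = displacement_km_dist
        disp = rng.uniform(lo, hi, n_queries)
    bearings = rng.uniform(0.0, 360.0, n_queries)

    lon_min, lon_max, lat_min, lat_max = (
        dataset.samples["x"].min(),
        dataset.samples["x"].max(),
        dataset.samples["y"].min(),
        dataset.samples["y"].max(),
    )
    ids, seiz, clipped = [], [], []
    truth_idx = dataset.truth.set_index("sampleID")
    for i, d, b in zip(qidx, disp, bearings):
        sid = dataset.genotypes.sample_ids[i]
        tlon = truth_idx.at[sid, "true_lon"]
        tlat = truth_idx.at[sid, "true_lat"]
        slon, slat = destination_point(tlon, tlat, b, d)
        clip = not (lon_min <= slon <= lon_max and lat_min <= slat <= lat_max)
        if clip:
            slon = min(max(slon, lon_min), lon_max)
            slat = min(max(slat, lat_min), lat_max)
        ids.append(sid)
        seiz.append((slon, slat))
        clipped.append(clip)

    samples = dataset.samples
    sel = samples["sampleID"].isin(ids)
    samples.loc[sel, "site_type"] = market_type
    order = {sid: k for k, sid in enumerate(ids)}
    rows = samples.loc[sel, "sampleID"].map(order).to_numpy()
    seiz_arr = np.asarray(seiz)
    samples.loc[sel, "x"] = seiz_arr[rows, 0]
    samples.loc[sel, "y"] = seiz_arr[rows, 1]
    samples.loc[sel, "is_reference"] = False

    seizure_df = pd.DataFrame(
        {"sampleID": ids, "lon": seiz_arr[:, 0], "lat": seiz_arr[:, 1], "clipped": clipped}
    )
    source_df = pd.DataFrame(
        {
            "sampleID": ids,
            "lon": [truth_idx.at[s, "true_lon"] for s in ids],
            "lat": [truth_idx.at[s, "true_lat"] for s in ids],
        }
    )
    return TradeScenario(ids, seizure_df, source_df, market_type)


def write_dataset(dataset: SyntheticDataset, vcf_path, samples_path) -> None:
    """Serialize to VCF v4.2 (GT-only) plus the sample-table TSV."""
    io.write_vcf(dataset.genotypes, vcf_path)
    io.write_sample_table(dataset.samples, samples_path)
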