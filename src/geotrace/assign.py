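"""Continuous-space geographic origin assignment.

A feed-forward network is trained to regress standardized (longitude,
latitude) on SNP dosages of geo-referenced reference samples (field
sites and restricted-range markets), then predicts coordinates for
query samples of unknown origin (long-range markets, seizures). An
ensemble of B bootstrap replicates — each resampling SNP columns with
replacement and retraining from a fresh seed — yields a cloud of
predicted points per query whose arithmetic-mean centroid is the point
estimate and whose mean great-circle distance to that centroid
("prediction variability") is a per-query confidence proxy.

Three validation schemes measure assignment error against known truth:
a spatially stratified one-third hold-out, leave-one-out
cross-validation (one retraining per held sample, no bootstrap), and
the fraction of held samples recovered within a given radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .geodesy import haversine_km
from .nn import MLPRegressor


@dataclass
class AssignmentModelConfig:
    """Network and training hyperparameters.

    Defaults follow the continuous-assignment family's conventions:
    dropout 0.25 and an early-stopping patience of 100 epochs guard
    against overfitting the small reference panels typical of wildlife
    datasets. ``train_fraction`` is the share of references used for
    gradient steps; the rest form the early-stopping validation split.
    """

    hidden_layers: int = 4
    hidden_width: int = 128
    dropout_rate: float = 0.25
    early_stop_patience: int = 100
    max_epochs: int = 1000
    train_fraction: float = 0.9
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class GenotypeEncoder:
    """Training-set encoding: per-site mean imputation, drop zero-variance sites."""

    kept_sites: np.ndarray
    site_means: np.ndarray

    def transform(self, matrix: GenotypeMatrix) -> np.ndarray:
        X = matrix.dosage_float()[:, self.kept_sites]
        fully_missing = np.isnan(X).all(axis=1)
        if fully_missing.any():
            warnings.warn(
                f"{int(fully_missing.sum())} sample(s) have no called genotypes at "
                "model sites and are effectively unassignable"
            )
        return np.where(np.isnan(X), self.site_means[None, :], X)


def encode_genotypes(train_matrix: GenotypeMatrix, query_matrix: GenotypeMatrix | None = None):
    """Fit the encoder on training samples and transform both sets.

    Returns (X_train, X_query or None, encoder).
    """
    G = train_matrix.dosage_float()
    means = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns -> NaN mean, dropped below
        var = np.nanvar(G, axis=0)
    keep = np.nonzero(np.nan_to_num(var, nan=0.0) > 0)[0]
    if keep.size < G.shape[1]:
        warnings.warn(f"dropping {G.shape[1] - keep.size} zero-variance/empty site(s)")
    enc = GenotypeEncoder(kept_sites=keep, site_means=means[keep])
    Xtr = enc.transform(train_matrix)
    Xq = enc.transform(query_matrix) if query_matrix is not None else None
    return Xtr, Xq, enc


@dataclass
class AssignmentFit:
    """A single trained network plus the coordinate scaler."""

    net: MLPRegressor
    coord_mean: np.ndarray
    coord_scale: np.ndarray
    val_loss: float
    epochs: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted (lon, lat) for encoded feature rows."""
        z = self.net.predict(np.asarray(X, float))
        return z * self.coord_scale[None, :] + self.coord_mean[None, :]


def train_assignment_model(features: np.ndarray, coords: np.ndarray,
                           config: AssignmentModelConfig) -> AssignmentFit:
    """Train one network on encoded features and (lon, lat) coordinates."""
    config.validate()
    X = np.asarray(features, float)
    Y = np.asarray(coords, float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 geo-referenced training samples")
    mean = Y.mean(axis=0)
    scale = np.maximum(Y.std(axis=0), 1e-8)
    Yz = (Y - mean) / scale

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    n_val = max(1, int(round((1.0 - config.train_fraction) * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training samples")
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    net = MLPRegressor(X.shape[1], 2, config.hidden_layers, config.hidden_width, rng)
    val_loss, epochs = net.fit(
        X[tr_idx], Yz[tr_idx], X[val_idx], Yz[val_idx],
        max_epochs=config.max_epochs, patience=config.early_stop_patience,
        learning_rate=config.learning_rate, dropout_rate=config.dropout_rate, rng=rng,
    )
    return AssignmentFit(net, mean, scale, val_loss, epochs)


@dataclass
class AssignmentResults:
    """Bootstrap ensemble output for a set of queries."""

    query_ids: list[str]
    bootstrap_predictions: np.ndarray  # B x n_queries x 2 (lon, lat)
    B: int

    @property
    def centroids(self) -> np.ndarray:
        """Arithmetic mean of the bootstrap cloud per query (lon, lat)."""
        return self.bootstrap_predictions.mean(axis=0)

    def variability_km(self) -> np.ndarray:
        """Mean great-circle distance of each bootstrap point to its centroid."""
        if self.B < 2:
            raise ValueError("prediction variability needs B >= 2 replicates")
        cent = self.centroids
        d = haversine_km(
            self.bootstrap_predictions[:, :, 0], self.bootstrap_predictions[:, :, 1],
            cent[None, :, 0], cent[None, :, 1],
        )
        return d.mean(axis=0)

    def table(self) -> pd.DataFrame:
        cent = self.centroids
        var = self.variability_km() if self.B >= 2 else np.full(len(self.query_ids), np.nan)
        return pd.DataFrame(
            {
                "sampleID": self.query_ids,
                "centroid_lon": cent[:, 0],
                "centroid_lat": cent[:, 1],
                "variability_km": var,
                "B": self.B,
            }
        )

    def long_table(self) -> pd.DataFrame:
        B, nq, _ = self.bootstrap_predictions.shape
        return pd.DataFrame(
            {
                "sampleID": np.tile(self.query_ids, B),
                "replicate": np.repeat(np.arange(B), nq),
                "lon": self.bootstrap_predictions[:, :, 0].ravel(),
                "lat": self.bootstrap_predictions[:, :, 1].ravel(),
            }
        )

    def summary(self) -> str:
        var = self.variability_km() if self.B >= 2 else None
        lines = [
            "Geographic assignment (bootstrap ensemble)",
            f"  queries:             {len(self.query_ids)}",
            f"  bootstrap replicates: {self.B}",
        ]
        if var is not None:
            lo, hi = np.percentile(var, [2.5, 97.5])
            lines.append(f"  prediction variability: mean {var.mean():.1f} km "
                         f"(95% interval {lo:.1f}-{hi:.1f} km)")
        return "\n".join(lines)


class AssignmentModel:
    """Continuous-space assignment model over a genotype dataset.

    Built from the full dataset plus the sample table; reference rows
    (trusted coordinates) train the network, query rows are predicted.
    """

    def __init__(self, genotypes: GenotypeMatrix, samples: pd.DataFrame,
                 config: AssignmentModelConfig | None = None):
        self.config = config or AssignmentModelConfig()
        ids = list(genotypes.sample_ids)
        meta = samples.set_index("sampleID").loc[ids]
        is_ref = meta["is_reference"].to_numpy(bool)
        self.ref_idx = np.nonzero(is_ref)[0]
        self.query_idx = np.nonzero(~is_ref)[0]
        self.genotypes = genotypes
        self.ref_coords = meta.loc[is_ref, ["x", "y"]].to_numpy(float)
        self.query_ids = [ids[i] for i in self.query_idx]
        ref = genotypes.take_samples(self.ref_idx)
        query = genotypes.take_samples(self.query_idx) if self.query_idx.size else None
        self.X_ref, self.X_query, self.encoder = encode_genotypes(ref, query)

    def fit(self, seed: int | None = None) -> AssignmentFit:
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        return train_assignment_model(self.X_ref, self.ref_coords, cfg)

    def fit_bootstrap(self, B: int = 100) -> AssignmentResults:
        return bootstrap_assign(
            self.X_ref, self.ref_coords, self.X_query, B=B, config=self.config,
            query_ids=self.query_ids,
        )


def bootstrap_assign(train_features: np.ndarray, coords: np.ndarray,
                     query_features: np.ndarray, B: int = 100,
                     config: AssignmentModelConfig | None = None,
                     query_ids=None) -> AssignmentResults:
    """Bootstrap ensemble: resample SNP columns with replacement, retrain
    from a fresh derived seed, and predict all queries, B times."""
    config = config or AssignmentModelConfig()
    if query_features is None or len(query_features) == 0:
        raise ValueError("no query samples to assign")
    nq = query_features.shape[0]
    if query_ids is None:
        query_ids = [f"Q{i}" for i in range(nq)]
    ss = np.random.SeedSequence([config.seed, 7])
    preds = np.empty((B, nq, 2))
    L = train_features.shape[1]
    for rep, rep_ss in enumerate(ss.spawn(B)):
        if B == 1:  # degenerate ensemble: one plain deterministic model
            cols = np.arange(L)
            rep_cfg = config
        else:
            rng = np.random.default_rng(rep_ss)
            cols = rng.integers(0, L, size=L)
            rep_cfg = replace(config, seed=int(rng.integers(2**31 - 1)))
        fit = train_assignment_model(train_features[:, cols], coords, rep_cfg)
        preds[rep] = fit.predict(query_features[:, cols])
    return AssignmentResults(list(query_ids), preds, B)


def prediction_variability(result: AssignmentResults) -> pd.DataFrame:
    """Per-query variability (km) plus ensemble-level summaries."""
    var = result.variability_km()
    return pd.DataFrame({"sampleID": result.query_ids, "variability_km": var})


@dataclass
class ValidationReport:
    """Held-out assignment errors under one validation scheme."""

    scheme: str
    table: pd.DataFrame  # sampleID, true/pred coords, error_km

    def summary(self, radii_km=(500.0, 1000.0)) -> dict:
        e = self.table["error_km"].to_numpy()
        out = {
            "scheme": self.scheme,
            "n": int(e.size),
            "mean_km": float(e.mean()),
            "median_km": float(np.median(e)),
            "q2.5_km": float(np.percentile(e, 2.5)),
            "q97.5_km": float(np.percentile(e, 97.5)),
        }
        for r in radii_km:
            out[f"fraction_within_{int(r)}km"] = fraction_within(self, r)
        return out


def fraction_within(report: ValidationReport, radius_km: float = 500.0) -> float:
    """Share of held-out samples assigned within ``radius_km`` of truth."""
    e = report.table["error_km"].to_numpy()
    if e.size == 0:
        raise ValueError("empty validation report")
    return float(np.mean(e <= radius_km))


def _spatial_bins(coords: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Equal-sized grid bins over the reference extent (bin id per sample)."""
    lon, lat = coords[:, 0], coords[:, 1]
    lon_edges = np.linspace(lon.min(), lon.max() + 1e-9, n_bins + 1)
    lat_edges = np.linspace(lat.min(), lat.max() + 1e-9, n_bins + 1)
    bi = np.clip(np.digitize(lon, lon_edges) - 1, 0, n_bins - 1)
    bj = np.clip(np.digitize(lat, lat_edges) - 1, 0, n_bins - 1)
    return bi * n_bins + bj


def one_third_holdout(genotypes: GenotypeMatrix, samples: pd.DataFrame,
                      config: AssignmentModelConfig | None = None,
                      fraction: float = 1.0 / 3.0, n_bins: int = 4,
                      seed: int = 0, B: int = 1) -> ValidationReport:
    """Hold out ~``fraction`` of references, stratified over spatial grid
    bins so the held set spans the sampled range, and measure the
    great-circle error of each held sample's predicted centroid."""
    config = config or AssignmentModelConfig()
    meta = samples.set_index("sampleID").loc[list(genotypes.sample_ids)]
    ref_idx = np.nonzero(meta["is_reference"].to_numpy(bool))[0]
    if ref_idx.size < 3:
        raise ValueError("too few reference samples for a hold-out")
    coords = meta.iloc[ref_idx][["x", "y"]].to_numpy(float)
    bins = _spatial_bins(coords, n_bins)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    # largest-remainder allocation over occupied bins: the held set totals
    # round(fraction * n_refs) while spanning the sampled range
    occupied = [np.nonzero(bins == b)[0] for b in np.unique(bins)]
    eligible = [m for m in occupied if m.size >= 2]
    if len(eligible) < len(occupied):
        warnings.warn("singleton spatial bin(s) kept entirely in training")
    target = int(round(fraction * ref_idx.size))
    caps = np.array([m.size - 1 for m in eligible])
    target = min(target, int(caps.sum()))
    quota = np.array([fraction * m.size for m in eligible])
    alloc = np.minimum(np.floor(quota).astype(int), caps)
    remainder = quota - np.floor(quota)
    order = np.argsort(-remainder)
    i = 0
    while alloc.sum() < target:
        b = order[i % len(order)]
        if alloc[b] < caps[b]:
            alloc[b] += 1
        i += 1
    held = []
    for m, k in zip(eligible, alloc):
        if k > 0:
            held.extend(rng.choice(m, size=k, replace=False))
    held = np.sort(np.asarray(held, dtype=int))
    if held.size == 0:
        raise ValueError("hold-out selected no samples; too few references per bin")
    train_local = np.setdiff1d(np.arange(ref_idx.size), held)

    train_gm = genotypes.take_samples(ref_idx[train_local])
    held_gm = genotypes.take_samples(ref_idx[held])
    Xtr, Xq, _ = encode_genotypes(train_gm, held_gm)
    cfg = replace(config, seed=int(rng.integers(2**31 - 1)))
    if B > 1:
        res = bootstrap_assign(Xtr, coords[train_local], Xq, B=B, config=cfg)
        pred = res.centroids
    else:
        pred = train_assignment_model(Xtr, coords[train_local], cfg).predict(Xq)
    true = coords[held]
    err = haversine_km(true[:, 0], true[:, 1], pred[:, 0], pred[:, 1])
    table = pd.DataFrame(
        {
            "sampleID": [genotypes.sample_ids[i] for i in ref_idx[held]],
            "true_lon": true[:, 0], "true_lat": true[:, 1],
            "pred_lon": pred[:, 0], "pred_lat": pred[:, 1],
            "error_km": np.atleast_1d(err),
        }
    )
    return ValidationReport("one_third_holdout", table)


def loocv(genotypes: GenotypeMatrix, samples: pd.DataFrame,
          config: AssignmentModelConfig | None = None, seed: int = 0) -> ValidationReport:
    """Leave-one-out cross-validation: one retraining per reference sample
    (no bootstrap), yielding a spatially localized error per reference."""
    config = config or AssignmentModelConfig()
    meta = samples.set_index("sampleID").loc[list(genotypes.sample_ids)]
    ref_idx = np.nonzero(meta["is_reference"].to_numpy(bool))[0]
    if ref_idx.size < 3:
        raise ValueError("LOOCV needs at least 3 references")
    coords = meta.iloc[ref_idx][["x", "y"]].to_numpy(float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    rows = []
    for k in range(ref_idx.size):
        keep = np.delete(np.arange(ref_idx.size), k)
        train_gm = genotypes.take_samples(ref_idx[keep])
        held_gm = genotypes.take_samples(ref_idx[[k]])
        Xtr, Xq, _ = encode_genotypes(train_gm, held_gm)
        cfg = replace(config, seed=int(rng.integers(2**31 - 1)))
        pred = train_assignment_model(Xtr, coords[keep], cfg).predict(Xq)[0]
        true = coords[k]
        rows.append(
            (
                genotypes.sample_ids[ref_idx[k]], true[0], true[1], pred[0], pred[1],
                haversine_km(true[0], true[1], pred[0], pred[1]),
            )
        )
    table = pd.DataFrame(
        rows, columns=["sampleID", "true_lon", "true_lat", "pred_lon", "pred_lat", "error_km"]
    )
    return ValidationReport("loocv", table)
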