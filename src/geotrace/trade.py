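"""Trade summaries and sourcing-hotspot surfaces.

Trade distance is the great-circle distance between a traded sample's
seizure/market sampling point and the centroid of its bootstrap
predicted origins; distances are summarized per site-type group.
Hotspots are a 2-D Gaussian kernel density over all bootstrap predicted
points (degree space, Scott bandwidth with a floor), normalized to
integrate to 1 over the evaluation grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assign import AssignmentResults, ValidationReport
from .geodesy import haversine_km

MIN_BANDWIDTH_DEG = 0.05


@dataclass
class TradeSummary:
    per_query: pd.DataFrame  # sampleID, site_type, seizure/centroid coords, trade_distance_km
    by_group: pd.DataFrame  # site_type, n, mean, min, max
    n_unknown_location: int

    def summary(self) -> str:
        lines = ["Trade-distance summary (seizure point to predicted source centroid)"]
        for _, row in self.by_group.iterrows():
            lines.append(
                f"  {row['site_type']:<24s} n={int(row['n']):<4d} "
                f"mean={row['mean_km']:.1f} km  range {row['min_km']:.1f}-{row['max_km']:.1f} km"
            )
        if self.n_unknown_location:
            lines.append(f"  (excluded, unknown seizure point: {self.n_unknown_location})")
        return "\n".join(lines)


def trade_distances(assignments: AssignmentResults, seizure_coords: pd.DataFrame,
                    site_types: pd.Series | dict | None = None) -> TradeSummary:
    """Per-query trade distances plus grouped summaries.

    ``seizure_coords`` needs columns sampleID, lon, lat; queries absent
    from it (or with NaN coordinates) are counted as unknown-location and
    excluded from distances.
    """
    cent = assignments.table().set_index("sampleID")
    seiz = seizure_coords.set_index("sampleID")
    rows, n_unknown = [], 0
    for sid in assignments.query_ids:
        if sid not in seiz.index or np.isnan(seiz.at[sid, "lon"]):
            n_unknown += 1
            continue
        slon, slat = float(seiz.at[sid, "lon"]), float(seiz.at[sid, "lat"])
        clon, clat = cent.at[sid, "centroid_lon"], cent.at[sid, "centroid_lat"]
        st = "unknown"
        if site_types is not None:
            st = site_types[sid] if sid in site_types else "unknown"
        rows.append(
            (sid, st, slon, slat, clon, clat, haversine_km(slon, slat, clon, clat))
        )
    per_query = pd.DataFrame(
        rows,
        columns=[
            "sampleID", "site_type", "seizure_lon", "seizure_lat",
            "centroid_lon", "centroid_lat", "trade_distance_km",
        ],
    )
    if len(per_query):
        by_group = (
            per_query.groupby("site_type")["trade_distance_km"]
            .agg(n="size", mean_km="mean", min_km="min", max_km="max")
            .reset_index()
        )
    else:
        by_group = pd.DataFrame(columns=["site_type", "n", "mean_km", "min_km", "max_km"])
    return TradeSummary(per_query, by_group, n_unknown)


@dataclass
class DensitySurface:
    lon_grid: np.ndarray  # length nx
    lat_grid: np.ndarray  # length ny
    density: np.ndarray  # ny x nx, integrates to 1 over the grid
    bandwidth: tuple

    def integral(self) -> float:
        dlon = self.lon_grid[1] - self.lon_grid[0] if len(self.lon_grid) > 1 else 1.0
        dlat = self.lat_grid[1] - self.lat_grid[0] if len(self.lat_grid) > 1 else 1.0
        return float(self.density.sum() * dlon * dlat)

    def argmax(self) -> tuple[float, float]:
        j, i = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return float(self.lon_grid[i]), float(self.lat_grid[j])

    def to_table(self) -> pd.DataFrame:
        lon, lat = np.meshgrid(self.lon_grid, self.lat_grid)
        return pd.DataFrame(
            {"lon": lon.ravel(), "lat": lat.ravel(), "density": self.density.ravel()}
        )


def hotspot_density(points: np.ndarray, grid_shape=(120, 120), bandwidth=None,
                    pad_deg: float = 0.5) -> DensitySurface:
    """Gaussian product-kernel KDE of predicted source points (degree space).

    ``points`` is (n, 2) lon/lat. Bandwidth defaults to Scott's rule per
    axis with a floor of 0.05 degrees (so a degenerate cloud yields a
    delta-like but finite surface). The returned density is renormalized
    to integrate to 1 over the evaluation grid.
    """
    pts = np.asarray(points, float)
    if pts.shape[0] < 2:
        raise ValueError("KDE needs at least 2 points")
    n = pts.shape[0]
    scott = n ** (-1.0 / 6.0)
    if bandwidth is None:
        bw = tuple(max(scott * pts[:, k].std(), MIN_BANDWIDTH_DEG) for k in (0, 1))
    else:
        bw = (float(bandwidth), float(bandwidth))
    nx, ny = grid_shape
    lon_grid = np.linspace(pts[:, 0].min() - pad_deg, pts[:, 0].max() + pad_deg, nx)
    lat_grid = np.linspace(pts[:, 1].min() - pad_deg, pts[:, 1].max() + pad_deg, ny)
    lon, lat = np.meshgrid(lon_grid, lat_grid)
    # manual product kernel: scipy's gaussian_kde shares one bandwidth matrix,
    # while the floor must apply per axis for degenerate clouds
    zx = (lon.ravel()[None, :] - pts[:, 0][:, None]) / bw[0]
    zy = (lat.ravel()[None, :] - pts[:, 1][:, None]) / bw[1]
    dens = np.exp(-0.5 * (zx**2 + zy**2)).sum(axis=0) / (2 * np.pi * bw[0] * bw[1] * n)
    dens = dens.reshape(ny, nx)
    dlon = lon_grid[1] - lon_grid[0]
    dlat = lat_grid[1] - lat_grid[0]
    total = dens.sum() * dlon * dlat
    return DensitySurface(lon_grid, lat_grid, dens / total, bw)


def write_report(out_dir, assignments: AssignmentResults | None = None,
                 validations: list[ValidationReport] | None = None,
                 trade: TradeSummary | None = None,
                 density: DensitySurface | None = None,
                 run_info: dict | None = None) -> dict:
    """Write the machine-readable TSV/JSON bundle; absent sections are
    marked explicitly in the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"sections": {}}
    if assignments is not None:
        assignments.table().to_csv(out / "assignments.tsv", sep="\t", index=False)
        assignments.long_table().to_csv(out / "assignments_bootstrap.tsv", sep="\t", index=False)
        manifest["sections"]["assignments"] = "assignments.tsv"
    else:
        manifest["sections"]["assignments"] = None
    if validations:
        summaries = []
        for rep in validations:
            rep.table.to_csv(out / f"validation_{rep.scheme}.tsv", sep="\t", index=False)
            summaries.append(rep.summary())
        pd.DataFrame(summaries).to_csv(out / "validation_summary.tsv", sep="\t", index=False)
        manifest["sections"]["validation"] = "validation_summary.tsv"
    else:
        manifest["sections"]["validation"] = None
    if trade is not None:
        trade.per_query.to_csv(out / "trade_distances.tsv", sep="\t", index=False)
        trade.by_group.to_csv(out / "trade_summary.tsv", sep="\t", index=False)
        manifest["sections"]["trade"] = "trade_summary.tsv"
    else:
        manifest["sections"]["trade"] = None
    if density is not None:
        density.to_table().to_csv(out / "hotspot_density.tsv", sep="\t", index=False)
        manifest["sections"]["hotspot_density"] = "hotspot_density.tsv"
    else:
        manifest["sections"]["hotspot_density"] = None
    manifest["run_info"] = run_info or {}
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
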