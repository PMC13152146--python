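"""Core in-memory containers: the dosage matrix and the sample table.

Genotypes are biallelic dosages (count of the alternate allele, 0/1/2)
stored as int8 with -1 for a missing call. The sample table is a pandas
DataFrame with the Locator-style column convention:
``sampleID, x (longitude), y (latitude; NaN when unknown), site_type``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: site-types whose coordinates are trusted and usable as references
REFERENCE_SITE_TYPES = ("field_site", "restricted_range_market")
#: site-types whose samples are queries for origin tracing
QUERY_SITE_TYPES = ("long_range_market", "seizure", "unknown")


@dataclass
class GenotypeMatrix:
    """Rectangular individuals x sites dosage matrix.

    Parameters
    ----------
    dosage : int8 array, shape (n_samples, n_sites)
        Alternate-allele counts in {0, 1, 2}; -1 marks a missing call.
    sample_ids : list of str
    contigs, positions : per-site location; sites must be sorted by
        (contig, position) with strictly increasing positions per contig.
    """

    dosage: np.ndarray
    sample_ids: list[str]
    contigs: np.ndarray
    positions: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x sites)")
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosage entries must be in {0,1,2} or -1 (missing)")
        self.contigs = np.asarray(self.contigs)
        self.positions = np.asarray(self.positions, dtype=int)
        if len(self.sample_ids) != self.dosage.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if len(self.positions) != self.dosage.shape[1]:
            raise ValueError("site annotation length mismatch")
        for ctg in pd.unique(self.contigs):
            pos = self.positions[self.contigs == ctg]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {ctg}")
        if self.ref is None:
            self.ref = np.full(self.n_sites, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(self.n_sites, "T", dtype=object)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    @property
    def site_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.contigs, self.positions)]

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes."""
        return self.dosage != MISSING

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing calls."""
        out = self.dosage.astype(float)
        out[self.dosage == MISSING] = np.nan
        return out

    def sample_missingness(self) -> np.ndarray:
        return 1.0 - self.called().mean(axis=1)

    def site_missingness(self) -> np.ndarray:
        return 1.0 - self.called().mean(axis=0)

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alternate-allele frequency over called genotypes (NaN if none)."""
        called = self.called()
        alt = np.where(called, self.dosage, 0).sum(axis=0).astype(float)
        chrom = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(chrom > 0, alt / chrom, np.nan)

    def minor_allele_counts(self) -> np.ndarray:
        """Count of the rarer allele among called genotypes, per site."""
        called = self.called()
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        chrom = 2 * called.sum(axis=0)
        return np.minimum(alt, chrom - alt)

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosage=self.dosage[idx],
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
        )

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            dosage=self.dosage[:, idx],
            contigs=self.contigs[idx],
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            dosage=self.dosage.copy(),
            sample_ids=list(self.sample_ids),
            contigs=self.contigs.copy(),
            positions=self.positions.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
        )


def make_sample_table(sample_ids, lons, lats, site_types) -> pd.DataFrame:
    """Assemble the Locator-style sample table (x=longitude, y=latitude)."""
    df = pd.DataFrame(
        {
            "sampleID": list(sample_ids),
            "x": np.asarray(lons, dtype=float),
            "y": np.asarray(lats, dtype=float),
            "site_type": list(site_types),
        }
    )
    df["is_reference"] = df["site_type"].isin(REFERENCE_SITE_TYPES) & df["y"].notna()
    return df
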