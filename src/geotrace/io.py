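"""VCF and sample-table I/O.

Genotypes travel as VCF v4.2 with a GT-only FORMAT field (missing calls
as ``./.``); reading goes through cyvcf2. Sample metadata is a TSV with
header ``sampleID  x  y  site_type`` (x = longitude, y = latitude, NA
allowed for unknown-origin samples).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=MD,Number=1,Type=Float,Description="Mean depth per site">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path, qual=None, mean_depth=None) -> None:
    """Write a GT-only VCF v4.2. ``qual``/``mean_depth`` are optional per-site arrays."""
    path = Path(path)
    n_sites = matrix.n_sites
    qual = np.full(n_sites, 99.0) if qual is None else np.asarray(qual, dtype=float)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for ctg in pd.unique(matrix.contigs):
            fh.write(f"##contig=<ID={ctg}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j in range(n_sites):
            info = "." if mean_depth is None else f"MD={mean_depth[j]:g}"
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.dosage[:, j])
            fh.write(
                f"{matrix.contigs[j]}\t{matrix.positions[j]}\t.\t{matrix.ref[j]}\t"
                f"{matrix.alt[j]}\t{qual[j]:g}\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a biallelic VCF into a GenotypeMatrix plus a per-site info table.

    The info table carries contig, position, variant_quality (QUAL), mean_depth
    (INFO/DP when present), is_indel and n_alleles for downstream filtering.
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, info = [], []
    for v in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=missing, 3=hom-alt
        gt = v.gt_types
        dos = np.where(gt == 2, MISSING, np.where(gt == 3, 2, gt)).astype(np.int8)
        rows.append(dos)
        alt = v.ALT[0] if v.ALT else ""
        info.append(
            {
                "contig": v.CHROM,
                "position": v.POS,
                "ref": v.REF,
                "alt": alt,
                "variant_quality": v.QUAL if v.QUAL is not None else np.nan,
                "mean_depth": v.INFO.get("MD", np.nan),
                "is_indel": v.is_indel,
                "n_alleles": 1 + len(v.ALT),
            }
        )
    vcf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")
    sites = pd.DataFrame(info)
    matrix = GenotypeMatrix(
        dosage=np.column_stack(rows) if rows else np.empty((len(sample_ids), 0)),
        sample_ids=sample_ids,
        contigs=sites["contig"].to_numpy(),
        positions=sites["position"].to_numpy(),
        ref=sites["ref"].to_numpy(dtype=object),
        alt=sites["alt"].to_numpy(dtype=object),
    )
    return matrix, sites


def write_sample_table(samples: pd.DataFrame, path) -> None:
    cols = ["sampleID", "x", "y", "site_type"]
    samples[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = {"sampleID", "x", "y", "site_type"} - set(df.columns)
    if missing:
        raise ValueError(f"sample table lacks columns: {sorted(missing)}")
    from .containers import REFERENCE_SITE_TYPES

    df["is_reference"] = df["site_type"].isin(REFERENCE_SITE_TYPES) & df["y"].notna()
    return df


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
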