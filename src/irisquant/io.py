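"""File interfaces: labelled regions, genotype/covariate/phenotype tables.

Genotypes are accepted either as a CSV (one row per individual, one column
per SNP, values 0/1/2 or blank) or as a biallelic VCF, in which case dosages
are recoded on the fly so 0/1/2 counts the *minor* allele in the file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import read_image, rgb_to_hsv
from .genetics import CovariateTable, GenotypeMatrix
from .quantification import CLASSES, ColourQuantification, LabeledPixelSet

__all__ = [
    "read_labelled_regions",
    "read_genotypes_csv",
    "read_genotypes_vcf",
    "read_covariates_csv",
    "quantifications_to_frame",
]

REGION_COLUMNS = ("image_path", "class", "row_min", "row_max", "col_min", "col_max")


def read_labelled_regions(csv_path: str | Path, images_dir: str | Path | None = None) -> LabeledPixelSet:
    """Load manually labelled rectangular iris regions into a training set.

    The CSV schema is ``image_path, class, row_min, row_max, col_min,
    col_max`` with inclusive pixel bounds; every rectangle's pixels are
    converted to HSV and labelled with the row's class.
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"labelled-region CSV is missing columns: {missing}")
    feats, labs, prov = [], [], []
    base = Path(images_dir) if images_dir else Path(csv_path).parent
    for path_str, group in df.groupby("image_path"):
        path = Path(path_str)
        if not path.is_absolute():
            path = base / path
        image = read_image(path)
        for _, row in group.iterrows():
            cls = row["class"]
            if cls not in CLASSES:
                raise ValueError(f"unknown pigment class {cls!r} in {csv_path}")
            patch = image.pixels[
                int(row.row_min): int(row.row_max) + 1,
                int(row.col_min): int(row.col_max) + 1,
            ].reshape(-1, 3)
            if patch.size == 0:
                raise ValueError(f"empty rectangle for {path_str}")
            feats.append(rgb_to_hsv(patch.astype(float)))
            labs.extend([cls] * len(patch))
        prov.append(str(path_str))
    return LabeledPixelSet(
        features=np.vstack(feats),
        labels=np.asarray(labs, dtype=object),
        provenance=tuple(prov),
    )


def read_genotypes_csv(path: str | Path, id_col: str = "sample_id") -> tuple[GenotypeMatrix, pd.Index]:
    """Individual × SNP dosage CSV → (GenotypeMatrix, sample index)."""
    df = pd.read_csv(path)
    if id_col not in df.columns:
        raise ValueError(f"genotype CSV must contain a {id_col!r} column")
    ids = pd.Index(df[id_col].astype(str))
    snp_cols = [c for c in df.columns if c != id_col]
    values = df[snp_cols].to_numpy(float)
    return GenotypeMatrix(values=values, snp_ids=tuple(snp_cols)), ids


def read_genotypes_vcf(path: str | Path) -> tuple[GenotypeMatrix, pd.Index]:
    """Biallelic VCF → minor-allele dosage matrix.

    Requires cyvcf2 (optional extra). ALT dosages are flipped per site
    wherever the ALT allele is the major one, so 0/1/2 always counts the
    minor allele.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = pd.Index(vcf.samples)
    snp_ids, cols, minors = [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        dosage = np.asarray(variant.gt_types, dtype=float)  # 0=hom-ref,1=het,2=unknown,3=hom-alt
        geno = np.where(dosage == 3, 2.0, dosage)
        geno[dosage == 2] = np.nan
        called = geno[~np.isnan(geno)]
        alt_freq = called.mean() / 2.0 if len(called) else 0.0
        if alt_freq > 0.5:
            geno = 2.0 - geno
            minors.append(variant.REF)
        else:
            minors.append(variant.ALT[0])
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        cols.append(geno)
    values = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return (
        GenotypeMatrix(values=values, snp_ids=tuple(snp_ids), minor_alleles=tuple(minors)),
        samples,
    )


def read_covariates_csv(path: str | Path, id_col: str = "sample_id") -> tuple[CovariateTable, pd.Index]:
    df = pd.read_csv(path)
    for col in (id_col, "age", "sex", "population"):
        if col not in df.columns:
            raise ValueError(f"covariate CSV must contain a {col!r} column")
    return (
        CovariateTable(
            age=df["age"].to_numpy(float),
            sex=df["sex"].to_numpy(float),
            population=df["population"].to_numpy(object),
        ),
        pd.Index(df[id_col].astype(str)),
    )


def quantifications_to_frame(rows: list[ColourQuantification]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])
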