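"""File formats: minimal VCF, dosage TSV, abundance TSV, metadata CSV, YAML
configuration.

All tabular artifacts are plain TSV/CSV so pipeline outputs stay diffable
and language-neutral.  Genotypes round-trip through either a minimal VCF
(GT field only) or a variants x samples dosage TSV.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .containers import (
    AbundanceMatrix,
    GenotypeMatrix,
    normalize_chrom,
    variant_key,
)

_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def read_genotypes(
    path, fmt: str = "auto", samples_meta: pd.DataFrame | None = None
) -> GenotypeMatrix:
    """Read genotypes from a VCF or a dosage TSV.

    ``fmt='auto'`` picks by file extension (.vcf -> VCF, otherwise TSV).
    Multi-allelic VCF records are skipped with a warning; GT fields map to
    dosages 0/1/2 with ./. as missing.  ``samples_meta`` (indexed by sample
    id) supplies modality/brain/sex/race annotations; without it an empty
    metadata frame is attached.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "dosage-tsv"
    if fmt == "vcf":
        gm = _read_vcf(path)
    elif fmt == "dosage-tsv":
        gm = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format: {fmt}")
    if samples_meta is not None:
        meta = samples_meta.reindex(gm.samples.index)
        gm = GenotypeMatrix(gm.dosage, gm.variants, meta)
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, meta = [], []
    for i, rec in enumerate(vcf):
        try:
            if len(rec.ALT) != 1:
                warnings.warn(
                    f"record {i + 1} ({rec.CHROM}:{rec.POS}): multi-allelic, skipped"
                )
                continue
            chrom = normalize_chrom(rec.CHROM)
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            g = rec.gt_types.astype(float)
            dosage = np.select(
                [g == 0, g == 1, g == 3], [0.0, 1.0, 2.0], default=np.nan
            )
            rows.append(dosage)
            meta.append(
                {
                    "chrom": chrom,
                    "pos": int(rec.POS),
                    "ref": rec.REF,
                    "alt": rec.ALT[0],
                }
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record at line ~{i + 1}: {exc}") from exc
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    variants = pd.DataFrame(meta)
    variants.index = pd.Index(
        [variant_key(r.chrom, r.pos, r.ref, r.alt) for r in variants.itertuples()],
        name="variant",
    )
    dosage = pd.DataFrame(
        np.vstack(rows).T, index=pd.Index(sample_ids, name="sample_id"),
        columns=variants.index,
    )
    samples = pd.DataFrame(index=dosage.index)
    return GenotypeMatrix(dosage, variants, samples)


def write_genotypes_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT as the only FORMAT field."""
    path = Path(path)
    def chrom_sort_key(c):
        return (0, int(c)) if str(c).isdigit() else (1, 0 if c == "X" else 1)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(g.variants["chrom"].unique(), key=chrom_sort_key):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples.index)
            + "\n"
        )
        dosage = g.dosage.to_numpy()
        order = np.lexsort(
            (g.variants["pos"].to_numpy(), g.variants["chrom"].to_numpy())
        )
        for j in order:
            row = g.variants.iloc[j]
            gts = "\t".join(
                _GT_STRINGS.get(d, "./.") if not np.isnan(d) else "./."
                for d in dosage[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{g.variants.index[j]}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ValueError(f"non-numeric dosage columns in {path}: {list(bad)[:5]}")
    meta = []
    for key in df.index:
        parts = str(key).split(":")
        if len(parts) != 4:
            raise ValueError(
                f"dosage TSV row key must be chrom:pos:ref:alt, got {key!r}"
            )
        meta.append(
            {
                "chrom": normalize_chrom(parts[0]),
                "pos": int(parts[1]),
                "ref": parts[2],
                "alt": parts[3],
            }
        )
    variants = pd.DataFrame(meta, index=pd.Index(df.index, name="variant"))
    dosage = df.T
    dosage.index.name = "sample_id"
    samples = pd.DataFrame(index=dosage.index)
    return GenotypeMatrix(dosage, variants, samples)


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    """Write a variants x samples dosage TSV (row key chrom:pos:ref:alt)."""
    g.dosage.T.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Abundance matrices
# ---------------------------------------------------------------------------

def write_abundance(matrix: AbundanceMatrix, prefix) -> None:
    """Write ``<prefix>.tsv`` (features x samples), ``<prefix>.samples.csv``
    and, when present, ``<prefix>.pairs.csv`` / ``<prefix>.features.csv``."""
    prefix = Path(prefix)
    matrix.values.to_csv(f"{prefix}.tsv", sep="\t", na_rep="")
    matrix.samples.to_csv(f"{prefix}.samples.csv")
    if matrix.replicate_pairs:
        pd.DataFrame(
            matrix.replicate_pairs, columns=["sample_a", "sample_b"]
        ).to_csv(f"{prefix}.pairs.csv", index=False)
    if matrix.features is not None:
        matrix.features.to_csv(f"{prefix}.features.csv")


def read_abundance(prefix) -> AbundanceMatrix:
    prefix = Path(prefix)
    values = pd.read_csv(f"{prefix}.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(f"{prefix}.samples.csv", index_col=0)
    samples.index = samples.index.astype(str)
    values.columns = values.columns.astype(str)
    pairs_path = Path(f"{prefix}.pairs.csv")
    pairs = []
    if pairs_path.exists():
        pdf = pd.read_csv(pairs_path)
        pairs = list(pdf.itertuples(index=False, name=None))
    feat_path = Path(f"{prefix}.features.csv")
    features = pd.read_csv(feat_path, index_col=0) if feat_path.exists() else None
    if features is not None:
        features.index = values.index
    return AbundanceMatrix(values, samples, features, pairs)


# ---------------------------------------------------------------------------
# Metadata and configuration
# ---------------------------------------------------------------------------

def write_metadata(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


KNOWN_CONFIG_KEYS = {
    "genotypes",
    "metadata",
    "proteomics",
    "pqtl_proteins",
    "sex_markers",
    "outdir",
    "rng_seed",
    "missing_rate_threshold",
    "variant_max_missing",
    "variant_min_maf",
    "hwe_alpha",
    "kinship_duplicate",
    "kinship_distant",
    "sex_f_male",
    "sex_f_female",
    "modmatch_alpha",
    "modmatch_window_bp",
    "modmatch_top_k",
}


def load_run_config(path) -> dict:
    """Load a pipeline YAML config, rejecting unknown keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg
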