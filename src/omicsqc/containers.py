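"""In-memory containers shared across the QC pipeline.

Two matrices carry almost all of the data flow:

* :class:`GenotypeMatrix` -- samples x variants dosage matrix (0/1/2, NaN for
  missing) with variant coordinates and per-sample claimed metadata (modality,
  brain of origin, sex, race).
* :class:`AbundanceMatrix` -- features x samples continuous log-abundances
  (NaN for missing) with batch labels, reference-standard flags and optional
  replicate-pair / genomic-coordinate annotations.

Dosage matrices always store diploid dosages; hemizygous male X genotypes are
encoded as {0, 2}, the way diploid variant callers report them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Prefix used for "brain identity unknown" sentinels in claimed metadata.
#: Each unknown sample gets a distinct sentinel so two unknown samples are
#: never treated as coming from the same brain.
UNKNOWN_PREFIX = "UNKNOWN"

AUTOSOMES = tuple(str(c) for c in range(1, 23))


def is_unknown_brain(label) -> bool:
    """True when a claimed brain label carries no identity information."""
    if label is None:
        return True
    if isinstance(label, float) and np.isnan(label):
        return True
    return isinstance(label, str) and label.startswith(UNKNOWN_PREFIX)


def unknown_brain_sentinel(sample_id: str) -> str:
    return f"{UNKNOWN_PREFIX}:{sample_id}"


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome names: strip 'chr' prefix, uppercase X/Y/MT."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() in ("x", "y", "mt", "m"):
        c = c.upper()
    return c


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{normalize_chrom(chrom)}:{int(pos)}:{ref}:{alt}"


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant and sample annotations.

    Attributes
    ----------
    dosage
        ``pd.DataFrame`` of shape (n_samples, n_variants); entries in
        {0, 1, 2} or NaN for missing. Index = sample ids, columns = variant
        keys ``chrom:pos:ref:alt``.
    variants
        Per-variant table indexed by variant key with columns ``chrom``
        (normalized string), ``pos`` (1-based int), ``ref``, ``alt``.
    samples
        Per-sample *claimed* metadata indexed by sample id. Recognized
        columns: ``modality``, ``brain_id``, ``sex``, ``race``. Extra
        columns are carried along untouched.
    """

    dosage: pd.DataFrame
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if not self.dosage.columns.equals(self.variants.index):
            raise ValueError("dosage columns must match variants index")
        if not self.dosage.index.equals(self.samples.index):
            raise ValueError("dosage index must match samples index")

    # -- basic dimensions -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    # -- chromosome views -------------------------------------------------
    @property
    def is_x(self) -> pd.Series:
        return self.variants["chrom"].astype(str) == "X"

    @property
    def is_autosomal(self) -> pd.Series:
        return self.variants["chrom"].astype(str).isin(AUTOSOMES)

    def autosomal(self) -> "GenotypeMatrix":
        return self.subset_variants(self.is_autosomal)

    def x_chromosome(self) -> "GenotypeMatrix":
        return self.subset_variants(self.is_x)

    # -- per-variant statistics -------------------------------------------
    def allele_freq(self) -> pd.Series:
        """Alternate allele frequency per variant (mean dosage / 2)."""
        return self.dosage.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def variant_missing_rate(self) -> pd.Series:
        return self.dosage.isna().mean(axis=0)

    def sample_missing_rate(self) -> pd.Series:
        return self.dosage.isna().mean(axis=1)

    # -- subsetting --------------------------------------------------------
    def subset_variants(self, mask_or_keys) -> "GenotypeMatrix":
        sub = self.variants.loc[mask_or_keys]
        return GenotypeMatrix(self.dosage[sub.index], sub, self.samples)

    def subset_samples(self, ids) -> "GenotypeMatrix":
        ids = pd.Index(ids)
        return GenotypeMatrix(
            self.dosage.loc[ids], self.variants, self.samples.loc[ids]
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosage.copy(), self.variants.copy(), self.samples.copy()
        )


@dataclass
class AbundanceMatrix:
    """Features x samples continuous abundance matrix with annotations.

    ``values`` holds log-scale abundances with NaN marking missing entries;
    ``samples`` is indexed by sample id and may carry ``batch``,
    ``is_reference`` and ``brain_id`` columns; ``features`` optionally maps
    each feature to genomic coordinates (``chrom``, ``pos``) for cis lookups.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame | None = None
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("values columns must match samples index")
        if self.features is not None and not self.values.index.equals(
            self.features.index
        ):
            raise ValueError("values index must match features index")
        for a, b in self.replicate_pairs:
            if a == b:
                raise ValueError(f"replicate pair references one sample: {a}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def feature_missing_rate(self) -> pd.Series:
        return self.values.isna().mean(axis=1)

    @property
    def batch(self) -> pd.Series:
        return self.samples["batch"]

    @property
    def is_reference(self) -> pd.Series:
        if "is_reference" in self.samples:
            return self.samples["is_reference"].astype(bool)
        return pd.Series(False, index=self.samples.index)

    def subset_features(self, mask_or_keys) -> "AbundanceMatrix":
        vals = self.values.loc[mask_or_keys]
        feats = self.features.loc[vals.index] if self.features is not None else None
        return AbundanceMatrix(vals, self.samples, feats, list(self.replicate_pairs))

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(),
            self.samples.copy(),
            None if self.features is None else self.features.copy(),
            list(self.replicate_pairs),
        )
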