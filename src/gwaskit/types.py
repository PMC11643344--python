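"""Core containers shared across the toolkit.

Genotypes are additive dosages: the count of A1 (minor-allele) copies per
sample and variant, stored as ``int8`` with :data:`MISSING` (-1) marking
no-calls.  Variant and sample metadata follow PLINK BIM/FAM column
semantics and live in plain :class:`pandas.DataFrame` objects with the
column sets declared below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in an integer dosage matrix.
MISSING: int = -1

#: BIM-style per-variant metadata columns (chromosome, identifier,
#: genetic distance in cM, 1-based bp position, counted allele A1, other
#: allele A2).
VARIANT_COLUMNS = ("chrom", "variant_id", "cm", "pos", "a1", "a2")

#: FAM-style per-sample metadata columns.  ``phenotype`` uses the PLINK
#: missing sentinel -9.
SAMPLE_COLUMNS = ("fid", "iid", "father", "mother", "sex", "phenotype")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class EmptyInputError(ValueError):
    """An input contains no usable records."""


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix.

    Parameters
    ----------
    dosages
        ``int8`` array of shape (n_samples, n_variants) with entries in
        {0, 1, 2, MISSING}.
    sample_ids
        Ordered ``(family_id, individual_id)`` pairs, one per row.
    variant_ids
        Ordered variant identifiers, one per column; unique.
    """

    dosages: np.ndarray
    sample_ids: list[tuple[str, str]] = field(default_factory=list)
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        self.sample_ids = [tuple(map(str, s)) for s in self.sample_ids]
        self.variant_ids = [str(v) for v in self.variant_ids]
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.variant_ids) != self.dosages.shape[1]:
            raise ValueError("variant_ids length does not match dosage columns")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant_ids must be unique")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"dosages contain values outside {{0,1,2,{MISSING}}}: {bad}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing calls, same shape as ``dosages``."""
        return self.dosages == MISSING

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Column subset preserving order of ``index``."""
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.dosages[:, index],
            list(self.sample_ids),
            [self.variant_ids[i] for i in index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """Row subset preserving order of ``index``."""
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.dosages[index, :],
            [self.sample_ids[i] for i in index],
            list(self.variant_ids),
        )


def make_variant_table(
    chrom, variant_id, pos, a1, a2, cm=None
) -> pd.DataFrame:
    """Assemble a BIM-semantics variant table."""
    n = len(variant_id)
    df = pd.DataFrame(
        {
            "chrom": [str(c) for c in chrom],
            "variant_id": [str(v) for v in variant_id],
            "cm": np.zeros(n) if cm is None else np.asarray(cm, dtype=float),
            "pos": np.asarray(pos, dtype=np.int64),
            "a1": [str(a) for a in a1],
            "a2": [str(a) for a in a2],
        }
    )
    validate_variant_table(df)
    return df


def validate_variant_table(df: pd.DataFrame) -> None:
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if (df["pos"] < 0).any():
        raise ValueError("variant positions must be >= 0")


def make_sample_table(
    fid, iid, father=None, mother=None, sex=None, phenotype=None
) -> pd.DataFrame:
    """Assemble a FAM-semantics sample table (defaults: unknown parents,
    sex code 0, phenotype -9)."""
    n = len(iid)
    df = pd.DataFrame(
        {
            "fid": [str(f) for f in fid],
            "iid": [str(i) for i in iid],
            "father": ["0"] * n if father is None else [str(f) for f in father],
            "mother": ["0"] * n if mother is None else [str(m) for m in mother],
            "sex": np.zeros(n, dtype=int) if sex is None else np.asarray(sex, dtype=int),
            "phenotype": np.full(n, -9.0) if phenotype is None else np.asarray(phenotype, dtype=float),
        }
    )
    validate_sample_table(df)
    return df


def validate_sample_table(df: pd.DataFrame) -> None:
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    pairs = list(zip(df["fid"], df["iid"]))
    if len(set(pairs)) != len(pairs):
        raise ValueError("(fid, iid) pairs must be unique")
    if not df["sex"].isin([0, 1, 2]).all():
        raise ValueError("sex codes must be in {0, 1, 2}")
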