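"""Per-variant quality statistics, filtering, and mean imputation.

MAF and heterozygosity are computed over non-missing calls only; a
variant with no calls at all gets NaN sentinels and missing rate 1.
Filter thresholds are boundary-inclusive (keep when ``maf >= maf_min``
and ``missing_rate <= missing_max``), matching PLINK ``--maf`` /
``--geno`` semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix


class EmptyFilterWarning(UserWarning):
    """No variants survived filtering."""


@dataclass
class VariantQC:
    """Per-variant statistics: minor-allele frequency, missing call rate,
    heterozygote rate.  NaN marks undefined values (all-missing columns)."""

    maf: np.ndarray
    missing_rate: np.ndarray
    het_rate: np.ndarray

    def to_frame(self, variant_ids=None, kept=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"maf": self.maf, "missing_rate": self.missing_rate, "het_rate": self.het_rate}
        )
        if variant_ids is not None:
            df.insert(0, "variant_id", list(variant_ids))
        if kept is not None:
            df["kept"] = np.asarray(kept, dtype=bool)
        return df


@dataclass
class FilterResult:
    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    kept_indices: np.ndarray
    n_removed: int


@dataclass
class GenotypeSummary:
    """Binned summaries backing the data-report plots."""

    het_per_sample: np.ndarray
    maf_bin_edges: np.ndarray
    maf_hist: np.ndarray
    # chrom -> (bin_edges_bp, counts)
    density: dict[str, tuple[np.ndarray, np.ndarray]]


def compute_variant_qc(g: GenotypeMatrix) -> VariantQC:
    """MAF, missing rate and het rate for every variant column."""
    if g.n_samples < 1:
        raise ValueError("need at least one sample")
    d = g.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(obs, d, 0).sum(axis=0) / (2.0 * n_obs)
        maf = np.minimum(f, 1.0 - f)
        het = (d == 1).sum(axis=0) / n_obs
    maf = np.where(n_obs == 0, np.nan, maf)
    het = np.where(n_obs == 0, np.nan, het)
    missing_rate = (g.n_samples - n_obs) / g.n_samples
    return VariantQC(maf=maf, missing_rate=missing_rate, het_rate=het)


def filter_variants(
    g: GenotypeMatrix,
    variants: pd.DataFrame,
    qc: VariantQC,
    maf_min: float = 0.0,
    missing_max: float = 1.0,
) -> FilterResult:
    """Keep variants with ``missing_rate <= missing_max`` and
    ``maf >= maf_min``; all-missing variants are always removed.  Order is
    preserved.  Warns (``EmptyFilterWarning``) if nothing survives."""
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must be in [0, 1]")
    keep = (
        ~np.isnan(qc.maf)
        & (qc.missing_rate <= missing_max)
        & (qc.maf >= maf_min)
    )
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size == 0:
        warnings.warn(
            f"no variants pass maf>={maf_min}, missing<={missing_max}",
            EmptyFilterWarning,
            stacklevel=2,
        )
    return FilterResult(
        genotypes=g.take_variants(kept_idx),
        variants=variants.iloc[kept_idx].reset_index(drop=True),
        kept_indices=kept_idx,
        n_removed=g.n_variants - kept_idx.size,
    )


def mean_impute(g: GenotypeMatrix) -> np.ndarray:
    """Replace each MISSING cell with its variant's non-missing mean dosage.

    Returns a float64 (n_samples, n_variants) array.  A variant with no
    observed calls violates the precondition and raises, naming it.
    """
    d = g.dosages
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmin(n_obs))
        raise ValueError(
            f"variant {g.variant_ids[j]!r} has no observed calls; cannot impute"
        )
    means = np.where(obs, d, 0).sum(axis=0) / n_obs
    return np.where(obs, d, means[np.newaxis, :]).astype(np.float64)


def genotype_summary(
    g: GenotypeMatrix,
    variants: pd.DataFrame,
    maf_bin_width: float = 0.05,
    density_bin_bp: int = 1_000_000,
) -> GenotypeSummary:
    """Deterministic binned summaries: per-sample heterozygosity, MAF
    histogram (bins of width 0.05 over [0, 0.5]), and per-chromosome
    marker-density histograms (fixed-width bp bins, 1 Mbp default)."""
    d = g.dosages
    obs = d != MISSING
    n_obs_per_sample = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        het = (d == 1).sum(axis=1) / n_obs_per_sample
    qc = compute_variant_qc(g)
    maf_edges = np.arange(0.0, 0.5 + maf_bin_width / 2, maf_bin_width)
    maf_hist, _ = np.histogram(np.nan_to_num(qc.maf), bins=maf_edges)
    density: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in variants.groupby("chrom", sort=True):
        top = int(sub["pos"].max())
        edges = np.arange(0, top + density_bin_bp + 1, density_bin_bp)
        counts, _ = np.histogram(sub["pos"], bins=edges)
        density[str(chrom)] = (edges, counts)
    return GenotypeSummary(
        het_per_sample=het, maf_bin_edges=maf_edges, maf_hist=maf_hist, density=density
    )


def write_qc_report(path, qc: VariantQC, variant_ids, kept=None) -> None:
    """TSV report: variant_id, maf, missing_rate, het_rate[, kept]."""
    qc.to_frame(variant_ids, kept).to_csv(Path(path), sep="\t", index=False)
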