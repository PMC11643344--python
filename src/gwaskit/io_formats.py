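"""Genotype and phenotype file I/O.

Readers and writers for the PLINK 1 binary triple (BED/BIM/FAM), VCF 4.x
(via cyvcf2, GT field required), and delimited phenotype tables, plus the
VCF -> PLINK converter with MAF / missing-rate filtering.

PLINK 1 BED layout: 3 magic bytes ``0x6C 0x1B 0x01`` (SNP-major), then
per variant ``ceil(n_samples/4)`` bytes of 2-bit codes, samples packed
low-order bit-pair first.  Codes: ``00`` hom A1 (dosage 2), ``01``
missing, ``10`` het (1), ``11`` hom A2 (0).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    EmptyInputError,
    FormatError,
    GenotypeMatrix,
    make_sample_table,
    make_variant_table,
    validate_sample_table,
    validate_variant_table,
)

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> A1 dosage, and its inverse.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 3, 1: 2, 2: 0, MISSING: 1}

_SYMBOLIC = ("<", ">", "[", "]", "*")


@dataclass
class VCFResult:
    """Parsed VCF: genotype triple plus a tally of skipped records."""

    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    samples: pd.DataFrame
    n_skipped_multiallelic: int


@dataclass
class ConversionReport:
    """Accounting for :func:`convert_vcf_to_plink`.

    Counts are additive:
    ``n_in == n_kept + n_skipped_multiallelic + n_removed_missing + n_removed_maf``
    with the missing-rate filter applied before the MAF filter.
    """

    n_in: int
    n_kept: int
    n_skipped_multiallelic: int
    n_removed_maf: int
    n_removed_missing: int

    def __post_init__(self) -> None:
        counts = (
            self.n_kept,
            self.n_skipped_multiallelic,
            self.n_removed_maf,
            self.n_removed_missing,
        )
        if any(c < 0 for c in counts) or sum(counts) != self.n_in:
            raise ValueError("conversion report counts are not additive")


@dataclass
class PhenotypeAlignment:
    """Trait vector aligned to a genotype sample order.

    ``values`` holds NaN at masked positions; ``mask`` is True where the
    trait is missing (absent from the file, non-numeric, or the -9/NA
    missing sentinel).
    """

    values: np.ndarray
    mask: np.ndarray
    n_matched: int
    n_unmatched: int
    n_non_numeric: int


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_vcf(path) -> VCFResult:
    """Read biallelic SNP records from a VCF into an A1-dosage matrix.

    A1 is assigned to the *minor* allele of the loaded cohort (ties break
    toward ALT); dosage counts A1 copies.  Records with more than one ALT
    allele or any symbolic allele are skipped and tallied.  A genotype
    with any missing allele slot is MISSING.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        first = fh.readline()
    if not first.startswith("##fileformat"):
        raise FormatError(f"{path}: missing ##fileformat VCF header line")

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise EmptyInputError(f"{path}: VCF header declares no samples")

    n = len(samples)
    columns: list[np.ndarray] = []
    chroms: list[str] = []
    vids: list[str] = []
    poss: list[int] = []
    a1s: list[str] = []
    a2s: list[str] = []
    n_skipped = 0
    seen_ids: dict[str, int] = {}

    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or any(s in alts[0] for s in _SYMBOLIC) or any(
            s in rec.REF for s in _SYMBOLIC
        ):
            n_skipped += 1
            continue
        alt = alts[0]
        alt_count = np.full(n, MISSING, dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            alleles = g[:-1]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                continue
            alt_count[i] = sum(1 for a in alleles if a == 1)
        obs = alt_count != MISSING
        n_obs = int(obs.sum())
        f_alt = float(alt_count[obs].sum()) / (2 * n_obs) if n_obs else 0.0
        if f_alt <= 0.5:  # tie -> ALT is A1
            a1, a2 = alt, rec.REF
            col = alt_count
        else:
            a1, a2 = rec.REF, alt
            col = np.where(obs, 2 - alt_count, MISSING).astype(np.int8)
        vid = rec.ID if rec.ID not in (None, ".", "") else f"{rec.CHROM}:{rec.POS}"
        if vid in seen_ids:
            seen_ids[vid] += 1
            vid = f"{vid}_{seen_ids[vid]}"
        else:
            seen_ids[vid] = 0
        columns.append(col)
        chroms.append(str(rec.CHROM))
        vids.append(vid)
        poss.append(int(rec.POS))
        a1s.append(a1)
        a2s.append(a2)

    dosages = (
        np.column_stack(columns) if columns else np.zeros((n, 0), dtype=np.int8)
    )
    g = GenotypeMatrix(dosages, [(s, s) for s in samples], vids)
    variants = make_variant_table(chroms, vids, poss, a1s, a2s)
    sample_table = make_sample_table(samples, samples)
    return VCFResult(g, variants, sample_table, n_skipped)


def _unpack_bed_payload(payload: bytes, n_samples: int, n_variants: int) -> np.ndarray:
    bpf = math.ceil(n_samples / 4)  # bytes per variant
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(n_variants, bpf)
    bits = np.unpackbits(raw, axis=1, bitorder="little")
    codes = bits[:, 0::2] + 2 * bits[:, 1::2]  # low-order bit-pair first
    return _CODE_TO_DOSAGE[codes[:, :n_samples]].T.copy()  # -> samples x variants


def read_plink(prefix) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK 1 binary triple ``prefix``.bed/.bim/.fam."""
    prefix = Path(prefix)
    paths = {ext: Path(f"{prefix}.{ext}") for ext in ("bed", "bim", "fam")}
    for ext, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing companion file: {p}")

    bim = pd.read_csv(
        paths["bim"],
        sep=r"\s+",
        header=None,
        names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "variant_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        paths["fam"],
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    n, m = len(fam), len(bim)

    blob = paths["bed"].read_bytes()
    if blob[:3] != BED_MAGIC:
        raise FormatError(
            f"{paths['bed']}: bad magic bytes {blob[:3]!r}; expected SNP-major PLINK 1 BED"
        )
    expected = math.ceil(n / 4) * m + 3
    if len(blob) != expected:
        raise FormatError(
            f"{paths['bed']}: {len(blob)} bytes, expected {expected} for {n} samples x {m} variants"
        )
    dosages = (
        _unpack_bed_payload(blob[3:], n, m) if m else np.zeros((n, 0), dtype=np.int8)
    )
    g = GenotypeMatrix(dosages, list(zip(fam["fid"], fam["iid"])), list(bim["variant_id"]))
    validate_variant_table(bim)
    validate_sample_table(fam)
    return g, bim, fam


def write_plink(g: GenotypeMatrix, variants: pd.DataFrame, samples: pd.DataFrame, prefix) -> dict[str, Path]:
    """Write the PLINK triple; bit-exact inverse of :func:`read_plink`."""
    if len(variants) != g.n_variants:
        raise ValueError(
            f"variant table has {len(variants)} rows for {g.n_variants} variants"
        )
    if len(samples) != g.n_samples:
        raise ValueError(
            f"sample table has {len(samples)} rows for {g.n_samples} samples"
        )
    validate_variant_table(variants)
    validate_sample_table(samples)
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {ext: Path(f"{prefix}.{ext}") for ext in ("bed", "bim", "fam")}

    n, m = g.n_samples, g.n_variants
    code_lut = np.empty(4, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        code_lut[d] = c  # index -1 wraps to slot 3 -> missing code
    codes = code_lut[g.dosages.T]  # variants x samples
    pad = (-n) % 4
    if pad:
        codes = np.pad(codes, ((0, 0), (0, pad)))  # pad bit-pairs are 00
    bits = np.zeros((m, codes.shape[1] * 2), dtype=np.uint8)
    bits[:, 0::2] = codes & 1
    bits[:, 1::2] = codes >> 1
    payload = np.packbits(bits, axis=1, bitorder="little").tobytes()
    paths["bed"].write_bytes(BED_MAGIC + payload)

    bim = variants.copy()
    bim["cm"] = bim["cm"].map(lambda x: int(x) if float(x).is_integer() else x)
    bim[["chrom", "variant_id", "cm", "pos", "a1", "a2"]].to_csv(
        paths["bim"], sep="\t", header=False, index=False
    )
    fam = samples.copy()
    fam["phenotype"] = fam["phenotype"].map(
        lambda x: int(x) if float(x).is_integer() else x
    )
    fam[["fid", "iid", "father", "mother", "sex", "phenotype"]].to_csv(
        paths["fam"], sep=" ", header=False, index=False
    )
    return paths


def convert_vcf_to_plink(
    vcf_path, prefix, maf_min: float = 0.0, missing_max: float = 1.0
) -> ConversionReport:
    """Convert a VCF to the PLINK triple, filtering variants.

    The missing-rate filter (keep ``missing_rate <= missing_max``; variants
    with no calls at all always removed) is applied before the MAF filter
    (keep ``maf >= maf_min``), and the report attributes each removal to
    the first filter that rejected it.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must be in [0, 1]")
    from .qc import compute_variant_qc

    res = read_vcf(vcf_path)
    g, variants = res.genotypes, res.variants
    qc = compute_variant_qc(g)

    all_missing = np.isnan(qc.maf)
    fail_missing = (qc.missing_rate > missing_max) | all_missing
    fail_maf = ~fail_missing & (np.nan_to_num(qc.maf) < maf_min)
    keep = ~fail_missing & ~fail_maf
    kept_idx = np.flatnonzero(keep)

    write_plink(
        g.take_variants(kept_idx),
        variants.iloc[kept_idx].reset_index(drop=True),
        res.samples,
        prefix,
    )
    return ConversionReport(
        n_in=g.n_variants + res.n_skipped_multiallelic,
        n_kept=int(keep.sum()),
        n_skipped_multiallelic=res.n_skipped_multiallelic,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_missing.sum()),
    )


def _sniff_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # any-whitespace


def read_phenotypes(path, g_sample_ids, match_on: str = "iid") -> PhenotypeAlignment:
    """Load a delimited phenotype file aligned to genotype sample order.

    The file carries either ``IID value`` (2 columns) or
    ``FID IID value`` (>= 3 columns), auto-detected by column count, with
    comma / tab / whitespace delimiters auto-detected.  Matching uses the
    individual ID alone by default, or the (FID, IID) pair with
    ``match_on="fid_iid"``.  ``NA`` and ``-9`` are missing; other
    non-numeric values are masked and counted.
    """
    if match_on not in ("iid", "fid_iid"):
        raise ValueError("match_on must be 'iid' or 'fid_iid'")
    path = Path(path)
    with _open_text(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise EmptyInputError(f"{path}: empty phenotype file")
    sep = _sniff_delimiter(lines[0])
    rows = [ln.split(sep) if sep else ln.split() for ln in lines]
    n_cols = len(rows[0])
    if n_cols < 2:
        raise FormatError(f"{path}: phenotype file needs >= 2 columns")

    def parse(row):
        if len(row) < 2:
            raise FormatError(f"{path}: ragged phenotype row {row!r}")
        if n_cols == 2:
            return (None, row[0].strip()), row[1].strip()
        return (row[0].strip(), row[1].strip()), row[2].strip()

    records = dict(parse(r) for r in rows)
    # A header row parses to a non-numeric value and an unmatched ID; it is
    # dropped silently if its value column is a non-numeric word and its ID
    # matches no sample, to tolerate "FID,IID,trait" style headers.
    g_sample_ids = [tuple(map(str, s)) for s in g_sample_ids]
    lookup: dict = {}
    for (fid, iid), val in records.items():
        key = iid if match_on == "iid" else (fid if fid is not None else iid, iid)
        if key in lookup:
            raise ValueError(f"{path}: duplicate phenotype ID {key!r}")
        lookup[key] = val

    n = len(g_sample_ids)
    values = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    n_matched = 0
    n_non_numeric = 0
    matched_keys = set()
    for i, (fid, iid) in enumerate(g_sample_ids):
        key = iid if match_on == "iid" else (fid, iid)
        if key not in lookup:
            continue
        n_matched += 1
        matched_keys.add(key)
        raw = lookup[key]
        try:
            val = float(raw)
        except ValueError:
            n_non_numeric += 1
            continue
        if val == -9 or not np.isfinite(val):
            continue
        values[i] = val
        mask[i] = False
    n_unmatched = len(lookup) - len(matched_keys)
    header_like = (
        n_unmatched > 0
        and n_matched > 0
        and _is_header_row(rows[0], n_cols)
    )
    if header_like:
        n_unmatched -= 1
    if n_matched == 0:
        raise ValueError(
            f"{path}: no phenotype IDs matched the genotype samples "
            f"(match_on={match_on!r}); check the ID scheme"
        )
    return PhenotypeAlignment(values, mask, n_matched, n_unmatched, n_non_numeric)


def _is_header_row(row: list[str], n_cols: int) -> bool:
    value = row[-1] if n_cols == 2 else row[2]
    try:
        float(value)
        return False
    except ValueError:
        return True
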