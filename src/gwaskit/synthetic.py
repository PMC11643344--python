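"""Synthetic genotypes and phenotypes for end-to-end testing.

Genotypes follow the Balding-Nichols model: each variant draws an
ancestral allele frequency uniformly from ``maf_range``; under
population structure (``fst > 0``) each population perturbs it with a
Beta distribution whose spread is governed by Fst, and genotypes are
Binomial(2, p) draws.  That is the simplest standard construction that
produces the allele-frequency confounding a mixed model must correct
for.  Phenotypes are additive: designed causal markers (drawn among
variants with MAF >= 0.05) get standard-normal effects on standardized
dosages, and noise is rescaled so the *sample* variance ratio equals the
requested heritability exactly — parameter-recovery tests therefore
have a sharp target.  Qualitative traits threshold the quantitative
liability at its median, giving balanced 0/1 classes.

The generator emulates the statistical shape of real crop GWAS panels
(hundreds to thousands of samples, 1e4-1e6 biallelic SNPs, population
structure, designed causal markers, missing calls); it has no linkage
disequilibrium, no relatedness beyond population membership, and no
genotyping-error structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, make_sample_table, make_variant_table
from .io_formats import write_plink

SCENARIOS = ("toy4x3", "structured_null", "single_causal", "gp_benchmark")


@dataclass
class SimTruth:
    """Ground truth of a simulated phenotype."""

    causal_indices: list[int]
    causal_effects: list[float]
    true_h2: float
    trait_type: str
    population_labels: list[int]


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    n_pops: int = 1,
    fst: float = 0.0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Balding-Nichols genotype simulation.

    Samples are split as evenly as possible across ``n_pops``
    populations; missing calls are masked i.i.d. at ``missing_rate``.
    Returns the genotype matrix, variant and sample tables, and the
    per-sample population labels.
    """
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    if not 0 <= fst < 1:
        raise ValueError("fst must be in [0, 1)")
    lo, hi = maf_range
    if not 0 < lo <= hi <= 0.5:
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    p_anc = rng.uniform(lo, hi, size=n_variants)
    labels = np.arange(n_samples) % n_pops
    labels.sort()
    dosages = np.empty((n_samples, n_variants), dtype=np.int8)
    for k in range(n_pops):
        rows = labels == k
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            p_k = rng.beta(a, b)
        else:
            p_k = p_anc
        dosages[rows] = rng.binomial(2, p_k, size=(int(rows.sum()), n_variants)).astype(
            np.int8
        )
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = MISSING

    vids = [f"snp{j + 1}" for j in range(n_variants)]
    variants = make_variant_table(
        chrom=["1"] * n_variants,
        variant_id=vids,
        pos=np.arange(1, n_variants + 1) * 1000,
        a1=["A"] * n_variants,
        a2=["G"] * n_variants,
    )
    iids = [f"s{i + 1:04d}" for i in range(n_samples)]
    samples = make_sample_table(iids, iids)
    g = GenotypeMatrix(dosages, [(i, i) for i in iids], vids)
    return g, variants, samples, labels


def simulate_phenotype(
    g: GenotypeMatrix,
    n_causal: int,
    h2: float,
    trait_type: str = "quantitative",
    seed: int = 0,
    population_labels=None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Additive phenotype with designed causal markers.

    Returns a phenotype table (fid, iid, value) in genotype sample order
    and the simulation ground truth.  ``h2`` is enforced on the sample
    variances exactly; ``trait_type="qualitative"`` thresholds the
    liability at its median into balanced {0, 1} classes.
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must be in [0, 1]")
    if n_causal > g.n_variants:
        raise ValueError("n_causal exceeds n_variants")
    if h2 > 0 and n_causal == 0:
        raise ValueError("h2 > 0 requires at least one causal variant")
    if trait_type not in ("quantitative", "qualitative"):
        raise ValueError("trait_type must be quantitative or qualitative")
    rng = np.random.default_rng(seed)

    from .qc import compute_variant_qc, mean_impute

    qc = compute_variant_qc(g)
    eligible = np.flatnonzero(np.nan_to_num(qc.maf) >= 0.05)
    if n_causal > eligible.size:
        raise ValueError(
            f"only {eligible.size} variants have MAF >= 0.05; cannot place {n_causal} causal markers"
        )
    causal = np.sort(rng.choice(eligible, size=n_causal, replace=False))
    effects = rng.standard_normal(n_causal)

    X = mean_impute(g)[:, causal] if n_causal else np.zeros((g.n_samples, 0))
    if n_causal:
        sd = X.std(axis=0)
        Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        genetic = Xs @ effects
    else:
        genetic = np.zeros(g.n_samples)

    noise = rng.standard_normal(g.n_samples)
    noise = noise - noise.mean()
    var_g = genetic.var()
    if var_g > 0:
        # residualize so the sample covariance of noise and genetic is 0,
        # making the h2 variance decomposition exact
        noise = noise - (noise @ genetic) / (genetic @ genetic) * genetic
    if h2 == 0:
        y = noise.copy()
        genetic = np.zeros_like(genetic)
    elif h2 == 1:
        y = genetic.copy()
    else:
        # scale noise so var(noise)/var(total) == 1 - h2 on this sample
        target_var_e = var_g * (1 - h2) / h2
        noise = noise / noise.std() * np.sqrt(target_var_e)
        y = genetic + noise

    if trait_type == "qualitative":
        y = (y > np.median(y)).astype(float)

    iids = [iid for _, iid in g.sample_ids]
    fids = [fid for fid, _ in g.sample_ids]
    pheno = pd.DataFrame({"fid": fids, "iid": iids, "value": y})
    truth = SimTruth(
        causal_indices=[int(i) for i in causal],
        causal_effects=[float(e) for e in effects],
        true_h2=float(h2),
        trait_type=trait_type,
        population_labels=(
            [int(x) for x in population_labels]
            if population_labels is not None
            else [0] * g.n_samples
        ),
    )
    return pheno, truth


def write_vcf(path, g: GenotypeMatrix, variants: pd.DataFrame) -> None:
    """Write genotypes as a minimal text VCF 4.2 (GT only).

    REF is written as A2 and ALT as A1, so the dosage is the ALT-allele
    count; the reader's minor-allele rule recovers the same matrix.
    """
    path = Path(path)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    iids = [iid for _, iid in g.sample_ids]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(iids) + "\n")
        for j, row in variants.iterrows():
            calls = "\t".join(gt_map[int(d)] for d in g.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['variant_id']}\t"
                f"{row['a2']}\t{row['a1']}\t.\t.\t.\tGT\t{calls}\n"
            )


def recode_to_minor(g: GenotypeMatrix, variants: pd.DataFrame):
    """Flip columns whose counted allele is the major one so dosage counts
    the cohort minor allele (ties untouched); swaps a1/a2 to match.

    Keeps fixture bundles self-consistent: the VCF reader assigns A1 to
    the minor allele, so writing minor-coded dosages makes VCF and PLINK
    members load identically.
    """
    d = g.dosages.copy()
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.where(obs, d, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
    flip = f > 0.5
    d[:, flip] = np.where(obs[:, flip], 2 - d[:, flip], MISSING).astype(np.int8)
    v = variants.copy()
    v.loc[flip, ["a1", "a2"]] = v.loc[flip, ["a2", "a1"]].to_numpy()
    return GenotypeMatrix(d, list(g.sample_ids), list(g.variant_ids)), v


def _toy4x3() -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Hand-specified 4-sample x 3-variant set with one MISSING cell.

    Dosage columns [0,1,2,2], [2,MISSING,0,1], [0,0,0,0] give per-variant
    MAFs 0.375, 0.5, 0.0 and missing rates 0, 0.25, 0.
    """
    dosages = np.array(
        [[0, 2, 0], [1, MISSING, 0], [2, 0, 0], [2, 1, 0]], dtype=np.int8
    )
    vids = ["toy1", "toy2", "toy3"]
    variants = make_variant_table(
        chrom=["1", "1", "2"],
        variant_id=vids,
        pos=[100, 200, 100],
        a1=["A", "C", "T"],
        a2=["G", "T", "C"],
    )
    iids = [f"t{i}" for i in range(1, 5)]
    samples = make_sample_table(iids, iids)
    return GenotypeMatrix(dosages, [(i, i) for i in iids], vids), variants, samples


def write_fixture_set(output_dir, scenario: str, seed: int = 0) -> dict[str, Path]:
    """Write a deterministic fixture bundle for a named scenario.

    Each bundle holds a VCF, the PLINK triple, a phenotype CSV and a
    truth JSON.  ``toy4x3`` is fully hand-specified (seed ignored except
    for the phenotype noise).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = None

    if scenario == "toy4x3":
        g, variants, samples = _toy4x3()
        pheno = pd.DataFrame(
            {"fid": [s[0] for s in g.sample_ids], "iid": [s[1] for s in g.sample_ids],
             "value": [1.0, 2.0, 3.0, 2.5]}
        )
        truth = SimTruth([], [], 0.0, "quantitative", [0, 0, 0, 0])
    elif scenario == "structured_null":
        g, variants, samples, labels = simulate_genotypes(
            200, 2000, n_pops=2, fst=0.1, seed=seed
        )
        rng = np.random.default_rng(seed + 1)
        y = 1.0 * labels + rng.standard_normal(g.n_samples)
        pheno = pd.DataFrame(
            {"fid": [s[0] for s in g.sample_ids], "iid": [s[1] for s in g.sample_ids], "value": y}
        )
        truth = SimTruth([], [], 0.0, "quantitative", [int(x) for x in labels])
    elif scenario == "single_causal":
        g, variants, samples, labels = simulate_genotypes(300, 1000, seed=seed)
        pheno, truth = simulate_phenotype(g, n_causal=1, h2=0.3, seed=seed)
    else:  # gp_benchmark
        g, variants, samples, labels = simulate_genotypes(500, 2000, seed=seed)
        pheno, truth = simulate_phenotype(g, n_causal=50, h2=0.6, seed=seed)

    g, variants = recode_to_minor(g, variants)
    paths = {
        "vcf": out / f"{scenario}.vcf",
        "prefix": out / scenario,
        "pheno": out / f"{scenario}_pheno.csv",
        "truth": out / f"{scenario}_truth.json",
    }
    write_vcf(paths["vcf"], g, variants)
    write_plink(g, variants, samples, paths["prefix"])
    pheno.to_csv(paths["pheno"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)
    return paths
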