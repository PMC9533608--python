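"""Synthetic structured-population data for exercising the design pipeline.

Generates a random reference genome, a set of diploid populations with
tunable differentiation, and everything the downstream modules need to be
tested without real sequencing data: a MAF spectrum with rare and common
alleles, missing genotypes, a read-depth layer, paralog-like systematically
heterozygous sites, X-linked sites (hemizygous males reported as diploid
homozygotes, the way a chip calls them), and Y-linked presence/absence
probes.

Population differentiation follows the Balding–Nichols model: each
population's allele frequency at a site is drawn from a Beta distribution
centred on the ancestral frequency p with dispersion set by FST,
Beta(p (1-F)/F, (1-p)(1-F)/F).  Sites are independent, so by default the
simulator induces no LD; :func:`simulate_ld_cohort` provides a
founder-haplotype block mode in which each population draws haplotypes from
a finite founder pool — small pools (bottlenecked populations) genuinely
elevate r2 between nearby sites.

All randomness flows from ``cfg.seed`` through a single integer-state
generator, so a configuration maps to byte-identical output files across
runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix, VariantRecord, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults model a small design study: 5 autosomal-scale scaffolds of 200 kb
    plus one X scaffold, one SNP per ~2 kb, three populations of 20 diploid
    samples at FST 0.1, a 2% missing-genotype rate, mean depth 8x (low-coverage
    WGS territory), 2% paralog-like sites and 6 Y probes.
    """

    seed: int = 0
    n_scaffolds: int = 5
    scaffold_length: int = 200_000
    snp_per_bp: float = 1 / 2_000
    n_populations: int = 3
    fst: float = 0.1
    n_samples_per_pop: int = 20
    sex_ratio: float = 0.5  # fraction male
    missing_rate: float = 0.02
    mean_depth: float = 8.0
    paralog_fraction: float = 0.02
    maf_spectrum: str = "uniform"  # ancestral freq ~ U(0.05, 0.95); "beta" for U-shaped
    x_scaffold: str = "scaffold_X"
    x_scaffold_length: int = 200_000
    n_y_probes: int = 6
    bottleneck_pops: set[int] = field(default_factory=set)
    bottleneck_factor: float = 5.0  # FST multiplier for bottlenecked populations
    duplicate_segment: bool = False  # plant a duplicated 101-mer for uniqueness tests

    def __post_init__(self) -> None:
        if not (0 < self.fst < 1):
            raise ValueError("fst must lie in (0, 1)")
        for rate in (self.missing_rate, self.paralog_fraction, self.sex_ratio):
            if not (0 <= rate <= 1):
                raise ValueError(f"rate out of [0, 1]: {rate}")


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


# -- reference --------------------------------------------------------------


def simulate_reference(cfg: SimConfig) -> dict[str, str]:
    """Random nucleotide scaffolds (autosomes + one X scaffold).

    With ``cfg.duplicate_segment`` a 101-bp block from the middle of the
    first scaffold is copied into the second, giving a known multi-mapping
    flank for the uniqueness screen.
    """
    rng = _rng(cfg, 1)
    ref: dict[str, str] = {}
    for i in range(cfg.n_scaffolds):
        seq = "".join(_BASES[rng.integers(0, 4, size=cfg.scaffold_length)])
        ref[f"scaffold_{i + 1}"] = seq
    ref[cfg.x_scaffold] = "".join(_BASES[rng.integers(0, 4, size=cfg.x_scaffold_length)])
    if cfg.duplicate_segment and cfg.n_scaffolds >= 2:
        src = ref["scaffold_1"]
        mid = len(src) // 2
        # the 101-mer window centred on 1-based position `mid`
        block = src[mid - 51 : mid + 50]
        tgt = ref["scaffold_2"]
        ref["scaffold_2"] = tgt[:1000] + block + tgt[1000 + len(block):]
    return ref


def write_reference_fasta(ref: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def scaffold_length_table(ref: Mapping[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"scaffold": list(ref), "length": [len(s) for s in ref.values()]}
    )


# -- cohort -----------------------------------------------------------------


def _ancestral_freqs(rng: np.random.Generator, n: int, spectrum: str) -> np.ndarray:
    if spectrum == "uniform":
        return rng.uniform(0.05, 0.95, size=n)
    if spectrum == "beta":
        # U-shaped spectrum: plenty of rare alleles alongside common ones
        return np.clip(rng.beta(0.4, 0.4, size=n), 0.01, 0.99)
    raise ValueError(f"unknown maf_spectrum {spectrum!r}")


def _bn_freqs(
    rng: np.random.Generator, p: np.ndarray, fst: float
) -> np.ndarray:
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)


def simulate_cohort(
    cfg: SimConfig, reference: Mapping[str, str]
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate genotypes for all populations against a reference.

    Returns ``(matrix, variant_truth, sample_truth)``:

    * autosomal sites: per-population frequencies from the Balding–Nichols
      beta around an ancestral frequency; genotypes Binomial(2, p_pop);
    * X-linked sites: females Binomial(2, p), males Binomial(1, p) doubled so
      hemizygous calls appear homozygous, as a chip reports them;
    * Y probes (scaffold ``Y_probes``): reference-allele call in every male,
      no-call in every female;
    * paralog-like sites: heterozygous in every sample;
    * missingness and a Poisson depth layer injected at the configured rates.

    The variant truth table carries ancestral and per-population frequencies
    and site-class flags; the sample table carries population and true sex.
    """
    if cfg.x_scaffold not in reference:
        raise ValueError(f"x_scaffold {cfg.x_scaffold!r} not in reference")
    rng = _rng(cfg, 2)

    samples: list[str] = []
    pops: list[int] = []
    for k in range(cfg.n_populations):
        for i in range(cfg.n_samples_per_pop):
            samples.append(f"pop{k + 1}_s{i + 1:03d}")
            pops.append(k)
    pops_arr = np.array(pops)
    n_samples = len(samples)
    is_male = rng.random(n_samples) < cfg.sex_ratio

    # site placement: Bernoulli thinning along each scaffold, edges left clear
    # so every site can carry a 101-mer design sequence
    variants: list[VariantRecord] = []
    site_scaffold: list[str] = []
    for name, seq in reference.items():
        lo, hi = 51, len(seq) - 50
        n_sites = rng.binomial(hi - lo, cfg.snp_per_bp)
        pos = np.sort(rng.choice(np.arange(lo, hi), size=n_sites, replace=False))
        for p in pos:
            ref_base = seq[p - 1].upper()
            alt = rng.choice([b for b in "ACGT" if b != ref_base])
            variants.append(VariantRecord(name, int(p), ref_base, alt))
            site_scaffold.append(name)
    n_sites = len(variants)
    is_x = np.array([sc == cfg.x_scaffold for sc in site_scaffold])

    anc = _ancestral_freqs(rng, n_sites, cfg.maf_spectrum)
    fst_per_pop = np.full(cfg.n_populations, cfg.fst)
    for k in cfg.bottleneck_pops:
        fst_per_pop[k] = min(0.9, cfg.fst * cfg.bottleneck_factor)
    pop_freqs = np.stack(
        [_bn_freqs(rng, anc, fst_per_pop[k]) for k in range(cfg.n_populations)]
    )  # pops x sites

    dosage = np.empty((n_samples, n_sites), dtype=np.int8)
    for k in range(cfg.n_populations):
        rows = pops_arr == k
        p = pop_freqs[k]
        dosage[rows] = rng.binomial(2, p, size=(int(rows.sum()), n_sites)).astype(np.int8)
        # X sites: males carry one copy, reported as a homozygous diploid call
        male_rows = rows & is_male
        if male_rows.any() and is_x.any():
            hap = rng.binomial(1, p[is_x], size=(int(male_rows.sum()), int(is_x.sum())))
            dosage[np.ix_(male_rows, is_x)] = (2 * hap).astype(np.int8)

    # paralog-like collapsed sites: every sample heterozygous
    n_paralog = int(round(cfg.paralog_fraction * int((~is_x).sum())))
    paralog_idx = rng.choice(np.where(~is_x)[0], size=n_paralog, replace=False)
    is_paralog = np.zeros(n_sites, dtype=bool)
    is_paralog[paralog_idx] = True
    dosage[:, paralog_idx] = 1

    # missingness then depth (missing cells get depth 0)
    miss = rng.random(dosage.shape) < cfg.missing_rate
    dosage[miss] = MISSING
    depth = rng.poisson(cfg.mean_depth, size=dosage.shape).astype(np.int32)
    depth[miss] = 0

    # Y-probe block appended after the genomic sites
    y_variants = []
    if cfg.n_y_probes > 0:
        y_dosage = np.full((n_samples, cfg.n_y_probes), MISSING, dtype=np.int8)
        y_dosage[is_male, :] = 0  # present -> reference-allele call
        y_miss = rng.random(y_dosage.shape) < cfg.missing_rate
        y_dosage[y_miss] = MISSING
        y_depth = rng.poisson(cfg.mean_depth, size=y_dosage.shape).astype(np.int32)
        y_depth[y_dosage == MISSING] = 0
        for j in range(cfg.n_y_probes):
            ref_base, alt_base = "A", "C"
            y_variants.append(VariantRecord("Y_probes", 100 * (j + 1), ref_base, alt_base))
        dosage = np.hstack([dosage, y_dosage])
        depth = np.hstack([depth, y_depth])

    all_variants = variants + y_variants
    m = GenotypeMatrix(samples=samples, variants=all_variants, dosage=dosage, depth=depth)

    variant_truth = pd.DataFrame(
        {
            "id": [v.id for v in all_variants],
            "scaffold": [v.scaffold for v in all_variants],
            "pos": [v.pos for v in all_variants],
            "is_x": list(is_x) + [False] * len(y_variants),
            "is_y_probe": [False] * n_sites + [True] * len(y_variants),
            "is_paralog": list(is_paralog) + [False] * len(y_variants),
            "ancestral_freq": list(anc) + [np.nan] * len(y_variants),
        }
    )
    for k in range(cfg.n_populations):
        variant_truth[f"freq_pop{k + 1}"] = list(pop_freqs[k]) + [np.nan] * len(y_variants)
    variant_truth = variant_truth.set_index("id")

    sample_truth = pd.DataFrame(
        {
            "sample_id": samples,
            "population": [f"pop{k + 1}" for k in pops],
            "sex": np.where(is_male, "M", "F"),
        }
    ).set_index("sample_id")
    return m, variant_truth, sample_truth


def simulate_ld_cohort(
    cfg: SimConfig,
    founders_per_pop: Mapping[int, int],
    n_sites: int = 100,
    block_size: int = 10,
    site_spacing: int = 1_000,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Founder-haplotype block mode for LD tests.

    Sites come in blocks of ``block_size``; within a block each population's
    chromosomes are drawn (with replacement) from a pool of
    ``founders_per_pop[k]`` founder haplotypes.  A small pool — the
    signature of a bottlenecked, low effective-size population — makes
    nearby sites co-segregate and drives r2 up; a large pool approaches
    linkage equilibrium.
    """
    rng = _rng(cfg, 3)
    samples, pops = [], []
    for k in range(cfg.n_populations):
        for i in range(cfg.n_samples_per_pop):
            samples.append(f"pop{k + 1}_s{i + 1:03d}")
            pops.append(k)
    pops_arr = np.array(pops)
    variants = [
        VariantRecord("scaffold_1", 1 + j * site_spacing, "A", "G")
        for j in range(n_sites)
    ]
    dosage = np.empty((len(samples), n_sites), dtype=np.int8)
    n_blocks = int(np.ceil(n_sites / block_size))
    for b in range(n_blocks):
        cols = slice(b * block_size, min((b + 1) * block_size, n_sites))
        width = cols.stop - cols.start
        freqs = rng.uniform(0.2, 0.8, size=width)
        for k in range(cfg.n_populations):
            nf = founders_per_pop.get(k, 2 * cfg.n_samples_per_pop)
            founders = rng.binomial(1, freqs, size=(nf, width))
            rows = np.where(pops_arr == k)[0]
            pick = rng.integers(0, nf, size=(len(rows), 2))
            dosage[rows, cols] = (founders[pick[:, 0]] + founders[pick[:, 1]]).astype(np.int8)
    m = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)
    truth = pd.DataFrame(
        {"sample_id": samples, "population": [f"pop{k + 1}" for k in pops]}
    ).set_index("sample_id")
    return m, truth


# -- output -----------------------------------------------------------------


def write_cohort_vcf(
    m: GenotypeMatrix,
    variant_truth: pd.DataFrame,
    sample_truth: pd.DataFrame,
    out_dir: str | Path,
    stem: str = "cohort",
) -> dict[str, Path]:
    """Write the cohort VCF plus truth/metadata TSVs; returns the paths.

    The VCF round-trips losslessly through :func:`markerpanel.genodata.read_vcf`
    and is byte-deterministic for a given configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / f"{stem}.vcf",
        "variant_truth": out_dir / f"{stem}.variant_truth.tsv",
        "sample_truth": out_dir / f"{stem}.sample_truth.tsv",
        "metadata": out_dir / f"{stem}.metadata.tsv",
    }
    write_vcf(m, paths["vcf"])
    variant_truth.to_csv(paths["variant_truth"], sep="\t")
    sample_truth.to_csv(paths["sample_truth"], sep="\t")
    meta = pd.DataFrame(
        {
            "sample_id": sample_truth.index,
            "cohort": stem,
            "group": sample_truth["population"]
            if "population" in sample_truth
            else "",
            "known_sex": sample_truth["sex"] if "sex" in sample_truth else "U",
        }
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    return paths
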