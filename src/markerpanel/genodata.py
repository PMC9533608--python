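"""Core data model and I/O for SNP-array design.

The central container is :class:`GenotypeMatrix`: a samples x variants matrix of
alt-allele dosages (0, 1, 2 or missing) with an optional per-cell read-depth
layer.  Everything downstream — quality filtering, panel selection, discriminant
analysis, sexing — operates on this matrix or on per-site summaries derived from
it (:class:`SiteStats`).

Coordinates are 1-based as in VCF.  Missing genotypes (including half-calls such
as ``0/.``) are encoded as :data:`MISSING` and are always distinguishable from a
homozygous-reference call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype. Stored in int8 matrices.
MISSING: int = -1

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class VariantRecord:
    """A biallelic SNP: one scaffold, one 1-based position, two single bases."""

    scaffold: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"not a SNP: {self.ref_allele}>{self.alt_allele}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"identical alleles at {self.scaffold}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def id(self) -> str:
        return canonical_key(self)


def canonical_key(v: VariantRecord) -> str:
    """Deterministic site key, invariant to swapping ref/alt labels.

    The same site called in two cohorts with opposite ref/alt polarisation
    collapses to a single key, which is what makes cross-cohort catalog
    algebra (unions/intersections) well defined.
    """
    a, b = sorted((v.ref_allele.upper(), v.alt_allele.upper()))
    return f"{v.scaffold}:{v.pos}:{a}:{b}"


@dataclass
class SiteStats:
    """Per-site summary over called genotypes.

    ``maf`` is folded (<= 0.5); ``ho`` is the fraction of called genotypes
    that are heterozygous; ``minor_allele_sample_count`` counts samples
    carrying at least one copy of the minor allele.
    """

    maf: float
    missingness: float
    ho: float
    n_called: int
    minor_allele_count: int
    minor_allele_sample_count: int
    degenerate: bool = False


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-dosage matrix with optional depth layer.

    dosage is int8 with values {0, 1, 2, MISSING}; depth, when present, is a
    non-negative int32 array of identical shape.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray
    depth: np.ndarray | None = None
    _vindex: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth layer shape mismatch")
        self._vindex = {v.id: i for i, v in enumerate(self.variants)}
        if len(self._vindex) != len(self.variants):
            raise ValueError("duplicate canonical keys in variant list")

    # -- indexing helpers -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, vid: str) -> int:
        return self._vindex[vid]

    def subset_variants(self, ids: Iterable[str]) -> "GenotypeMatrix":
        """New matrix restricted to the given variant ids (matrix order kept)."""
        wanted = set(ids)
        cols = [i for i, v in enumerate(self.variants) if v.id in wanted]
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in cols],
            dosage=self.dosage[:, cols].copy(),
            depth=None if self.depth is None else self.depth[:, cols].copy(),
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            samples=list(names),
            variants=list(self.variants),
            dosage=self.dosage[rows, :].copy(),
            depth=None if self.depth is None else self.depth[rows, :].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=list(self.variants),
            dosage=self.dosage.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )


# -- per-site / per-sample statistics -------------------------------------


def site_stats(m: GenotypeMatrix, variant_index: int) -> SiteStats:
    """Summary statistics for one site.

    With called genotype counts (n_hom_ref, n_het, n_hom_alt):
    alt frequency p = (2 n_hom_alt + n_het) / (2 n_called), maf = min(p, 1-p),
    ho = n_het / n_called.  A site with zero called genotypes is returned with
    maf = ho = 0 and ``degenerate=True`` rather than raising.
    """
    col = m.dosage[:, variant_index]
    called = col != MISSING
    n_called = int(called.sum())
    n = m.n_samples
    missingness = (n - n_called) / n
    if n_called == 0:
        return SiteStats(0.0, missingness, 0.0, 0, 0, 0, degenerate=True)
    n_het = int((col == 1).sum())
    n_hom_alt = int((col == 2).sum())
    alt_count = 2 * n_hom_alt + n_het
    total = 2 * n_called
    p = alt_count / total
    if alt_count <= total - alt_count:
        minor_count = alt_count
        carriers = int(((col == 1) | (col == 2)).sum())
    else:
        minor_count = total - alt_count
        carriers = int(((col == 1) | (col == 0)).sum())
    return SiteStats(
        # from integer counts: exact at threshold boundaries like 4/20
        maf=minor_count / total,
        missingness=missingness,
        ho=n_het / n_called,
        n_called=n_called,
        minor_allele_count=minor_count,
        minor_allele_sample_count=carriers,
    )


def all_site_stats(m: GenotypeMatrix) -> pd.DataFrame:
    """Vectorised :func:`site_stats` over every site; one row per variant."""
    d = m.dosage
    called = d != MISSING
    n_called = called.sum(axis=0)
    n_het = (d == 1).sum(axis=0)
    n_hom_alt = (d == 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ho = np.where(n_called > 0, n_het / n_called, 0.0)
    alt_count = 2 * n_hom_alt + n_het
    minor_is_alt = alt_count <= (2 * n_called - alt_count)
    minor_count = np.where(minor_is_alt, alt_count, 2 * n_called - alt_count)
    alt_carriers = ((d == 1) | (d == 2)).sum(axis=0)
    ref_carriers = ((d == 1) | (d == 0)).sum(axis=0)
    carriers = np.where(minor_is_alt, alt_carriers, ref_carriers)
    with np.errstate(divide="ignore", invalid="ignore"):
        # integer-count ratio: exact at threshold boundaries like 4/20
        maf = np.where(n_called > 0, minor_count / (2 * n_called), 0.0)
    return pd.DataFrame(
        {
            "maf": maf,
            "missingness": (m.n_samples - n_called) / m.n_samples,
            "ho": ho,
            "n_called": n_called,
            "minor_allele_count": minor_count,
            "minor_allele_sample_count": carriers,
            "degenerate": n_called == 0,
        },
        index=m.variant_ids,
    )


def sample_heterozygosity(
    m: GenotypeMatrix, variant_subset: Iterable[str]
) -> pd.DataFrame:
    """Per-sample observed heterozygosity over a variant subset.

    Returns a DataFrame indexed by sample with columns ``ho`` (NaN when
    undetermined), ``n_called`` and ``undetermined``.  Samples with zero
    non-missing calls in the subset are flagged undetermined rather than
    given an arbitrary value.
    """
    ids = list(variant_subset)
    if not ids:
        raise ValueError("variant subset is empty")
    cols = [m.variant_index(v) for v in ids]
    d = m.dosage[:, cols]
    called = (d != MISSING).sum(axis=1)
    het = (d == 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ho = np.where(called > 0, het / called, np.nan)
    return pd.DataFrame(
        {"ho": ho, "n_called": called, "undetermined": called == 0},
        index=m.samples,
    )


# -- VCF I/O ----------------------------------------------------------------


def read_vcf(path: str | Path, require_biallelic_snp: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Genotypes are mapped to alt-allele dosage; ``./.`` and half-calls become
    :data:`MISSING`; phased and unphased genotypes are treated identically.
    When ``require_biallelic_snp`` is set, multiallelic and non-SNP records
    are dropped with a logged count.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    have_depth = False
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            if require_biallelic_snp:
                n_dropped += 1
                continue
            raise ValueError(
                f"non-biallelic-SNP record at {rec.CHROM}:{rec.POS} "
                "with require_biallelic_snp disabled"
            )
        variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:  # ./., .|., half-calls
                continue
            row[i] = a + b
        dosage_rows.append(row)
        try:
            dp = rec.format("DP")
        except KeyError:  # DP absent from header
            dp = None
        if dp is not None:
            have_depth = True
            depth_rows.append(np.maximum(dp[:, 0], 0).astype(np.int32))
        else:
            depth_rows.append(np.zeros(len(samples), dtype=np.int32))
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    dosage = (
        np.array(dosage_rows, dtype=np.int8).T
        if dosage_rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depth = (
        np.array(depth_rows, dtype=np.int32).T
        if (have_depth and depth_rows)
        else None
    )
    keys = [v.id for v in variants]
    if len(set(keys)) != len(keys):
        dupes = pd.Series(keys).value_counts()
        raise ValueError(
            f"duplicate canonical keys in VCF: {dupes[dupes > 1].index.tolist()[:5]}"
        )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage, depth=depth)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(m: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 (GT, plus DP when a depth layer is present).

    Output is byte-deterministic for a given matrix, so identical runs
    produce identical files.
    """
    path = Path(path)
    with_depth = m.depth is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_depth:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        scaffolds = dict.fromkeys(v.scaffold for v in m.variants)
        for sc in scaffolds:
            fh.write(f"##contig=<ID={sc}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.samples)
            + "\n"
        )
        fmt = "GT:DP" if with_depth else "GT"
        # matrix order is preserved so read(write(m)) is the identity
        for j in range(m.n_variants):
            v = m.variants[j]
            fields = [v.scaffold, str(v.pos), v.id, v.ref_allele, v.alt_allele, ".", "PASS", ".", fmt]
            for i in range(m.n_samples):
                cell = _GT_STRING[int(m.dosage[i, j])]
                if with_depth:
                    cell += f":{int(m.depth[i, j])}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# -- sample metadata --------------------------------------------------------


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated sample table (sample_id, cohort, group, known_sex).

    ``known_sex`` takes values M/F/U; missing columns are filled with "U" or
    empty strings so downstream code can rely on their presence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata table must have a sample_id column")
    for col, default in (("cohort", ""), ("group", ""), ("known_sex", "U")):
        if col not in df.columns:
            df[col] = default
    bad = set(df["known_sex"]) - {"M", "F", "U"}
    if bad:
        raise ValueError(f"{path}: invalid known_sex values {sorted(bad)}")
    return df.set_index("sample_id")
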