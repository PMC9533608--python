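"""Cohort-aware variant filtering.

Each sequencing cohort in an array-design study gets its own
:class:`FilterProfile` — a named bundle of thresholds (MAF floor, missingness
cap, heterozygosity cap, per-call depth minimum, ...) reflecting its coverage
and sample size.  :func:`apply_profile` applies the rules in a fixed order and
returns a :class:`FilterReport` that accounts for every input variant exactly
once: a variant is attributed to the first rule that rejects it.

The heterozygosity cap (default 0.49) removes sites where essentially every
sample is heterozygous — the classic signature of collapsed paralogs rather
than true SNPs.  The density and linked-loci screens are specific to
reduced-representation (GBS) data, where clusters of nearby calls and
perfectly co-segregating neighbours are usually artefacts of a single locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix, all_site_stats


@dataclass
class FilterProfile:
    """Thresholds for one cohort's filtering column.

    A value of ``None`` (or 0 for depth/count fields) disables the rule.
    ``maf_strict`` selects a strict ``>`` comparison for the MAF floor; the
    default is inclusive ``>=``.
    """

    name: str = "custom"
    min_maf: float | None = None
    maf_strict: bool = False
    max_missing: float | None = None
    max_ho: float | None = None
    min_depth_per_call: int = 0
    min_alt_reads: int = 0
    max_variants_per_window: int | None = None
    window_bp: int = 100
    min_rare_allele_samples: int = 0
    min_group_genotyped: float | None = None

    def __post_init__(self) -> None:
        for frac in (self.min_maf, self.max_missing, self.max_ho, self.min_group_genotyped):
            if frac is not None and not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction threshold out of [0,1]: {frac}")
        if self.max_variants_per_window is not None and self.window_bp <= 0:
            raise ValueError("window_bp must be > 0 when the density screen is enabled")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterProfile":
        return cls(**json.loads(Path(path).read_text()))


def builtin_profiles() -> dict[str, FilterProfile]:
    """Preset profiles for the usual array-design cohort types.

    - three whole-genome profiles (a large ~180-sample 5X cohort, the small
      10-sample 5X cohorts, and a 20-sample 30X cohort) differing in their
      missingness tolerance and per-call depth minimum;
    - a GBS profile with the density screen, alt-read support and a strict
      MAF floor;
    - a stacks-like GBS profile keyed on per-group call rate and rare-allele
      carrier counts rather than a MAF floor.
    """
    return {
        "WGS_5X_EastCan": FilterProfile(
            name="WGS_5X_EastCan",
            min_maf=0.2,
            max_missing=0.30,
            max_ho=0.49,
            min_depth_per_call=3,
        ),
        "WGS_5X_small": FilterProfile(
            name="WGS_5X_small",
            min_maf=0.2,
            max_missing=0.50,
            max_ho=0.49,
            min_depth_per_call=3,
        ),
        "WGS_30X": FilterProfile(
            name="WGS_30X",
            min_maf=0.2,
            max_missing=0.10,
            max_ho=0.49,
            min_depth_per_call=12,
        ),
        "GBS_platypus": FilterProfile(
            name="GBS_platypus",
            min_maf=0.2,
            maf_strict=True,
            max_missing=0.30,  # = minimum 70% of samples genotyped
            max_ho=0.49,
            min_alt_reads=10,
            max_variants_per_window=3,
            window_bp=100,
        ),
        "GBS_stacks_like": FilterProfile(
            name="GBS_stacks_like",
            max_ho=0.49,
            min_depth_per_call=4,
            min_rare_allele_samples=2,
            min_group_genotyped=0.60,
        ),
    }


@dataclass
class FilterReport:
    """Accounting of one filtering run.

    ``input_count == len(survivors) + sum(rule_drops.values())`` always holds;
    every variant is attributed to the first rule that rejected it.
    """

    profile_name: str
    input_count: int
    rule_drops: dict[str, int]
    survivors: list[str]
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_count)]
        rows += [(f"dropped_{rule}", n) for rule, n in self.rule_drops.items()]
        rows.append(("survivors", self.n_survivors))
        return pd.DataFrame(rows, columns=["step", "n"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def depth_mask(m: GenotypeMatrix, min_depth: int) -> GenotypeMatrix:
    """Set genotypes supported by fewer than ``min_depth`` reads to MISSING.

    This reproduces a caller-side minimum-read requirement as a post-hoc
    genotype mask.  ``min_depth == 0`` is the identity.
    """
    if min_depth <= 0:
        return m.copy()
    if m.depth is None:
        raise ValueError("depth_mask requires a depth layer")
    out = m.copy()
    out.dosage[out.depth < min_depth] = MISSING
    return out


def density_screen(
    variants: Sequence, max_per_window: int, window_bp: int
) -> set[str]:
    """Drop variants in any length-``window_bp`` window holding too many calls.

    Sliding window over each scaffold: any run of ``max_per_window + 1``
    consecutive variants spanning fewer than ``window_bp`` bases marks all of
    its members for removal.  Returns the surviving id-set.
    """
    df = pd.DataFrame(
        {"id": [v.id for v in variants],
         "scaffold": [v.scaffold for v in variants],
         "pos": [v.pos for v in variants]}
    )
    drop: set[str] = set()
    k = max_per_window  # a window may hold up to k variants
    for _, sub in df.groupby("scaffold", sort=False):
        pos = sub["pos"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            raise ValueError("density_screen requires variants sorted by (scaffold, pos)")
        ids = sub["id"].to_numpy()
        for j in range(len(pos) - k):
            if pos[j + k] - pos[j] < window_bp:  # k+1 variants inside one window
                drop.update(ids[j : j + k + 1])
    return set(df["id"]) - drop


def discard_linked(
    m: GenotypeMatrix, window_bp: int, min_overlap: int = 10
) -> set[str]:
    """Drop downstream duplicates of nearby, identically-genotyped variants.

    Within each scaffold, a variant closer than ``window_bp`` to an already
    kept variant is dropped when their dosage vectors agree at every jointly
    called sample (with at least ``min_overlap`` shared calls).  The left-most
    member of each matching chain is kept.
    """
    keep: set[str] = set()
    by_scaffold: dict[str, list[int]] = {}
    for i, v in enumerate(m.variants):
        by_scaffold.setdefault(v.scaffold, []).append(i)
    for idxs in by_scaffold.values():
        pos = [m.variants[i].pos for i in idxs]
        if pos != sorted(pos):
            raise ValueError("discard_linked requires variants sorted by (scaffold, pos)")
        kept_here: list[int] = []
        for i in idxs:
            vi = m.variants[i]
            linked = False
            for j in reversed(kept_here):
                if vi.pos - m.variants[j].pos >= window_bp:
                    break
                a, b = m.dosage[:, i], m.dosage[:, j]
                shared = (a != MISSING) & (b != MISSING)
                if shared.sum() >= min_overlap and np.array_equal(a[shared], b[shared]):
                    linked = True
                    break
            if not linked:
                kept_here.append(i)
                keep.add(vi.id)
    return keep


def _alt_read_support(m: GenotypeMatrix) -> np.ndarray:
    # AD is not carried by the data model; approximate per-site alt support
    # as sum(depth * dosage / 2) over carriers (exact for unbiased calls).
    if m.depth is None:
        raise ValueError("min_alt_reads rule requires a depth layer")
    d = np.where(m.dosage == MISSING, 0, m.dosage).astype(np.float64)
    return (m.depth * d / 2.0).sum(axis=0)


def apply_profile(
    m: GenotypeMatrix,
    profile: FilterProfile,
    groups: pd.Series | None = None,
    keep_dropped_ids: bool = False,
) -> FilterReport:
    """Run one cohort's filtering column and account for every variant.

    Rule order: depth mask -> density screen -> alt-read support ->
    missingness -> heterozygosity cap -> MAF floor -> rare-allele carriers ->
    per-group call rate.  Thresholds keep the boundary value (missing <= cap,
    ho <= cap, maf >= floor) except when ``maf_strict`` requests ``>``.
    """
    if m.n_variants == 0:
        raise ValueError("empty genotype matrix")
    work = depth_mask(m, profile.min_depth_per_call)
    alive = pd.Series(True, index=pd.Index(work.variant_ids))
    drops: dict[str, int] = {}
    dropped_ids: dict[str, list[str]] = {}

    def reject(rule: str, bad_index) -> None:
        bad_mask = alive.index.isin(bad_index) & alive.to_numpy()
        bad = alive.index[bad_mask]
        drops[rule] = len(bad)
        if keep_dropped_ids:
            dropped_ids[rule] = list(bad)
        alive[bad_mask] = False

    if profile.max_variants_per_window is not None:
        surv = density_screen(work.variants, profile.max_variants_per_window, profile.window_bp)
        reject("density", alive.index[~alive.index.isin(surv)])

    stats = all_site_stats(work)

    if profile.min_alt_reads > 0:
        support = pd.Series(_alt_read_support(work), index=alive.index)
        reject("alt_reads", support.index[support < profile.min_alt_reads])
    if profile.max_missing is not None:
        reject("missingness", stats.index[stats["missingness"] > profile.max_missing])
    if profile.max_ho is not None:
        reject("ho", stats.index[stats["ho"] > profile.max_ho])
    if profile.min_maf is not None:
        if profile.maf_strict:
            bad = stats.index[~(stats["maf"] > profile.min_maf)]
        else:
            bad = stats.index[~(stats["maf"] >= profile.min_maf)]
        reject("maf", bad)
    if profile.min_rare_allele_samples > 0:
        reject(
            "rare_allele_samples",
            stats.index[stats["minor_allele_sample_count"] < profile.min_rare_allele_samples],
        )
    if profile.min_group_genotyped is not None and groups is not None:
        groups = groups.reindex(work.samples)
        bad_mask = np.zeros(work.n_variants, dtype=bool)
        called = work.dosage != MISSING
        for g in groups.dropna().unique():
            rows = (groups == g).to_numpy()
            frac = called[rows].mean(axis=0)
            bad_mask |= frac < profile.min_group_genotyped
        reject("group_genotyped", alive.index[bad_mask])

    survivors = list(alive.index[alive])
    report = FilterReport(
        profile_name=profile.name,
        input_count=m.n_variants,
        rule_drops=drops,
        survivors=survivors,
        dropped=dropped_ids,
    )
    assert report.input_count == report.n_survivors + sum(drops.values())
    return report
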