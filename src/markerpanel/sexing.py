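"""Genotype-based sex inference.

Two independent classifiers are combined:

* **X heterozygosity** — males carry one X, so every genuine X-linked SNP is
  reported homozygous in males while females show typical diploid
  heterozygosity; per-sample mean Ho over X-linked SNPs is bimodal, and a
  sample below the threshold (default 0.03) is called male.  SNPs in
  pseudoautosomal regions break the assumption (males can be heterozygous
  there), so the X set is first refined to SNPs monomorphic in males.
* **Y-gene probes** — probes inside a male-specific gene (SRY) return a call
  in males and systematically no-call in females; a sample missing at least
  half the functional probes (default 0.50) is called female.

The two calls are reconciled into a consensus with explicit conflict
flagging, and optionally checked against known metadata sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix, sample_heterozygosity

logger = logging.getLogger(__name__)


@dataclass
class SexingConfig:
    x_scaffolds: set[str] = field(default_factory=set)
    ho_threshold: float = 0.03
    sry_missing_threshold: float = 0.50
    min_x_snps: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.ho_threshold < 1) or not (0 < self.sry_missing_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")


def x_variant_ids(m: GenotypeMatrix, cfg: SexingConfig) -> list[str]:
    if not cfg.x_scaffolds:
        raise ValueError("no X scaffolds configured")
    ids = [v.id for v in m.variants if v.scaffold in cfg.x_scaffolds]
    if not ids:
        raise ValueError("no variants on the configured X scaffolds")
    return ids


def refine_x_snps(
    m: GenotypeMatrix,
    cfg: SexingConfig,
    known_males: Iterable[str] | None = None,
) -> tuple[list[str], bool]:
    """Restrict X-linked SNPs to those monomorphic (never het) in males.

    With ``known_males`` given, any X SNP heterozygous in at least one known
    male is dropped (pseudoautosomal proxy).  Without metadata a two-pass
    self-refinement is used: provisional sexes from all X SNPs, then SNPs
    heterozygous in any provisional male are dropped.  Returns the retained
    id-set (input order) and a degraded-confidence flag raised when no males
    were available or fewer than ``min_x_snps`` SNPs survive.
    """
    ids = x_variant_ids(m, cfg)
    degraded = False
    if known_males is not None:
        males = [s for s in known_males if s in m.samples]
    else:
        ho = sample_heterozygosity(m, ids)
        males = list(ho.index[(ho["ho"] < cfg.ho_threshold) & ~ho["undetermined"]])
    if not males:
        logger.warning("refine_x_snps: no males available; X set left unrefined")
        return ids, True
    rows = [m.samples.index(s) for s in males]
    kept = []
    for vid in ids:
        col = m.dosage[rows, m.variant_index(vid)]
        if not np.any(col == 1):
            kept.append(vid)
    if len(kept) < cfg.min_x_snps:
        logger.warning(
            "refine_x_snps: only %d X SNPs retained (< %d); confidence degraded",
            len(kept), cfg.min_x_snps,
        )
        degraded = True
    return kept, degraded


def sex_from_x(
    m: GenotypeMatrix, refined_snps: Iterable[str], cfg: SexingConfig
) -> pd.DataFrame:
    """Per-sample X heterozygosity and sex call.

    ``sex_x`` is M when x_ho < ho_threshold (strict), F otherwise, U when a
    sample has fewer than ``min_x_snps`` called X genotypes.
    """
    ids = list(refined_snps)
    if not ids:
        raise ValueError("refined X SNP set is empty")
    ho = sample_heterozygosity(m, ids)
    sex = np.where(ho["ho"] < cfg.ho_threshold, "M", "F")
    sex = np.where(ho["n_called"] < cfg.min_x_snps, "U", sex)
    return pd.DataFrame(
        {"x_ho": ho["ho"], "n_x_snps_used": ho["n_called"], "sex_x": sex},
        index=ho.index,
    )


def sex_from_sry(
    y_calls: GenotypeMatrix | pd.DataFrame, cfg: SexingConfig
) -> pd.DataFrame:
    """Per-sample sex from Y-probe call rates.

    Accepts either a GenotypeMatrix of Y probes (MISSING = no-call) or a
    boolean samples x probes DataFrame of call/no-call.  Dead probes (no call
    in any sample) are excluded before the missing fraction is computed; a
    missing fraction at or above ``sry_missing_threshold`` gives F, else M.
    """
    if isinstance(y_calls, GenotypeMatrix):
        called = pd.DataFrame(
            y_calls.dosage != MISSING, index=y_calls.samples, columns=y_calls.variant_ids
        )
    else:
        called = y_calls.astype(bool)
    functional = called.columns[called.any(axis=0)]
    if len(functional) == 0:
        raise ValueError("no functional Y probe (no probe called in any sample)")
    if len(functional) < called.shape[1]:
        logger.info(
            "sex_from_sry: excluding %d dead probe(s)", called.shape[1] - len(functional)
        )
    frac_missing = 1.0 - called[functional].mean(axis=1)
    sex = np.where(frac_missing >= cfg.sry_missing_threshold, "F", "M")
    return pd.DataFrame(
        {"sry_call_rate": 1.0 - frac_missing, "sex_sry": sex}, index=called.index
    )


def consensus_sex(
    x_calls: pd.DataFrame,
    sry_calls: pd.DataFrame | None = None,
    known_sex: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict[str, float | int]]:
    """Combine the two classifiers into per-sample SexCall rows.

    ``consensus`` is ``conflict`` iff both methods are determined and
    disagree; a single determined method carries the call (flagged
    ``single_method``).  The summary reports between-method agreement and,
    when metadata is supplied, concordance against known M/F entries.
    """
    out = x_calls.copy()
    if sry_calls is not None:
        out = out.join(sry_calls, how="outer")
    else:
        out["sry_call_rate"] = np.nan
        out["sex_sry"] = "U"
    out["sex_x"] = out["sex_x"].fillna("U")
    out["sex_sry"] = out["sex_sry"].fillna("U")

    def combine(row) -> str:
        a, b = row["sex_x"], row["sex_sry"]
        if a != "U" and b != "U":
            return a if a == b else "conflict"
        if a != "U":
            return a
        if b != "U":
            return b
        return "U"

    out["consensus"] = out.apply(combine, axis=1)
    out["single_method"] = ((out["sex_x"] == "U") ^ (out["sex_sry"] == "U"))

    both = out[(out["sex_x"] != "U") & (out["sex_sry"] != "U")]
    summary: dict[str, float | int] = {
        "n_samples": len(out),
        "n_conflicts": int((out["consensus"] == "conflict").sum()),
        "method_agreement": float((both["sex_x"] == both["sex_sry"]).mean())
        if len(both)
        else float("nan"),
    }
    if known_sex is not None:
        known = known_sex.reindex(out.index)
        mask = known.isin(["M", "F"]) & out["consensus"].isin(["M", "F"])
        summary["n_known"] = int(mask.sum())
        summary["known_concordance"] = (
            float((out.loc[mask, "consensus"] == known[mask]).mean()) if mask.any() else float("nan")
        )
        out["concordant_with_known"] = np.where(
            mask, out["consensus"] == known, np.nan
        )
    return out, summary
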