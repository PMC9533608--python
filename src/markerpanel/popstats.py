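"""Linkage-disequilibrium summaries.

LD between unphased biallelic sites is measured as the squared Pearson
correlation of alt-allele dosages over jointly called samples (composite r2,
the standard phase-free estimator).  Per-group average LD over a marker panel
is a density diagnostic: too high means adjacent markers are redundant, too
low means the panel undersamples the genome; small effective populations show
elevated averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix


@dataclass
class LDConfig:
    pairing: str = "adjacent"  # or "all_pairs_within"
    max_pair_distance: int = 500_000
    min_shared_calls: int = 10

    def __post_init__(self) -> None:
        if self.max_pair_distance <= 0:
            raise ValueError("max_pair_distance must be > 0")
        if self.pairing not in ("adjacent", "all_pairs_within"):
            raise ValueError(f"unknown pairing mode {self.pairing!r}")


def r2(d1: np.ndarray, d2: np.ndarray, min_shared_calls: int = 10) -> float:
    """Composite r2 of two dosage vectors over jointly called samples.

    Returns NaN (undefined) when fewer than ``min_shared_calls`` samples are
    jointly called or when either vector is constant on the shared set.
    """
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    shared = (d1 != MISSING) & (d2 != MISSING)
    if shared.sum() < min_shared_calls:
        return float("nan")
    a = d1[shared].astype(float)
    b = d2[shared].astype(float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairs(m: GenotypeMatrix, cfg: LDConfig) -> list[tuple[int, int]]:
    by_scaffold: dict[str, list[int]] = {}
    for i, v in enumerate(m.variants):
        by_scaffold.setdefault(v.scaffold, []).append(i)
    pairs: list[tuple[int, int]] = []
    for idxs in by_scaffold.values():
        idxs = sorted(idxs, key=lambda i: m.variants[i].pos)
        if cfg.pairing == "adjacent":
            for i, j in zip(idxs, idxs[1:]):
                if m.variants[j].pos - m.variants[i].pos <= cfg.max_pair_distance:
                    pairs.append((i, j))
        else:
            for a in range(len(idxs)):
                for b in range(a + 1, len(idxs)):
                    i, j = idxs[a], idxs[b]
                    if m.variants[j].pos - m.variants[i].pos > cfg.max_pair_distance:
                        break
                    pairs.append((i, j))
    return pairs


def group_average_ld(
    m: GenotypeMatrix, groups: pd.Series, cfg: LDConfig | None = None
) -> pd.DataFrame:
    """Mean composite r2 per group over the configured site pairs.

    Returns one row per group: n_samples, n_pairs (eligible), n_defined
    (pairs with a defined r2 in that group) and mean_r2 (NaN when no pair is
    defined, e.g. a group of clones where every vector is constant).
    """
    cfg = cfg or LDConfig()
    labels = groups.reindex(m.samples)
    pairs = _pairs(m, cfg)
    rows = []
    for g in sorted(labels.dropna().unique()):
        rmask = (labels == g).to_numpy()
        if rmask.sum() < cfg.min_shared_calls:
            raise ValueError(
                f"group {g!r} has {rmask.sum()} samples < min_shared_calls={cfg.min_shared_calls}"
            )
        vals = [
            r2(m.dosage[rmask, i], m.dosage[rmask, j], cfg.min_shared_calls)
            for i, j in pairs
        ]
        vals = np.array(vals, dtype=float)
        defined = ~np.isnan(vals)
        rows.append(
            {
                "group": g,
                "n_samples": int(rmask.sum()),
                "n_pairs": len(pairs),
                "n_defined": int(defined.sum()),
                "mean_r2": float(vals[defined].mean()) if defined.any() else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("group")
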