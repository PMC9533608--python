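"""Catalog algebra, even-spacing selection, probe screens and design output.

The genome-wide panel of an array is built in stages: per-cohort survivor
catalogs are pooled (union within a geographic pool, intersection across
pools, both keyed on canonical site keys so opposite ref/alt polarisation
collapses), then thinned to an even genome-wide spacing by a greedy
per-scaffold selector aiming at a target inter-marker gap (default 50 kb,
bounded between 30 and 60 kb), and finally screened for probe designability:
no other variant within the flanking 20 bp, and a flank sequence occurring at
a single genomic locus.  Surviving sites are emitted as 101-mer design
sequences with the allele block at position 51; probes that fail on the array
are swapped for the nearest candidate in a -20 kb / +10 kb window.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .genodata import VariantRecord, reverse_complement


@dataclass
class SpacingConfig:
    """Inter-marker spacing targets in bp (defaults: 50 kb aim, 30–60 kb band)."""

    target_gap: int = 50_000
    min_gap: int = 30_000
    max_gap: int = 60_000

    def __post_init__(self) -> None:
        if not (0 < self.min_gap <= self.target_gap <= self.max_gap):
            raise ValueError(
                f"need 0 < min_gap <= target_gap <= max_gap, got "
                f"{self.min_gap}/{self.target_gap}/{self.max_gap}"
            )


@dataclass
class PanelSelection:
    """Selected variants with panel tags and per-variant design status."""

    variants: list[VariantRecord]
    tags: dict[str, set[str]] = field(default_factory=dict)  # id -> tag set
    status: dict[str, str] = field(default_factory=dict)  # id -> design status
    gaps: list[int] = field(default_factory=list)
    overlength_gaps: list[int] = field(default_factory=list)

    VALID_TAGS = {"genome_wide", "assignment", "behaviour", "sry"}
    VALID_STATUS = {"candidate", "designed", "failed_no_call", "failed_monomorphic", "replaced"}

    @property
    def ids(self) -> set[str]:
        return {v.id for v in self.variants}

    def tag_all(self, tag: str) -> None:
        if tag not in self.VALID_TAGS:
            raise ValueError(f"unknown panel tag {tag!r}")
        for v in self.variants:
            self.tags.setdefault(v.id, set()).add(tag)

    def to_frame(self, design_sequences: Mapping[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            rows.append(
                {
                    "id": v.id,
                    "scaffold": v.scaffold,
                    "pos": v.pos,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                    "tags": ",".join(sorted(self.tags.get(v.id, set()))),
                    "status": self.status.get(v.id, "candidate"),
                    "design_sequence": (design_sequences or {}).get(v.id, ""),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path, design_sequences: Mapping[str, str] | None = None) -> None:
        self.to_frame(design_sequences).to_csv(path, sep="\t", index=False)


@dataclass
class CoverageStats:
    n_selected: int
    mean_gap: float
    median_gap: float
    n_gaps_over: int
    gap_threshold: int
    represented_fraction: float


# -- catalog algebra --------------------------------------------------------


def pool_union(catalogs: Iterable[Iterable[str]]) -> set[str]:
    """Union of variant catalogs, deduplicated by canonical key."""
    out: set[str] = set()
    for cat in catalogs:
        out |= set(cat)
    return out


def intersect_pools(pool_a: Iterable[str], pool_b: Iterable[str]) -> set[str]:
    """Sites present in both pools (canonical keys)."""
    return set(pool_a) & set(pool_b)


# -- even spacing -----------------------------------------------------------


def _group_sorted(variants: Sequence[VariantRecord]) -> dict[str, list[VariantRecord]]:
    by_scaffold: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_scaffold.setdefault(v.scaffold, []).append(v)
    for sc, vs in by_scaffold.items():
        pos = [v.pos for v in vs]
        if pos != sorted(pos):
            raise ValueError(f"candidates on {sc} not sorted by position")
    return by_scaffold


def select_spaced(
    candidates: Sequence[VariantRecord], cfg: SpacingConfig | None = None
) -> tuple[PanelSelection, list[int]]:
    """Greedy even-spacing selection, independently per scaffold.

    The first candidate of each scaffold anchors the walk.  From the last
    selected position L, the candidate inside [L+min_gap, L+max_gap] closest
    to L+target_gap is taken (ties to the smaller position); if the window is
    empty, the first candidate beyond L+max_gap is taken and the over-length
    gap recorded.  Candidates below L+min_gap are skipped.

    Returns the selection and the list of realised gaps.
    """
    cfg = cfg or SpacingConfig()
    selected: list[VariantRecord] = []
    gaps: list[int] = []
    overlength: list[int] = []
    for sc, vs in _group_sorted(candidates).items():
        pos = [v.pos for v in vs]
        selected.append(vs[0])
        last_pos = pos[0]
        while True:
            lo = bisect_left(pos, last_pos + cfg.min_gap)
            hi = bisect_right(pos, last_pos + cfg.max_gap)
            if lo < hi:
                window = pos[lo:hi]
                target = last_pos + cfg.target_gap
                best = min(range(len(window)), key=lambda k: (abs(window[k] - target), window[k]))
                choice = lo + best
            else:
                choice = bisect_right(pos, last_pos + cfg.max_gap)
                if choice >= len(pos):
                    break
                overlength.append(pos[choice] - last_pos)
            gaps.append(pos[choice] - last_pos)
            selected.append(vs[choice])
            last_pos = pos[choice]
    sel = PanelSelection(variants=selected, gaps=gaps, overlength_gaps=overlength)
    sel.tag_all("genome_wide")
    return sel, gaps


def coverage_stats(
    selection: PanelSelection,
    scaffold_lengths: Mapping[str, int],
    gap_threshold: int = 100_000,
) -> CoverageStats:
    """Gap statistics and the assembly fraction on scaffolds carrying a marker."""
    gaps = np.array(selection.gaps, dtype=float)
    covered_scaffolds = {v.scaffold for v in selection.variants}
    total = sum(scaffold_lengths.values())
    represented = sum(
        length for sc, length in scaffold_lengths.items() if sc in covered_scaffolds
    )
    return CoverageStats(
        n_selected=len(selection.variants),
        mean_gap=float(gaps.mean()) if gaps.size else float("nan"),
        median_gap=float(np.median(gaps)) if gaps.size else float("nan"),
        n_gaps_over=int((gaps > gap_threshold).sum()),
        gap_threshold=gap_threshold,
        represented_fraction=represented / total if total else 0.0,
    )


# -- probe design screens ---------------------------------------------------


def flank_window_screen(
    candidates: Iterable[str],
    full_catalog: Sequence[VariantRecord],
    half_window: int = 20,
) -> set[str]:
    """Keep candidates with no other catalog variant within ±``half_window`` bp.

    ``full_catalog`` must hold every detected variant — including ones removed
    by quality filters — because any nearby polymorphism interferes with probe
    hybridisation regardless of its own quality.
    """
    pos_by_scaffold: dict[str, np.ndarray] = {}
    for sc, vs in _group_sorted(full_catalog).items():
        pos_by_scaffold[sc] = np.array([v.pos for v in vs])
    catalog_ids = {v.id: v for v in full_catalog}
    kept: set[str] = set()
    for cid in candidates:
        v = catalog_ids.get(cid)
        if v is None:
            raise KeyError(f"candidate {cid} absent from full catalog")
        pos = pos_by_scaffold[v.scaffold]
        lo = np.searchsorted(pos, v.pos - half_window, side="left")
        hi = np.searchsorted(pos, v.pos + half_window, side="right")
        # the candidate itself always lies in its own window
        if hi - lo == 1:
            kept.add(cid)
    return kept


def flank_uniqueness(
    reference: Fasta | str | Path,
    v: VariantRecord,
    flank_len: int = 50,
) -> str:
    """Classify a variant's flank window as ``unique``, ``multi`` or ``edge``.

    The (2*flank_len + 1)-mer centred on the site is matched exactly against
    both strands of the reference with the variant base free to be either
    allele, so both allele versions hit the native locus; each genomic
    occurrence of the window therefore contributes two matches.  ``unique``
    means exactly the native locus matched (count 2); any extra occurrence —
    a duplicated flank elsewhere — yields ``multi``.  ``edge`` flags windows
    overrunning the scaffold, which cannot be designed.
    """
    fa = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    if v.scaffold not in fa:
        raise KeyError(f"scaffold {v.scaffold} absent from reference")
    length = len(fa[v.scaffold])
    if v.pos - flank_len < 1 or v.pos + flank_len > length:
        return "edge"
    left = str(fa[v.scaffold][v.pos - 1 - flank_len : v.pos - 1]).upper()
    right = str(fa[v.scaffold][v.pos : v.pos + flank_len]).upper()
    pattern = re.compile(f"(?=({re.escape(left)}.{re.escape(right)}))")
    rc = re.compile(
        f"(?=({re.escape(reverse_complement(right))}.{re.escape(reverse_complement(left))}))"
    )
    occ = 0
    for name in fa.keys():
        seq = str(fa[name][:]).upper()
        occ += sum(1 for _ in pattern.finditer(seq))
        occ += sum(1 for _ in rc.finditer(seq))
    # palindromic windows would match themselves on both strands; the native
    # locus is guaranteed to contribute at least one forward hit
    total = 2 * occ  # both allele versions match every occurrence
    return "unique" if total == 2 else "multi"


def make_design_sequence(
    reference: Fasta | str | Path, v: VariantRecord, flank_len: int = 50
) -> str:
    """101-mer array design string: 50 bp flank + ``[A/B]`` block + 50 bp flank.

    Alleles are shown alphabetically at position 51; flanks are uppercase
    reference sequence.  Sites too close to a scaffold edge are rejected.
    """
    fa = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    if v.scaffold not in fa:
        raise KeyError(f"scaffold {v.scaffold} absent from reference")
    length = len(fa[v.scaffold])
    if v.pos < flank_len + 1 or v.pos > length - flank_len:
        raise ValueError(
            f"variant {v.id} too close to scaffold edge for a "
            f"{2 * flank_len + 1}-mer design sequence"
        )
    left = str(fa[v.scaffold][v.pos - 1 - flank_len : v.pos - 1]).upper()
    right = str(fa[v.scaffold][v.pos : v.pos + flank_len]).upper()
    a, b = sorted((v.ref_allele.upper(), v.alt_allele.upper()))
    return f"{left}[{a}/{b}]{right}"


# -- replacement search -----------------------------------------------------


def select_replacements(
    failed: Sequence[VariantRecord],
    candidates: Sequence[VariantRecord],
    upstream: int = 20_000,
    downstream: int = 10_000,
) -> dict[str, str | None]:
    """Map each failed probe to the nearest eligible replacement, or None.

    For a failed site at P the window [P - upstream, P + downstream] on the
    same scaffold is searched (inclusive ends); the candidate minimising
    |pos - P| wins, ties broken downstream.  Sites with an empty window are
    returned as None (to be re-designed rather than replaced).
    """
    cand_by_scaffold = _group_sorted(candidates)
    out: dict[str, str | None] = {}
    for f in failed:
        vs = cand_by_scaffold.get(f.scaffold, [])
        pos = [v.pos for v in vs]
        lo = bisect_left(pos, f.pos - upstream)
        hi = bisect_right(pos, f.pos + downstream)
        best: VariantRecord | None = None
        best_key: tuple[int, int] | None = None
        for v in vs[lo:hi]:
            if v.id == f.id:
                continue
            # tie on distance -> prefer downstream (pos > P sorts first)
            key = (abs(v.pos - f.pos), 0 if v.pos > f.pos else 1)
            if best_key is None or key < best_key:
                best, best_key = v, key
        out[f.id] = best.id if best is not None else None
    return out


# -- export -----------------------------------------------------------------


def scaffold_lengths_from_fasta(reference: Fasta | str | Path) -> dict[str, int]:
    fa = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    return {name: len(fa[name]) for name in fa.keys()}
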