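"""Shared fixtures and independent oracles.

The oracles here (Weir–Cockerham FST, naive spacing walk) are deliberately
written from the textbook definitions, separate from the package code paths
they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from markerpanel.genodata import MISSING, GenotypeMatrix, VariantRecord


def make_matrix(dosage, scaffold="sc1", start_pos=100, spacing=100, depth=None,
                samples=None) -> GenotypeMatrix:
    """Matrix from a literal (samples x variants) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_variants = dosage.shape
    variants = [
        VariantRecord(scaffold, start_pos + j * spacing, "A", "G")
        for j in range(n_variants)
    ]
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage, depth=depth)


def site_from_counts(n_hom_ref: int, n_het: int, n_hom_alt: int, n_missing: int = 0):
    """Column of dosages realising given genotype counts."""
    return [0] * n_hom_ref + [1] * n_het + [2] * n_hom_alt + [MISSING] * n_missing


def weir_cockerham_fst(dosage: np.ndarray, pops: np.ndarray) -> float:
    """Multi-population Weir–Cockerham (1984) theta over loci.

    ``dosage``: samples x loci with MISSING allowed; ``pops``: integer
    population label per sample.  Ratio-of-sums estimator: sum(a) over
    sum(a + b + c).
    """
    pop_ids = np.unique(pops)
    r = len(pop_ids)
    num = 0.0
    den = 0.0
    for j in range(dosage.shape[1]):
        col = dosage[:, j]
        n_i, p_i, h_i = [], [], []
        for k in pop_ids:
            sub = col[(pops == k) & (col != MISSING)]
            if len(sub) < 2:
                n_i = []
                break
            n_i.append(len(sub))
            p_i.append(sub.mean() / 2.0)
            h_i.append((sub == 1).mean())
        if not n_i:
            continue
        n_i = np.array(n_i, dtype=float)
        p_i = np.array(p_i)
        h_i = np.array(h_i)
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def naive_spacing_walk(positions, min_gap, target_gap, max_gap):
    """Literal restatement of the even-spacing rule with plain list scans."""
    pos = list(positions)
    selected = [pos[0]]
    while True:
        last = selected[-1]
        window = [p for p in pos if last + min_gap <= p <= last + max_gap]
        if window:
            best = min(window, key=lambda p: (abs(p - (last + target_gap)), p))
            selected.append(best)
            continue
        beyond = [p for p in pos if p > last + max_gap]
        if not beyond:
            return selected
        selected.append(beyond[0])


@pytest.fixture(scope="session")
def sim_cohort():
    """One default-condition simulated cohort shared by read-only tests."""
    from markerpanel.simdata import SimConfig, simulate_cohort, simulate_reference

    cfg = SimConfig(seed=11)
    ref = simulate_reference(cfg)
    m, vtruth, struth = simulate_cohort(cfg, ref)
    return cfg, ref, m, vtruth, struth
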