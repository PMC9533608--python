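"""Assignment-panel selection via discriminant analysis of principal components.

DAPC first compresses the (samples x variants) dosage matrix with PCA, then
runs a linear discriminant analysis on the retained principal-component
scores, maximising between-group relative to within-group variation for
predefined groups (here: ecotypes / genetic groups).  Because both steps are
linear, every variant gets a well-defined contribution to each discriminant
axis: the squared composition of its PC loadings with the discriminant
coefficients, normalised to sum to one per axis.  The highest-contributing
variants are the most group-diagnostic markers and form the assignment panel.

Hierarchically structured populations are handled by a sequence of contrasts
(:class:`HierarchicalScheme`): each level subsets the samples and regroups
them (e.g. isolated population vs rest, then ecotype vs ecotype, then
subgroup structure), and the panel is the union of the per-contrast top
loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genodata import MISSING, GenotypeMatrix, VariantRecord
from .panelbuild import PanelSelection


@dataclass
class DAPCConfig:
    """Settings for one DAPC fit.

    ``n_pcs=None`` retains the axes reaching ``var_explained`` cumulative
    variance, capped at n_samples/3 (retaining too many PCs overfits the
    discriminant step).  ``score_mode`` picks how per-variant scores are
    collapsed across discriminant axes for ranking: the maximum over axes
    (default; keeps variants discriminating on any axis) or an
    eigenvalue-weighted sum.
    """

    n_pcs: int | None = None
    n_da: int | None = None
    var_explained: float = 0.80
    center: bool = True
    scale: bool = False
    top_n: int = 2_000
    score_mode: str = "max"  # or "weighted"
    seed: int = 0


@dataclass
class DAPCModel:
    """Fitted transforms plus per-variant discriminant contributions."""

    variant_ids: list[str]
    groups: list[str]
    train_means: np.ndarray  # per-variant imputation/centering means
    train_scales: np.ndarray
    pc_loadings: np.ndarray  # variants x n_pcs
    da_coefficients: np.ndarray  # n_pcs x n_da
    da_eigenvalues: np.ndarray
    group_centroids: np.ndarray  # groups x n_da
    var_contributions: np.ndarray  # variants x n_da, columns sum to 1
    config: DAPCConfig

    @property
    def n_da(self) -> int:
        return self.da_coefficients.shape[1]

    def variant_scores(self) -> np.ndarray:
        if self.config.score_mode == "weighted":
            w = self.da_eigenvalues / self.da_eigenvalues.sum()
            return self.var_contributions @ w
        return self.var_contributions.max(axis=1)


@dataclass
class Contrast:
    """One level of a hierarchical scheme: a sample filter plus a relabelling."""

    name: str
    subset: Callable[[pd.Series], pd.Series]  # labels -> boolean mask
    relabel: Callable[[pd.Series], pd.Series] = field(default=lambda s: s)


@dataclass
class HierarchicalScheme:
    contrasts: list[Contrast]


def three_level_scheme(
    isolated: str, migratory: str, boreal_groups: Sequence[str]
) -> HierarchicalScheme:
    """The canonical three-level design for a caribou-like structure:
    (1) isolated mountain population vs everything else, (2) migratory vs
    boreal with the mountain samples excluded, (3) structure among the boreal
    subgroups only.
    """
    boreal = set(boreal_groups)

    def lvl1(labels: pd.Series) -> pd.Series:
        return pd.Series(True, index=labels.index)

    def relabel1(labels: pd.Series) -> pd.Series:
        return labels.where(labels == isolated, "other")

    def lvl2(labels: pd.Series) -> pd.Series:
        return labels != isolated

    def relabel2(labels: pd.Series) -> pd.Series:
        return labels.where(labels == migratory, "boreal")

    def lvl3(labels: pd.Series) -> pd.Series:
        return labels.isin(boreal)

    return HierarchicalScheme(
        [
            Contrast("isolated_vs_rest", lvl1, relabel1),
            Contrast("migratory_vs_boreal", lvl2, relabel2),
            Contrast("boreal_subgroups", lvl3),
        ]
    )


# -- fitting ----------------------------------------------------------------


def _impute_center_scale(
    dosage: np.ndarray, center: bool, scale: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = dosage.astype(np.float64)
    missing = dosage == MISSING
    x[missing] = np.nan
    means = np.nanmean(x, axis=0)
    means = np.where(np.isnan(means), 0.0, means)  # all-missing variant
    inds = np.where(missing)
    x[inds] = means[inds[1]]
    if center:
        x = x - means
    if scale:
        sd = x.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        x = x / sd
    else:
        sd = np.ones(x.shape[1])
    return x, means, sd


def dapc_fit(
    m: GenotypeMatrix, groups: pd.Series, cfg: DAPCConfig | None = None
) -> DAPCModel:
    """Fit a DAPC model to grouped samples.

    Missing dosages are mean-imputed per variant before centering (keeps the
    transform linear); PCA retains ``cfg.n_pcs`` axes; the discriminant step
    is an eigen-solver LDA on the PC scores.  Per-variant contribution to
    axis a is (sum_k pc_loadings[j,k] * da_coef[k,a])^2 normalised to sum
    to 1 over variants j.
    """
    cfg = cfg or DAPCConfig()
    labels = groups.reindex(m.samples)
    if labels.isna().any():
        raise ValueError("group labels missing for some samples")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("DAPC needs at least 2 groups")

    x, means, sd = _impute_center_scale(m.dosage, cfg.center, cfg.scale)
    max_rank = min(m.n_samples - 1, m.n_variants)
    if cfg.n_pcs is not None:
        if cfg.n_pcs > max_rank:
            raise ValueError(f"n_pcs={cfg.n_pcs} exceeds data rank {max_rank}")
        n_pcs = cfg.n_pcs
    else:
        probe = PCA(n_components=max_rank, random_state=cfg.seed).fit(x)
        cum = np.cumsum(probe.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, cfg.var_explained) + 1)
        n_pcs = max(1, min(n_pcs, m.n_samples // 3, max_rank))

    pca = PCA(n_components=n_pcs, random_state=cfg.seed).fit(x)
    loadings = pca.components_.T  # variants x n_pcs
    # project with the loadings directly (not pca.transform) so training and
    # assignment go through the identical linear map
    scores = x @ loadings

    n_da = cfg.n_da if cfg.n_da is not None else len(uniq) - 1
    n_da = min(n_da, len(uniq) - 1, n_pcs)
    lda = LinearDiscriminantAnalysis(solver="eigen", n_components=n_da)
    lda.fit(scores, labels.to_numpy())
    coef = lda.scalings_[:, :n_da]  # n_pcs x n_da
    eig = getattr(lda, "explained_variance_ratio_", np.ones(n_da))[:n_da]

    da_scores = scores @ coef
    centroids = np.vstack([da_scores[(labels == g).to_numpy()].mean(axis=0) for g in uniq])

    contrib = (loadings @ coef) ** 2  # variants x n_da
    colsum = contrib.sum(axis=0)
    colsum[colsum == 0] = 1.0
    contrib = contrib / colsum

    return DAPCModel(
        variant_ids=m.variant_ids,
        groups=list(uniq),
        train_means=means,
        train_scales=sd,
        pc_loadings=loadings,
        da_coefficients=coef,
        da_eigenvalues=np.asarray(eig, dtype=float),
        group_centroids=centroids,
        var_contributions=contrib,
        config=cfg,
    )


def top_loadings(
    model: DAPCModel, top_n: int | None = None, variants: Sequence[VariantRecord] | None = None
) -> list[str]:
    """Rank variants by discriminant contribution and return the top ``top_n``.

    Score = max contribution over discriminant axes (or eigenvalue-weighted
    sum per config); ties broken by (scaffold, pos) when variant records are
    supplied, else by id.
    """
    top_n = top_n if top_n is not None else model.config.top_n
    scores = model.variant_scores()
    if variants is not None:
        keys = {v.id: (v.scaffold, v.pos) for v in variants}
        order = sorted(
            range(len(scores)),
            key=lambda j: (-scores[j], keys[model.variant_ids[j]]),
        )
    else:
        order = sorted(range(len(scores)), key=lambda j: (-scores[j], model.variant_ids[j]))
    return [model.variant_ids[j] for j in order[:top_n]]


def hierarchical_panel(
    m: GenotypeMatrix,
    groups: pd.Series,
    scheme: HierarchicalScheme,
    cfg: DAPCConfig | None = None,
) -> tuple[PanelSelection, dict[str, list[str]]]:
    """Run each contrast and union the per-contrast top loadings into a panel.

    Returns the selection (tagged ``assignment``) and the per-contrast lists;
    a variant selected by several contrasts appears once in the panel.
    """
    cfg = cfg or DAPCConfig()
    labels = groups.reindex(m.samples)
    per_contrast: dict[str, list[str]] = {}
    for c in scheme.contrasts:
        mask = c.subset(labels)
        sub_samples = [s for s, keep in mask.items() if keep]
        sub_labels = c.relabel(labels.loc[sub_samples])
        counts = sub_labels.value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError(
                f"contrast {c.name!r} needs >= 2 groups with >= 2 samples each, "
                f"got {counts.to_dict()}"
            )
        sub = m.subset_samples(sub_samples)
        model = dapc_fit(sub, sub_labels, cfg)
        per_contrast[c.name] = top_loadings(model, cfg.top_n, m.variants)
    chosen: dict[str, list[str]] = {}
    for name, ids in per_contrast.items():
        for vid in ids:
            chosen.setdefault(vid, []).append(name)
    by_id = {v.id: v for v in m.variants}
    sel = PanelSelection(variants=[by_id[vid] for vid in chosen])
    sel.tag_all("assignment")
    return sel, per_contrast


def assign_samples(
    m_new: GenotypeMatrix, model: DAPCModel
) -> pd.DataFrame:
    """Assign new samples to the fitted groups by nearest DA-space centroid.

    New samples must share the model's variants; missing dosages are imputed
    with the training means.  Scores are normalised inverse distances to the
    centroids (summing to 1); all-missing samples are flagged low-confidence.
    """
    idx = [m_new.variant_index(vid) for vid in model.variant_ids]
    d = m_new.dosage[:, idx].astype(np.float64)
    missing = m_new.dosage[:, idx] == MISSING
    all_missing = missing.all(axis=1)
    inds = np.where(missing)
    d[inds] = model.train_means[inds[1]]
    if model.config.center:
        d = d - model.train_means
    if model.config.scale:
        d = d / model.train_scales
    da = (d @ model.pc_loadings) @ model.da_coefficients
    dist = np.linalg.norm(da[:, None, :] - model.group_centroids[None, :, :], axis=2)
    inv = 1.0 / (dist + 1e-12)
    post = inv / inv.sum(axis=1, keepdims=True)
    best = post.argmax(axis=1)
    out = pd.DataFrame(
        {
            "assigned_group": [model.groups[b] for b in best],
            "score": post[np.arange(len(best)), best],
            "low_confidence": all_missing,
        },
        index=m_new.samples,
    )
    for g_i, g in enumerate(model.groups):
        out[f"score_{g}"] = post[:, g_i]
    return out
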