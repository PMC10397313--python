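"""Marker-score cell typing and gene-set module scores.

Primary typing standardizes each marker gene across all spots on the slide
(z-score), averages z within each cell-type panel, and assigns the spot the
panel with the highest average score. Subtypes (e.g., exhausted T cells) are
scored the same way within the spots of their parent type.

SAA-high hepatocytes (Hep1) are called by the difference of two gene-set
module scores: GS1 (the SAA program, containing SAA1/SAA2) minus GS2 (the
complementary hepatocyte program). The module score of a set is the mean
expression of its genes minus the mean of control genes sampled from the
same average-expression bins, so depth and abundance effects cancel.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .binning import norm_layer

__all__ = [
    "score_panels",
    "module_score",
    "classify_hep",
    "annotate_spots",
]


def _dense_columns(adata: ad.AnnData, genes: list[str]) -> np.ndarray:
    """Dense (n_spots, len(genes)) block of the normalized layer."""
    idx = adata.var_names.get_indexer(genes)
    if (idx < 0).any():
        missing = [g for g, i in zip(genes, idx) if i < 0]
        raise KeyError(f"genes absent from matrix: {missing}")
    X = norm_layer(adata)
    return np.asarray(X[:, idx].todense())


def score_panels(
    adata: ad.AnnData,
    panels: dict[str, list[str]],
) -> pd.DataFrame:
    """Score each spot against each marker panel and label by argmax.

    Each panel gene is z-scored across spots of the normalized layer; the
    panel score is the mean z over the panel's genes that are present in the
    matrix. Zero-variance genes are excluded (with a warning); a panel with
    no usable genes scores NaN and can never be the argmax. Ties are broken
    by panel order in ``panels``.

    Returns a DataFrame indexed like ``adata.obs`` with one score column per
    panel plus a ``label`` column.
    """
    if not panels:
        raise ValueError("no panels supplied")
    panel_names = list(panels)
    all_genes = sorted({g for genes in panels.values() for g in genes})
    present = [g for g in all_genes if g in adata.var_names]
    absent = sorted(set(all_genes) - set(present))
    if absent:
        warnings.warn(f"marker genes absent from matrix: {absent}", stacklevel=2)
    block = _dense_columns(adata, present)
    mu = block.mean(axis=0)
    sd = block.std(axis=0, ddof=0)
    usable = sd > 0
    if not usable.all():
        dropped = [g for g, u in zip(present, usable) if not u]
        warnings.warn(f"zero-variance marker genes excluded: {dropped}", stacklevel=2)
    z = np.zeros_like(block)
    z[:, usable] = (block[:, usable] - mu[usable]) / sd[usable]
    col_of = {g: j for j, g in enumerate(present)}

    scores = np.full((adata.n_obs, len(panel_names)), np.nan)
    for j, name in enumerate(panel_names):
        cols = [col_of[g] for g in panels[name] if g in col_of and usable[col_of[g]]]
        if cols:
            scores[:, j] = z[:, cols].mean(axis=1)
    out = pd.DataFrame(scores, columns=panel_names, index=adata.obs_names)
    filled = np.where(np.isnan(scores), -np.inf, scores)
    if np.isinf(filled).all(axis=1).any():
        raise ValueError("at least one spot has no scorable panel")
    # argmax takes the first maximum, i.e. ties resolve by panel order
    out["label"] = [panel_names[j] for j in filled.argmax(axis=1)]
    return out


def module_score(
    adata: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Expression-bin-matched gene-set score per spot.

    Genes are ranked by their average normalized expression across spots and
    cut into ``n_bins`` equal-size bins; for every set gene, ``n_ctrl``
    control genes are sampled (with replacement) from its bin. The score is
    mean(set genes) − mean(control genes) per spot, on the normalized layer.
    Deterministic for a fixed ``seed``.
    """
    genes = [g for g in gene_set if g in adata.var_names]
    if not genes:
        raise ValueError("gene set is disjoint from the matrix genes")
    X = norm_layer(adata)
    avg = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(avg, kind="stable")
    n_genes = adata.n_vars
    bin_id = np.empty(n_genes, dtype=np.int64)
    bin_id[order] = np.minimum(
        (np.arange(n_genes) * n_bins) // max(n_genes, 1), n_bins - 1
    )
    rng = np.random.default_rng(seed)
    set_idx = adata.var_names.get_indexer(genes)
    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero(bin_id == bin_id[gi])
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_idx)
    set_mean = np.asarray(X[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


def classify_hep(
    adata: ad.AnnData,
    gs1: list[str],
    gs2: list[str],
    hep_mask: np.ndarray,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Call Hep1 (SAA-high) vs Hep2 hepatocytes by module-score difference.

    ``hep_mask`` marks the spots previously typed as hepatocytes; all other
    spots receive NA. A hepatocyte is Hep1 iff score(GS1) − score(GS2) > 0.
    """
    if set(gs1) == set(gs2):
        raise ValueError("GS1 and GS2 are identical: degenerate gene sets")
    hep_mask = np.asarray(hep_mask, dtype=bool)
    s1 = module_score(adata, gs1, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    s2 = module_score(adata, gs2, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1)
    out = pd.Series(pd.NA, index=adata.obs_names, dtype="object", name="hep_class")
    out[hep_mask] = np.where((s1 - s2)[hep_mask] > 0, "Hep1", "Hep2")
    return out


def annotate_spots(
    adata: ad.AnnData,
    panels: dict[str, list[str]],
    subtype_panels: dict[str, dict[str, list[str]]] | None = None,
    gs1: list[str] | None = None,
    gs2: list[str] | None = None,
    seed: int = 0,
    subtype_z_min: float = 3.0,
) -> pd.DataFrame:
    """Full annotation: primary type, optional subtypes, optional Hep1 call.

    ``subtype_panels`` maps a parent primary type to its subtype panels,
    e.g. ``{"T/NK": {"conventional": [...], "exhausted-T": [...]}}``; the
    first panel is the parent's default subtype. Subtype scoring is
    restricted to the spots of the parent type, and a non-default subtype is
    called only when its panel score clears ``subtype_z_min`` standard errors
    of the null panel-score noise.

    Returns a DataFrame with spot_id index and columns x_um, y_um,
    cell_type, subtype, hep_class.
    """
    primary = score_panels(adata, panels)
    out = pd.DataFrame(
        {
            "x_um": adata.obs["x_um"].to_numpy(),
            "y_um": adata.obs["y_um"].to_numpy(),
            "cell_type": primary["label"].to_numpy(),
        },
        index=adata.obs_names,
    )
    out["subtype"] = pd.NA
    if subtype_panels:
        for parent, sub in subtype_panels.items():
            mask = (out["cell_type"] == parent).to_numpy()
            if not mask.any():
                continue
            sub_scores = score_panels(adata[mask], sub)
            # Rare-subtype guard. When one subtype dominates the parent
            # population, z-scores centre on it: every panel score sits at ~0
            # for majority spots (bare argmax is a coin flip), while spots of
            # *other* primary types that leaked into the parent label score
            # deeply negative on the default panel (a bare score difference
            # flags them). A non-default subtype therefore needs conjunctive
            # evidence: its own panel score must clear subtype_z_min null
            # standard errors (null panel score = mean of m standard-normal
            # gene z-scores, sd 1/sqrt(m)) AND beat the default panel by
            # subtype_z_min of the difference's null sd. Everything else
            # keeps the first (default) subtype label.
            names = list(sub)
            default = names[0]
            m_d = max(len(sub[default]), 1)
            s_default = sub_scores[default].to_numpy()
            called = np.full(mask.sum(), default, dtype=object)
            best = np.full(mask.sum(), -np.inf)
            for name in names[1:]:
                m_s = max(len(sub[name]), 1)
                thr_abs = subtype_z_min / np.sqrt(m_s)
                thr_diff = subtype_z_min * np.sqrt(1.0 / m_s + 1.0 / m_d)
                s = sub_scores[name].to_numpy()
                hit = (s >= thr_abs) & (s - s_default >= thr_diff) & (s > best)
                called[hit] = name
                best = np.where(hit, s, best)
            out.loc[mask, "subtype"] = called
    out["hep_class"] = pd.NA
    if gs1 is not None and gs2 is not None:
        hep_mask = (out["cell_type"] == "hepatocyte").to_numpy()
        if hep_mask.any():
            out["hep_class"] = classify_hep(adata, gs1, gs2, hep_mask, seed=seed)
    out.index.name = "spot_id"
    return out
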