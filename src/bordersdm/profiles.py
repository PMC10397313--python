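"""Per-layer and per-tile profiling along the border normal direction.

Layer composition is the fraction of spots of each cell type among the
spots assigned to a layer, under either denominator convention: "all"
(every assigned spot) or "nonparenchymal" (malignant/cholangiocyte and
hepatocyte spots excluded). With ``use_subtypes=True`` spots carrying a
subtype call (exhausted T cells) are counted as their subtype and the parent
type keeps the remainder, so fractions never double-count.

The gene-signature score reported per unit (bin1000 unit or tile) is the
mean z-score of the set's genes across units — a deliberately simple
directional statistic, not a GSVA reimplementation.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .config import DISTANT_LABEL, LAYER_LABELS, PARENCHYMAL_TYPES

__all__ = [
    "layer_composition",
    "gradient_summary",
    "signature_score",
    "distant_reference",
]


def _effective_types(assignment: pd.DataFrame, use_subtypes: bool) -> pd.Series:
    types = assignment["cell_type"].astype(object).copy()
    if use_subtypes and "subtype" in assignment.columns:
        sub = assignment["subtype"]
        mask = sub.notna() & (sub != "conventional") & (sub.astype(str) != "NA")
        types[mask] = sub[mask]
    return types


def layer_composition(
    assignment: pd.DataFrame,
    denominator: str = "all",
    use_subtypes: bool = False,
    layers: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Cell-type counts and fractions per layer.

    ``assignment`` is the spot table from :func:`bordersdm.sdm.assign_spots`
    (columns layer, cell_type, optionally subtype). Returns a tidy frame
    (layer, cell_type, n, n_denominator, fraction, denominator); layers with
    an empty denominator are flagged with NaN fractions.
    """
    if denominator not in ("all", "nonparenchymal"):
        raise ValueError("denominator must be 'all' or 'nonparenchymal'")
    layers = layers if layers is not None else LAYER_LABELS + (DISTANT_LABEL,)
    df = assignment[assignment["layer"].isin(layers)].copy()
    df["etype"] = _effective_types(df, use_subtypes)
    if denominator == "nonparenchymal":
        df = df[~df["cell_type"].isin(PARENCHYMAL_TYPES)]
    all_types = sorted(df["etype"].unique())
    rows = []
    for layer in layers:
        sub = df[df["layer"] == layer]
        n_denom = len(sub)
        counts = sub["etype"].value_counts()
        for t in all_types:
            n = int(counts.get(t, 0))
            rows.append(
                {
                    "layer": layer,
                    "cell_type": t,
                    "n": n,
                    "n_denominator": n_denom,
                    "fraction": n / n_denom if n_denom else np.nan,
                    "denominator": denominator,
                }
            )
    return pd.DataFrame(rows)


def gradient_summary(
    profiles: pd.DataFrame,
    cell_type: str,
    layers: tuple[str, ...] = LAYER_LABELS,
) -> pd.DataFrame:
    """Across-slide mean ± sd per layer with adjacent-layer two-sample t-tests.

    ``profiles`` stacks per-slide outputs of :func:`layer_composition` with a
    ``slide_id`` column. The t-test is a plain two-sample Student's t between
    the slide-level fractions of adjacent layers; with fewer than 2 slides
    (or zero variance) the statistics are NA.
    """
    sub = profiles[(profiles["cell_type"] == cell_type) & profiles["layer"].isin(layers)]
    by_layer = {
        layer: sub.loc[sub["layer"] == layer, "fraction"].dropna().to_numpy()
        for layer in layers
    }
    rows = []
    for i, layer in enumerate(layers):
        vals = by_layer[layer]
        t_stat = p_val = np.nan
        if i + 1 < len(layers):
            nxt = by_layer[layers[i + 1]]
            spread = max(np.std(vals) if len(vals) else 0.0, np.std(nxt) if len(nxt) else 0.0)
            if len(vals) >= 2 and len(nxt) >= 2 and spread > 1e-12:
                t_stat, p_val = stats.ttest_ind(vals, nxt)
        rows.append(
            {
                "layer": layer,
                "cell_type": cell_type,
                "n_slides": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "sd": float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan,
                "t_next": t_stat,
                "p_next": p_val,
            }
        )
    return pd.DataFrame(rows)


def signature_score(units: ad.AnnData, gene_set: list[str]) -> np.ndarray:
    """Mean z-score of a gene set per unit (tile or bin1000 spot).

    Each gene of the set is z-scored across units on the normalized layer;
    the unit's score is the mean z over the set. Requires >= 2 units so the
    variance is defined. This is a directional signature summary standing in
    for pathway-level scoring, not a GSVA implementation.
    """
    from .binning import norm_layer  # local import to avoid cycle at module load

    if units.n_obs < 2:
        raise ValueError("need at least 2 units for a signature score")
    genes = [g for g in gene_set if g in units.var_names]
    if not genes:
        raise ValueError("gene set absent from the matrix")
    idx = units.var_names.get_indexer(genes)
    X = np.asarray(norm_layer(units)[:, idx].todense())
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    ok = sd > 0
    z = np.zeros_like(X)
    z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return z.mean(axis=1)


def distant_reference(
    assignment: pd.DataFrame,
    denominator: str = "all",
    use_subtypes: bool = False,
) -> dict:
    """Profile of the distant reference bands (2.00–2.25 mm from the border).

    Returns a dict with the spot subset, a composition profile per side
    (tumor side negative d), and per-side presence flags.
    """
    spots = assignment[assignment["layer"] == DISTANT_LABEL].copy()
    spots["side"] = np.where(spots["d_um"] > 0, "paratumor", "tumor")
    flags = {
        side: bool((spots["side"] == side).any()) for side in ("tumor", "paratumor")
    }
    profiles = {}
    for side in ("tumor", "paratumor"):
        sub = spots[spots["side"] == side].copy()
        if sub.empty:
            profiles[side] = None
            continue
        sub["layer"] = DISTANT_LABEL
        profiles[side] = layer_composition(
            sub, denominator=denominator, use_subtypes=use_subtypes, layers=(DISTANT_LABEL,)
        )
    return {"spots": spots, "profiles": profiles, "present": flags}
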