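"""Tangential composition patterns in the invasive zone.

For every tangential position t the cell counts of the two bilateral
first-layer tiles (+1, t) and (−1, t) are merged, parenchymal types
(malignant/cholangiocyte, hepatocyte) are excluded, and the remainder is
normalized into a composition vector. Vectors are compared by Pearson
correlation, clustered by average-linkage hierarchical clustering on the
1 − r distance, and each resulting pattern is tested for enrichment in
recurrent patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency
from sklearn.metrics import silhouette_score

from .config import PARENCHYMAL_TYPES
from .synth import ARCHETYPE_TYPES

__all__ = [
    "build_tangential_vectors",
    "cluster_patterns",
    "recurrence_enrichment",
    "PatternResult",
]


def build_tangential_vectors(
    assignment: pd.DataFrame,
    include_types: tuple[str, ...] = ARCHETYPE_TYPES,
    slide_id: str | None = None,
    patient_id: str | None = None,
    tiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merged bilateral composition vector per tangential position.

    Counts of the included (nonparenchymal) types are summed over the two
    bilateral first-layer tiles at the same tangential position and
    normalized to fractions. When the tile geometry frame is supplied, the
    merge is by arc position: equal-area cuts of the two layers can be offset
    by up to a tile width where the border bends, so a common set of cut
    positions (the per-cut mean of the two layers) is applied to every
    spot's arc coordinate. Without it, tiles are paired by index.

    Positions with zero included cells are marked missing (NaN composition)
    rather than dropped, so callers can report coverage. Returns a frame
    with columns patient_id, slide_id, t, n, missing and one column per
    included type.
    """
    inv = assignment[assignment["layer"].isin(("-1", "+1"))].copy()
    inv = inv[~inv["cell_type"].isin(PARENCHYMAL_TYPES)]
    inv = inv[inv["cell_type"].isin(include_types)]
    if "tile" not in assignment.columns:
        raise ValueError("assignment lacks tile indices; run assign_spots first")
    n_t = 0
    if len(assignment):
        tile_num = pd.to_numeric(assignment["tile"], errors="coerce")
        n_t = int(np.nanmax(tile_num)) if tile_num.notna().any() else 0
    if n_t == 0:
        raise ValueError("no tiled spots in the invasive zone")
    if tiles is not None and "s_um" in inv.columns:
        tm = tiles[tiles["layer"] == "-1"].sort_values("tile")
        tp = tiles[tiles["layer"] == "+1"].sort_values("tile")
        if len(tm) == n_t and len(tp) == n_t:
            cuts = (tm["s_start"].to_numpy() + tp["s_start"].to_numpy()) / 2.0
            inv["t"] = np.clip(
                np.searchsorted(cuts[1:], inv["s_um"].to_numpy(), side="right") + 1,
                1, n_t,
            )
        else:
            inv["t"] = inv["tile"].astype(int)
    else:
        inv["t"] = inv["tile"].astype(int)
    counts = (
        inv.groupby(["t", "cell_type"], observed=True).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=range(1, n_t + 1), columns=list(include_types), fill_value=0)
    total = counts.sum(axis=1)
    if int(total.sum()) == 0:
        raise ValueError("no nonparenchymal cells in the invasive zone of this slide")
    frac = counts.div(total.replace(0, np.nan), axis=0)
    out = frac.reset_index().rename(columns={"index": "t"})
    out.insert(0, "slide_id", slide_id)
    out.insert(0, "patient_id", patient_id)
    out["n"] = total.to_numpy()
    out["missing"] = out["n"] == 0
    return out


@dataclass
class PatternResult:
    vectors: pd.DataFrame  # the non-missing vectors that were clustered
    correlation: np.ndarray
    linkage: np.ndarray
    labels: np.ndarray  # pattern index 1..k per clustered vector
    k: int
    silhouette_by_k: dict[int, float]
    pattern_means: pd.DataFrame
    flagged_constant: np.ndarray  # vectors assigned post hoc by nearest centroid


def _composition_matrix(vectors: pd.DataFrame, include_types: tuple[str, ...]) -> np.ndarray:
    return vectors.loc[:, list(include_types)].to_numpy(dtype=float)


def _merge_minor_clusters(
    X: np.ndarray, labels: np.ndarray, min_size: int
) -> np.ndarray | None:
    """Reassign clusters below ``min_size`` to the nearest major centroid.

    Average linkage on correlation distance detaches far outlier vectors
    before splitting genuinely adjacent patterns, so raw tree cuts waste
    clusters on splinters; folding splinters back into the major patterns
    makes the cut count the number of *patterns*, not the number of
    outliers. Returns None when fewer than 2 major clusters remain.
    """
    sizes = pd.Series(labels).value_counts()
    major = sizes[sizes >= min_size].index
    if len(major) < 2:
        return None
    out = labels.copy()
    centroids = {m: X[labels == m].mean(axis=0) for m in major}
    for m in sizes.index.difference(major):
        for i in np.flatnonzero(labels == m):
            out[i] = min(centroids, key=lambda c: ((centroids[c] - X[i]) ** 2).sum())
    return out


def cluster_patterns(
    vectors: pd.DataFrame,
    k: int | str = "auto",
    k_range: tuple[int, int] = (2, 10),
    include_types: tuple[str, ...] = ARCHETYPE_TYPES,
    min_cluster_frac: float = 0.01,
) -> PatternResult:
    """Cluster tangential vectors into composition patterns.

    Distance is 1 − Pearson r between composition vectors; linkage is
    average. With ``k="auto"`` every tree cut in ``k_range`` is considered:
    clusters holding less than ``min_cluster_frac`` of the vectors are folded
    into the nearest major pattern (they are outlier splinters, not
    patterns), and the cut whose folded labelling maximizes the mean
    silhouette width wins; ``k`` is the resulting number of major patterns.
    Pattern indices are renumbered by decreasing cluster size. Constant
    (zero-variance) vectors cannot enter a correlation and are assigned
    afterwards to the nearest pattern centroid (Euclidean), flagged in the
    result.
    """
    vec = vectors[~vectors["missing"]].reset_index(drop=True)
    X = _composition_matrix(vec, include_types)
    if len(X) < 2:
        raise ValueError("need at least 2 non-missing vectors")
    constant = X.std(axis=1) < 1e-12
    Xc = X[~constant]
    if len(Xc) < 2:
        raise ValueError("fewer than 2 non-degenerate vectors")
    corr = np.corrcoef(Xc)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    sil: dict[int, float] = {}
    min_size = max(2, int(np.ceil(min_cluster_frac * len(Xc))))
    if k == "auto":
        best_lab, best_s = None, -np.inf
        lo, hi = k_range
        for kk in range(lo, min(hi, len(Xc) - 1) + 1):
            raw = hierarchy.fcluster(Z, t=kk, criterion="maxclust")
            lab = _merge_minor_clusters(Xc, raw, min_size)
            if lab is None or len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(dist, lab, metric="precomputed")
            sil[kk] = float(s)
            if s > best_s:
                best_lab, best_s = lab, s
        if best_lab is None:
            raise ValueError("silhouette selection failed; supply k explicitly")
        labels_core = best_lab
        k = len(np.unique(labels_core))
    else:
        labels_core = hierarchy.fcluster(Z, t=int(k), criterion="maxclust")
        k = len(np.unique(labels_core))
    # renumber patterns by decreasing size for stable, order-free naming
    sizes = pd.Series(labels_core).value_counts()
    remap = {old: new + 1 for new, old in enumerate(sizes.index)}
    labels_core = np.array([remap[v] for v in labels_core])
    centroids = np.vstack(
        [Xc[labels_core == p].mean(axis=0) for p in range(1, int(k) + 1)]
    )
    labels = np.zeros(len(X), dtype=int)
    labels[~constant] = labels_core
    if constant.any():
        for i in np.flatnonzero(constant):
            labels[i] = 1 + int(np.argmin(((centroids - X[i]) ** 2).sum(axis=1)))
    means = pd.DataFrame(
        [X[labels == p].mean(axis=0) for p in range(1, int(k) + 1)],
        index=pd.Index(range(1, int(k) + 1), name="pattern"),
        columns=list(include_types),
    )
    vec = vec.copy()
    vec["pattern"] = labels
    return PatternResult(
        vectors=vec,
        correlation=corr,
        linkage=Z,
        labels=labels,
        k=int(k),
        silhouette_by_k=sil,
        pattern_means=means,
        flagged_constant=constant,
    )


def recurrence_enrichment(labeled_vectors: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-pattern recurrence enrichment with a chi-squared test.

    ``labeled_vectors`` carries patient_id and pattern columns; ``meta`` maps
    patient_id → recurrence (bool). The enrichment score of a pattern is
    log2 of (the recurrent fraction among the pattern's vectors) over (the
    overall recurrent fraction); the chi-squared test is computed once on
    the K × 2 pattern-by-recurrence contingency table and reported on every
    row. With a single recurrence class, scores are NA and no test is run.
    """
    df = labeled_vectors.merge(meta[["patient_id", "recurrence"]], on="patient_id", how="left")
    if df["recurrence"].isna().any():
        missing = df.loc[df["recurrence"].isna(), "patient_id"].unique()
        raise ValueError(f"patients missing recurrence status: {sorted(missing)}")
    table = pd.crosstab(df["pattern"], df["recurrence"].astype(bool))
    table = table.reindex(columns=[False, True], fill_value=0)
    overall = table[True].sum() / table.to_numpy().sum()
    rows = []
    single_class = (table.sum(axis=0) == 0).any()
    p_value = np.nan
    if not single_class:
        _, p_value, _, _ = chi2_contingency(table.to_numpy())
    for pattern, row in table.iterrows():
        n = int(row.sum())
        rec_frac = row[True] / n if n else np.nan
        score = np.nan
        if not single_class and n and rec_frac > 0:
            score = float(np.log2(rec_frac / overall))
        rows.append(
            {
                "pattern": pattern,
                "n_vectors": n,
                "n_recurrent": int(row[True]),
                "recurrent_fraction": rec_frac,
                "enrichment_score": score,
                "chi2_p": p_value,
            }
        )
    return pd.DataFrame(rows)


def linkage_to_newick(result: PatternResult) -> str:
    """Export the linkage tree in Newick text form."""
    tree = hierarchy.to_tree(result.linkage)

    def _rec(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"v{node.id}:{length:.6g}"
        left = _rec(node.left, node.dist)
        right = _rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _rec(tree, tree.dist) + ";"
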