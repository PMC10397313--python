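"""Bin-level convolution of nanoscale records and per-spot normalization.

Stereo-seq captures single transcripts on a ~0.5 µm DNB grid; individual
bins are too sparse to analyse, so records are convolved into square
pseudo-spots: 50 × 50 bins (25 µm, roughly one cell) for typing, and
1000 × 1000 bins (500 µm) as local-bulk microenvironment units.

The spots × genes matrix lives in an :class:`anndata.AnnData`: sparse counts
in ``X``, spot centroids (µm) in ``obs``, the bin size and pitch in ``uns``,
and CPM normalization as the ``"cpm"`` layer.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .config import DEFAULT_BIN_PITCH_UM
from .io_gem import GemTable

__all__ = ["aggregate_bins", "cpm_normalize", "norm_layer"]


def aggregate_bins(
    gem: GemTable,
    bin_size: int,
    bin_pitch_um: float = DEFAULT_BIN_PITCH_UM,
) -> ad.AnnData:
    """Convolve a GEM table into square pseudo-spots of ``bin_size`` bins.

    A record at bin (x, y) contributes its count to the spot with grid index
    (x // bin_size, y // bin_size) for its gene. Spots with no records are
    omitted; total counts are conserved.

    Returns an AnnData with sparse integer counts; ``obs`` carries the spot
    grid indices (``sx``, ``sy``) and the centroid of each spot's square in
    µm (``x_um``, ``y_um``).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be a positive integer")
    frame = gem.frame
    sx = frame["x"].to_numpy().astype(np.int64) // bin_size
    sy = frame["y"].to_numpy().astype(np.int64) // bin_size
    spot_key = sx * (sy.max() + 1 if len(sy) else 1) + sy
    spot_codes, spot_uniques = pd.factorize(spot_key, sort=True)
    if isinstance(frame["gene"].dtype, pd.CategoricalDtype):
        raw_codes = frame["gene"].cat.codes.to_numpy()
        used, gene_codes = np.unique(raw_codes, return_inverse=True)
        gene_uniques = frame["gene"].cat.categories.to_numpy()[used]
    else:
        gene_codes, gene_uniques = pd.factorize(frame["gene"].to_numpy(), sort=True)
    n_spots, n_genes = len(spot_uniques), len(gene_uniques)
    X = sparse.coo_matrix(
        (frame["count"].to_numpy(dtype=np.int32), (spot_codes, gene_codes)),
        shape=(n_spots, n_genes),
    ).tocsr()
    X.sum_duplicates()

    divisor = sy.max() + 1 if len(sy) else 1
    usx = spot_uniques // divisor
    usy = spot_uniques % divisor
    half = bin_size * bin_pitch_um / 2.0
    obs = pd.DataFrame(
        {
            "sx": usx.astype(np.int64),
            "sy": usy.astype(np.int64),
            "x_um": usx * bin_size * bin_pitch_um + half,
            "y_um": usy * bin_size * bin_pitch_um + half,
        },
        index=pd.Index([f"{x}_{y}" for x, y in zip(usx, usy)], name="spot_id"),
    )
    var = pd.DataFrame(index=pd.Index(gene_uniques, name="gene"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["bin_size"] = int(bin_size)
    adata.uns["bin_pitch_um"] = float(bin_pitch_um)
    return adata


def cpm_normalize(adata: ad.AnnData, log1p: bool = False) -> ad.AnnData:
    """Fill the ``"cpm"`` layer: each nonzero spot's row rescaled to sum 1e6.

    With ``log1p=True`` the layer holds log1p(CPM) instead. All-zero spots
    pass through as zero rows. Returns the same AnnData (modified in place)
    for chaining.
    """
    X = adata.X.tocsr().astype(np.float64) if sparse.issparse(adata.X) else sparse.csr_matrix(
        np.asarray(adata.X, dtype=np.float64)
    )
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(1e6, totals, out=np.zeros_like(totals), where=totals > 0)
    cpm = sparse.diags(scale) @ X
    if log1p:
        cpm = cpm.log1p()
    adata.layers["cpm"] = cpm.tocsr()
    adata.uns["cpm_log1p"] = bool(log1p)
    return adata


def norm_layer(adata: ad.AnnData) -> sparse.csr_matrix:
    """Return the CPM layer, computing it on the fly if absent."""
    if "cpm" not in adata.layers:
        cpm_normalize(adata)
    return adata.layers["cpm"]
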