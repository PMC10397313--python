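import numpy as np
import pandas as pd
import pytest

from bordersdm import (
    aggregate_bins,
    annotate_spots,
    cpm_normalize,
    generate_slide,
)
from bordersdm.config import SlideConfig
from bordersdm.io_gem import GemTable
from bordersdm.synth import BorderSpec, ExpressionModel

#: Seed used for every session-scoped fixture.
FIXED_SEED = 11


def make_gem(records):
    """GemTable from a list of (gene, x, y, count) tuples."""
    return GemTable.from_records(
        pd.DataFrame(records, columns=["gene", "x", "y", "count"])
    )


def random_gem(rng, n_records=1000, n_genes=20, extent=500):
    genes = [f"g{i}" for i in range(n_genes)]
    return make_gem(
        [
            (genes[rng.integers(n_genes)], rng.integers(extent), rng.integers(extent),
             int(rng.integers(1, 6)))
            for _ in range(n_records)
        ]
    )


@pytest.fixture(scope="session")
def expression_model():
    return ExpressionModel()


@pytest.fixture(scope="session")
def small_slide():
    """A 4×4 mm slide with expression — shared by typing/profile tests."""
    cfg = SlideConfig(slide_extent_um=(4000.0, 4000.0))
    return generate_slide(
        config=cfg,
        border=BorderSpec(amplitude_um=300.0, period_um=4000.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_adata(small_slide):
    adata = aggregate_bins(small_slide.gem, 50)
    cpm_normalize(adata, log1p=True)
    return adata


@pytest.fixture(scope="session")
def small_annotation(small_adata, expression_model):
    m = expression_model
    return annotate_spots(
        small_adata, m.panels, m.subtype_panels, m.gs1, m.gs2, seed=3
    )


@pytest.fixture(scope="session")
def default_slide_products(expression_model):
    """The full-size (10×10 mm) default slide pushed through the pipeline.

    Generated once per session: the GEM table is aggregated at bin50 and
    bin1000, spots are typed, and the truth table kept; the GEM frame is
    released afterwards to bound the suite's memory footprint.
    """
    slide = generate_slide(seed=FIXED_SEED)
    gem_total = slide.gem.total_count
    adata = aggregate_bins(slide.gem, 50)
    cpm_normalize(adata, log1p=True)
    units = aggregate_bins(slide.gem, 1000)
    units_total = int(units.X.sum())
    n_units = units.n_obs
    slide.gem = None  # free ~1 GB
    m = expression_model
    annotation = annotate_spots(adata, m.panels, m.subtype_panels, m.gs1, m.gs2, seed=3)
    return {
        "slide": slide,
        "adata": adata,
        "annotation": annotation,
        "gem_total": gem_total,
        "n_units": n_units,
        "units_total": units_total,
    }


def ray_casting_inside(poly, points):
    """Even–odd ray-casting point-in-polygon oracle (boundary-inclusive up
    to float tolerance); ``poly`` is a shapely Polygon (exterior only)."""
    xs, ys = np.asarray(poly.exterior.coords).T
    px, py = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(xs) - 1
    for i in range(n):
        x1, y1, x2, y2 = xs[i], ys[i], xs[i + 1], ys[i + 1]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    return inside
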