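"""Ground-truthed synthetic slides with the statistical structure the
invasive-zone analysis assumes.

A slide is a 25 µm grid of pseudo-spot cells (one spot ≈ one cell) split by a
curved tumor border: malignant-dominated tissue below the curve (negative
signed distance), hepatocyte-dominated liver above. Cell-type fractions vary
by border layer with the planted gradients the analysis is meant to recover:
macrophages rise from 3.9% (layer −3) to 8.6% (layer −1), exhausted T cells
from 0.09% to 0.54%, the total immune fraction exceeds 30% in layer −1, and
SAA-high hepatocytes (Hep1) are confined to the first paratumor layer.

Within a layer, spot types are a random permutation of a deterministic
type-count vector (largest-remainder rounding of the planted fractions), so
the realized per-layer fractions equal the planted ones up to rounding and
any downstream discrepancy measures pipeline error, not sampling noise.

Gene counts follow a negative-binomial depth model (gamma-mixed Poisson):
per-spot depth ~ Gamma(1/α, mean·α) with mean 2000 and dispersion α = 0.5,
distributed over genes proportionally to a per-type weight vector in which
the type's 10 marker genes are up-weighted 2³-fold over a fixed log-normal
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .config import (
    BIN50,
    EXHAUSTED_T,
    PRIMARY_TYPES,
    SlideConfig,
)
from .io_gem import GemTable
from .sdm import BorderCurve, signed_distance

__all__ = [
    "BorderSpec",
    "CompositionProfile",
    "ExpressionModel",
    "SyntheticSlide",
    "Cohort",
    "default_composition",
    "default_archetypes",
    "generate_slide",
    "generate_cohort",
]

#: Composition rows exist for the six layers, the two distant bands, and the
#: remaining bulk tissue on each side ("bulk-" tumor, "bulk+" paratumor).
PROFILE_ROWS = ("-3", "-2", "-1", "+1", "+2", "+3", "distant-", "distant+", "bulk-", "bulk+")

#: All generated categories: the nine primary types plus exhausted-T.
GENERATED_TYPES = PRIMARY_TYPES[:3] + ("T/NK", EXHAUSTED_T) + PRIMARY_TYPES[4:]

_TYPE_CODES = {
    "malignant": "MAL",
    "hepatocyte": "HEP",
    "macrophage": "MAC",
    "T/NK": "TNK",
    "B": "B",
    "plasma": "PLA",
    "DC": "DC",
    "endothelial": "END",
    "fibroblast": "FIB",
}

_DEFAULT_FRACTIONS = {
    #            mal    hep    mac    T/NK   exhT    B     plas   DC     endo   fib
    "-1":       (0.460, 0.040, 0.086, 0.1396, 0.0054, 0.040, 0.025, 0.024, 0.050, 0.130),
    "-2":       (0.582, 0.030, 0.060, 0.0970, 0.0030, 0.030, 0.020, 0.018, 0.050, 0.110),
    "-3":       (0.6850, 0.020, 0.039, 0.0691, 0.0009, 0.025, 0.015, 0.012, 0.050, 0.084),
    "distant-": (0.755, 0.010, 0.030, 0.0495, 0.0005, 0.020, 0.010, 0.010, 0.050, 0.065),
    "bulk-":    (0.755, 0.010, 0.030, 0.0495, 0.0005, 0.020, 0.010, 0.010, 0.050, 0.065),
    "+1":       (0.010, 0.700, 0.050, 0.0795, 0.0005, 0.020, 0.015, 0.015, 0.050, 0.060),
    "+2":       (0.005, 0.780, 0.040, 0.0598, 0.0002, 0.015, 0.010, 0.010, 0.045, 0.035),
    "+3":       (0.005, 0.820, 0.035, 0.0499, 0.0001, 0.010, 0.008, 0.007, 0.040, 0.025),
    "distant+": (0.005, 0.860, 0.025, 0.0399, 0.0001, 0.008, 0.005, 0.007, 0.035, 0.015),
    "bulk+":    (0.005, 0.860, 0.025, 0.0399, 0.0001, 0.008, 0.005, 0.007, 0.035, 0.015),
}

_TYPE_ORDER = (
    "malignant",
    "hepatocyte",
    "macrophage",
    "T/NK",
    EXHAUSTED_T,
    "B",
    "plasma",
    "DC",
    "endothelial",
    "fibroblast",
)

#: Nonparenchymal types over which tangential archetypes are defined.
ARCHETYPE_TYPES = ("macrophage", "T/NK", "B", "plasma", "DC", "endothelial", "fibroblast")

# Dominance is deliberately strong: with ~20-40 nonparenchymal cells per
# merged tile pair, weaker archetypes are not mutually identifiable by any
# composition clustering (checked by multinomial simulation), whereas the
# study's subregions did resolve into five distinct patterns.
_DEFAULT_ARCHETYPES = {
    # pattern:   mac    T/NK    B     plas   DC     endo   fib
    1: (0.05, 0.08, 0.04, 0.02, 0.03, 0.08, 0.70),  # fibroblast dominant
    2: (0.40, 0.05, 0.03, 0.02, 0.03, 0.04, 0.43),  # fibroblast + macrophage
    3: (0.72, 0.08, 0.04, 0.02, 0.04, 0.05, 0.05),  # macrophage dominant
    4: (0.05, 0.38, 0.36, 0.07, 0.04, 0.04, 0.06),  # B + T/NK dominant
    5: (0.05, 0.08, 0.04, 0.02, 0.04, 0.67, 0.10),  # endothelial dominant
}

#: Archetype mixture for non-recurrent patients; recurrent patients get the
#: same mixture with pattern-3 odds multiplied by 3 and pattern-1 odds by 1/3.
_DEFAULT_MIXTURE = (0.35, 0.15, 0.10, 0.20, 0.20)
_DEFAULT_RECURRENCE_ODDS = {1: 1.0 / 3.0, 3: 3.0}


@dataclass
class CompositionProfile:
    """Per-layer cell-type fractions (rows sum to 1)."""

    frame: pd.DataFrame  # index: PROFILE_ROWS, columns: _TYPE_ORDER

    def __post_init__(self) -> None:
        f = self.frame
        if (f.to_numpy() < 0).any():
            raise ValueError("composition fractions must be >= 0")
        sums = f.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-9)]
            raise ValueError(f"layer fractions must sum to 1; offending rows: {dict(bad)}")

    def row(self, label: str) -> np.ndarray:
        return self.frame.loc[label].to_numpy(dtype=float)


def default_composition() -> CompositionProfile:
    frame = pd.DataFrame.from_dict(_DEFAULT_FRACTIONS, orient="index", columns=_TYPE_ORDER)
    return CompositionProfile(frame.loc[list(PROFILE_ROWS)])


def default_archetypes() -> pd.DataFrame:
    """The five tangential composition archetypes (rows sum to 1)."""
    return pd.DataFrame.from_dict(_DEFAULT_ARCHETYPES, orient="index", columns=ARCHETYPE_TYPES)


@dataclass
class BorderSpec:
    """Parametric truth border spanning the slide left-to-right.

    Tumor lies on the negative-signed-distance side (below the curve);
    paratumor liver above.
    """

    kind: str = "sinusoid"  # "straight" | "sinusoid"
    amplitude_um: float = 400.0
    period_um: float = 5000.0
    phase: float = 0.0
    y_offset_um: float | None = None  # default: slide mid-height

    def polyline(self, extent_um: tuple[float, float], spacing_um: float = 5.0) -> np.ndarray:
        w, h = extent_um
        y0 = h / 2.0 if self.y_offset_um is None else self.y_offset_um
        x = np.arange(0.0, w + spacing_um / 2, spacing_um)
        x[-1] = min(x[-1], w)
        if self.kind == "straight":
            y = np.full_like(x, y0)
        elif self.kind == "sinusoid":
            y = y0 + self.amplitude_um * np.sin(2 * np.pi * x / self.period_um + self.phase)
        else:
            raise ValueError(f"unknown border kind: {self.kind!r}")
        if (y <= 0).any() or (y >= h).any():
            raise ValueError("border curve leaves the slide; reduce amplitude or recenter")
        return np.column_stack([x, y])

    def curve(self, extent_um: tuple[float, float]) -> BorderCurve:
        # traveling +x puts the paratumor (upper) side on the left: positive
        return BorderCurve(self.polyline(extent_um))


@dataclass
class ExpressionModel:
    """Marker-structured negative-binomial expression model.

    Each of the 9 primary types has 10 marker genes up-weighted by
    2**marker_log2fc over a fixed log-normal baseline; T/NK carries two
    subtype panels (conventional / exhausted), and hepatocytes carry the
    SAA program: GS1 (SAA1, SAA2 and four partners) high in Hep1, GS2 high
    in Hep2.
    """

    n_genes: int = 240
    marker_log2fc: float = 3.0
    saa_log2fc: float = 4.0
    gs1_log2fc: float = 3.0
    gs2_log2fc: float = 2.0
    depth_mean: float = 2000.0
    dispersion: float = 0.5
    baseline_sigma: float = 1.5
    baseline_seed: int = 12345

    genes: list[str] = field(init=False)
    panels: dict[str, list[str]] = field(init=False)
    subtype_panels: dict[str, dict[str, list[str]]] = field(init=False)
    gs1: list[str] = field(init=False)
    gs2: list[str] = field(init=False)
    baseline: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.marker_log2fc <= 0 or self.depth_mean <= 0 or self.dispersion <= 0:
            raise ValueError("fold changes, depth mean and dispersion must be positive")
        self.panels = {
            t: [f"MK-{c}-{i:02d}" for i in range(1, 11)] for t, c in _TYPE_CODES.items()
        }
        tex = [f"MK-TEX-{i:02d}" for i in range(1, 11)]
        tconv = [f"MK-TCV-{i:02d}" for i in range(1, 11)]
        self.subtype_panels = {"T/NK": {"conventional": tconv, EXHAUSTED_T: tex}}
        self.gs1 = ["SAA1", "SAA2", "GS1-03", "GS1-04", "GS1-05", "GS1-06"]
        self.gs2 = [f"GS2-{i:02d}" for i in range(1, 7)]
        structured = (
            [g for p in self.panels.values() for g in p] + tconv + tex + self.gs1 + self.gs2
        )
        n_bg = self.n_genes - len(structured)
        if n_bg < 10:
            raise ValueError(f"n_genes must be >= {len(structured) + 10}")
        self.genes = structured + [f"BG-{i:04d}" for i in range(1, n_bg + 1)]
        rng = np.random.default_rng(self.baseline_seed)
        self.baseline = rng.lognormal(mean=0.0, sigma=self.baseline_sigma, size=self.n_genes)
        # marker panels are curated for robust detectability (CD163, ALB,
        # MZB1, ...), so structured genes get at least the median abundance;
        # without the floor, markers from the log-normal tail are pure shot
        # noise in the cells that express them
        self.baseline[: len(structured)] = np.maximum(self.baseline[: len(structured)], 1.0)

    def _boost(self, weights: np.ndarray, genes: list[str], log2fc: float) -> None:
        idx = [self.genes.index(g) for g in genes]
        weights[idx] *= 2.0**log2fc

    def class_probabilities(self) -> pd.DataFrame:
        """Per-class gene sampling probabilities; classes are the generated
        types with hepatocyte split into Hep1/Hep2 and T/NK into subtypes."""
        rows = {}
        for t in GENERATED_TYPES:
            w = self.baseline.copy()
            if t == EXHAUSTED_T:
                self._boost(w, self.panels["T/NK"], self.marker_log2fc)
                self._boost(w, self.subtype_panels["T/NK"][EXHAUSTED_T], self.marker_log2fc)
            elif t == "T/NK":
                self._boost(w, self.panels["T/NK"], self.marker_log2fc)
                self._boost(w, self.subtype_panels["T/NK"]["conventional"], self.marker_log2fc)
            elif t == "hepatocyte":
                continue  # split into Hep1/Hep2 below
            else:
                self._boost(w, self.panels[t], self.marker_log2fc)
            rows[t] = w
        for hep_class in ("Hep1", "Hep2"):
            w = self.baseline.copy()
            self._boost(w, self.panels["hepatocyte"], self.marker_log2fc)
            if hep_class == "Hep1":
                self._boost(w, ["SAA1", "SAA2"], self.saa_log2fc)
                self._boost(w, self.gs1[2:], self.gs1_log2fc)
            else:
                self._boost(w, self.gs2, self.gs2_log2fc)
            rows[hep_class] = w
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=self.genes)
        return frame.div(frame.sum(axis=1), axis=0)


@dataclass
class SyntheticSlide:
    gem: GemTable | None
    truth: pd.DataFrame
    border_xy: np.ndarray
    curve: BorderCurve
    config: SlideConfig
    manifest: dict


@dataclass
class Cohort:
    slides: list[SyntheticSlide]
    meta: pd.DataFrame  # patient_id, recurrence, slide_id
    truth_patterns: pd.DataFrame  # patient_id, slide_id, t, archetype
    archetypes: pd.DataFrame
    mixtures: pd.DataFrame  # per recurrence status


def _largest_remainder_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, proportional to fractions."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _layer_label_from_distance(d: np.ndarray, half_widths=(250.0, 500.0, 750.0),
                               distant=(2000.0, 2250.0)) -> np.ndarray:
    """Truth region label per spot: layers, distant bands, or bulk by side."""
    ad = np.abs(d)
    labels = np.where(d > 0, "bulk+", "bulk-").astype(object)
    bounds = (0.0,) + tuple(half_widths)
    for i in range(1, len(half_widths) + 1):
        lo, hi = bounds[i - 1], bounds[i]
        m = (ad > lo) & (ad <= hi) if i > 1 else ad <= hi
        labels[m & (d > 0)] = f"+{i}"
        labels[m & (d <= 0)] = f"-{i}"  # on-border ties go to the first tumor layer
    dist_m = (ad >= distant[0]) & (ad <= distant[1])
    labels[dist_m & (d > 0)] = "distant+"
    labels[dist_m & (d <= 0)] = "distant-"
    return labels


def _spot_grid(config: SlideConfig, bin_size: int = BIN50):
    pitch = bin_size * config.bin_pitch_um
    w, h = config.slide_extent_um
    nx, ny = int(w // pitch), int(h // pitch)
    sx, sy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    sx, sy = sx.ravel(), sy.ravel()
    x = sx * pitch + pitch / 2.0
    y = sy * pitch + pitch / 2.0
    return sx, sy, x, y


def _assign_types(labels: np.ndarray, profile: CompositionProfile, rng: np.random.Generator) -> np.ndarray:
    """Permutation assignment of generated types within each region label."""
    types = np.empty(len(labels), dtype=object)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        counts = _largest_remainder_counts(profile.row(lab), len(idx))
        pool = np.repeat(np.array(_TYPE_ORDER, dtype=object), counts)
        types[idx] = rng.permutation(pool)
    return types


def _synthesize_counts(
    classes: np.ndarray,
    model: ExpressionModel,
    rng: np.random.Generator,
    chunk: int = 40_000,
) -> sparse.csr_matrix:
    """Gamma-Poisson counts, one row per spot, columns = model.genes."""
    probs = model.class_probabilities()
    shape = 1.0 / model.dispersion
    scale = model.depth_mean * model.dispersion
    n = len(classes)
    class_codes, class_names = pd.factorize(classes)
    P = probs.loc[class_names].to_numpy()
    blocks = []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        depth = rng.gamma(shape, scale, size=stop - start)
        lam = depth[:, None] * P[class_codes[start:stop]]
        counts = rng.poisson(lam).astype(np.int32)
        blocks.append(sparse.csr_matrix(counts))
    return sparse.vstack(blocks, format="csr")


def _emit_gem(
    counts: sparse.csr_matrix,
    sx: np.ndarray,
    sy: np.ndarray,
    genes: list[str],
    rng: np.random.Generator,
    bin_size: int = BIN50,
    per_dnb: bool = False,
) -> GemTable:
    coo = counts.tocoo()
    spot_i, gene_i, c = coo.row, coo.col, coo.data.astype(np.int32)
    if per_dnb:
        # one record per transcript, each at its own random DNB bin
        spot_i = np.repeat(spot_i, c)
        gene_i = np.repeat(gene_i, c)
        c = np.ones(len(spot_i), dtype=np.int32)
    x = (sx[spot_i] * bin_size + rng.integers(0, bin_size, size=len(spot_i))).astype(np.int32)
    y = (sy[spot_i] * bin_size + rng.integers(0, bin_size, size=len(spot_i))).astype(np.int32)
    gene_names = pd.Categorical.from_codes(gene_i, categories=pd.Index(genes).astype(str))
    frame = pd.DataFrame({"gene": gene_names, "x": x, "y": y, "count": c})
    return GemTable.from_records(frame)


def generate_slide(
    config: SlideConfig | None = None,
    border: BorderSpec | None = None,
    profile: CompositionProfile | None = None,
    model: ExpressionModel | None = None,
    seed: int = 0,
    hep1_fraction: float = 0.6,
    with_expression: bool = True,
    per_dnb: bool = False,
    slide_id: str = "S1",
) -> SyntheticSlide:
    """Generate one ground-truthed slide.

    Returns the GEM table (unless ``with_expression=False``), the truth
    annotation (cell type, subtype, Hep1 status, truth layer, signed
    distance per spot) and the truth border polyline.
    """
    config = config or SlideConfig()
    border = border or BorderSpec()
    profile = profile or default_composition()
    model = model or ExpressionModel()
    if per_dnb:
        w, h = config.slide_extent_um
        if w * h > 1.1e6:
            raise ValueError("per-DNB emission is a toy mode; keep the slide <= 1 mm²")
    rng = np.random.default_rng(seed)
    curve = border.curve(config.slide_extent_um)
    sx, sy, x, y = _spot_grid(config)
    d, _ = signed_distance(curve, np.column_stack([x, y]))
    labels = _layer_label_from_distance(d)
    types = _assign_types(labels, profile, rng)

    # Hep1 confined to the first paratumor layer
    classes = types.copy()
    hep_class = np.full(len(types), pd.NA, dtype=object)
    hep_mask = types == "hepatocyte"
    hep_class[hep_mask] = "Hep2"
    classes[hep_mask] = "Hep2"
    hep_plus1 = np.flatnonzero(hep_mask & (labels == "+1"))
    n_hep1 = int(round(hep1_fraction * len(hep_plus1)))
    hep1_idx = rng.choice(hep_plus1, size=n_hep1, replace=False) if n_hep1 else []
    hep_class[hep1_idx] = "Hep1"
    classes[hep1_idx] = "Hep1"

    primary = np.where(types == EXHAUSTED_T, "T/NK", types)
    subtype = np.full(len(types), pd.NA, dtype=object)
    subtype[types == EXHAUSTED_T] = EXHAUSTED_T
    subtype[(primary == "T/NK") & (types != EXHAUSTED_T)] = "conventional"

    truth = pd.DataFrame(
        {
            "spot_id": [f"{a}_{b}" for a, b in zip(sx, sy)],
            "x_um": x,
            "y_um": y,
            "cell_type": primary,
            "subtype": subtype,
            "hep_class": hep_class,
            "layer_truth": labels,
            "d_um": d,
        }
    )
    gem = None
    if with_expression:
        counts = _synthesize_counts(classes, model, rng)
        gem = _emit_gem(counts, sx, sy, model.genes, rng, per_dnb=per_dnb)
    manifest = {
        "slide_id": slide_id,
        "seed": int(seed),
        "n_spots": int(len(truth)),
        "hep1_fraction": float(hep1_fraction),
        "border": {"kind": border.kind, "amplitude_um": border.amplitude_um,
                   "period_um": border.period_um, "phase": border.phase},
        "depth_mean": model.depth_mean,
        "dispersion": model.dispersion,
    }
    return SyntheticSlide(gem=gem, truth=truth, border_xy=curve.vertices, curve=curve,
                          config=config, manifest=manifest)


def _recurrent_mixture(base: np.ndarray, odds: dict[int, float]) -> np.ndarray:
    w = base.copy()
    for pattern, o in odds.items():
        w[pattern - 1] *= o
    return w / w.sum()


def generate_cohort(
    n_patients: int = 16,
    archetypes: pd.DataFrame | None = None,
    recurrence_mixture: tuple[float, ...] | None = None,
    recurrence_odds: dict[int, float] | None = None,
    n_recurrent: int | None = None,
    config: SlideConfig | None = None,
    profile: CompositionProfile | None = None,
    seed: int = 0,
    run_mean_tiles: float = 25.0,
    n_tangential: int = 100,
    with_expression: bool = False,
    model: ExpressionModel | None = None,
) -> Cohort:
    """Generate a patient cohort with planted tangential archetype labels.

    Each patient's invasive zone (layers ±1) is divided into
    ``n_tangential`` equal-arc segments; contiguous runs of segments (mean
    length ``run_mean_tiles``) draw an archetype from the patient's mixture,
    and the nonparenchymal composition of spots in those segments follows the
    archetype. Recurrent patients over-represent archetype 3 (macrophage
    dominant) and under-represent archetype 1 (fibroblast dominant) with the
    planted odds in ``recurrence_odds``.
    """
    archetypes = archetypes if archetypes is not None else default_archetypes()
    if len(archetypes) < 2:
        raise ValueError("need at least 2 archetypes")
    base = np.asarray(recurrence_mixture if recurrence_mixture is not None else _DEFAULT_MIXTURE,
                      dtype=float)
    if len(base) != len(archetypes):
        raise ValueError("mixture length must match the number of archetypes")
    base = base / base.sum()
    odds = recurrence_odds if recurrence_odds is not None else dict(_DEFAULT_RECURRENCE_ODDS)
    rec_mix = _recurrent_mixture(base, odds)
    config = config or SlideConfig()
    profile = profile or default_composition()
    if n_recurrent is None:
        n_recurrent = n_patients // 2
    rng = np.random.default_rng(seed)
    arch_ids = np.asarray(archetypes.index)
    arch_comp = archetypes.to_numpy(dtype=float)
    arch_comp = arch_comp / arch_comp.sum(axis=1, keepdims=True)

    slides, meta_rows, label_rows = [], [], []
    for i in range(n_patients):
        patient = f"P{i + 1:02d}"
        slide_id = f"{patient}-M"
        recurrent = i < n_recurrent
        mix = rec_mix if recurrent else base
        # contiguous archetype runs along the 100 tangential segments
        t_labels = np.empty(n_tangential, dtype=arch_ids.dtype)
        pos = 0
        while pos < n_tangential:
            run = int(rng.geometric(1.0 / run_mean_tiles))
            a = arch_ids[rng.choice(len(arch_ids), p=mix)]
            t_labels[pos: pos + run] = a
            pos += run
        border = BorderSpec(phase=2 * np.pi * i / n_patients)
        slide = _generate_patterned_slide(
            config, border, profile, archetypes=arch_comp, arch_ids=arch_ids,
            t_labels=t_labels, n_tangential=n_tangential,
            seed=int(rng.integers(0, 2**31 - 1)), slide_id=slide_id,
            with_expression=with_expression, model=model,
        )
        slides.append(slide)
        meta_rows.append({"patient_id": patient, "recurrence": recurrent, "slide_id": slide_id})
        for t in range(n_tangential):
            label_rows.append(
                {"patient_id": patient, "slide_id": slide_id, "t": t + 1,
                 "archetype": int(t_labels[t])}
            )
    meta = pd.DataFrame(meta_rows)
    truth_patterns = pd.DataFrame(label_rows)
    mixtures = pd.DataFrame(
        {"non-recurrent": base, "recurrent": rec_mix}, index=archetypes.index
    ).T
    return Cohort(slides=slides, meta=meta, truth_patterns=truth_patterns,
                  archetypes=archetypes, mixtures=mixtures)


def _generate_patterned_slide(
    config: SlideConfig,
    border: BorderSpec,
    profile: CompositionProfile,
    archetypes: np.ndarray,
    arch_ids: np.ndarray,
    t_labels: np.ndarray,
    n_tangential: int,
    seed: int,
    slide_id: str,
    with_expression: bool = False,
    model: ExpressionModel | None = None,
) -> SyntheticSlide:
    """One cohort slide: default layer profile everywhere, except that the
    nonparenchymal composition of layers ±1 follows the planted archetype of
    each tangential segment (exhausted-T folded into T/NK)."""
    rng = np.random.default_rng(seed)
    curve = border.curve(config.slide_extent_um)
    sx, sy, x, y = _spot_grid(config)
    pts = np.column_stack([x, y])
    d, s_arc = signed_distance(curve, pts)
    labels = _layer_label_from_distance(d)
    types = _assign_types(labels, profile, rng)

    # overwrite the nonparenchymal draw inside the invasive zone
    t_index = np.clip((s_arc / curve.length * n_tangential).astype(int) + 1, 1, n_tangential)
    invasive = np.isin(labels, ("-1", "+1"))
    type_arr = np.array(ARCHETYPE_TYPES, dtype=object)
    for lab in ("-1", "+1"):
        row = profile.row(lab)
        paren = {t: row[_TYPE_ORDER.index(t)] for t in ("malignant", "hepatocyte")}
        paren_total = sum(paren.values())
        nonparen_total = 1.0 - paren_total
        in_layer = labels == lab
        for t in range(1, n_tangential + 1):
            idx = np.flatnonzero(in_layer & (t_index == t))
            if idx.size == 0:
                continue
            comp = archetypes[np.flatnonzero(arch_ids == t_labels[t - 1])[0]]
            p = np.concatenate([
                [paren["malignant"], paren["hepatocyte"]], nonparen_total * comp
            ])
            draw = rng.choice(len(p), size=idx.size, p=p / p.sum())
            full_types = np.concatenate([["malignant", "hepatocyte"], type_arr])
            types[idx] = full_types[draw]

    del invasive
    hep_class = np.full(len(types), pd.NA, dtype=object)
    hep_class[types == "hepatocyte"] = "Hep2"
    primary = np.where(types == EXHAUSTED_T, "T/NK", types)
    subtype = np.full(len(types), pd.NA, dtype=object)
    subtype[types == EXHAUSTED_T] = EXHAUSTED_T
    truth = pd.DataFrame(
        {
            "spot_id": [f"{a}_{b}" for a, b in zip(sx, sy)],
            "x_um": x,
            "y_um": y,
            "cell_type": primary,
            "subtype": subtype,
            "hep_class": hep_class,
            "layer_truth": labels,
            "d_um": d,
            "t_truth": np.where(np.isin(labels, ("-1", "+1")), t_index, 0),
        }
    )
    gem = None
    if with_expression:
        model = model or ExpressionModel()
        classes = types.copy()
        classes[types == "hepatocyte"] = "Hep2"
        counts = _synthesize_counts(classes, model, rng)
        gem = _emit_gem(counts, sx, sy, model.genes, rng)
    manifest = {"slide_id": slide_id, "seed": int(seed), "patterned": True}
    return SyntheticSlide(gem=gem, truth=truth, border_xy=curve.vertices, curve=curve,
                          config=config, manifest=manifest)
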