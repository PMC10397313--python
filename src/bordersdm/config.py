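"""Run-level configuration objects and their (de)serialization.

All geometry downstream of file I/O is computed in micrometres (µm).
Coordinates stored in GEM files are integer DNB-bin indices; the physical
position of a bin index ``i`` is ``i * bin_pitch_um`` with the origin at the
lower-left corner of the slide, x rightward and y upward.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Physical pitch of one DNB bin (centre-to-centre), µm.
DEFAULT_BIN_PITCH_UM = 0.5

#: Pseudo-spot window: 50 × 50 DNB bins = 25 µm squares, ~one cell.
BIN50 = 50
#: Microenvironment unit: 1000 × 1000 DNB bins = 500 µm squares.
BIN1000 = 1000

#: Offset distances bounding the infiltrating layers, µm (each side).
LAYER_HALF_WIDTHS_UM = (250.0, 500.0, 750.0)
#: The "distant" reference band, µm from the border (each side).
DISTANT_BAND_UM = (2000.0, 2250.0)
#: Tangential tiles per layer.
N_TILES = 100
#: Degrees of freedom of the border-smoothing cubic spline.
SPLINE_DF = 20

#: Canonical layer labels, tumor side negative, paratumor side positive.
LAYER_LABELS = ("-3", "-2", "-1", "+1", "+2", "+3")
DISTANT_LABEL = "distant"
NONE_LABEL = "none"

#: The nine primary cell types plus the exhausted-T subtype used throughout.
PRIMARY_TYPES = (
    "malignant",
    "hepatocyte",
    "macrophage",
    "T/NK",
    "B",
    "plasma",
    "DC",
    "endothelial",
    "fibroblast",
)
EXHAUSTED_T = "exhausted-T"
#: Immune cell types (exhausted-T counted separately when subtypes are split).
IMMUNE_TYPES = ("macrophage", "T/NK", "B", "plasma", "DC")
#: Parenchymal types excluded from the "nonparenchymal" denominator and from
#: tangential pattern vectors (malignant spots cover cholangiocytes too).
PARENCHYMAL_TYPES = ("malignant", "hepatocyte")


@dataclass
class SlideConfig:
    """Physical description of one slide."""

    bin_pitch_um: float = DEFAULT_BIN_PITCH_UM
    slide_extent_um: tuple[float, float] = (10_000.0, 10_000.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_pitch_um <= 0:
            raise ValueError("bin_pitch_um must be positive")
        w, h = self.slide_extent_um
        if w <= 0 or h <= 0:
            raise ValueError("slide extents must be positive")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the defaults used throughout.

    ``seed`` is the single user-facing seed; stages derive their own streams
    from it by fixed offsets so reruns are byte-identical.
    """

    slide: SlideConfig = field(default_factory=SlideConfig)
    # binning
    bin_size: int = BIN50
    unit_bin_size: int = BIN1000
    log1p: bool = True
    # border digitization
    pixel_um: float = 25.0
    denoise_window: int = 5
    keep_fraction: float = 0.4
    spline_df: int = SPLINE_DF
    half_widths_um: tuple[float, ...] = LAYER_HALF_WIDTHS_UM
    distant_band_um: tuple[float, float] = DISTANT_BAND_UM
    n_tiles: int = N_TILES
    # typing
    module_n_bins: int = 25
    module_n_ctrl: int = 100
    # patterns
    pattern_k: int | str = "auto"
    seed: int = 0

    def validate(self) -> None:
        if self.bin_size <= 0 or self.unit_bin_size <= 0:
            raise ValueError("bin sizes must be positive")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        if self.denoise_window % 2 != 1:
            raise ValueError("denoise_window must be odd")
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.n_tiles < 1:
            raise ValueError("n_tiles must be >= 1")
        if tuple(self.half_widths_um) != tuple(sorted(self.half_widths_um)):
            raise ValueError("half_widths_um must be increasing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["slide"]["slide_extent_um"] = list(self.slide.slide_extent_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        slide = d.pop("slide", {})
        if not isinstance(slide, SlideConfig):
            slide = SlideConfig(
                bin_pitch_um=slide.get("bin_pitch_um", DEFAULT_BIN_PITCH_UM),
                slide_extent_um=tuple(slide.get("slide_extent_um", (10_000.0, 10_000.0))),
                rng_seed=slide.get("rng_seed", 0),
            )
        known = {f.name for f in dataclasses.fields(cls)} - {"slide"}
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("half_widths_um", "distant_band_um"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(slide=slide, **kwargs)
        cfg.validate()
        return cfg

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".json":
            return cls.from_dict(json.loads(path.read_text()))
        return cls.from_dict(yaml.safe_load(path.read_text()))


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the run seed by a fixed offset."""
    offsets = {
        "simulate": 11,
        "cohort": 23,
        "typing": 37,
        "module_score": 41,
        "patterns": 53,
    }
    return (int(seed) * 1000 + offsets.get(stage, 97)) % (2**31 - 1)
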