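"""Pipeline configuration.

A run is fully specified by the species geometry (expected cell length/width in
micrometres), the spatial calibration of the microscope (``cal_factor``,
micrometres per pixel), the imaging modality, and the frame sampling period.
Everything else has defaults derived from those four values, so a minimal
config file only needs to state them.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

MODALITIES = ("phase-contrast", "bright-field", "fluorescence")


@dataclass
class SpeciesConfig:
    """Expected cell geometry of the imaged species.

    Defaults correspond to *Salmonella enterica* Typhimurium rods:
    width (diameter) 1.1 um, length 3.5 um.
    """

    cell_length: float = 3.5   # um, expected pole-to-pole length
    cell_width: float = 1.1    # um, expected diameter
    cal_factor: float = 0.125  # um per pixel
    modality: str = "phase-contrast"

    def __post_init__(self) -> None:
        if not (self.cell_length >= self.cell_width > 0):
            raise ValueError("require cell_length >= cell_width > 0")
        if self.cal_factor <= 0:
            raise ValueError("cal_factor must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; one of {MODALITIES}")

    @property
    def cell_length_px(self) -> float:
        return self.cell_length / self.cal_factor

    @property
    def cell_width_px(self) -> float:
        return self.cell_width / self.cal_factor


@dataclass
class SegmentationConfig:
    """Tunables of the single-cell segmentation stage.

    ``t_valley`` is the deep-valley ("bow tie") width-ratio threshold; a local
    width minimum qualifies as a division septum when its ratio to the nearest
    flanking maxima on both sides is at or below this value.  ``point_sigma2``
    is the per-pixel Gaussian variance used when a complex object is re-encoded
    as a 2-D point cloud; it is kept below 0.5 (half the inter-pixel distance)
    so point abundance tracks the distance transform rather than pooling
    between pixel centres.
    """

    t_valley: float = 0.70
    point_sigma2: float = 0.3
    adaptive_window_px: int = 0      # 0 -> derived from species geometry
    adaptive_offset: float = 0.05    # fraction of dynamic range
    rng_seed: int = 0
    em_max_iter: int = 500
    em_tol: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 < self.t_valley < 1.0:
            raise ValueError("t_valley must lie in (0, 1)")
        if not 0.0 < self.point_sigma2 < 0.5:
            raise ValueError("point_sigma2 must lie in (0, 0.5)")


@dataclass
class PipelineConfig:
    """Union of everything a full run needs; round-trips to key=value files."""

    species: SpeciesConfig = field(default_factory=SpeciesConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    sampling_period: float = 5.0   # minutes between frames
    clahe_clip_limit: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    denoise_method: str = "wavelet"
    rolling_ball_radius_px: int = 0  # 0 -> 5x expected cell width in px

    def resolved_ball_radius(self) -> int:
        if self.rolling_ball_radius_px > 0:
            return self.rolling_ball_radius_px
        return max(3, int(round(5.0 * self.species.cell_width_px)))

    def resolved_adaptive_window(self) -> int:
        w = self.segmentation.adaptive_window_px
        if w <= 0:
            # just above the cell width, so the local mean tracks the bright
            # ridges between touching cells instead of averaging them away
            w = int(round(1.7 * self.species.cell_width_px))
        if w % 2 == 0:
            w += 1
        return max(3, w)

    # -- flat key=value serialization -------------------------------------

    def to_flat(self) -> dict[str, str]:
        flat: dict[str, str] = {}
        for prefix, obj in (("species", self.species), ("segmentation", self.segmentation)):
            for f in dataclasses.fields(obj):
                flat[f"{prefix}.{f.name}"] = repr(getattr(obj, f.name))
        for name in ("sampling_period", "clahe_clip_limit", "clahe_tiles",
                     "denoise_method", "rolling_ball_radius_px"):
            flat[name] = repr(getattr(self, name))
        return flat

    def save(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in sorted(self.to_flat().items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        import ast

        flat: dict[str, object] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            flat[key.strip()] = ast.literal_eval(value.strip())
        species_kw = {k.split(".", 1)[1]: v for k, v in flat.items() if k.startswith("species.")}
        seg_kw = {k.split(".", 1)[1]: v for k, v in flat.items() if k.startswith("segmentation.")}
        top = {k: v for k, v in flat.items() if "." not in k}
        if "clahe_tiles" in top:
            top["clahe_tiles"] = tuple(top["clahe_tiles"])  # type: ignore[arg-type]
        return cls(species=SpeciesConfig(**species_kw),
                   segmentation=SegmentationConfig(**seg_kw), **top)  # type: ignore[arg-type]


def point_budget(n_candidates: int, species: SpeciesConfig) -> int:
    """Number of data points N used to represent a complex object.

    N = ceil( 1/2 * C * CellLength*CellWidth / CalFactor^2 ), i.e. C/2 times
    the expected single-cell footprint in pixels, so objects that plausibly
    hide more cells are represented by proportionally more points.
    """
    if n_candidates < 1:
        raise ValueError("need at least one candidate centre")
    area_px = species.cell_length * species.cell_width / species.cal_factor ** 2
    # epsilon guards the ceiling against float residue (e.g. x.0000000001)
    return math.ceil(0.5 * n_candidates * area_px - 1e-9)


def min_fragment_area(species: SpeciesConfig) -> float:
    """Smallest credible single-cell area A in pixels.

    A = 1/4 * pi * (CellWidth/CalFactor)^2 — the area of the two semicircular
    pole caps of a rod, i.e. a disc of radius half the expected cell width.
    Fragments below A are merged into the touching neighbour that maximizes
    solidity.
    """
    return 0.25 * math.pi * (species.cell_width / species.cal_factor) ** 2
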