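"""Pipeline configuration.

All physical distances are stored in micrometres and converted to pixels
through ``pixel_size_um`` only, so the same rule set applies at any
magnification.  Defaults follow the original imaging setup: 0.25 um/px
(120 px = 30 um), 5 min frame interval.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Parameters for every stage of the MLD cytometry pipeline.

    Attributes
    ----------
    pixel_size_um : float
        Micrometres per pixel.  All um-valued rules below are divided by
        this to obtain pixel distances.
    frame_interval_min : float
        Minutes between successive frames.
    fusion_region_px : int
        Block size for the absolute-gradient focal fusion.
    peak_window_px : int
        Odd window for the row/column peak finder.
    threshold_sigma : float
        Multiplier on the image standard deviation in the background
        threshold ``theta = mu + threshold_sigma * sigma``.
    threshold_population_sigma : bool
        Use the population (ddof=0) standard deviation; sample (ddof=1)
        if False.
    seed_spawn_um : float
        An element farther than this from every seed spawns a new seed
        (30 um = "~3 cell diameters").
    seed_removal_um : float
        A seed with no element within this radius is removed (12.5 um).
    split_separation_um : float
        Mean pairwise element separation above which a cluster is tested
        for splitting (15 um = "~1.5 cell diameters").
    split_seed_offset_px : float
        Offset of the extra seed injected during a split test (10 px).
    kmeans_tol_px, kmeans_max_iter :
        k-means convergence controls.
    link_radius_um : float
        Maximum frame-to-frame centroid link distance (10 um, the
        average single cell diameter).
    baseline_window_frames : int
        Frames of stable separation used as the pre-contraction baseline
        of the mitotic curve.
    contraction_fraction : float
        Fraction of baseline below which a contraction phase is declared.
    auto_seed_radius_um : float
        Linking radius for automatic first-frame seeding by connected
        components of elements.
    """

    pixel_size_um: float = 0.25
    frame_interval_min: float = 5.0
    # imaging
    fusion_region_px: int = 32
    peak_window_px: int = 5
    threshold_sigma: float = 1.0
    threshold_population_sigma: bool = True
    # clustering
    seed_spawn_um: float = 30.0
    seed_removal_um: float = 12.5
    split_separation_um: float = 15.0
    split_seed_offset_px: float = 10.0
    kmeans_tol_px: float = 0.5
    kmeans_max_iter: int = 100
    first_frame_seed_mode: str = "auto"  # "auto" | "manual"
    auto_seed_radius_um: float = 30.0
    # tracking
    link_radius_um: float = 10.0
    # mitosis
    baseline_window_frames: int = 12
    contraction_fraction: float = 0.6
    min_mitotic_baseline_um: float = 2.5
    # io
    tiff_layout: str = "zstack_per_time"  # or "single_plane_series"

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size_um

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_size_um

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.peak_window_px < 3 or self.peak_window_px % 2 == 0:
            raise ValueError("peak_window_px must be odd and >= 3")
        if self.fusion_region_px < 2:
            raise ValueError("fusion_region_px must be >= 2")
        if not 0 < self.contraction_fraction < 1:
            raise ValueError("contraction_fraction must be in (0, 1)")
        if self.first_frame_seed_mode not in ("auto", "manual"):
            raise ValueError("first_frame_seed_mode must be 'auto' or 'manual'")
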