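"""Ground-truthed simulator of quantum-dot labelled cell movies.

Emulates the study system at desk scale: adherent cells carrying 10-50
bright vesicular point sources on a perinuclear annulus, random-walk
motility, mitotic rounding (the vesicle cloud condenses over ~30 min),
binomial partitioning of vesicles between daughters that then migrate
apart, focal-plane spread of the spots, Gaussian background noise, and
cells entering or leaving the field of view.  Every movie comes with
per-frame ground truth (cell identities, positions, vesicle ownership,
division times), so each pipeline stage can be validated without any
external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .imaging import FrameStack

MAX_CELLS = 10_000


@dataclass
class SimConfig:
    """Simulation parameters.

    Physical defaults follow the imaging setup being emulated: a
    336x256 um field at 0.25 um/px, 8 focal planes, 5 min frames,
    10-50 vesicles per cell, 10 um cell diameter, 23 +/- 2 h
    inter-mitotic time.  ``snr`` is the ratio of the mean in-focus spot
    peak to the expected background threshold (background mean plus one
    standard deviation); when set it overrides ``spot_peak_intensity``.
    """

    field_um: tuple[float, float] = (336.0, 256.0)  # (width, height)
    pixel_size_um: float = 0.25
    n_planes: int = 8
    frame_interval_min: float = 5.0
    n_frames: int = 48
    initial_cells: int = 10
    vesicles_per_cell: tuple[int, int] = (10, 50)
    cell_diameter_um: float = 10.0
    imt_hours_mean: float = 23.0
    imt_hours_sd: float = 2.0
    motility_um_per_h: float = 6.0
    spot_peak_intensity: float = 2200.0
    snr: float | None = None
    background_mean: float = 400.0
    background_sd: float = 20.0
    saturation_level: float = 4095.0  # 12-bit detector full scale
    rng_seed: int = 0
    # vesicle geometry
    ring_radius_um: float = 3.2
    ring_radius_sd_um: float = 0.6
    vesicle_jitter_um: float = 0.3
    spot_sigma_um: float = 0.5
    z_sigma_planes: float = 1.0
    intensity_spread: float = 0.3  # vesicle brightness ~ U(1-s, 1+s) x peak
    # mitotic choreography
    contraction_min: float = 30.0
    contraction_scale: float = 0.25
    reexpansion_min: float = 60.0
    separation_fast_um_h: float = 36.0   # relative, anaphase/telophase burst
    separation_fast_min: float = 20.0
    separation_slow_um_h: float = 12.0   # relative, post-mitotic migration
    separation_target_um: float = 30.0
    # population
    initial_age_uniform: bool = True
    min_initial_spacing_um: float = 25.0
    contact_distance_um: float = 12.0   # adherent cells exclude each other
    contact_push_um: float = 2.0        # max exclusion displacement per frame
    entry_rate_per_h: float = 0.0
    border_margin_um: float = 20.0
    exit_margin_um: float = 5.0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "frame_interval_min", "cell_diameter_um",
                     "imt_hours_mean", "spot_peak_intensity", "background_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.vesicles_per_cell
        if not (1 <= lo <= hi <= 200):
            raise ValueError("vesicles_per_cell must lie within [1, 200]")
        if self.n_frames < 1 or self.initial_cells < 0:
            raise ValueError("n_frames >= 1 and initial_cells >= 0 required")

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def shape_px(self) -> tuple[int, int]:
        w, h = self.field_um
        return int(round(h / self.pixel_size_um)), int(round(w / self.pixel_size_um))

    @property
    def resolved_spot_peak(self) -> float:
        if self.snr is not None:
            return self.snr * (self.background_mean + self.background_sd)
        return self.spot_peak_intensity

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("field_um", "vesicles_per_cell"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrueCell:
    """Ground-truth record of one simulated cell."""

    cell_id: int
    parent_id: int | None
    birth_frame: int
    end_frame: int = -1
    end_reason: str = "movie_end"  # "division" | "exit" | "movie_end"
    division_frame: int | None = None
    daughter_ids: list[int] = field(default_factory=list)
    vesicle_ids: list[int] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Simulator-emitted truth for a whole movie."""

    config: SimConfig
    cells: dict[int, TrueCell] = field(default_factory=dict)
    # positions_um[cell_id][frame] = (x_um, y_um)
    positions_um: dict[int, dict[int, tuple[float, float]]] = field(default_factory=dict)
    divisions: list[dict] = field(default_factory=list)
    entries: list[tuple[int, int]] = field(default_factory=list)  # (frame, cell)
    exits: list[tuple[int, int]] = field(default_factory=list)

    def n_cells(self, frame: int) -> int:
        return sum(1 for c in self.cells.values()
                   if frame in self.positions_um.get(c.cell_id, {}))

    def alive_at(self, frame: int) -> list[int]:
        return [cid for cid, pos in self.positions_um.items() if frame in pos]


class _Cell:
    """Internal mutable simulation state of one live cell."""

    __slots__ = ("cid", "pos", "birth_h", "div_h", "ring", "z", "brightness",
                 "vesicle_ids", "drift_axis", "age0_h")

    def __init__(self, cid: int, pos: np.ndarray, birth_h: float, div_h: float,
                 ring: np.ndarray, z: np.ndarray, brightness: np.ndarray,
                 vesicle_ids: list[int], drift_axis: np.ndarray | None = None,
                 age0_h: float = 0.0) -> None:
        self.cid = cid
        self.pos = pos
        self.birth_h = birth_h
        self.div_h = div_h
        self.ring = ring              # (n, 2) um offsets from the cell centre
        self.z = z                    # (n,) focal position in plane units
        self.brightness = brightness  # (n,) in-focus peak intensity
        self.vesicle_ids = vesicle_ids
        self.drift_axis = drift_axis  # post-division separation direction
        self.age0_h = age0_h          # age already served at movie start

    def scale(self, t_h: float, cfg: SimConfig) -> float:
        """Vesicle-cloud contraction/expansion factor at absolute time t."""
        s = 1.0
        to_div = self.div_h - t_h
        c_h = cfg.contraction_min / 60.0
        if 0.0 <= to_div < c_h:
            frac = 1.0 - to_div / c_h
            s = 1.0 - (1.0 - cfg.contraction_scale) * frac
        if self.drift_axis is not None:  # a daughter re-expanding after birth
            age = t_h - self.birth_h
            r_h = cfg.reexpansion_min / 60.0
            if age < r_h:
                s = min(s, cfg.contraction_scale
                        + (1.0 - cfg.contraction_scale) * age / r_h)
        return s

    def drift_um_h(self, t_h: float, cfg: SimConfig) -> float:
        """Per-daughter separation drift speed at absolute time t."""
        if self.drift_axis is None:
            return 0.0
        age = t_h - self.birth_h
        fast_h = cfg.separation_fast_min / 60.0
        fast_um = cfg.separation_fast_um_h * fast_h
        if age < fast_h:
            return cfg.separation_fast_um_h / 2.0
        slow_um = cfg.separation_target_um - fast_um
        if slow_um > 0 and age < fast_h + slow_um / cfg.separation_slow_um_h:
            return cfg.separation_slow_um_h / 2.0
        return 0.0


def _draw_imt(rng: np.random.Generator, cfg: SimConfig) -> float:
    return float(max(rng.normal(cfg.imt_hours_mean, cfg.imt_hours_sd), 8.0))


def _new_vesicles(rng: np.random.Generator, cfg: SimConfig, n: int,
                  id_start: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    angles = rng.uniform(0, 2 * np.pi, n)
    radii = np.clip(rng.normal(cfg.ring_radius_um, cfg.ring_radius_sd_um, n),
                    0.5, cfg.cell_diameter_um / 2.0)
    ring = np.stack([radii * np.cos(angles), radii * np.sin(angles)], axis=1)
    z = np.clip(rng.normal((cfg.n_planes - 1) / 2.0, max(cfg.n_planes / 4.0, 1e-9), n),
                0, cfg.n_planes - 1) if cfg.n_planes > 1 else np.zeros(n)
    s = cfg.intensity_spread
    brightness = cfg.resolved_spot_peak * rng.uniform(1 - s, 1 + s, n)
    ids = list(range(id_start, id_start + n))
    return ring, z, brightness, ids


class Simulation:
    """Stateful movie simulation; truth and rendering share one clock."""

    def __init__(self, config: SimConfig) -> None:
        self.cfg = config
        root = np.random.default_rng(config.rng_seed)
        self.rng_truth, self.rng_render = root.spawn(2)
        self.truth = GroundTruth(config)
        self._cells: list[_Cell] = []
        self._next_cell = 0
        self._next_vesicle = 0
        self._init_population()

    # -- setup -----------------------------------------------------------
    def _init_population(self) -> None:
        cfg, rng = self.cfg, self.rng_truth
        w, h = cfg.field_um
        m = cfg.border_margin_um
        positions: list[np.ndarray] = []
        attempts = 0
        while len(positions) < cfg.initial_cells and attempts < 20000:
            attempts += 1
            p = rng.uniform([m, m], [w - m, h - m])
            if all(np.linalg.norm(p - q) >= cfg.min_initial_spacing_um
                   for q in positions):
                positions.append(p)
        if len(positions) < cfg.initial_cells:
            raise ValueError("could not place initial cells at the requested "
                             "spacing; enlarge the field or reduce the count")
        for p in positions:
            age = (rng.uniform(0, cfg.imt_hours_mean)
                   if cfg.initial_age_uniform else 0.0)
            imt = _draw_imt(rng, cfg)
            while imt <= age:  # cell must still have a division ahead of it
                age = age * 0.5
            self._spawn(p, birth_h=0.0, div_h=imt - age, parent=None,
                        frame=0, age0_h=age)

    def _spawn(self, pos: np.ndarray, birth_h: float, div_h: float,
               parent: int | None, frame: int, age0_h: float = 0.0,
               inherited=None, drift_axis=None) -> _Cell:
        cfg = self.cfg
        cid = self._next_cell
        self._next_cell += 1
        if self._next_cell > MAX_CELLS:
            raise RuntimeError("simulation exceeded the desk-scale cell limit")
        if inherited is None:
            n = int(self.rng_truth.integers(cfg.vesicles_per_cell[0],
                                            cfg.vesicles_per_cell[1] + 1))
            ring, z, bright, vids = _new_vesicles(self.rng_truth, cfg, n,
                                                  self._next_vesicle)
            self._next_vesicle += n
        else:
            ring, z, bright, vids = inherited
        cell = _Cell(cid, np.array(pos, dtype=float), birth_h, div_h,
                     ring, z, bright, vids, drift_axis, age0_h)
        self._cells.append(cell)
        self.truth.cells[cid] = TrueCell(cid, parent, frame,
                                         vesicle_ids=list(vids))
        self.truth.positions_um[cid] = {}
        return cell

    # -- per-frame dynamics ---------------------------------------------
    def step(self, frame: int) -> list[_Cell]:
        """Advance to ``frame`` (0-based) and return the live cells."""
        cfg = self.cfg
        rng = self.rng_truth
        t_h = frame * cfg.frame_interval_h
        dt_h = cfg.frame_interval_h

        if frame > 0:
            # motility: random walk with mean step speed motility_um_per_h
            sigma = cfg.motility_um_per_h * dt_h / np.sqrt(np.pi / 2.0)
            for cell in self._cells:
                step = rng.normal(0.0, sigma, 2)
                drift = cell.drift_um_h(t_h, cfg)
                if drift > 0.0:
                    step = step + cell.drift_axis * drift * dt_h
                cell.pos = cell.pos + step

            # adherent exclusion: overlapping cells push each other apart
            # (contact inhibition keeps neighbouring vesicle clouds distinct)
            if cfg.contact_distance_um > 0 and len(self._cells) > 1:
                self._resolve_contacts()

            # divisions due in (t-dt, t]
            for cell in list(self._cells):
                if cell.div_h <= t_h:
                    self._divide(cell, frame, t_h)

            # entries
            if cfg.entry_rate_per_h > 0:
                for _ in range(rng.poisson(cfg.entry_rate_per_h * dt_h)):
                    self._enter(frame, t_h)

            # exits
            w, h = cfg.field_um
            mm = cfg.exit_margin_um
            for cell in list(self._cells):
                x, y = cell.pos
                if not (-mm <= x <= w + mm and -mm <= y <= h + mm):
                    rec = self.truth.cells[cell.cid]
                    rec.end_frame = frame - 1
                    rec.end_reason = "exit"
                    self.truth.exits.append((frame, cell.cid))
                    self._cells.remove(cell)

        for cell in self._cells:
            self.truth.positions_um[cell.cid][frame] = (float(cell.pos[0]),
                                                        float(cell.pos[1]))
            self.truth.cells[cell.cid].end_frame = frame
        return self._cells

    def _resolve_contacts(self) -> None:
        cfg = self.cfg
        pos = np.array([c.pos for c in self._cells])
        n = len(pos)
        d = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(d, axis=2)
        push = np.zeros_like(pos)
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] < cfg.contact_distance_um:
                    gap = cfg.contact_distance_um - dist[i, j]
                    if dist[i, j] > 1e-9:
                        u = d[i, j] / dist[i, j]
                    else:
                        u = np.array([1.0, 0.0])
                    step = min(gap / 2.0, cfg.contact_push_um)
                    push[i] += u * step
                    push[j] -= u * step
        for c, p in zip(self._cells, push):
            c.pos = c.pos + p

    def _divide(self, cell: _Cell, frame: int, t_h: float) -> None:
        cfg, rng = self.cfg, self.rng_truth
        n = len(cell.vesicle_ids)
        # binomial partition; re-draw until both daughters are seeded
        while True:
            take = rng.random(n) < 0.5
            if n < 2 or (take.any() and (~take).any()):
                break
        axis = rng.normal(0, 1, 2)
        axis /= max(np.linalg.norm(axis), 1e-12)
        offset = 0.5  # um initial nucleo-centre separation
        for sign, mask in ((1.0, take), (-1.0, ~take)):
            # full-size ring offsets; the post-birth re-expansion ramp in
            # scale() renders the cloud condensed right after division
            inherited = (cell.ring[mask],
                         cell.z[mask], cell.brightness[mask],
                         [cell.vesicle_ids[i] for i in np.nonzero(mask)[0]])
            d = self._spawn(cell.pos + sign * axis * offset, birth_h=t_h,
                            div_h=t_h + _draw_imt(rng, cfg), parent=cell.cid,
                            frame=frame, inherited=inherited,
                            drift_axis=sign * axis)
            self.truth.cells[cell.cid].daughter_ids.append(d.cid)
        rec = self.truth.cells[cell.cid]
        rec.end_frame = frame - 1
        rec.end_reason = "division"
        rec.division_frame = frame
        self.truth.divisions.append(dict(
            frame=frame, mother=cell.cid,
            daughters=list(rec.daughter_ids),
            x_um=float(cell.pos[0]), y_um=float(cell.pos[1])))
        self._cells.remove(cell)

    def _enter(self, frame: int, t_h: float) -> None:
        cfg, rng = self.cfg, self.rng_truth
        w, h = cfg.field_um
        side = rng.integers(0, 4)
        u = rng.uniform(0, 1)
        pos = {0: (u * w, 1.0), 1: (u * w, h - 1.0),
               2: (1.0, u * h), 3: (w - 1.0, u * h)}[int(side)]
        cell = self._spawn(np.array(pos), birth_h=t_h,
                           div_h=t_h + _draw_imt(rng, cfg), parent=None,
                           frame=frame)
        self.truth.entries.append((frame, cell.cid))

    # -- rendering -------------------------------------------------------
    def vesicle_positions_um(self, frame: int, jitter: bool = True
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(x,y) um positions, z, brightness and owning cell of every
        vesicle at the current frame (call after ``step``)."""
        cfg = self.cfg
        t_h = frame * cfg.frame_interval_h
        xs, zs, bs, owner = [], [], [], []
        for cell in self._cells:
            s = cell.scale(t_h, cfg)
            pos = cell.pos + cell.ring * s
            if jitter and cfg.vesicle_jitter_um > 0:
                pos = pos + self.rng_render.normal(
                    0, cfg.vesicle_jitter_um, cell.ring.shape)
            xs.append(pos)
            zs.append(cell.z)
            bs.append(cell.brightness)
            owner.append(np.full(len(cell.z), cell.cid))
        if not xs:
            z = np.zeros(0)
            return np.zeros((0, 2)), z, z, z.astype(int)
        return (np.concatenate(xs), np.concatenate(zs),
                np.concatenate(bs), np.concatenate(owner).astype(int))

    def render_frame(self, frame: int) -> FrameStack:
        """Render the current frame (after ``step(frame)``) to a FrameStack."""
        cfg = self.cfg
        H, W = cfg.shape_px
        rng = self.rng_render
        pos_um, z, bright, _owner = self.vesicle_positions_um(frame)
        planes = rng.normal(cfg.background_mean, cfg.background_sd,
                            (cfg.n_planes, H, W))
        if len(pos_um):
            _add_spots(planes, pos_um / cfg.pixel_size_um, z, bright, cfg)
        planes = np.clip(np.rint(planes), 0, cfg.saturation_level
                         ).astype(np.uint16)
        return FrameStack(planes, frame, frame * cfg.frame_interval_min,
                          cfg.pixel_size_um)


def _add_spots(planes: np.ndarray, pos_px: np.ndarray, z: np.ndarray,
               brightness: np.ndarray, cfg: SimConfig) -> None:
    """Scatter-add Gaussian spots into each focal plane.

    Per-vesicle plane weights follow a Gaussian z-profile normalised so
    the best-focus plane carries the full nominal peak.
    """
    n_planes, H, W = planes.shape
    sigma = cfg.spot_sigma_um / cfg.pixel_size_um
    r = max(int(np.ceil(3 * sigma)), 2)
    size = 2 * r + 1
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]

    cx, cy = pos_px[:, 0], pos_px[:, 1]
    ix, iy = np.round(cx).astype(int), np.round(cy).astype(int)
    fx, fy = cx - ix, cy - iy
    # (n, size, size) sub-pixel-centred Gaussian profiles
    prof = np.exp(-((dx[None] - fx[:, None, None]) ** 2
                    + (dy[None] - fy[:, None, None]) ** 2) / (2 * sigma ** 2))

    plane_idx = np.arange(n_planes)
    wz = np.exp(-(plane_idx[None, :] - z[:, None]) ** 2
                / (2 * cfg.z_sigma_planes ** 2))
    wz /= np.maximum(wz.max(axis=1, keepdims=True), 1e-12)

    for p in range(n_planes):
        amp = brightness * wz[:, p]
        keep = amp > 0.02 * brightness
        if not keep.any():
            continue
        patches = prof[keep] * amp[keep, None, None]
        yy = iy[keep, None, None] + dy[None]
        xx = ix[keep, None, None] + dx[None]
        inside = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        flat = yy[inside] * W + xx[inside]
        np.add.at(planes[p].reshape(-1), flat, patches[inside])


def simulate_truth(config: SimConfig) -> GroundTruth:
    """Run the cell dynamics only (no pixel rendering)."""
    sim = Simulation(config)
    for f in range(config.n_frames):
        sim.step(f)
    return sim.truth


def iter_movie(config: SimConfig):
    """Yield (FrameStack, Simulation) per frame; truth grows as it runs."""
    sim = Simulation(config)
    for f in range(config.n_frames):
        sim.step(f)
        yield sim.render_frame(f), sim


def simulate_movie(config: SimConfig) -> tuple[list[FrameStack], GroundTruth]:
    """Render a full movie.  Identical ``rng_seed`` gives bit-identical
    pixel data and ground truth."""
    sim = Simulation(config)
    frames = []
    for f in range(config.n_frames):
        sim.step(f)
        frames.append(sim.render_frame(f))
    return frames, sim.truth


def truth_to_dict(gt: GroundTruth) -> dict:
    return {
        "config": gt.config.to_dict(),
        "cells": {str(cid): dataclasses.asdict(c) for cid, c in gt.cells.items()},
        "positions_um": {str(cid): {str(f): list(p) for f, p in pos.items()}
                         for cid, pos in gt.positions_um.items()},
        "divisions": gt.divisions,
        "entries": [list(e) for e in gt.entries],
        "exits": [list(e) for e in gt.exits],
    }


def render_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a movie fixture: one multi-page TIFF per timepoint plus the
    ground truth (JSON) and the configuration (YAML), in the exact
    dialect the pipeline readers consume."""
    import tifffile

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        sim = Simulation(config)
        for f in range(config.n_frames):
            sim.step(f)
            stack = sim.render_frame(f)
            tifffile.imwrite(out / f"t{f:04d}.tif", stack.planes,
                             photometric="minisblack")
        gt_path = out / "ground_truth.json"
        gt_path.write_text(json.dumps(truth_to_dict(sim.truth), indent=1))
        cfg_path = out / "sim_config.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    except OSError as exc:
        raise OSError(f"cannot write fixture under {out}: {exc}") from exc
    return {"dir": out, "ground_truth": gt_path, "config": cfg_path}


def load_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    cfg = SimConfig.from_dict(data["config"])
    gt = GroundTruth(cfg)
    for cid, c in data["cells"].items():
        gt.cells[int(cid)] = TrueCell(**c)
    for cid, pos in data["positions_um"].items():
        gt.positions_um[int(cid)] = {int(f): tuple(p) for f, p in pos.items()}
    gt.divisions = data["divisions"]
    gt.entries = [tuple(e) for e in data["entries"]]
    gt.exits = [tuple(e) for e in data["exits"]]
    return gt
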