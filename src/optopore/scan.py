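"""Meander scan planning, stage timing, focus-plane correction and the
virtual-instrument control loop.

The dish is covered by a mosaic of camera fields of view (FOVs) visited
in a serpentine ("meander") order so consecutive stage moves are one FOV
long.  Within each FOV the control loop acquires a still image, detects
target positions, centres each position on the (fixed) laser focus by
moving the stage, and gates the illumination with a mechanical shutter.
Timing is governed by a small set of instrument constants (stage speed,
shutter/illumination duration, camera exposure, per-position detection
cost); the run produces an auditable event log from which throughput is
computed exactly.

No real hardware is driven: stage and shutter are virtual devices that
honour the same command contracts, so the whole loop is testable on
synthetic dishes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .detect import DetectionParams, TargetPosition, rake_detect, deduplicate_targets

__all__ = [
    "FOVGrid",
    "MeanderPlan",
    "TileStop",
    "TimingModel",
    "FocusPlane",
    "Event",
    "RunLog",
    "RunResult",
    "VirtualStage",
    "VirtualShutter",
    "HardwareError",
    "DegenerateGeometryError",
    "plan_meander",
    "fit_focus_plane",
    "predict_focus_z",
    "stage_move_time",
    "simulate_run",
    "execute_run",
]


class HardwareError(RuntimeError):
    """A virtual device violated its command contract."""


class DegenerateGeometryError(ValueError):
    """Calibration points do not determine a plane."""


@dataclass(frozen=True)
class FOVGrid:
    """Rectangular mosaic of fields of view on the stage."""

    n_rows: int
    n_cols: int
    fov_width_um: float
    fov_height_um: float
    origin_stage_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least 1 row and 1 column")
        if self.fov_width_um <= 0 or self.fov_height_um <= 0:
            raise ValueError("FOV dimensions must be positive")

    def tile_centre(self, i: int, j: int) -> tuple[float, float]:
        ox, oy = self.origin_stage_um
        return (ox + j * self.fov_width_um, oy + i * self.fov_height_um)


@dataclass(frozen=True)
class TileStop:
    i: int
    j: int
    x_um: float
    y_um: float


@dataclass(frozen=True)
class MeanderPlan:
    """Serpentine visiting order of the mosaic tiles."""

    tiles: tuple[TileStop, ...]
    grid: FOVGrid

    def __len__(self) -> int:
        return len(self.tiles)

    @property
    def indices(self) -> list[tuple[int, int]]:
        return [(t.i, t.j) for t in self.tiles]


def plan_meander(grid: FOVGrid) -> MeanderPlan:
    """Serpentine plan: row 0 left-to-right, row 1 right-to-left, ...

    Every tile appears exactly once and consecutive tiles are grid
    neighbours, so each inter-FOV stage move is exactly one FOV long.
    """
    stops = []
    for i in range(grid.n_rows):
        cols = range(grid.n_cols) if i % 2 == 0 else range(grid.n_cols - 1, -1, -1)
        for j in cols:
            x, y = grid.tile_centre(i, j)
            stops.append(TileStop(i=i, j=j, x_um=x, y_um=y))
    return MeanderPlan(tiles=tuple(stops), grid=grid)


@dataclass(frozen=True)
class TimingModel:
    """Instrument time constants, all in milliseconds.

    Defaults reflect a motorised microscope stage that needs ~15 ms to
    change position by 10 um (acceleration and stop included) plus a fixed
    per-move overhead, a ~150 ms move between FOVs, a 20-50 ms camera
    exposure, sub-ms per-position detection, and a user-set illumination
    window (default 100 ms).
    """

    stage_ms_per_10um: float = 15.0
    stage_overhead_ms: float = 20.0
    illumination_ms: float = 100.0
    fov_reposition_ms: float = 150.0
    camera_exposure_ms: float = 35.0
    detection_ms_per_position: float = 1.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be nonnegative")


def stage_move_time(distance_um: float, timing: TimingModel) -> float:
    """Milliseconds for a within-FOV centring move.

    Linear in distance with a 10-um floor (acceleration/stop dominate
    short moves) plus the fixed per-move overhead.
    """
    if distance_um < 0:
        raise ValueError("distance must be nonnegative")
    return timing.stage_overhead_ms + timing.stage_ms_per_10um * max(distance_um, 10.0) / 10.0


@dataclass(frozen=True)
class FocusPlane:
    """Least-squares focus plane z = a*x + b*y + c (all um)."""

    a: float
    b: float
    c: float
    rms_residual_um: float = 0.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.a, self.b, self.c))):
            raise ValueError("plane coefficients must be finite")
        if self.rms_residual_um < 0:
            raise ValueError("residual must be nonnegative")


def fit_focus_plane(points) -> FocusPlane:
    """Fit the tilt of the dish from (x, y, z) calibration points.

    The optimal objective height varies across the dish when the culture
    dish sits slightly tilted; with >= 3 non-collinear calibration points
    the height correction at any stage position is interpolated from the
    least-squares plane through them.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of (x, y, z)")
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fitting needs at least 3 points")
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(pts.shape[0])])
    if np.linalg.matrix_rank(A) < 3:
        raise DegenerateGeometryError("calibration points are collinear in (x, y)")
    coeffs, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    resid = pts[:, 2] - A @ coeffs
    return FocusPlane(
        a=float(coeffs[0]),
        b=float(coeffs[1]),
        c=float(coeffs[2]),
        rms_residual_um=float(np.sqrt(np.mean(resid**2))),
    )


def predict_focus_z(plane: FocusPlane, x_um: float, y_um: float) -> float:
    """Height correction at a stage position, from the fitted plane."""
    return plane.a * x_um + plane.b * y_um + plane.c


@dataclass(frozen=True)
class Event:
    timestamp_ms: float
    kind: str  # move | expose | detect | open_shutter | close_shutter | fov_advance
    duration_ms: float
    payload: dict = field(default_factory=dict)


@dataclass
class RunLog:
    """Ordered event trace of one automated run, plus totals."""

    events: list[Event]
    n_positions: int
    elapsed_ms: float
    throughput_per_s: float

    def to_jsonl(self) -> str:
        return "\n".join(
            json.dumps(
                {
                    "timestamp_ms": e.timestamp_ms,
                    "kind": e.kind,
                    "duration_ms": e.duration_ms,
                    **({"payload": e.payload} if e.payload else {}),
                }
            )
            for e in self.events
        )

    def summary(self) -> dict:
        return {
            "n_events": len(self.events),
            "n_positions": self.n_positions,
            "elapsed_ms": self.elapsed_ms,
            "throughput_per_s": self.throughput_per_s,
        }


@dataclass
class RunResult:
    """Outcome of a closed-loop run: the log and what was detected."""

    log: RunLog
    targets_by_fov: dict


class VirtualStage:
    """Motorised x-y(-z) stage stand-in: absolute moves, reports position."""

    def __init__(self) -> None:
        self._pos = (0.0, 0.0, 0.0)

    def move_to(self, x_um: float, y_um: float, z_um: float | None = None) -> None:
        z = self._pos[2] if z_um is None else z_um
        self._pos = (x_um, y_um, z)

    @property
    def position(self) -> tuple[float, float, float]:
        return self._pos


class VirtualShutter:
    """Mechanical laser shutter stand-in."""

    def __init__(self) -> None:
        self.is_open = False
        self.cycles = 0

    def open(self) -> None:
        if self.is_open:
            raise HardwareError("shutter already open")
        self.is_open = True

    def close(self) -> None:
        if not self.is_open:
            raise HardwareError("shutter already closed")
        self.is_open = False
        self.cycles += 1


def _position_xy_um(pos, tile: TileStop, grid: FOVGrid) -> tuple[float, float]:
    """Stage coordinates of a target: FOV-frame offset about the tile centre."""
    if isinstance(pos, TargetPosition):
        x, y = pos.x_um, pos.y_um
    else:
        x, y = pos
    return (
        tile.x_um + x - grid.fov_width_um / 2.0,
        tile.y_um + y - grid.fov_height_um / 2.0,
    )


def simulate_run(targets_by_fov: dict, plan: MeanderPlan, timing: TimingModel) -> RunLog:
    """Pure timing simulation of a run over pre-detected targets.

    ``targets_by_fov`` maps tile index (i, j) to its target positions
    (TargetPosition or (x_um, y_um) in the FOV frame).  Per FOV: stage
    repositioning, camera exposure, detection, then per position a
    centring move and a shutter-gated illumination.  The elapsed time is
    exactly the sum of all event durations.
    """
    tile_lookup = {(t.i, t.j): t for t in plan.tiles}
    unknown = set(targets_by_fov) - set(tile_lookup)
    if unknown:
        raise ValueError(f"targets reference tiles not in the plan: {sorted(unknown)}")

    events: list[Event] = []
    t = 0.0
    n_positions = 0
    first = plan.tiles[0]
    stage_xy = (first.x_um, first.y_um)
    for tile in plan.tiles:
        events.append(Event(t, "fov_advance", timing.fov_reposition_ms, {"tile": [tile.i, tile.j]}))
        t += timing.fov_reposition_ms
        stage_xy = (tile.x_um, tile.y_um)
        events.append(Event(t, "expose", timing.camera_exposure_ms))
        t += timing.camera_exposure_ms
        targets = targets_by_fov.get((tile.i, tile.j), [])
        detect_ms = timing.detection_ms_per_position * len(targets)
        events.append(Event(t, "detect", detect_ms, {"n_positions": len(targets)}))
        t += detect_ms
        for pos in targets:
            xy = _position_xy_um(pos, tile, plan.grid)
            dist = math.hypot(xy[0] - stage_xy[0], xy[1] - stage_xy[1])
            move_ms = stage_move_time(dist, timing)
            events.append(Event(t, "move", move_ms, {"x_um": xy[0], "y_um": xy[1]}))
            t += move_ms
            stage_xy = xy
            events.append(Event(t, "open_shutter", timing.illumination_ms))
            t += timing.illumination_ms
            events.append(Event(t, "close_shutter", 0.0))
            n_positions += 1
    throughput = n_positions / (t / 1000.0) if t > 0 else 0.0
    return RunLog(events=events, n_positions=n_positions, elapsed_ms=t, throughput_per_s=throughput)


def execute_run(
    image_source,
    detector_params: DetectionParams,
    plan: MeanderPlan,
    timing: TimingModel,
    stage: VirtualStage | None = None,
    shutter: VirtualShutter | None = None,
    focus_plane: FocusPlane | None = None,
) -> RunResult:
    """Closed control loop against virtual hardware.

    Per tile of the plan: move the stage to the FOV, acquire a still
    image from ``image_source`` (a callable ``(i, j) -> image`` or a
    mapping), detect and deduplicate targets, then centre and illuminate
    each one (status pending -> illuminated), applying the focus-plane
    height correction when one is supplied.  The stage is read back after
    every commanded move; a mismatch aborts with a diagnostic.
    """
    stage = stage if stage is not None else VirtualStage()
    shutter = shutter if shutter is not None else VirtualShutter()
    get_image = image_source if callable(image_source) else lambda i, j: image_source[(i, j)]

    def _checked_move(x: float, y: float, z: float | None) -> None:
        stage.move_to(x, y, z)
        px, py, pz = stage.position
        ok = math.isclose(px, x, abs_tol=1e-9) and math.isclose(py, y, abs_tol=1e-9)
        if z is not None:
            ok = ok and math.isclose(pz, z, abs_tol=1e-9)
        if not ok:
            raise HardwareError(
                f"stage reported position ({px}, {py}, {pz}) after commanded move "
                f"to ({x}, {y}, {z}); aborting run"
            )

    events: list[Event] = []
    t = 0.0
    n_positions = 0
    targets_by_fov: dict[tuple[int, int], list[TargetPosition]] = {}
    stage_xy = (plan.tiles[0].x_um, plan.tiles[0].y_um)
    for tile in plan.tiles:
        z = predict_focus_z(focus_plane, tile.x_um, tile.y_um) if focus_plane else None
        _checked_move(tile.x_um, tile.y_um, z)
        events.append(Event(t, "fov_advance", timing.fov_reposition_ms, {"tile": [tile.i, tile.j]}))
        t += timing.fov_reposition_ms
        stage_xy = (tile.x_um, tile.y_um)

        image = get_image(tile.i, tile.j)
        events.append(Event(t, "expose", timing.camera_exposure_ms))
        t += timing.camera_exposure_ms

        raw = rake_detect(image, detector_params)
        kept = deduplicate_targets(raw, detector_params.separation_um)
        targets_by_fov[(tile.i, tile.j)] = kept
        detect_ms = timing.detection_ms_per_position * len(kept)
        events.append(Event(t, "detect", detect_ms, {"n_positions": len(kept)}))
        t += detect_ms

        for pos in kept:
            xy = _position_xy_um(pos, tile, plan.grid)
            zt = predict_focus_z(focus_plane, xy[0], xy[1]) if focus_plane else None
            _checked_move(xy[0], xy[1], zt)
            dist = math.hypot(xy[0] - stage_xy[0], xy[1] - stage_xy[1])
            move_ms = stage_move_time(dist, timing)
            events.append(Event(t, "move", move_ms, {"x_um": xy[0], "y_um": xy[1]}))
            t += move_ms
            stage_xy = xy
            shutter.open()
            events.append(Event(t, "open_shutter", timing.illumination_ms))
            t += timing.illumination_ms
            shutter.close()
            events.append(Event(t, "close_shutter", 0.0))
            pos.status = "illuminated"
            n_positions += 1

    throughput = n_positions / (t / 1000.0) if t > 0 else 0.0
    log = RunLog(events=events, n_positions=n_positions, elapsed_ms=t, throughput_per_s=throughput)
    return RunResult(log=log, targets_by_fov=targets_by_fov)
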