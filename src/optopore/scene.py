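"""Synthetic dish scenes with per-cell ground truth.

Renders the two kinds of image the optoporation pipeline consumes:

* low-contrast bright-field views of an adherent monolayer, where each
  cell is visible only as a contour ring of modest amplitude on a flat
  background — the regime the rake edge detector is designed for;
* registered tri-channel fluorescence views (DAPI / ethidium bromide /
  calcein) of the same dish after treatment and staining, with per-cell
  intensities drawn from class-conditional distributions so that the
  three outcome classes (intact, optoporated-alive, dead) are encoded in
  the channels the way a stained CHO dish encodes them.

Every scene carries a :class:`GroundTruth` (label image plus per-cell
records) so detection recall, segmentation accuracy and classification
error can be measured exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "ChannelModel",
    "SceneSpec",
    "CellTruth",
    "GroundTruth",
    "generate_brightfield",
    "generate_fluorescence",
]

CLASS_NAMES = ("intact", "optoporated_alive", "dead")

# Independent substreams derived from the root seed by fixed offsets.
_PLACEMENT_STREAM = 0
_CLASS_STREAM = 1
_CHANNEL_STREAM = 2
_NOISE_STREAM = {"brightfield": 3, "dapi": 4, "etbr": 5, "calcein": 6}

_RING_WIDTH_PX = 2.0  # radial extent of the bright-field contour ring


@dataclass(frozen=True)
class ChannelModel:
    """Class-conditional (mean, sd) of the three fluorescence channels."""

    dapi: tuple[float, float]
    etbr: tuple[float, float]
    calcein: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("dapi", "etbr", "calcein"):
            mean, sd = getattr(self, name)
            if mean < 0 or sd < 0:
                raise ValueError(f"{name} mean/sd must be nonnegative, got {(mean, sd)}")


def default_channel_models() -> dict[str, ChannelModel]:
    """Default intensity models on a 12-bit scale.

    Control (intact) DAPI clusters around 1000 counts; perforated cells
    (optoporated or dead) shift well above that, with a tail that clips at
    the 4095 ceiling.  EtBr marks dead cells only; calcein marks living
    cells only.
    """
    return {
        "intact": ChannelModel(dapi=(1000.0, 100.0), etbr=(0.0, 0.0), calcein=(1500.0, 200.0)),
        "optoporated_alive": ChannelModel(dapi=(3000.0, 700.0), etbr=(0.0, 0.0), calcein=(1500.0, 200.0)),
        "dead": ChannelModel(dapi=(3000.0, 700.0), etbr=(2000.0, 300.0), calcein=(0.0, 0.0)),
    }


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of a synthetic dish."""

    image_height_px: int = 512
    image_width_px: int = 512
    pixel_size_um: float = 0.5
    n_cells: int = 50
    cell_radius_um: tuple[float, float] = (5.0, 7.0)
    edge_contrast: float = 50.0
    background_level: float = 200.0
    noise_sd: float = 2.0
    bit_depth: int = 12
    class_fractions: tuple[float, float, float] = (1.0, 0.0, 0.0)
    channel_models: dict[str, ChannelModel] = field(default_factory=default_channel_models)
    non_overlapping: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        rmin, rmax = self.cell_radius_um
        if rmin <= 0 or rmax < rmin:
            raise ValueError(f"invalid cell_radius_um range {self.cell_radius_um}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.bit_depth not in (8, 12):
            raise ValueError("bit_depth must be 8 or 12")
        if len(self.class_fractions) != 3 or any(f < 0 for f in self.class_fractions):
            raise ValueError("class_fractions must be 3 nonnegative reals")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        missing = [c for c in CLASS_NAMES if c not in self.channel_models]
        if missing:
            raise ValueError(f"channel_models missing classes: {missing}")

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_models"] = {
            cls: {ch: list(getattr(m, ch)) for ch in ("dapi", "etbr", "calcein")}
            for cls, m in self.channel_models.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        if "channel_models" in d:
            d["channel_models"] = {
                name: ChannelModel(**{ch: tuple(v) for ch, v in m.items()})
                for name, m in d["channel_models"].items()
            }
        for key in ("cell_radius_um", "class_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CellTruth:
    """Ground truth for a single rendered cell."""

    label: int
    centroid_row: float
    centroid_col: float
    radius_um: float
    cell_class: str
    true_means: dict[str, float]


@dataclass
class GroundTruth:
    """Per-cell truth plus the shared label image (0 = background)."""

    cells: list[CellTruth]
    label_image: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cells_to_json(self) -> str:
        return json.dumps([asdict(c) for c in self.cells], indent=1)

    @classmethod
    def cells_from_json(cls, text: str, label_image: np.ndarray) -> "GroundTruth":
        return cls(cells=[CellTruth(**c) for c in json.loads(text)], label_image=label_image)


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement cannot be satisfied."""


def _place_cells(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample cell centres (px) and radii (px) from the placement stream.

    Rejection sampling keeps centre-to-centre distance >= sum of radii in
    non-overlapping mode.  Cells are kept fully inside the frame.
    """
    rng = np.random.default_rng(spec.seed + _PLACEMENT_STREAM)
    rmin_px = spec.cell_radius_um[0] / spec.pixel_size_um
    rmax_px = spec.cell_radius_um[1] / spec.pixel_size_um
    h, w = spec.image_height_px, spec.image_width_px
    if spec.n_cells and (2 * rmax_px >= h or 2 * rmax_px >= w):
        raise ValueError("cells do not fit inside the image frame")
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    max_attempts = 1000 * max(spec.n_cells, 1)
    attempts = 0
    while len(centres) < spec.n_cells:
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {spec.n_cells} non-overlapping cells "
                f"in a {h}x{w} frame after {max_attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(rmin_px, rmax_px)
        cr = rng.uniform(r, h - 1 - r)
        cc = rng.uniform(r, w - 1 - r)
        if spec.non_overlapping:
            ok = all(
                np.hypot(cr - pr, cc - pc) >= r + prr
                for (pr, pc), prr in zip(centres, radii)
            )
            if not ok:
                continue
        centres.append((cr, cc))
        radii.append(r)
    return np.asarray(centres, dtype=float).reshape(-1, 2), np.asarray(radii, dtype=float)


def _assign_classes(spec: SceneSpec) -> np.ndarray:
    """Draw one outcome class per cell from the class stream."""
    rng = np.random.default_rng(spec.seed + _CLASS_STREAM)
    idx = rng.choice(3, size=spec.n_cells, p=np.asarray(spec.class_fractions, dtype=float))
    return idx


def _label_image(spec: SceneSpec, centres: np.ndarray, radii: np.ndarray) -> np.ndarray:
    labels = np.zeros((spec.image_height_px, spec.image_width_px), dtype=np.int32)
    rows = np.arange(spec.image_height_px)[:, None]
    cols = np.arange(spec.image_width_px)[None, :]
    for i, ((cr, cc), r) in enumerate(zip(centres, radii), start=1):
        r_int = int(np.ceil(r)) + 1
        r0, r1 = max(0, int(cr) - r_int), min(spec.image_height_px, int(cr) + r_int + 1)
        c0, c1 = max(0, int(cc) - r_int), min(spec.image_width_px, int(cc) + r_int + 1)
        d = np.hypot(rows[r0:r1] - cr, cols[0, c0:c1][None, :] - cc)
        labels[r0:r1, c0:c1][d <= r] = i
    return labels


def _finalize(spec: SceneSpec, image: np.ndarray, channel: str) -> np.ndarray:
    """Add channel noise, clip to the bit depth, cast to the integer dtype."""
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + _NOISE_STREAM[channel])
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return np.clip(np.rint(image), 0, spec.max_value).astype(spec.dtype)


def _ground_truth(spec: SceneSpec, centres, radii, classes, true_means) -> GroundTruth:
    labels = _label_image(spec, centres, radii)
    cells = [
        CellTruth(
            label=i + 1,
            centroid_row=float(centres[i, 0]),
            centroid_col=float(centres[i, 1]),
            radius_um=float(radii[i] * spec.pixel_size_um),
            cell_class=CLASS_NAMES[classes[i]],
            true_means={ch: float(true_means[ch][i]) for ch in true_means},
        )
        for i in range(spec.n_cells)
    ]
    return GroundTruth(cells=cells, label_image=labels)


def _true_channel_means(spec: SceneSpec, classes: np.ndarray) -> dict[str, np.ndarray]:
    """Per-cell true mean intensity in each channel, from the channel stream.

    Values are drawn cell by cell (channels inner loop) so the stream layout
    is reproducible by an independent generator following the same policy.
    """
    rng = np.random.default_rng(spec.seed + _CHANNEL_STREAM)
    means: dict[str, list[float]] = {"dapi": [], "etbr": [], "calcein": []}
    for k in classes:
        model = spec.channel_models[CLASS_NAMES[k]]
        for ch in ("dapi", "etbr", "calcein"):
            mean, sd = getattr(model, ch)
            v = rng.normal(mean, sd) if sd > 0 else float(mean)
            means[ch].append(max(v, 0.0))
    return {ch: np.asarray(v, dtype=float) for ch, v in means.items()}


def generate_brightfield(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a low-contrast bright-field view of the dish.

    Each cell is a flat interior near the background level surrounded by a
    contour ring of amplitude ``edge_contrast`` — the only feature the edge
    detector has to work with, as in a real bright-field view of an
    adherent monolayer.

    Returns the image (uint8/uint16 per ``bit_depth``) and the ground truth.
    """
    centres, radii = _place_cells(spec)
    classes = _assign_classes(spec)
    true_means = _true_channel_means(spec, classes)

    image = np.full((spec.image_height_px, spec.image_width_px), float(spec.background_level))
    # small per-cell interior offset, deterministic continuation of the
    # placement stream so bright-field rendering stays independent of the
    # fluorescence streams
    rng = np.random.default_rng(spec.seed + _PLACEMENT_STREAM + 10)
    interior_offsets = rng.uniform(-0.1, 0.1, size=spec.n_cells) * spec.edge_contrast
    rows = np.arange(spec.image_height_px)
    cols = np.arange(spec.image_width_px)
    for i in range(spec.n_cells):
        cr, cc = centres[i]
        r = radii[i]
        r_int = int(np.ceil(r)) + 1
        r0, r1 = max(0, int(cr) - r_int), min(spec.image_height_px, int(cr) + r_int + 1)
        c0, c1 = max(0, int(cc) - r_int), min(spec.image_width_px, int(cc) + r_int + 1)
        d = np.hypot(rows[r0:r1, None] - cr, cols[None, c0:c1] - cc)
        interior = d <= r - _RING_WIDTH_PX
        ring = (d <= r) & ~interior
        win = image[r0:r1, c0:c1]
        win[interior] = spec.background_level + interior_offsets[i]
        win[ring] = spec.background_level + spec.edge_contrast
    out = _finalize(spec, image, "brightfield")
    return out, _ground_truth(spec, centres, radii, classes, true_means)


def generate_fluorescence(
    spec: SceneSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Render registered DAPI, EtBr and calcein views of the same dish.

    The three channels share one label image.  Each cell's pixel values
    are its class-conditional true intensity times a nucleus-weighted
    radial profile: the base level at the rim rising to 1.5x at the
    centre, as stain accumulates toward the nucleus.  Every pixel of a
    cell is therefore >= its true intensity, so clipping at
    ``2**bit_depth - 1`` both saturates whole cells whose intensity
    exceeds the camera range and produces the saturation pile-up seen
    when perforated cells take up far more DAPI than the range allows.
    """
    centres, radii = _place_cells(spec)
    classes = _assign_classes(spec)
    true_means = _true_channel_means(spec, classes)
    truth = _ground_truth(spec, centres, radii, classes, true_means)

    rows = np.arange(spec.image_height_px)
    cols = np.arange(spec.image_width_px)
    profiles = []
    for i in range(spec.n_cells):
        cr, cc = centres[i]
        r = radii[i]
        r_int = int(np.ceil(r)) + 1
        r0, r1 = max(0, int(cr) - r_int), min(spec.image_height_px, int(cr) + r_int + 1)
        c0, c1 = max(0, int(cc) - r_int), min(spec.image_width_px, int(cc) + r_int + 1)
        d = np.hypot(rows[r0:r1, None] - cr, cols[None, c0:c1] - cc)
        inside = d <= r
        profiles.append((slice(r0, r1), slice(c0, c1), inside, 1.0 + 0.5 * (1.0 - (d[inside] / r) ** 2)))

    images = []
    for ch in ("dapi", "etbr", "calcein"):
        img = np.zeros((spec.image_height_px, spec.image_width_px), dtype=float)
        for i, (rs, cs, inside, prof) in enumerate(profiles):
            img[rs, cs][inside] = true_means[ch][i] * prof
        images.append(_finalize(spec, img, ch))
    return images[0], images[1], images[2], truth
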