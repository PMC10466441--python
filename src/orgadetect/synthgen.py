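"""Synthetic brightfield organoid scenes with exact ground truth.

The generator emulates the two morphologies seen in gastric-organoid
brightfield imaging at 100x:

* **active** organoids — near-circular bodies with a smooth border, a dark
  thick rim (the epithelial wall) and a brighter central lumen;
* **aging** (senescent) organoids — filled, darker bodies with an irregular,
  radially perturbed outline and no lumen.

Scenes are rendered over a noisy, optionally shaded background. Everything is
a pure function of the spec (including its seeds), so a :class:`SceneSpec`
renders bit-identically every time, and every rendered organoid comes with
the tight axis-aligned bounding box of its actual pixel mask.

Intensities are 8-bit grayscale. The paper's pixel calibration (0.833 um per
pixel edge) is carried by the downstream detection containers, not here: the
generator works purely in pixels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image

from .boxes import BoundingBox
from .voc_io import Annotation, write_voc

__all__ = [
    "OrganoidSpec",
    "SceneSpec",
    "PhenotypeRecord",
    "SceneConfig",
    "PhenotypeConfig",
    "PlacementError",
    "sample_scene",
    "render_scene",
    "sample_phenotype_table",
    "save_scene",
    "write_phenotype_csv",
    "read_phenotype_csv",
    "generate_dataset",
]


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an organoid."""


@dataclass(frozen=True)
class OrganoidSpec:
    """One organoid to render: geometry, morphology and appearance.

    ``boundary_roughness`` is the maximum relative radial perturbation of the
    outline (0 for active organoids, up to 0.5 for aging ones), so the tight
    box side never exceeds ``diameter_px * (1 + boundary_roughness)``.
    ``texture_seed`` makes the outline harmonics and interior speckle a pure
    function of the spec.
    """

    center_x: float
    center_y: float
    diameter_px: float
    morphology: Literal["active", "aging"]
    rim_thickness_px: float = 0.0
    boundary_roughness: float = 0.0
    intensity_contrast: float = 1.0
    texture_seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ValueError("diameter_px must be positive")
        if not (0.0 < self.intensity_contrast <= 1.0):
            raise ValueError("intensity_contrast must lie in (0, 1]")
        if self.morphology == "active" and self.boundary_roughness != 0.0:
            raise ValueError("active organoids have boundary_roughness = 0")
        if self.morphology == "aging" and not (0.0 < self.boundary_roughness <= 0.5):
            raise ValueError("aging organoids need boundary_roughness in (0, 0.5]")

    @property
    def max_radius_px(self) -> float:
        return 0.5 * self.diameter_px * (1.0 + self.boundary_roughness)


@dataclass(frozen=True)
class SceneSpec:
    """Complete generative description of one image."""

    width_px: int
    height_px: int
    organoids: tuple[OrganoidSpec, ...]
    background_mean: float = 150.0
    background_noise_sd: float = 8.0
    shading_amplitude: float = 6.0
    max_overlap_iou: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class PhenotypeRecord:
    """One (sample, passage) row of the senescence phenotype table."""

    sample_id: str
    passage: int
    sabgal_positivity: float
    single_cell_diameter_um: float

    def __post_init__(self) -> None:
        if self.passage < 0:
            raise ValueError("passage must be >= 0")
        if not (0.0 <= self.sabgal_positivity <= 1.0):
            raise ValueError("sabgal_positivity must lie in [0, 1]")
        if self.single_cell_diameter_um <= 0:
            raise ValueError("single_cell_diameter_um must be positive")


@dataclass(frozen=True)
class SceneConfig:
    """Sampling distribution for scenes.

    Diameters are log-normal (right-skewed organoid sizes), clipped to
    ``diameter_range_px`` and to what fits the canvas. ``aging_fraction`` is
    the Bernoulli probability that an organoid is senescent.
    """

    width_px: int = 512
    height_px: int = 512
    count_range: tuple[int, int] = (3, 8)
    diameter_log_mean: float = 4.0  # exp(4.0) ~ 55 px median
    diameter_log_sd: float = 0.25
    diameter_range_px: tuple[float, float] = (24.0, 120.0)
    aging_fraction: float = 0.3
    contrast_range: tuple[float, float] = (0.6, 1.0)
    rim_fraction: float = 0.18  # rim thickness as a fraction of diameter
    roughness_range: tuple[float, float] = (0.15, 0.35)
    background_mean: float = 150.0
    background_noise_sd: float = 8.0
    shading_amplitude: float = 6.0
    max_overlap_iou: float = 0.0
    max_retries: int = 1000


@dataclass(frozen=True)
class PhenotypeConfig:
    """Monotone-in-passage senescence trends plus Gaussian noise."""

    passages: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_samples: int = 10
    positivity_baseline: float = 0.10
    positivity_slope: float = 0.12  # per passage
    diameter_baseline_um: float = 12.0
    diameter_slope_um: float = 1.5  # per passage
    noise_sd: float = 0.04  # on positivity; diameter noise scales by 10x um
    min_diameter_um: float = 1.0


def _nominal_box(cx: float, cy: float, r: float) -> tuple[float, float, float, float]:
    return (cx - r, cy - r, cx + r, cy + r)


def _box_iou(a: tuple, b: tuple) -> float:
    ix = min(a[2], b[2]) - max(a[0], b[0])
    iy = min(a[3], b[3]) - max(a[1], b[1])
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    area = lambda t: (t[2] - t[0]) * (t[3] - t[1])
    return inter / (area(a) + area(b) - inter)


def sample_scene(config: SceneConfig, seed: int) -> SceneSpec:
    """Draw one :class:`SceneSpec` from the generator distribution.

    Placement is rejection sampling on the nominal (maximal) bounding boxes:
    a candidate is rejected while its IoU with any placed organoid exceeds
    ``config.max_overlap_iou``; after ``config.max_retries`` failures a
    :class:`PlacementError` names the unplaceable organoid.
    """
    if not (0.0 <= config.aging_fraction <= 1.0):
        raise ValueError("aging_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = config.count_range
    count = int(rng.integers(lo, hi + 1))
    organoids: list[OrganoidSpec] = []
    placed: list[tuple] = []
    for i in range(count):
        aging = bool(rng.random() < config.aging_fraction)
        roughness = float(rng.uniform(*config.roughness_range)) if aging else 0.0
        d_max_canvas = min(config.width_px, config.height_px) / (1.0 + roughness) - 2.0
        d_lo, d_hi = config.diameter_range_px
        d_hi = min(d_hi, d_max_canvas)
        if d_hi < d_lo:
            raise PlacementError(
                f"organoid {i}: diameter range {config.diameter_range_px} does not fit "
                f"a {config.width_px}x{config.height_px} canvas"
            )
        for attempt in range(config.max_retries):
            d = float(np.clip(rng.lognormal(config.diameter_log_mean, config.diameter_log_sd), d_lo, d_hi))
            r = 0.5 * d * (1.0 + roughness)
            cx = float(rng.uniform(r + 1.0, config.width_px - r - 1.0))
            cy = float(rng.uniform(r + 1.0, config.height_px - r - 1.0))
            cand = _nominal_box(cx, cy, r)
            if all(_box_iou(cand, p) <= config.max_overlap_iou for p in placed):
                break
        else:
            raise PlacementError(
                f"organoid {i} of {count}: no placement found in "
                f"{config.max_retries} attempts (max_overlap_iou={config.max_overlap_iou})"
            )
        placed.append(cand)
        organoids.append(
            OrganoidSpec(
                center_x=cx,
                center_y=cy,
                diameter_px=d,
                morphology="aging" if aging else "active",
                rim_thickness_px=0.0 if aging else max(3.0, config.rim_fraction * d),
                boundary_roughness=roughness,
                intensity_contrast=float(rng.uniform(*config.contrast_range)),
                texture_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return SceneSpec(
        width_px=config.width_px,
        height_px=config.height_px,
        organoids=tuple(organoids),
        background_mean=config.background_mean,
        background_noise_sd=config.background_noise_sd,
        shading_amplitude=config.shading_amplitude,
        max_overlap_iou=config.max_overlap_iou,
        seed=seed,
    )


def _outline_radius(spec: OrganoidSpec, theta: np.ndarray) -> np.ndarray:
    """Radius of the (possibly perturbed) outline at polar angles ``theta``.

    Aging outlines superpose 3 random low-order harmonics whose amplitudes
    are normalised so the total perturbation never exceeds
    ``boundary_roughness`` in relative terms.
    """
    r0 = 0.5 * spec.diameter_px
    if spec.morphology == "active" or spec.boundary_roughness == 0.0:
        return np.full_like(theta, r0)
    trng = np.random.default_rng(spec.texture_seed)
    orders = trng.integers(2, 7, size=3)
    amps = trng.uniform(0.3, 1.0, size=3)
    phases = trng.uniform(0.0, 2.0 * np.pi, size=3)
    amps = amps / amps.sum()  # worst-case |sum| == 1

    def radius(t: np.ndarray) -> np.ndarray:
        pert = sum(a * np.cos(k * t + p) for a, k, p in zip(amps, orders, phases))
        return r0 * (1.0 + spec.boundary_roughness * pert)

    # normalise so the outline's mean axis extent equals the nominal
    # diameter: the tight box then measures the organoid without the upward
    # bias a raw perturbation would give
    tt = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    rr = radius(tt)
    xx, yy = rr * np.cos(tt), rr * np.sin(tt)
    scale = 2.0 * spec.diameter_px / ((xx.max() - xx.min()) + (yy.max() - yy.min()))
    return radius(theta) * scale


def _render_organoid(spec: OrganoidSpec, canvas: np.ndarray, bg_mean: float) -> BoundingBox:
    """Paint one organoid onto ``canvas`` in place; return its tight box."""
    h, w = canvas.shape
    rmax = spec.max_radius_px
    x0 = max(int(np.floor(spec.center_x - rmax - 1)), 0)
    x1 = min(int(np.ceil(spec.center_x + rmax + 2)), w)
    y0 = max(int(np.floor(spec.center_y - rmax - 1)), 0)
    y1 = min(int(np.ceil(spec.center_y + rmax + 2)), h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs + 0.5 - spec.center_x
    dy = ys + 0.5 - spec.center_y
    dist = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    r_out = _outline_radius(spec, theta)
    c = spec.intensity_contrast

    if spec.morphology == "active":
        rim_in = np.maximum(r_out - spec.rim_thickness_px, 0.0)
        rim = (dist <= r_out) & (dist > rim_in)
        lumen = dist <= rim_in
        mask = rim | lumen
        patch = canvas[y0:y1, x0:x1]
        patch[rim] = bg_mean - c * 95.0
        patch[lumen] = bg_mean + c * 45.0
    else:
        mask = dist <= r_out
        trng = np.random.default_rng(spec.texture_seed + 1)
        speckle = trng.normal(0.0, 9.0, size=mask.shape)
        patch = canvas[y0:y1, x0:x1]
        patch[mask] = bg_mean - c * 70.0 + speckle[mask]

    if not mask.any():
        raise ValueError("organoid rendered to an empty mask")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    return BoundingBox(
        xmin=float(x0 + cols[0]),
        ymin=float(y0 + rows[0]),
        xmax=float(x0 + cols[-1] + 1),
        ymax=float(y0 + rows[-1] + 1),
        label=spec.morphology,
    )


def render_scene(
    spec: SceneSpec, labels: Literal["morphology", "organoid"] = "morphology"
) -> tuple[np.ndarray, list[BoundingBox]]:
    """Render a :class:`SceneSpec` to an 8-bit grayscale image plus tight boxes.

    ``labels="organoid"`` collapses both morphologies to the single detection
    class used by the one-class vitality model; ``"morphology"`` keeps the
    active/aging two-class scheme.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.full((spec.height_px, spec.width_px), spec.background_mean, dtype=np.float64)
    if spec.shading_amplitude > 0:
        yy = np.linspace(0, np.pi, spec.height_px)[:, None]
        xx = np.linspace(0, np.pi, spec.width_px)[None, :]
        phase_y, phase_x = rng.uniform(0, np.pi, size=2)
        canvas += spec.shading_amplitude * np.cos(yy + phase_y) * np.cos(xx + phase_x)
    canvas += rng.normal(0.0, spec.background_noise_sd, size=canvas.shape)

    boxes: list[BoundingBox] = []
    for org in spec.organoids:
        box = _render_organoid(org, canvas, spec.background_mean)
        if labels == "organoid":
            box = BoundingBox(box.xmin, box.ymin, box.xmax, box.ymax, label="organoid")
        boxes.append(box)
    image = np.clip(canvas, 0, 255).astype(np.uint8)
    return image, boxes


def sample_phenotype_table(config: PhenotypeConfig, seed: int) -> list[PhenotypeRecord]:
    """Generate the per-(sample, passage) senescence phenotype table.

    SA-beta-Gal positivity and single-cell diameter both increase linearly in
    passage number (plus Gaussian noise, clipped to their valid ranges),
    mirroring the gradual senescence phenotype of passaged organoid cultures.
    """
    if config.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[PhenotypeRecord] = []
    for s in range(config.n_samples):
        sid = f"S{s:03d}"
        for p in config.passages:
            pos = config.positivity_baseline + config.positivity_slope * p
            pos += rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            dia = config.diameter_baseline_um + config.diameter_slope_um * p
            dia += rng.normal(0.0, 10.0 * config.noise_sd) if config.noise_sd > 0 else 0.0
            records.append(
                PhenotypeRecord(
                    sample_id=sid,
                    passage=int(p),
                    sabgal_positivity=float(np.clip(pos, 0.0, 1.0)),
                    single_cell_diameter_um=float(max(dia, config.min_diameter_um)),
                )
            )
    return records


def save_scene(
    image: np.ndarray,
    boxes: Sequence[BoundingBox],
    image_path: str | Path,
    xml_path: str | Path | None = None,
) -> None:
    """Write the image (PNG/TIFF by extension) and its VOC XML annotation."""
    image_path = Path(image_path)
    Image.fromarray(image, mode="L").save(image_path)
    if xml_path is None:
        xml_path = image_path.with_suffix(".xml")
    ann = Annotation(str(image_path), image.shape[1], image.shape[0], list(boxes))
    write_voc(ann, xml_path)


PHENOTYPE_HEADER = ["sample_id", "passage", "sabgal_positivity", "single_cell_diameter_um"]


def write_phenotype_csv(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PHENOTYPE_HEADER)
        for r in records:
            writer.writerow([r.sample_id, r.passage, r.sabgal_positivity, r.single_cell_diameter_um])


def read_phenotype_csv(path: str | Path) -> list[PhenotypeRecord]:
    out: list[PhenotypeRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PhenotypeRecord(
                    sample_id=row["sample_id"],
                    passage=int(row["passage"]),
                    sabgal_positivity=float(row["sabgal_positivity"]),
                    single_cell_diameter_um=float(row["single_cell_diameter_um"]),
                )
            )
    return out


def generate_dataset(
    n_images: int,
    config: SceneConfig,
    seed: int,
    out_dir: str | Path,
    labels: Literal["morphology", "organoid"] = "organoid",
) -> list[Path]:
    """Render ``n_images`` scenes to ``out_dir`` (PNG + VOC XML); returns image paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for i in range(n_images):
        spec = sample_scene(config, seed=int(rng.integers(0, 2**31 - 1)))
        image, boxes = render_scene(spec, labels=labels)
        p = out_dir / f"scene_{i:04d}.png"
        save_scene(image, boxes, p)
        paths.append(p)
    return paths
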