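"""Synthetic single-cell 2D scenes with a controllable radial law.

A scene is a circular cell with a concentric circular nucleus.  Objects
(mitochondria) are placed at normalized radii drawn from a radial law
(see :mod:`mitomorph.synth.laws`), rendered either as short thick segments
("tubular", the reticular phenotype) or as round blobs ("round", the
fragmented phenotype), smoothed and corrupted with additive Gaussian noise.

Because the placement law lives on the same normalized axis the radial
analysis reports on (nuclear envelope at 25 %, periphery at 100 %), the
analytic median of the law is the ground-truth mean distribution radius of
the scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw

from ..scene import CellScene2D
from .laws import NUCLEUS_EDGE, PERIPHERY, GaussianLaw, RadialLaw, law_from_dict


@dataclass(frozen=True)
class SceneSpec2D:
    """Parameters of a synthetic 2D cell scene."""

    image_size: int = 512
    nucleus_radius_frac: float = 0.35  # nucleus radius / cell radius
    radial_law: RadialLaw | dict = field(default_factory=lambda: GaussianLaw(65, 10))
    n_objects: int = 300
    morphology_mix: float = 0.7  # fraction of tubular objects
    tube_length_px: float = 14.0
    tube_width_px: float = 2.6
    blob_radius_px: float = 3.0
    noise_sd: float = 2.0
    smoothing_sigma: float = 1.0  # px; anti-aliasing of the rendered mask
    amplitude: float = 100.0
    pixel_size: float = 0.1  # µm
    seed: int = 0

    def law(self) -> RadialLaw:
        if isinstance(self.radial_law, dict):
            return law_from_dict(self.radial_law)
        return self.radial_law

    def validate(self) -> None:
        if not 0 < self.nucleus_radius_frac < 1:
            raise ValueError("nucleus_radius_frac must be in (0, 1): nucleus "
                             "strictly inside the cell boundary")
        if not 0 <= self.morphology_mix <= 1:
            raise ValueError("morphology_mix must be in [0, 1]")
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        self.law()  # raises if support leaves [25, 100]


@dataclass
class GroundTruth2D:
    """What the generator knows: per-object table, label image, analytic MDR."""

    table: pd.DataFrame  # object_id, norm_radius, angle, morphology
    labels: np.ndarray  # label image of the rendered (pre-smoothing) objects
    analytic_mdr: float
    cell_radius_px: float
    nucleus_radius_px: float


def norm_to_pixel_radius(norm_r: np.ndarray, r_nuc: float, r_cell: float) -> np.ndarray:
    """Invert the per-angle normalization for the concentric circular geometry."""
    norm_r = np.asarray(norm_r, dtype=float)
    inside = norm_r <= NUCLEUS_EDGE
    out = np.empty_like(norm_r)
    out[inside] = norm_r[inside] / NUCLEUS_EDGE * r_nuc
    out[~inside] = r_nuc + (norm_r[~inside] - NUCLEUS_EDGE) / (
        PERIPHERY - NUCLEUS_EDGE
    ) * (r_cell - r_nuc)
    return out


def _stamp_tube(canvas, labels, oid, cy, cx, length, width, phi):
    # rotated rectangle via its 4 corners
    ux, uy = np.cos(phi), np.sin(phi)
    px, py = -uy, ux
    hl, hw = length / 2.0, width / 2.0
    rows = cy + np.array([-hl * uy - hw * py, -hl * uy + hw * py,
                          hl * uy + hw * py, hl * uy - hw * py])
    cols = cx + np.array([-hl * ux - hw * px, -hl * ux + hw * px,
                          hl * ux + hw * px, hl * ux - hw * px])
    rr, cc = draw.polygon(rows, cols, shape=canvas.shape)
    canvas[rr, cc] += 1.0  # overlapping objects add signal, as fluorophores do
    labels[rr, cc] = oid


def _stamp_blob(canvas, labels, oid, cy, cx, radius):
    rr, cc = draw.disk((cy, cx), radius, shape=canvas.shape)
    canvas[rr, cc] += 1.0
    labels[rr, cc] = oid


def make_ring_scene(
    edge: str = "nucleus",
    image_size: int = 512,
    nucleus_radius_frac: float = 0.35,
    pixel_size: float = 0.1,
) -> CellScene2D:
    """A convention-check scene: all signal on the 1-pixel ring adjacent to
    the chosen boundary ('nucleus' envelope or 'cell' periphery), no noise.

    The radial normalization must map the nuclear envelope to 25 % and the
    periphery to 100 %, so the density of these scenes is a spike at those
    coordinates (up to half-pixel rasterization).
    """
    size = image_size
    c0 = (size - 1) / 2.0
    r_cell = 0.45 * size
    r_nuc = nucleus_radius_frac * r_cell
    cell_mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((c0, c0), r_cell, shape=cell_mask.shape)
    cell_mask[rr, cc] = True
    nucleus_mask = np.zeros_like(cell_mask)
    rr, cc = draw.disk((c0, c0), r_nuc, shape=cell_mask.shape)
    nucleus_mask[rr, cc] = True
    mask = nucleus_mask if edge == "nucleus" else cell_mask
    if edge not in ("nucleus", "cell"):
        raise ValueError("edge must be 'nucleus' or 'cell'")
    ring = mask & ~ndi.binary_erosion(mask)
    intensity = ring.astype(float) * 100.0
    return CellScene2D(
        intensity=intensity,
        nucleus_mask=nucleus_mask,
        cell_mask=cell_mask,
        pixel_size=pixel_size,
        center=(c0, c0),
    )


def make_cell_scene_2d(spec: SceneSpec2D) -> tuple[CellScene2D, GroundTruth2D]:
    """Render a ground-truthed synthetic cell scene.

    Returns the scene (intensity + nucleus/cell masks) and the ground truth
    (per-object normalized radius and morphology class, the rendered label
    image, and the analytic MDR of the radial law).
    """
    spec.validate()
    law = spec.law()
    rng = np.random.default_rng(spec.seed)

    size = spec.image_size
    c0 = (size - 1) / 2.0
    r_cell = 0.45 * size
    r_nuc = spec.nucleus_radius_frac * r_cell

    cell_mask = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((c0, c0), r_cell, shape=cell_mask.shape)
    cell_mask[rr, cc] = True
    nucleus_mask = np.zeros_like(cell_mask)
    rr, cc = draw.disk((c0, c0), r_nuc, shape=cell_mask.shape)
    nucleus_mask[rr, cc] = True

    n = spec.n_objects
    norm_r = law.sample(n, rng)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    tubular = rng.random(n) < spec.morphology_mix
    pix_r = norm_to_pixel_radius(norm_r, r_nuc, r_cell)
    cy = c0 + pix_r * np.sin(theta)
    cx = c0 + pix_r * np.cos(theta)
    phi = rng.uniform(0, np.pi, size=n)

    canvas = np.zeros((size, size), dtype=float)
    labels = np.zeros((size, size), dtype=np.int32)
    for i in range(n):
        oid = i + 1
        if tubular[i]:
            _stamp_tube(canvas, labels, oid, cy[i], cx[i],
                        spec.tube_length_px, spec.tube_width_px, phi[i])
        else:
            _stamp_blob(canvas, labels, oid, cy[i], cx[i], spec.blob_radius_px)

    intensity = ndi.gaussian_filter(canvas * spec.amplitude, spec.smoothing_sigma)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0, spec.noise_sd, size=intensity.shape)
    intensity = np.clip(intensity, 0, None)
    intensity[~cell_mask] = 0.0

    table = pd.DataFrame(
        {
            "object_id": np.arange(1, n + 1),
            "norm_radius": norm_r,
            "angle": theta,
            "morphology": np.where(tubular, "tubular", "round"),
        }
    )
    truth = GroundTruth2D(
        table=table,
        labels=labels,
        analytic_mdr=law.median(),
        cell_radius_px=r_cell,
        nucleus_radius_px=r_nuc,
    )
    scene = CellScene2D(
        intensity=intensity,
        nucleus_mask=nucleus_mask,
        cell_mask=cell_mask,
        pixel_size=spec.pixel_size,
        center=(c0, c0),
    )
    return scene, truth
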