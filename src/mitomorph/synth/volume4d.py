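"""Synthetic 4D (t, z, y, x) mitochondrial scenes.

Objects are axis-aligned ellipsoids with log-normally distributed volumes,
moving by constant drift plus isotropic diffusion (Euler steps at the frame
interval, reflecting at the volume margins so no object ever leaves the
field).  Photoconversion relabels the content of every object inside the
conversion region at t = 0; scripted fusion events merge two live objects
into one whose continuous volume is exactly the sum of its parents and whose
channel content mixes in proportion to parent volumes.

Ground truth is recorded at two levels: a per-frame table (voxel counts and
centroids measured on the rendered noise-free mask, plus the continuous model
volume) and the full label volume, so every downstream measurement can be
checked against what was actually drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ..scene import VolumeSeries


@dataclass(frozen=True)
class MotionLaw:
    speed_um_s: float = 0.0  # magnitude of the per-object constant drift
    diffusion_um2_s: float = 0.0  # isotropic diffusion coefficient


@dataclass(frozen=True)
class SceneSpec3D:
    shape: tuple[int, int, int, int] = (10, 32, 96, 96)  # (t, z, y, x)
    voxel_size: tuple[float, float, float] = (0.2, 0.2, 0.2)  # µm (z, y, x)
    frame_interval_s: float = 1.0
    n_objects: int = 10
    volume_mean_um3: float = 3.8  # lognormal mean of true object volume
    volume_sd_um3: float = 1.5
    aspect_max: float = 2.5  # max long/short axis ratio of the ellipsoids
    motion: MotionLaw = field(default_factory=MotionLaw)
    fusion_script: tuple[tuple[int, int, int], ...] = ()  # (t, id_a, id_b)
    convert: str | None = None  # None, "half_x", or "ids:<i,j,...>"
    min_separation_factor: float = 1.3  # × sum of bounding radii at placement
    noise_sd: float = 2.0
    smoothing_sigma: float = 1.0  # voxels
    amplitude: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 4 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be a positive (t, z, y, x) tuple")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if self.volume_mean_um3 <= 0 or self.volume_sd_um3 < 0:
            raise ValueError("volume law parameters must be positive")
        # replay the fusion script against the id set
        alive = set(range(1, self.n_objects + 1))
        n_frames = self.shape[0]
        for t, a, b in sorted(self.fusion_script):
            if not 0 <= t < n_frames:
                raise ValueError(f"fusion time {t} outside the series")
            if a == b:
                raise ValueError("fusion requires two distinct objects")
            for oid in (a, b):
                if oid not in alive:
                    raise ValueError(
                        f"fusion at t={t} references object {oid}, which is "
                        "dead or absent at that time"
                    )
            alive.discard(b)


@dataclass
class GroundTruth3D:
    table: pd.DataFrame  # per frame × object truth
    labels: np.ndarray  # (t, z, y, x) int32 label volumes


@dataclass
class _Obj:
    oid: int
    volume_um3: float  # continuous model volume
    axes_vox: np.ndarray  # semi-axes (z, y, x), voxels
    pos: np.ndarray  # centroid, voxel coordinates (z, y, x)
    vel: np.ndarray  # voxels / frame
    conv: float = 0.0  # converted content fraction
    alive: bool = True


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return np.log(mean), 0.0
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _axes_from_volume(vol_um3, aspect, voxel_size, long_axis):
    vox_vol = np.prod(voxel_size)
    v_vox = vol_um3 / vox_vol
    c = (3.0 * v_vox / (4.0 * np.pi * aspect)) ** (1.0 / 3.0)
    axes = np.full(3, c)
    axes[long_axis] = aspect * c
    return axes


def _paint(volume, labels, obj: _Obj, amplitude, weight):
    z0, y0, x0 = obj.pos
    az, ay, ax = obj.axes_vox
    zlo, zhi = int(np.floor(z0 - az)), int(np.ceil(z0 + az)) + 1
    ylo, yhi = int(np.floor(y0 - ay)), int(np.ceil(y0 + ay)) + 1
    xlo, xhi = int(np.floor(x0 - ax)), int(np.ceil(x0 + ax)) + 1
    zlo, ylo, xlo = max(zlo, 0), max(ylo, 0), max(xlo, 0)
    zhi = min(zhi, volume.shape[0])
    yhi = min(yhi, volume.shape[1])
    xhi = min(xhi, volume.shape[2])
    zz, yy, xx = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
    inside = (
        ((zz - z0) / az) ** 2 + ((yy - y0) / ay) ** 2 + ((xx - x0) / ax) ** 2
    ) <= 1.0
    volume[zlo:zhi, ylo:yhi, xlo:xhi][inside] = amplitude * weight
    labels[zlo:zhi, ylo:yhi, xlo:xhi][inside] = obj.oid


def _push_apart(obj: _Obj, others: list[_Obj], dims: np.ndarray) -> None:
    """Move ``obj`` until it no longer overlaps any live object.

    A fusion product is placed at the volume-weighted centroid of its
    parents, which can land on a bystander; objects are impenetrable, so the
    product is nudged away until the scene stays spatially resolved.
    """
    for _ in range(50):
        hit = None
        for other in others:
            if other is obj or not other.alive:
                continue
            need = obj.axes_vox.max() + other.axes_vox.max() + 2.0
            d = float(np.linalg.norm(obj.pos - other.pos))
            if d < need:
                hit = (other, d, need)
                break
        if hit is None:
            return
        other, d, need = hit
        direction = obj.pos - other.pos
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        lo = obj.axes_vox + 3.0
        obj.pos = np.clip(obj.pos + direction * (need - d + 0.5), lo, dims - lo)


def _reflect(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    # reflect into [lo, hi] per axis (assumes overshoot < one interval width)
    pos = np.where(pos < lo, 2 * lo - pos, pos)
    pos = np.where(pos > hi, 2 * hi - pos, pos)
    return np.clip(pos, lo, hi)


def make_volume_series(spec: SceneSpec3D) -> tuple[VolumeSeries, GroundTruth3D]:
    """Simulate and render a ground-truthed volumetric time series.

    Returns a one-channel ("mito") series, or a two-channel ("green" =
    non-converted, "red" = converted) series when ``spec.convert`` is set,
    together with the per-frame truth table and label volumes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_t, n_z, n_y, n_x = spec.shape
    dims = np.array([n_z, n_y, n_x], dtype=float)
    voxel_size = np.asarray(spec.voxel_size, dtype=float)
    vox_vol = float(np.prod(voxel_size))
    dt = spec.frame_interval_s

    mu, sig = _lognormal_params(spec.volume_mean_um3, spec.volume_sd_um3)
    objs: list[_Obj] = []
    for oid in range(1, spec.n_objects + 1):
        vol = float(np.exp(rng.normal(mu, sig)))
        aspect = rng.uniform(1.2, spec.aspect_max)
        long_axis = rng.integers(1, 3)  # elongate in y or x (imaging plane)
        axes = _axes_from_volume(vol, aspect, voxel_size, long_axis)
        margin = axes + 3.0
        if np.any(dims - 2 * margin <= 0):
            raise ValueError("objects too large for the volume shape")
        # rejection-sample a position keeping objects separated at t0
        for _ in range(2000):
            pos = rng.uniform(margin, dims - margin)
            ok = True
            for other in objs:
                d = np.linalg.norm((pos - other.pos) * 1.0)
                need = spec.min_separation_factor * (
                    axes.max() + other.axes_vox.max()
                )
                if d < need:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError("could not place objects with the requested "
                               "separation; reduce n_objects or sizes")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        vel = direction * spec.motion.speed_um_s * dt / voxel_size
        objs.append(_Obj(oid, vol, axes, pos, vel))

    by_id = {o.oid: o for o in objs}
    script = sorted(spec.fusion_script)

    diff_step_vox = (
        np.sqrt(2.0 * spec.motion.diffusion_um2_s * dt) / voxel_size
        if spec.motion.diffusion_um2_s > 0
        else np.zeros(3)
    )

    two_channel = spec.convert is not None
    names = ("green", "red") if two_channel else ("mito",)
    data = {n: np.zeros(spec.shape, dtype=float) for n in names}
    labels_4d = np.zeros(spec.shape, dtype=np.int32)
    rows = []

    for t in range(n_t):
        if t > 0:
            for o in objs:
                if not o.alive:
                    continue
                step = o.vel + rng.normal(size=3) * diff_step_vox
                lo = o.axes_vox + 3.0
                o.pos = _reflect(o.pos + step, lo, dims - lo)
        # apply scripted fusions scheduled for this frame (before rendering)
        for ft, a, b in [e for e in script if e[0] == t]:
            oa, ob = by_id[a], by_id[b]
            vtot = oa.volume_um3 + ob.volume_um3
            oa.conv = (oa.conv * oa.volume_um3 + ob.conv * ob.volume_um3) / vtot
            oa.pos = (oa.pos * oa.volume_um3 + ob.pos * ob.volume_um3) / vtot
            oa.vel = (oa.vel * oa.volume_um3 + ob.vel * ob.volume_um3) / vtot
            aspect = oa.axes_vox.max() / oa.axes_vox.min()
            long_axis = int(np.argmax(oa.axes_vox))
            oa.volume_um3 = vtot
            oa.axes_vox = _axes_from_volume(vtot, aspect, voxel_size, long_axis)
            lo = oa.axes_vox + 3.0
            oa.pos = _reflect(oa.pos, lo, dims - lo)
            ob.alive = False
            _push_apart(oa, objs, dims)

        clean = {n: np.zeros((n_z, n_y, n_x)) for n in names}
        lab = labels_4d[t]
        for o in objs:
            if not o.alive:
                continue
            if two_channel:
                scratch = np.zeros((n_z, n_y, n_x))
                _paint(scratch, lab, o, spec.amplitude, 1.0)
                clean["green"] += scratch * (1.0 - o.conv)
                clean["red"] += scratch * o.conv
            else:
                _paint(clean["mito"], lab, o, spec.amplitude, 1.0)

        if t == 0 and two_channel:
            _apply_conversion(spec, objs, lab)
            # re-split the channels with the post-conversion fractions
            clean = {n: np.zeros((n_z, n_y, n_x)) for n in names}
            for o in objs:
                if not o.alive:
                    continue
                scratch = np.zeros((n_z, n_y, n_x))
                _paint(scratch, lab, o, spec.amplitude, 1.0)
                clean["green"] += scratch * (1.0 - o.conv)
                clean["red"] += scratch * o.conv

        for o in objs:
            if not o.alive:
                continue
            sel = lab == o.oid
            count = int(sel.sum())
            com = ndi.center_of_mass(sel) if count else (np.nan,) * 3
            rows.append(
                {
                    "frame": t,
                    "time_s": t * dt,
                    "object_id": o.oid,
                    "voxel_count": count,
                    "volume_um3": count * vox_vol,
                    "true_volume_um3": o.volume_um3,
                    "centroid_z_um": com[0] * voxel_size[0],
                    "centroid_y_um": com[1] * voxel_size[1],
                    "centroid_x_um": com[2] * voxel_size[2],
                    "converted_fraction": o.conv,
                }
            )

        for n in names:
            arr = ndi.gaussian_filter(clean[n], spec.smoothing_sigma)
            if spec.noise_sd > 0:
                arr = arr + rng.normal(0, spec.noise_sd, size=arr.shape)
            data[n][t] = np.clip(arr, 0, None)

    series = VolumeSeries(
        channels=data,
        voxel_size=tuple(voxel_size),
        frame_interval=dt,
    )
    truth = GroundTruth3D(table=pd.DataFrame(rows), labels=labels_4d)
    return series, truth


def _apply_conversion(spec: SceneSpec3D, objs: list[_Obj], lab: np.ndarray) -> None:
    """Instantaneous photoconversion at t = 0.

    ``convert="half_x"`` converts the voxel content inside the x > centre
    half-volume (objects straddling the boundary get a fractional label);
    ``convert="ids:1,3"`` converts the listed objects wholly.
    """
    mode = spec.convert
    if mode is None:
        return
    if mode.startswith("ids:"):
        ids = {int(s) for s in mode[4:].split(",") if s}
        for o in objs:
            if o.oid in ids:
                o.conv = 1.0
        return
    if mode == "half_x":
        half = lab.shape[2] // 2
        for o in objs:
            sel = lab == o.oid
            total = sel.sum()
            if total:
                o.conv = float(sel[:, :, half:].sum() / total)
        return
    raise ValueError(f"unknown conversion mode {mode!r}")


def random_fusion_script(
    n_objects: int,
    converted_ids: set[int],
    p_fuse_per_frame: float,
    n_frames: int,
    rng: np.random.Generator,
) -> tuple[tuple[int, int, int], ...]:
    """Draw a stochastic fusion script between differently-labelled partners.

    Each frame, every still-unfused converted object fuses with probability
    ``p_fuse_per_frame`` with a random live non-converted partner.  Each
    event therefore creates one double-coloured object, and the expected
    growth of the double-coloured count scales with the number of converted
    objects — the scaling the doubling comparison relies on.
    """
    converted = sorted(converted_ids)
    nonconverted = [i for i in range(1, n_objects + 1) if i not in converted_ids]
    events = []
    used_conv: set[int] = set()
    used_non: set[int] = set()
    for t in range(1, n_frames):
        for a in converted:
            if a in used_conv:
                continue
            pool = [b for b in nonconverted if b not in used_non]
            if not pool:
                break
            if rng.random() < p_fuse_per_frame:
                b = pool[int(rng.integers(len(pool)))]
                events.append((t, a, b))
                used_conv.add(a)
                used_non.add(b)
    return tuple(events)
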