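"""Frame-to-frame linking, track speed statistics and fusion counting.

Linking is globally greedy gated nearest-neighbour assignment: candidate
(track, object) pairs are sorted by centroid distance and accepted in
ascending order, skipping pairs beyond ``max_disp`` per frame step; optional
gap closing lets a track skip up to ``max_gap`` frames (the gate scales with
the number of skipped steps).  On unambiguous scenes this equals the
exhaustive minimum-total-distance assignment, which the tests verify.

Fusion is read out from photoconversion: objects are segmented on the
converted channel, their summed intensity measured in both channels, and an
object is "double-coloured" when each channel carries at least a configured
fraction of its total two-channel intensity — evidence that converted and
non-converted content mixed, i.e. that a fusion happened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Track:
    track_id: int
    frames: list[int] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)  # µm (z, y, x)
    object_ids: list[int] = field(default_factory=list)

    def speeds(self) -> np.ndarray:
        """Instantaneous speeds |Δcentroid| / Δt over consecutive steps, µm/s."""
        if len(self.positions) < 2:
            return np.array([])
        pos = np.asarray(self.positions)
        dt = np.diff(np.asarray(self.times))
        return np.linalg.norm(np.diff(pos, axis=0), axis=1) / dt

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    tracks: list[Track]
    frame_interval: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            sp = tr.speeds()
            for i, (f, t, p) in enumerate(zip(tr.frames, tr.times, tr.positions)):
                rows.append(
                    {
                        "track_id": tr.track_id,
                        "frame": f,
                        "time_s": t,
                        "z_um": p[0],
                        "y_um": p[1],
                        "x_um": p[2],
                        "speed_um_s": sp[i - 1] if i > 0 else np.nan,
                    }
                )
        return pd.DataFrame(rows)


_POS_COLS = ["centroid_z_um", "centroid_y_um", "centroid_x_um"]


def link_tracks(
    tables: list[pd.DataFrame],
    frame_interval: float,
    max_disp: float,  # µm per frame step
    max_gap: int = 0,
    timestamps: list[float] | None = None,
) -> TrackSet:
    """Link per-frame object tables into trajectories (greedy gated matching)."""
    if timestamps is None:
        timestamps = [i * frame_interval for i in range(len(tables))]
    if any(t1 <= t0 for t0, t1 in zip(timestamps, timestamps[1:])):
        raise ValueError("timestamps must be strictly increasing")

    tracks: list[Track] = []
    active: list[Track] = []  # tracks that may still be extended
    next_id = 1
    for fi, table in enumerate(tables):
        pts = (
            table[_POS_COLS].to_numpy(dtype=float)
            if len(table)
            else np.empty((0, 3))
        )
        oids = table["object_id"].to_numpy() if len(table) else np.array([], int)
        # candidate pairs within the (gap-scaled) displacement gate
        cands = []
        for ti, tr in enumerate(active):
            gap_steps = fi - tr.frames[-1]
            if gap_steps > max_gap + 1:
                continue
            gate = max_disp * gap_steps
            d = np.linalg.norm(pts - tr.positions[-1], axis=1)
            for oi in np.nonzero(d <= gate)[0]:
                cands.append((d[oi], ti, int(oi)))
        cands.sort(key=lambda c: c[0])
        used_t: set[int] = set()
        used_o: set[int] = set()
        for d, ti, oi in cands:
            if ti in used_t or oi in used_o:
                continue
            used_t.add(ti)
            used_o.add(oi)
            tr = active[ti]
            tr.frames.append(fi)
            tr.times.append(timestamps[fi])
            tr.positions.append(pts[oi])
            tr.object_ids.append(int(oids[oi]))
        for oi in range(len(pts)):
            if oi not in used_o:
                tr = Track(track_id=next_id)
                next_id += 1
                tr.frames.append(fi)
                tr.times.append(timestamps[fi])
                tr.positions.append(pts[oi])
                tr.object_ids.append(int(oids[oi]))
                tracks.append(tr)
                active.append(tr)
        active = [tr for tr in active if fi - tr.frames[-1] <= max_gap]
    return TrackSet(tracks=tracks, frame_interval=frame_interval)


def speed_statistics(tracks: TrackSet, min_track_len: int = 3) -> dict:
    """Per-cell speed summary from per-track maxima.

    Tracks shorter than ``min_track_len`` frames are excluded and counted in
    the QC fields.  The headline number is the mean over tracks of each
    track's maximum instantaneous speed (µm/s).
    """
    qualifying = [t for t in tracks.tracks if t.n_frames >= min_track_len]
    if not qualifying:
        raise ValueError("no tracks of the required length")
    maxima = np.array([t.speeds().max() for t in qualifying])
    means = np.array([t.speeds().mean() for t in qualifying])
    return {
        "n_tracks": len(qualifying),
        "n_excluded_short": len(tracks.tracks) - len(qualifying),
        "max_speeds_um_s": maxima,
        "mean_speeds_um_s": means,
        "mean_of_max_um_s": float(maxima.mean()),
        "mean_of_mean_um_s": float(means.mean()),
    }


def count_double_colored(
    table: pd.DataFrame,
    converted_channel: str = "red",
    other_channel: str = "green",
    frac_threshold: float = 0.1,
) -> dict:
    """Count objects carrying substantial signal in both channels.

    ``table`` is an ObjectTable segmented on the converted channel with
    ``intensity_<channel>`` columns for both channels.  An object is
    double-coloured when each channel's summed intensity is at least
    ``frac_threshold`` of its total two-channel intensity.
    """
    for ch in (converted_channel, other_channel):
        col = f"intensity_{ch}"
        if col not in table.columns:
            raise ValueError(f"missing channel intensity column {col!r}")
    a = table[f"intensity_{converted_channel}"].to_numpy(dtype=float)
    b = table[f"intensity_{other_channel}"].to_numpy(dtype=float)
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(total > 0, a / total, 0.0)
        fb = np.where(total > 0, b / total, 0.0)
    double = (fa >= frac_threshold) & (fb >= frac_threshold)
    return {
        "n_objects": int(len(table)),
        "n_double_colored": int(double.sum()),
        "double_ids": table["object_id"].to_numpy()[double].tolist(),
        "frac_threshold": frac_threshold,
    }


def fusion_series(
    tables: list[pd.DataFrame],
    timestamps: np.ndarray,
    frac_threshold: float = 0.1,
    converted_channel: str = "red",
    other_channel: str = "green",
) -> pd.DataFrame:
    """Per-frame double-coloured counts as a FusionSeries table."""
    rows = []
    for t, table in zip(timestamps, tables):
        res = count_double_colored(
            table,
            converted_channel=converted_channel,
            other_channel=other_channel,
            frac_threshold=frac_threshold,
        )
        rows.append(
            {
                "time_s": float(t),
                "n_double_colored": res["n_double_colored"],
                "n_objects": res["n_objects"],
                "frac_threshold": frac_threshold,
            }
        )
    return pd.DataFrame(rows)


def photoconversion_fusion_analysis(
    series,
    frac_threshold: float = 0.1,
    converted_channel: str = "red",
    other_channel: str = "green",
    **segmentation_kwargs,
) -> pd.DataFrame:
    """Segment the converted channel per frame and count double-coloured objects.

    The converted channel is thresholded with a single (two-class) Otsu so
    that half-brightness mixed objects — the signature of fusion — are kept;
    erosion, speckle removal and per-channel intensity measurement follow
    the standard chain.  Returns the FusionSeries table.
    """
    from .segment3d import run_segmentation

    segmentation_kwargs.setdefault("threshold_method", "otsu")
    tables = []
    for t in range(series.n_frames):
        frame = series.frame(t, channel=converted_channel)
        _, table = run_segmentation(frame, **segmentation_kwargs)
        tables.append(table)
    return fusion_series(
        tables,
        series.timestamps(),
        frac_threshold=frac_threshold,
        converted_channel=converted_channel,
        other_channel=other_channel,
    )


def fusion_growth(series: pd.DataFrame) -> dict:
    """Least-squares growth rate of the double-coloured count.

    Returns the absolute slope (count/s) and the slope normalized by the
    mean total object count (count/s per object) — the quantity that should
    be invariant when a condition simply has more mitochondria but the same
    per-pair fusion propensity.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 frames to fit a growth rate")
    t = series["time_s"].to_numpy(dtype=float)
    y = series["n_double_colored"].to_numpy(dtype=float)
    slope = float(np.polyfit(t, y, 1)[0])
    mean_n = float(series["n_objects"].mean())
    return {
        "slope_per_s": slope,
        "normalized_slope_per_s_per_object": slope / mean_n if mean_n else np.nan,
        "mean_object_count": mean_n,
    }
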