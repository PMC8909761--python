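"""Benchmark computations that exercise the full pipeline on ground-truthed
synthetic scenes.

Each function defines one self-contained check — scene family, problem size
and measured quantity — so the validation suite and any report script run
the identical computation.  Problem sizes are chosen so every check runs in
seconds to a few minutes on one CPU while keeping estimator noise well
inside the bands being checked (the sampling error of an empirical median,
for instance, scales as n^(-1/2), which sets the object counts used here).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import dynamics, radial, segment3d
from .morphometry import stereology_mean_estimate
from .stats import compare_two_groups, kruskal_wallis
from .synth import (
    DeltaLaw,
    EMSceneSpec,
    GaussianLaw,
    MotionLaw,
    SceneSpec2D,
    SceneSpec3D,
    UniformLaw,
    make_cell_scene_2d,
    make_em_image,
    make_ring_scene,
    make_volume_series,
    random_fusion_script,
)

VOXEL_LLSM = (0.15, 0.15, 0.15)  # µm; LLSM-like near-isotropic sampling


def mdr_law_agreement(seed: int = 1, n_objects: int = 5000) -> dict[str, dict]:
    """Pipeline MDR vs the analytic median for delta/uniform/gaussian laws."""
    laws = {
        "delta": DeltaLaw(60),
        "uniform": UniformLaw(25, 100),
        "gaussian": GaussianLaw(70, 5),
    }
    out = {}
    for name, law in laws.items():
        spec = SceneSpec2D(radial_law=law, n_objects=n_objects, seed=seed)
        scene, truth = make_cell_scene_2d(spec)
        measured = radial.mdr_for_scene(scene).mdr
        out[name] = {
            "measured": measured,
            "analytic": truth.analytic_mdr,
            "error": measured - truth.analytic_mdr,
        }
    return out


def boundary_conventions() -> dict[str, float]:
    """Normalized position of the nuclear-envelope and periphery spikes."""
    out = {}
    for edge, key in (("nucleus", "nucleus_edge"), ("cell", "periphery")):
        scene = make_ring_scene(edge)
        density = radial.normalize_radius(
            radial.to_polar(scene, n_radii=1024), n_bins=200
        )
        out[key] = radial.spike_position(density)
    return out


def speckle_survivor_boundary() -> int:
    """Smallest component size surviving the speckle filter at defaults."""
    lab = np.zeros((12, 12, 64), int)
    for i, size in enumerate(range(5, 16)):  # components of 5..15 voxels
        lab[i, i, :size] = i + 1
    kept = segment3d.remove_speckles(lab)
    sizes = np.bincount(kept.ravel())[1:]
    return int(sizes.min())


def _count_scene(seed: int, n_objects: int = 50) -> SceneSpec3D:
    return SceneSpec3D(
        shape=(1, 48, 224, 224),
        voxel_size=VOXEL_LLSM,
        n_objects=n_objects,
        volume_mean_um3=3.8,
        volume_sd_um3=1.5,
        seed=seed,
    )


def count_recovery(seed: int = 1, n_scenes: int = 50) -> dict:
    """Fraction of seeded 50-object scenes with exact count recovery."""
    exact = 0
    counts = []
    for i in range(n_scenes):
        spec = _count_scene(seed * 1000 + i)
        series, _ = make_volume_series(spec)
        _, table = segment3d.run_segmentation(series.frame(0), measure_channels=False)
        counts.append(len(table))
        exact += len(table) == spec.n_objects
    return {"fraction_exact": exact / n_scenes, "counts": counts}


def volume_ratio_two_populations(seed: int = 1, n_scenes: int = 3) -> dict:
    """Measured mean-volume ratio for populations with true ratio 2.0.

    Mean volumes follow the control/knockdown contrast (3.8 vs 1.9 µm³);
    the shell-loss correction is calibrated at run time on separate
    reference scenes before measuring.
    """
    delta = 0.5 * (
        segment3d.calibrate_shell_correction(VOXEL_LLSM, 1.9, seed=seed * 7 + 1)
        + segment3d.calibrate_shell_correction(VOXEL_LLSM, 3.8, seed=seed * 7 + 2)
    )
    means = {1.9: [], 3.8: []}
    for i in range(n_scenes):
        for mean in (1.9, 3.8):
            spec = SceneSpec3D(
                shape=(1, 48, 224, 224),
                voxel_size=VOXEL_LLSM,
                n_objects=50,
                volume_mean_um3=mean,
                volume_sd_um3=0.3 * mean,
                seed=seed * 100 + i,
            )
            series, _ = make_volume_series(spec)
            _, table = segment3d.run_segmentation(
                series.frame(0), measure_channels=False, shell_correction_um=delta
            )
            means[mean].append(table["volume_corrected_um3"].mean())
    ratio = float(np.mean(means[3.8]) / np.mean(means[1.9]))
    return {
        "ratio": ratio,
        "shell_correction_um": delta,
        "mean_small_um3": float(np.mean(means[1.9])),
        "mean_large_um3": float(np.mean(means[3.8])),
    }


def stereology_bias(seed: int = 1, fractions=(5.0, 15.0, 30.0),
                    n_offsets: int = 100) -> dict:
    """Mean point-count estimate vs pixel-count truth at several densities."""
    out = {}
    for frac in fractions:
        _, mask, _ = make_em_image(EMSceneSpec(target_area_fraction=frac, seed=seed))
        truth = 100.0 * mask.mean()
        mean_est, _ = stereology_mean_estimate(
            mask, np.ones_like(mask), n_offsets=n_offsets, seed=seed
        )
        out[frac] = {"estimate": mean_est, "pixel_truth": truth,
                     "bias_pp": mean_est - truth}
    return out


def drift_speed_recovery(seed: int = 1, speed: float = 0.5) -> dict:
    """Relative error of the recovered drift speed on a pure-drift scene."""
    spec = SceneSpec3D(
        shape=(8, 40, 160, 160),
        voxel_size=VOXEL_LLSM,
        n_objects=8,
        volume_sd_um3=0.8,
        motion=MotionLaw(speed_um_s=speed),
        seed=seed,
    )
    series, _ = make_volume_series(spec)
    tables = [
        segment3d.run_segmentation(series.frame(t), measure_channels=False)[1]
        for t in range(series.n_frames)
    ]
    tracks = dynamics.link_tracks(tables, series.frame_interval, max_disp=2.5 * speed)
    stats = dynamics.speed_statistics(tracks)
    recovered = stats["mean_of_mean_um_s"]
    return {
        "true_speed": speed,
        "recovered": recovered,
        "relative_error": abs(recovered - speed) / speed,
        "n_tracks": stats["n_tracks"],
    }


def linking_matches_exhaustive(seed: int = 1, n_instances: int = 30) -> dict:
    """Greedy gated linking vs brute-force min-total-distance assignment on
    small (≤ 6 object) two-frame instances with unambiguous displacements."""
    import itertools

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, 7))
        a = rng.uniform(0, 30, size=(n, 3))
        b = a + rng.normal(0, 0.2, size=a.shape)
        best_cost, best = np.inf, None
        for perm in itertools.permutations(range(n)):
            d = [np.linalg.norm(a[i] - b[j]) for i, j in enumerate(perm)]
            if max(d) > 1.5:
                continue
            if sum(d) < best_cost:
                best_cost, best = sum(d), dict(enumerate(perm))
        tables = [
            pd.DataFrame(
                {
                    "object_id": np.arange(1, n + 1),
                    "centroid_z_um": p[:, 0],
                    "centroid_y_um": p[:, 1],
                    "centroid_x_um": p[:, 2],
                }
            )
            for p in (a, b)
        ]
        ts = dynamics.link_tracks(tables, 1.0, max_disp=1.5)
        got = {
            tr.object_ids[0] - 1: tr.object_ids[1] - 1
            for tr in ts.tracks
            if tr.n_frames == 2
        }
        agree += got == best
    return {"fraction_agree": agree / n_instances, "n_instances": n_instances}


def scripted_fusion_counts(seed: int = 1, ks=(0, 1, 3, 5)) -> dict:
    """Final double-coloured count for scripted k-fusion scenes."""
    out = {}
    for k in ks:
        n = 16
        conv = list(range(1, 9))
        script = tuple((2 + i, conv[i], 8 + 1 + i) for i in range(k))
        spec = SceneSpec3D(
            shape=(10, 32, 160, 160),
            voxel_size=VOXEL_LLSM,
            n_objects=n,
            convert="ids:" + ",".join(map(str, conv)),
            fusion_script=script,
            volume_mean_um3=2.5,
            volume_sd_um3=0.6,
            seed=seed * 10 + k,
        )
        series, _ = make_volume_series(spec)
        fs = dynamics.photoconversion_fusion_analysis(series)
        out[k] = int(fs["n_double_colored"].iloc[-1])
    return out


def fusion_doubling(seed: int = 1, n_seeds: int = 20,
                    p_fuse: float = 0.08) -> dict:
    """Growth-rate scaling with object count at equal per-object propensity.

    With twice the mitochondria (and twice the converted subset) the absolute
    double-coloured growth rate should double while the count-normalized
    rate stays put.  Returns ratios with Monte-Carlo standard errors.
    """
    rates = {10: [], 20: []}
    norms = {10: [], 20: []}
    for i in range(n_seeds):
        for n in (10, 20):
            rng = np.random.default_rng(seed * 10000 + i)
            conv = set(range(1, n // 2 + 1))
            script = random_fusion_script(n, conv, p_fuse, 10, rng)
            spec = SceneSpec3D(
                shape=(10, 32, 150, 150),
                voxel_size=VOXEL_LLSM,
                n_objects=n,
                convert="ids:" + ",".join(map(str, sorted(conv))),
                fusion_script=script,
                volume_mean_um3=2.5,
                volume_sd_um3=0.8,
                seed=seed * 1000 + i,
            )
            series, _ = make_volume_series(spec)
            fs = dynamics.photoconversion_fusion_analysis(series)
            growth = dynamics.fusion_growth(fs)
            rates[n].append(growth["slope_per_s"])
            norms[n].append(growth["normalized_slope_per_s_per_object"])

    def ratio_with_se(num, den):
        num, den = np.asarray(num), np.asarray(den)
        r = num.mean() / den.mean()
        # delta-method SE of a ratio of independent means
        se = r * np.sqrt(
            num.var(ddof=1) / (len(num) * num.mean() ** 2)
            + den.var(ddof=1) / (len(den) * den.mean() ** 2)
        )
        return float(r), float(se)

    abs_ratio, abs_se = ratio_with_se(rates[20], rates[10])
    norm_ratio, norm_se = ratio_with_se(norms[20], norms[10])
    return {
        "absolute_ratio": abs_ratio,
        "absolute_se": abs_se,
        "normalized_ratio": norm_ratio,
        "normalized_se": norm_se,
    }


def mann_whitney_enumeration_check(seed: int = 1) -> bool:
    """Exact MW p equals full enumeration for tie-free samples up to n = 6."""
    import itertools

    rng = np.random.default_rng(seed)
    for na in (2, 3, 4, 5, 6):
        for nb in (2, 4, 6):
            pool = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = pool[:na], pool[na:]
            entry = compare_two_groups(a, b)
            ranks = sps.rankdata(np.concatenate([a, b]))
            u_obs = ranks[:na].sum() - na * (na + 1) / 2
            mu = na * nb / 2
            us = [
                sum(c) - na * (na + 1) / 2
                for c in itertools.combinations(range(1, na + nb + 1), na)
            ]
            p_enum = np.mean(np.abs(np.asarray(us) - mu) >= abs(u_obs - mu) - 1e-12)
            if abs(entry.p_value - p_enum) > 1e-12:
                return False
    return True


def null_type_i_error(seed: int = 1, n_reps: int = 1000, alpha: float = 0.05) -> dict:
    """Empirical rejection rates of MW and KW under the null."""
    rng = np.random.default_rng(seed)
    rej_mw = 0
    rej_kw = 0
    for _ in range(n_reps):
        a, b = rng.normal(size=30), rng.normal(size=30)
        if compare_two_groups(a, b).p_value < alpha:
            rej_mw += 1
        g = [rng.normal(size=30) for _ in range(3)]
        if kruskal_wallis(g)[1] < alpha:
            rej_kw += 1
    return {"mannwhitney": rej_mw / n_reps, "kruskal_wallis": rej_kw / n_reps}
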