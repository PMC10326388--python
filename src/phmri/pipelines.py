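"""End-to-end study pipelines.

These tie the stages together the way the two analyses are actually run:

* drug challenge: simulate (or load) one scan per subject, map per-subject
  activation, count per-region activated voxels, and compare dose groups
  nonparametrically;
* resting state: preprocess, extract node series, correlate, Fisher-Z,
  group edge test, threshold, and compare subregion degrees.

Both are deterministic for a fixed seed and are what the CLI, the examples
and the acceptance checks call.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import activation as act
from . import connectivity as conn
from . import group_stats as gs
from . import preprocess as pre
from .core import AtlasVolume, BoldScan
from .io import AnalysisConfig
from .synthetic import (
    PhmriSimConfig,
    RestingSimConfig,
    simulate_phmri_subject,
    simulate_resting_subject,
)

__all__ = [
    "simulate_phmri_study",
    "run_activation_study",
    "activation_study_from_sim",
    "preprocess_resting",
    "run_connectivity_group",
    "run_connectivity_study",
]

log = logging.getLogger("phmri")


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent per-subject seeds below 2**31, derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def simulate_phmri_study(
    atlas: AtlasVolume,
    cfg: PhmriSimConfig,
    seed: int | None = None,
) -> dict[str, list[tuple[BoldScan, object]]]:
    """One simulated drug-challenge scan per subject, per dose group."""
    seed = cfg.seed if seed is None else seed
    n_total = sum(cfg.n_per_group.values())
    seeds = iter(_child_seeds(seed, n_total))
    study: dict[str, list] = {}
    for dose, n in cfg.n_per_group.items():
        study[dose] = []
        for i in range(n):
            sid = f"{dose}_{i:02d}"
            t0 = time.perf_counter()
            scan, truth = simulate_phmri_subject(
                atlas, cfg, dose, seed=next(seeds), subject_id=sid
            )
            log.info("stage=simulate subject=%s wall=%.2fs", sid, time.perf_counter() - t0)
            study[dose].append((scan, truth))
    return study


def run_activation_study(
    study: dict[str, list[tuple[BoldScan, object]]],
    atlas: AtlasVolume,
    config: AnalysisConfig | None = None,
) -> dict:
    """Activation mapping and dose-group statistics for a full study.

    Returns per-subject activation maps, the positive-VOA region table,
    the Kruskal-Wallis dose-response table, the vehicle-versus-peak-dose
    rank-sum post-hoc table with its across-region FDR boundary, and
    per-group composite maps.
    """
    cfg = config or AnalysisConfig()
    params = act.FdrParams(q=cfg.fdr_q, c_v=cfg.c_v)
    maps: dict[str, list[act.ActivationMap]] = {}
    rows = []
    for dose, subjects in study.items():
        maps[dose] = []
        for scan, _truth in subjects:
            t0 = time.perf_counter()
            pre.detect_motion_outliers(scan, threshold=cfg.motion_outlier_z)
            amap = act.activation_map(
                scan,
                baseline_window=cfg.baseline_window,
                response_window=cfg.response_window,
                params=params,
                magnitude_threshold_pct=cfg.magnitude_threshold_pct,
                atlas_labels=atlas.labels if cfg.per_roi_fdr else None,
                per_roi=cfg.per_roi_fdr,
                magnitude_as_alpha=cfg.magnitude_as_alpha,
            )
            amap.condition = dose
            maps[dose].append(amap)
            voa = act.region_voa(amap.significance, atlas, sign="positive")
            for _, r in voa.iterrows():
                rows.append({
                    "region_id": int(r["region_id"]),
                    "subject_id": scan.subject_id,
                    "group": dose,
                    "value": int(r["n_voxels"]),
                })
            log.info(
                "stage=activation subject=%s wall=%.2fs", scan.subject_id,
                time.perf_counter() - t0,
            )
    table = pd.DataFrame(rows)
    groups = list(study)
    kw = gs.kruskal_wallis_by_region(table, group_order=groups)

    # post-hoc contrast between the first group (reference/vehicle) and the
    # group with the largest total median activation
    ref = groups[0]
    # total activated volume is a robust peak-dose pick: per-region medians
    # are mostly zero in weakly responding groups
    totals = table[table["group"] != ref].groupby("group")["value"].sum()
    peak = str(totals.idxmax()) if len(totals) else groups[-1]
    posthoc = gs.wilcoxon_posthoc(table, ref, peak)
    boundary, keep = gs.region_fdr_cutoff(
        posthoc["p_value"].to_numpy(), q=cfg.posthoc_fdr_q
    )
    posthoc = posthoc.assign(fdr_kept=keep)

    composites = {
        dose: act.composite_map(m, target_shape=atlas.labels.shape)
        for dose, m in maps.items()
    }
    return {
        "maps": maps,
        "region_table": table,
        "kruskal_wallis": kw,
        "posthoc": posthoc,
        "posthoc_groups": (ref, peak),
        "fdr_boundary_p": boundary,
        "composites": composites,
    }


def activation_study_from_sim(
    atlas: AtlasVolume,
    sim_cfg: PhmriSimConfig,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Convenience: simulate a study and analyze it in one call."""
    study = simulate_phmri_study(atlas, sim_cfg, seed=seed)
    out = run_activation_study(study, atlas, config=config)
    out["study"] = study
    return out


def preprocess_resting(scan: BoldScan, config: AnalysisConfig | None = None) -> BoldScan:
    """Standard resting-state chain, in pipeline order.

    Motion-outlier detection, optional slice-timing correction, band-pass
    filtering, detrending, spatial smoothing, then nuisance regression
    (motion outliers, six motion parameters, white matter and CSF means).
    Returns a new scan holding the residual data.
    """
    cfg = config or AnalysisConfig()
    t0 = time.perf_counter()
    pre.detect_motion_outliers(scan, threshold=cfg.motion_outlier_z)
    data = scan.data
    if cfg.slice_timing:
        data = pre.slice_timing_correct(data)
    filtered = np.zeros_like(data)
    filtered[scan.mask] = pre.bandpass(
        data[scan.mask], scan.tr_seconds,
        low_hz=cfg.bandpass_low_hz, high_hz=cfg.bandpass_high_hz,
    )
    filtered[scan.mask] = pre.detrend(filtered[scan.mask])
    smoothed = pre.gaussian_smooth(filtered, cfg.smooth_fwhm_mm, scan.voxel_size)
    interim = BoldScan(
        data=smoothed, tr_seconds=scan.tr_seconds, mask=scan.mask,
        motion_params=scan.motion_params, outlier_flags=scan.outlier_flags,
        tissue_means=scan.tissue_means, voxel_size=scan.voxel_size,
        subject_id=scan.subject_id,
    )
    resid = pre.nuisance_regress(interim)
    log.info("stage=preprocess subject=%s wall=%.2fs", scan.subject_id,
             time.perf_counter() - t0)
    return BoldScan(
        data=resid, tr_seconds=scan.tr_seconds, mask=scan.mask,
        motion_params=scan.motion_params, outlier_flags=scan.outlier_flags,
        tissue_means=scan.tissue_means, voxel_size=scan.voxel_size,
        subject_id=scan.subject_id,
    )


def run_connectivity_group(
    scans: list[BoldScan],
    atlas: AtlasVolume,
    config: AnalysisConfig | None = None,
    preprocess: bool = True,
) -> dict:
    """Group-level connectivity: per-subject correlations to a thresholded
    network with degrees."""
    cfg = config or AnalysisConfig()
    if len(scans) < 3:
        raise ValueError("group connectivity needs at least 3 subjects")
    z_stack = []
    node_ids = None
    for scan in scans:
        s = preprocess_resting(scan, cfg) if preprocess else scan
        ids, series = conn.region_timeseries(s, atlas)
        if node_ids is None:
            node_ids = ids
        elif not np.array_equal(node_ids, ids):
            raise ValueError("subjects disagree on the supported node set")
        edges = conn.pairwise_correlation(series, node_ids=ids)
        z_stack.append(edges.z)
    Z = conn.group_edge_test(np.stack(z_stack))
    network = conn.threshold_network(Z, cutoff=cfg.z_cutoff, node_ids=node_ids)
    return {"node_ids": node_ids, "group_z": Z, "network": network,
            "n_subjects": len(scans)}


def run_connectivity_study(
    groups: dict[str, list[BoldScan]],
    atlas: AtlasVolume,
    subregion_map: dict[str, list[int]],
    config: AnalysisConfig | None = None,
    preprocess: bool = True,
) -> dict:
    """Two-condition connectivity comparison (e.g., vehicle vs drug)."""
    cfg = config or AnalysisConfig()
    if len(groups) != 2:
        raise ValueError("connectivity comparison expects exactly two groups")
    (name_a, scans_a), (name_b, scans_b) = groups.items()
    res_a = run_connectivity_group(scans_a, atlas, cfg, preprocess=preprocess)
    res_b = run_connectivity_group(scans_b, atlas, cfg, preprocess=preprocess)
    comparison = conn.compare_degrees(
        res_a["network"], res_b["network"], subregion_map
    )
    comparison = comparison.rename(
        columns={"mean_a": f"mean_{name_a}", "sd_a": f"sd_{name_a}",
                 "mean_b": f"mean_{name_b}", "sd_b": f"sd_{name_b}"}
    )
    return {"groups": (name_a, name_b), name_a: res_a, name_b: res_b,
            "degree_comparison": comparison}


def simulate_resting_group(
    atlas: AtlasVolume,
    cfg: RestingSimConfig,
    n_subjects: int,
    seed: int,
    label: str = "",
) -> list[BoldScan]:
    """One resting scan per subject from a shared covariance network."""
    seeds = _child_seeds(seed, n_subjects)
    return [
        simulate_resting_subject(atlas, cfg, seed=s, subject_id=f"{label}_{i:02d}")
        for i, s in enumerate(seeds)
    ]
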