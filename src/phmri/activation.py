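"""Voxelwise BOLD percent-change activation mapping.

The activation analysis contrasts two acquisition windows of a drug-challenge
scan: a pre-injection baseline and a late post-injection response window.
Per voxel it computes the percent signal change between window means, a
Welch (heteroscedastic, two-tailed) t-test between the windows' acquisition
values, a rank-based false-positive filter

    P_(i) <= (i / V) * q / c(V)

applied step-up over the V tested voxels (q = 0.2 and c(V) = 1 by default,
a conservative expected-false-positive control), and a minimum
|percent-change| gate that screens out normal BOLD fluctuation.  Surviving
voxels keep their percent-change value with a sign label; everything else is
zeroed when subject maps are combined into atlas-space composite maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AffineTransform, AtlasVolume, BoldScan
from .preprocess import resample_trilinear

__all__ = [
    "FdrParams",
    "ActivationMap",
    "percent_change",
    "voxel_ttest",
    "fdr_filter",
    "significance_mask",
    "activation_map",
    "composite_map",
    "region_voa",
    "time_course",
    "epoch_contrast",
    "DEFAULT_BASELINE_WINDOW",
    "DEFAULT_RESPONSE_WINDOW",
]

#: Inclusive acquisition-index windows of the standard design: 41 baseline
#: acquisitions against 46 late response acquisitions.
DEFAULT_BASELINE_WINDOW: tuple[int, int] = (5, 45)
DEFAULT_RESPONSE_WINDOW: tuple[int, int] = (300, 345)


@dataclass(frozen=True)
class FdrParams:
    """Parameters of the rank-based false-positive filter."""

    q: float = 0.2
    c_v: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.q <= 1):
            raise ValueError("q must be in (0, 1]")
        if self.c_v < 1:
            raise ValueError("c_v must be >= 1")


@dataclass
class ActivationMap:
    """Per-subject activation result in a common space.

    ``percent_change`` keeps the raw percent values everywhere (NaN where
    invalid); ``significance`` is +1 / -1 / 0 per voxel.  Composite maps zero
    the non-significant voxels; the raw values are retained here.
    """

    percent_change: np.ndarray
    significance: np.ndarray
    subject_id: str = ""
    condition: str = ""

    def zeroed(self) -> np.ndarray:
        """Percent-change map with non-significant voxels set to zero."""
        out = np.where(self.significance != 0, self.percent_change, 0.0)
        return np.where(np.isfinite(out), out, 0.0)


def _window_slice(window: tuple[int, int], flags: np.ndarray) -> np.ndarray:
    lo, hi = int(window[0]), int(window[1])
    idx = np.arange(lo, hi + 1)
    return idx[~flags[idx]]


def _check_windows(
    scan: BoldScan,
    baseline_window: tuple[int, int],
    response_window: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    n_t = scan.n_acquisitions
    for name, (lo, hi) in (("baseline", baseline_window), ("response", response_window)):
        if not (0 <= lo <= hi < n_t):
            raise ValueError(f"{name} window [{lo},{hi}] outside scan length {n_t}")
    if not (baseline_window[1] < response_window[0] or response_window[1] < baseline_window[0]):
        raise ValueError("baseline and response windows must be disjoint")
    b = _window_slice(baseline_window, scan.outlier_flags)
    r = _window_slice(response_window, scan.outlier_flags)
    if len(b) < 3 or len(r) < 3:
        raise ValueError("each window needs at least 3 unflagged acquisitions")
    return b, r


def percent_change(
    scan: BoldScan,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    response_window: tuple[int, int] = DEFAULT_RESPONSE_WINDOW,
) -> np.ndarray:
    """Per-voxel percent signal change between window means.

    ``100 * (mean(response) - mean(baseline)) / mean(baseline)``, with
    motion-flagged acquisitions excluded from both means.  Voxels with
    non-positive baseline mean (or outside the mask) are NaN.
    """
    b_idx, r_idx = _check_windows(scan, baseline_window, response_window)
    series = scan.masked_series()
    base = series[:, b_idx].mean(axis=1)
    resp = series[:, r_idx].mean(axis=1)
    pc = np.full(base.shape, np.nan)
    valid = base > 0
    pc[valid] = 100.0 * (resp[valid] - base[valid]) / base[valid]
    out = np.full(scan.mask.shape, np.nan)
    out[scan.mask] = pc
    return out


def voxel_ttest(
    scan: BoldScan,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    response_window: tuple[int, int] = DEFAULT_RESPONSE_WINDOW,
) -> np.ndarray:
    """Per-voxel Welch two-sample two-tailed t-test between the windows.

    Unequal variances are assumed (heteroscedastic).  A voxel whose values
    are constant and equal in both windows gets p = 1 by convention;
    constant-but-different windows get p = 0 (infinite separation).
    """
    b_idx, r_idx = _check_windows(scan, baseline_window, response_window)
    series = scan.masked_series()
    a = series[:, r_idx]
    b = series[:, b_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
    var_a = a.var(axis=1)
    var_b = b.var(axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    out = np.full(scan.mask.shape, np.nan)
    out[scan.mask] = p
    return out


def fdr_filter(p_values: np.ndarray, params: FdrParams = FdrParams()) -> np.ndarray:
    """Step-up rank filter: keep all ranks up to the largest i with
    ``P_(i) <= (i/V) * q / c(V)``.

    Returns a boolean keep-mask aligned with the input vector.  NaN entries
    are never kept and do not count toward V.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    keep = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    pv = p[finite]
    if pv.size == 0:
        return keep.reshape(np.shape(p_values))
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    V = pv.size
    order = np.argsort(pv, kind="stable")
    thresholds = (np.arange(1, V + 1) * params.q) / (V * params.c_v)
    qualifying = np.flatnonzero(pv[order] <= thresholds)
    if qualifying.size:
        k = qualifying[-1]
        kept_local = np.zeros(V, dtype=bool)
        kept_local[order[: k + 1]] = True
        keep[finite] = kept_local
    return keep.reshape(np.shape(p_values))


def significance_mask(
    percent_map: np.ndarray,
    p_map: np.ndarray,
    params: FdrParams = FdrParams(),
    magnitude_threshold_pct: float = 1.0,
    atlas_labels: np.ndarray | None = None,
    per_roi: bool = False,
    magnitude_as_alpha: bool = False,
) -> np.ndarray:
    """Sign-labelled significance mask (+1 positive, -1 negative, 0 none).

    A voxel is significant iff it survives the rank filter AND passes the
    fluctuation gate.  By default the gate is ``|percent change| >=
    magnitude_threshold_pct`` (1%, screening normal BOLD fluctuation); with
    ``magnitude_as_alpha=True`` the gate is instead ``p <= threshold/100``
    (the alternative alpha-level reading).

    With ``per_roi=True`` the filter is run separately within each atlas
    region (V = region voxel count); otherwise over the whole tested voxel
    population at once.
    """
    percent_map = np.asarray(percent_map, dtype=float)
    p_map = np.asarray(p_map, dtype=float)
    if percent_map.shape != p_map.shape:
        raise ValueError("percent-change and p-value maps must be aligned")
    if per_roi:
        if atlas_labels is None:
            raise ValueError("per_roi filtering requires atlas labels")
        keep = np.zeros(p_map.shape, dtype=bool)
        for rid in np.unique(atlas_labels[atlas_labels > 0]):
            sel = atlas_labels == rid
            keep[sel] = fdr_filter(p_map[sel], params)
    else:
        keep = fdr_filter(p_map, params)
    if magnitude_as_alpha:
        gate = p_map <= magnitude_threshold_pct / 100.0
    else:
        gate = np.abs(percent_map) >= magnitude_threshold_pct
    sig = keep & gate & np.isfinite(percent_map)
    return np.where(sig, np.sign(percent_map), 0.0).astype(np.int8)


def activation_map(
    scan: BoldScan,
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
    response_window: tuple[int, int] = DEFAULT_RESPONSE_WINDOW,
    params: FdrParams = FdrParams(),
    magnitude_threshold_pct: float = 1.0,
    **sig_kwargs,
) -> ActivationMap:
    """Full single-subject chain: percent change, Welch t, filter, gate."""
    pc = percent_change(scan, baseline_window, response_window)
    p = voxel_ttest(scan, baseline_window, response_window)
    sig = significance_mask(
        pc, p, params=params,
        magnitude_threshold_pct=magnitude_threshold_pct, **sig_kwargs,
    )
    return ActivationMap(percent_change=pc, significance=sig, subject_id=scan.subject_id)


def composite_map(
    subject_maps: list[ActivationMap],
    transforms: list[AffineTransform] | None = None,
    target_shape: tuple[int, int, int] | None = None,
    source_voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    target_voxel_size: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Atlas-space group-mean percent-change map.

    Each subject's map (non-significant voxels zeroed) is carried into the
    target grid by trilinear interpolation through that subject's transform;
    the composite voxel is the mean over subjects, with out-of-field
    (missing) contributions excluded rather than counted as zero.
    """
    if not subject_maps:
        raise ValueError("composite_map needs at least one subject")
    if transforms is None:
        transforms = [AffineTransform.identity() for _ in subject_maps]
    if len(transforms) != len(subject_maps):
        raise ValueError("one transform per subject map is required")
    if target_shape is None:
        target_shape = subject_maps[0].percent_change.shape
    stack = np.stack([
        resample_trilinear(
            m.zeroed(), t, target_shape,
            source_voxel_size=source_voxel_size,
            target_voxel_size=target_voxel_size,
        )
        for m, t in zip(subject_maps, transforms)
    ])
    import warnings

    with warnings.catch_warnings():
        # voxels outside every subject's field of view are all-NaN: they
        # stay NaN in the composite, silently
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(stack, axis=0)


def region_voa(
    significance: np.ndarray,
    atlas: AtlasVolume,
    sign: str = "positive",
) -> pd.DataFrame:
    """Volume of activation: per-region count of significant voxels of a sign.

    Returns a table (region_id, region_name, n_voxels) covering every atlas
    region, background excluded.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    significance = np.asarray(significance)
    if significance.shape != atlas.labels.shape:
        raise ValueError("significance mask must be in atlas space")
    target = 1 if sign == "positive" else -1
    hits = atlas.labels[significance == target]
    counts = np.bincount(hits, minlength=atlas.n_regions + 1)
    ids = atlas.region_ids
    missing = [int(i) for i in ids if int(i) not in atlas.region_names]
    if missing:
        raise KeyError(f"atlas region ids without names: {missing}")
    return pd.DataFrame({
        "region_id": ids,
        "region_name": [atlas.region_names[int(i)] for i in ids],
        "n_voxels": counts[1:],
    })


def time_course(
    scan: BoldScan,
    atlas: AtlasVolume,
    region_ids: set[int] | list[int],
    baseline_window: tuple[int, int] = DEFAULT_BASELINE_WINDOW,
) -> np.ndarray:
    """Percent-change time course of a (composite) region set.

    Per acquisition: 100 * (mean over region voxels - baseline) / baseline,
    with the baseline taken as the mean of the region signal over the
    unflagged baseline-window acquisitions.
    """
    region_ids = sorted(int(r) for r in region_ids)
    if not region_ids:
        raise ValueError("empty region set")
    sel = np.isin(atlas.labels, region_ids) & scan.mask
    if not sel.any():
        raise ValueError(f"regions {region_ids} have no voxels in the atlas/mask")
    series = scan.data[sel].mean(axis=0)
    b_idx = _window_slice(baseline_window, scan.outlier_flags)
    if len(b_idx) < 3:
        raise ValueError("baseline window needs at least 3 unflagged acquisitions")
    base = series[b_idx].mean()
    if base <= 0:
        raise ValueError("non-positive baseline signal")
    return 100.0 * (series - base) / base


def epoch_contrast(
    scan: BoldScan,
    epochs: list[tuple[str, int, int]],
    atlas: AtlasVolume | None = None,
    region_ids: set[int] | list[int] | None = None,
) -> pd.DataFrame:
    """Percent change of each labelled epoch against the first (baseline).

    ``epochs`` are (label, start, stop) inclusive windows; they must not
    overlap.  Supports challenge designs such as baseline / gas exposure /
    post-exposure blocks.  If an atlas and region set are given the signal
    is the region-set mean; otherwise the whole-mask mean.
    """
    if len(epochs) < 2:
        raise ValueError("need at least two epochs (first one is the baseline)")
    spans = sorted((int(lo), int(hi), str(lbl)) for lbl, lo, hi in epochs)
    for (lo1, hi1, _), (lo2, _hi2, _) in zip(spans, spans[1:]):
        if lo2 <= hi1:
            raise ValueError("epochs must not overlap")
    if atlas is not None and region_ids:
        sel = np.isin(atlas.labels, sorted(int(r) for r in region_ids)) & scan.mask
    else:
        sel = scan.mask
    series = scan.data[sel].mean(axis=0)

    means = {}
    for lbl, lo, hi in epochs:
        idx = _window_slice((lo, hi), scan.outlier_flags)
        if len(idx) < 3:
            raise ValueError(f"epoch '{lbl}' has fewer than 3 unflagged acquisitions")
        means[lbl] = series[idx].mean()
    base_label = epochs[0][0]
    base = means[base_label]
    if base <= 0:
        raise ValueError("non-positive baseline epoch mean")
    rows = [
        {
            "epoch": lbl,
            "mean_signal": means[lbl],
            "percent_change": 100.0 * (means[lbl] - base) / base,
        }
        for lbl, _, _ in epochs
    ]
    return pd.DataFrame(rows)
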