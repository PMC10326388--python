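"""Bring raw 4D scans to analysis-ready form.

Masking, motion-outlier detection, detrending, spatial smoothing, temporal
band-pass filtering, nuisance regression, slice-timing correction, and
affine registration into atlas space with trilinear resampling.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, optimize, signal

from .core import AffineTransform, AtlasVolume, BoldScan

__all__ = [
    "detect_motion_outliers",
    "detrend",
    "gaussian_smooth",
    "bandpass",
    "slice_timing_correct",
    "nuisance_regress",
    "register_affine",
    "resample_trilinear",
    "centred_affine",
    "RegistrationError",
    "FWHM_TO_SIGMA",
]

#: FWHM = sigma * 2*sqrt(2 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class RegistrationError(RuntimeError):
    """Raised when the affine optimizer fails to converge usefully."""


def detect_motion_outliers(scan: BoldScan, threshold: float = 5.0) -> np.ndarray:
    """Flag acquisitions whose global in-mask mean is a robust-z outlier.

    The robust z-score uses the median and the MAD (scaled to be consistent
    with the standard deviation under normality); new flags are unioned with
    any flags already on the scan.  Returns the updated flag vector (the scan
    is updated in place as well).
    """
    if scan.n_acquisitions < 10:
        raise ValueError("need at least 10 acquisitions to estimate outliers")
    if not scan.mask.any():
        raise ValueError("empty brain mask")
    g = scan.masked_series().mean(axis=0)
    med = np.median(g)
    mad = np.median(np.abs(g - med))
    if mad == 0:
        z = np.zeros_like(g)
    else:
        z = (g - med) / (1.4826 * mad)
    flags = np.abs(z) > threshold
    scan.outlier_flags = scan.outlier_flags | flags
    return scan.outlier_flags


def detrend(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the per-series least-squares linear trend (and mean)."""
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 3:
        raise ValueError("need at least 3 samples to detrend")
    return signal.detrend(x, axis=axis, type="linear")


def gaussian_smooth(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Spatial Gaussian smoothing at the given FWHM (mm).

    For 4D input each volume is smoothed independently (no temporal
    blurring).  ``fwhm_mm = 0`` returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size]
    if volume.ndim == 3:
        return ndimage.gaussian_filter(volume, sigma=sigma_vox)
    if volume.ndim == 4:
        return ndimage.gaussian_filter(volume, sigma=sigma_vox + [0.0])
    raise ValueError("expected a 3D or 4D array")


def bandpass(
    x: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    order: int = 4,
    axis: int = -1,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    Forward-backward filtering (sosfiltfilt) doubles the effective order and
    cancels phase delay, so event timing is preserved.
    """
    nyquist = 0.5 / tr_seconds
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be below Nyquist {nyquist}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def slice_timing_correct(
    data: np.ndarray,
    slice_axis: int = 2,
    slice_order: str = "interleaved",
    ref_slice: int = 0,
) -> np.ndarray:
    """Per-slice temporal linear interpolation to a reference slice's timing.

    Acquisition offsets are assumed uniform within a TR, ordered either
    sequentially or interleaved (odd slices first).  Off by default in the
    pipelines; the synthetic generator does not simulate slice offsets.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("slice timing correction expects 4D data")
    n_slices = data.shape[slice_axis]
    if slice_order == "sequential":
        acq_order = np.arange(n_slices)
    elif slice_order == "interleaved":
        acq_order = np.argsort(np.r_[np.arange(0, n_slices, 2), np.arange(1, n_slices, 2)])
    else:
        raise ValueError("slice_order must be 'sequential' or 'interleaved'")
    offsets = acq_order / n_slices  # fraction of TR
    ref = offsets[ref_slice]
    t = np.arange(data.shape[3], dtype=float)
    out = np.empty_like(data)
    for s in range(n_slices):
        sl = [slice(None)] * 4
        sl[slice_axis] = s
        series = data[tuple(sl)]
        shifted_t = t + (offsets[s] - ref)
        out[tuple(sl)] = _interp_along_last(series, shifted_t, t)
    return out


def _interp_along_last(y: np.ndarray, t_src: np.ndarray, t_query: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(t_src, t_query) - 1, 0, len(t_src) - 2)
    w = (t_query - t_src[idx]) / (t_src[idx + 1] - t_src[idx])
    w = np.clip(w, 0.0, 1.0)
    return y[..., idx] * (1 - w) + y[..., idx + 1] * w


def build_nuisance_design(scan: BoldScan) -> tuple[np.ndarray, list[str]]:
    """Assemble the nuisance design matrix.

    Columns: intercept, six motion parameters, one indicator per flagged
    outlier acquisition (spike regression keeps the time axis intact), mean
    white-matter and CSF series.  Collinear columns are dropped with a
    warning (the intercept is always kept).
    """
    n_t = scan.n_acquisitions
    cols: list[np.ndarray] = [np.ones(n_t)]
    names = ["intercept"]
    if scan.motion_params is not None:
        for i in range(6):
            cols.append(scan.motion_params[:, i])
            names.append(f"motion_{i}")
    for k, t_idx in enumerate(np.flatnonzero(scan.outlier_flags)):
        ind = np.zeros(n_t)
        ind[t_idx] = 1.0
        cols.append(ind)
        names.append(f"outlier_{t_idx}")
    for tissue in ("white_matter", "csf"):
        if tissue in scan.tissue_means:
            cols.append(np.asarray(scan.tissue_means[tissue], dtype=float))
            names.append(tissue)
    X = np.column_stack(cols)

    # greedy rank check: drop columns that add no rank
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear nuisance regressor '{names[j]}'")
    return X[:, keep], [names[j] for j in keep]


def nuisance_regress(scan: BoldScan) -> np.ndarray:
    """OLS residual of every in-mask voxel series on the nuisance design.

    Residuals are exactly orthogonal to every retained design column.
    Returns a 4D array (zero outside the mask).
    """
    X, names = build_nuisance_design(scan)
    if scan.n_acquisitions <= X.shape[1] + 2:
        raise ValueError("too few acquisitions for the nuisance design")
    Y = scan.masked_series().T  # (t, vox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = np.zeros(scan.data.shape)
    out[scan.mask] = resid.T
    return out


def resample_trilinear(
    volume: np.ndarray,
    transform: AffineTransform,
    target_shape: tuple[int, int, int],
    source_voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    target_voxel_size: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Resample a source volume onto a target grid through a world transform.

    ``transform`` maps source-world to target-world coordinates; each target
    voxel is inverse-mapped and filled by trilinear interpolation of the
    source.  Voxels falling outside the source field of view are NaN
    (missing), never zero.
    """
    volume = np.asarray(volume, dtype=float)
    if target_voxel_size is None:
        target_voxel_size = source_voxel_size
    inv = transform.inverse().matrix
    idx = np.indices(target_shape, dtype=float).reshape(3, -1)
    world_t = idx * np.asarray(target_voxel_size, dtype=float)[:, None]
    world_s = inv[:3, :3] @ world_t + inv[:3, 3:4]
    coords = world_s / np.asarray(source_voxel_size, dtype=float)[:, None]
    out = ndimage.map_coordinates(
        volume, coords, order=1, mode="constant", cval=np.nan
    )
    return out.reshape(target_shape)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized correlation over jointly finite voxels."""
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 10:
        return -1.0
    x = a[ok] - a[ok].mean()
    y = b[ok] - b[ok].mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)


def _params_to_transform(p: np.ndarray, centre_mm: np.ndarray | None = None) -> AffineTransform:
    T = AffineTransform.from_params(
        translation_mm=tuple(p[0:3]),
        rotation_rad=tuple(p[3:6]),
        scale=tuple(np.exp(p[6:9])),
    )
    if centre_mm is None:
        return T
    # conjugate so rotation and scale act about the volume centre: this
    # decorrelates scale from translation in the search space
    M = np.eye(4)
    M[:3, 3] = centre_mm
    Minv = np.eye(4)
    Minv[:3, 3] = -centre_mm
    return AffineTransform(M @ T.matrix @ Minv)


def centred_affine(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    rotation_rad: tuple[float, float, float] = (0.0, 0.0, 0.0),
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> AffineTransform:
    """Affine whose rotation and scale act about the volume centre."""
    centre = (np.asarray(shape, dtype=float) - 1) / 2 * np.asarray(voxel_size)
    p = np.r_[translation_mm, rotation_rad, np.log(scale)]
    return _params_to_transform(p, centre)


def register_affine(
    subject_volume: np.ndarray,
    reference: np.ndarray | AtlasVolume,
    subject_voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    reference_voxel_size: tuple[float, float, float] | None = None,
    init: AffineTransform | None = None,
    smooth_levels_vox: tuple[float, ...] = (2.0, 1.0, 0.0),
    min_ncc: float = 0.5,
) -> AffineTransform:
    """Estimate the 9-parameter subject-to-reference world transform.

    Maximizes normalized correlation between the transformed subject volume
    and the reference image, coarse-to-fine over a Gaussian smoothing
    pyramid, with Powell's method at each level.  Scales are optimized in
    log space so the search is symmetric around 1.

    Raises :class:`RegistrationError` if the final similarity stays below
    ``min_ncc``.
    """
    if isinstance(reference, AtlasVolume):
        if reference_voxel_size is None:
            reference_voxel_size = reference.voxel_size
        reference = np.asarray(reference.labels > 0, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if reference_voxel_size is None:
        reference_voxel_size = subject_voxel_size

    centre = (np.asarray(reference.shape, dtype=float) - 1) / 2 * np.asarray(
        reference_voxel_size
    )

    p = np.zeros(9)
    if init is not None:
        # strip the centre conjugation before decomposing
        M = np.eye(4)
        M[:3, 3] = -centre
        Minv = np.eye(4)
        Minv[:3, 3] = centre
        d = AffineTransform(M @ init.matrix @ Minv).decompose()
        p[0:3] = d["translation"]
        R = d["rotation"]
        p[3] = np.arctan2(R[2, 1], R[2, 2])
        p[4] = -np.arcsin(np.clip(R[2, 0], -1, 1))
        p[5] = np.arctan2(R[1, 0], R[0, 0])
        p[6:9] = np.log(d["scale"])

    for sig in smooth_levels_vox:
        mov = ndimage.gaussian_filter(subject_volume, sig) if sig > 0 else subject_volume
        ref = ndimage.gaussian_filter(reference, sig) if sig > 0 else reference

        def cost(q: np.ndarray) -> float:
            res = resample_trilinear(
                mov, _params_to_transform(q, centre), ref.shape,
                source_voxel_size=subject_voxel_size,
                target_voxel_size=reference_voxel_size,
            )
            # out-of-field treated as background during the search: avoids
            # spurious optima from a shrinking overlap region
            return -_ncc(np.nan_to_num(res), ref)

        # initial search directions scaled to each parameter's natural unit
        step = np.r_[np.full(3, 0.5 * min(reference_voxel_size)),
                     np.full(3, 0.02), np.full(3, 0.02)]
        res = optimize.minimize(
            cost, p, method="Powell",
            options={"xtol": 1e-5, "ftol": 1e-9, "maxiter": 5000,
                     "direc": np.diag(step)},
        )
        p = res.x

    final = resample_trilinear(
        subject_volume, _params_to_transform(p, centre), reference.shape,
        source_voxel_size=subject_voxel_size,
        target_voxel_size=reference_voxel_size,
    )
    score = _ncc(final, reference)
    if score < min_ncc:
        raise RegistrationError(
            f"affine registration failed to converge (final NCC {score:.3f} "
            f"< {min_ncc}); params={p}"
        )
    return _params_to_transform(p, centre)
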