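"""Synthetic atlases and BOLD scans with known ground truth.

Everything downstream of the scanner is testable against this module: it
generates (i) a Voronoi parcellation of an ellipsoidal "brain", (ii)
pharmacological-MRI scans in which selected regions mount a slow
percent-scale BOLD response on top of AR(1) noise, drift and motion spikes,
and (iii) resting-state scans whose region time courses follow a prescribed
covariance network.  Ground truth (which voxels are active, at what
amplitude) is returned alongside every simulated scan.

The default parameter values encode the study design this package targets:
350-acquisition drug scans (TR 6 s) with a 50-acquisition pre-injection
baseline, a response ramping from injection to a plateau near acquisition
286, peak amplitudes of a few percent with an inverted-U dose profile, and
150-acquisition resting scans (TR 1 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.spatial import cKDTree

from .core import AtlasVolume, BoldScan

__all__ = [
    "PhmriSimConfig",
    "RestingSimConfig",
    "GroundTruth",
    "generate_atlas",
    "simulate_phmri_subject",
    "simulate_resting_subject",
    "block_covariance",
    "DEFAULT_AMPLITUDES",
    "DEFAULT_GROUP_SIZES",
]

#: Peak percent-change per dose group: the inverted-U design (middle dose
#: strongest, flanked by weaker responses).
DEFAULT_AMPLITUDES: dict[str, float] = {
    "vehicle": 0.0,
    "1mg": 0.5,
    "3mg": 2.0,
    "10mg": 0.5,
}

#: Subjects per dose group.
DEFAULT_GROUP_SIZES: dict[str, int] = {"vehicle": 6, "1mg": 7, "3mg": 7, "10mg": 7}


@dataclass
class PhmriSimConfig:
    """Design parameters for a simulated pharmacological-MRI scan.

    Windows are inclusive acquisition-index ranges.  ``noise_sd``,
    amplitudes and ``drift_slope`` are in percent of the baseline level.
    """

    n_acquisitions: int = 350
    tr_seconds: float = 6.0
    baseline_window: tuple[int, int] = (5, 45)
    response_window: tuple[int, int] = (300, 345)
    active_regions: frozenset[int] = frozenset()
    amplitude_by_dose: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    onset_acquisition: int = 50
    ramp_length: int = 236
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.3
    drift_slope: float = 0.001  # percent per acquisition
    motion_spike_prob: float = 0.01
    baseline_level: float = 1000.0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.active_regions = frozenset(int(r) for r in self.active_regions)
        for name, win in (("baseline", self.baseline_window),
                          ("response", self.response_window)):
            lo, hi = win
            if not (0 <= lo <= hi < self.n_acquisitions):
                raise ValueError(f"{name}_window {win} outside [0, {self.n_acquisitions})")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be strictly positive")
        if not (0 <= self.ar1_coefficient < 1):
            raise ValueError("ar1_coefficient must be in [0, 1)")
        missing = set(self.n_per_group) - set(self.amplitude_by_dose)
        if missing:
            raise ValueError(f"amplitude_by_dose missing dose labels: {sorted(missing)}")


@dataclass
class RestingSimConfig:
    """Design parameters for a simulated resting-state scan."""

    n_timepoints: int = 150
    tr_seconds: float = 1.0
    node_covariance: np.ndarray | None = None
    observation_noise_sd: float = 0.3
    signal_scale_pct: float = 1.0  # node fluctuations, percent of baseline level
    baseline_level: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.node_covariance is not None:
            self.node_covariance = validate_covariance(self.node_covariance)


def validate_covariance(cov: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Check symmetry, unit diagonal and positive semidefiniteness."""
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("node covariance must be square")
    if not np.allclose(cov, cov.T, atol=tol):
        raise ValueError("node covariance must be symmetric")
    if not np.allclose(np.diag(cov), 1.0, atol=1e-6):
        raise ValueError("node covariance must have unit diagonal")
    w = np.linalg.eigvalsh(cov)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError("node covariance is not positive semidefinite")
    return cov


def block_covariance(
    block_sizes: list[int],
    within: float = 0.6,
    between: float = 0.0,
) -> np.ndarray:
    """Unit-diagonal block covariance: ``within`` correlation inside each
    block, ``between`` across blocks.  Convenient for planting resting-state
    network modules."""
    n = int(sum(block_sizes))
    cov = np.full((n, n), float(between))
    start = 0
    for size in block_sizes:
        cov[start:start + size, start:start + size] = within
        start += size
    np.fill_diagonal(cov, 1.0)
    return validate_covariance(cov)


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal in-brain mask filling ~90% of each axis."""
    grids = np.indices(shape, dtype=float)
    centre = [(s - 1) / 2.0 for s in shape]
    semi = [0.45 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0


def generate_atlas(
    n_regions: int,
    shape: tuple[int, int, int],
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (0.3125, 0.3125, 1.2),
) -> AtlasVolume:
    """Partition an ellipsoidal brain into ``n_regions`` Voronoi regions.

    Region seeds are drawn uniformly from in-brain voxels and every in-brain
    voxel is labelled by its nearest seed, so each region is nonempty and the
    regions partition the brain exactly.  Deterministic for a given seed.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if any(s < 4 for s in shape):
        raise ValueError("each atlas dimension must be at least 4 voxels")
    mask = _ellipsoid_mask(shape)
    coords = np.argwhere(mask)
    if n_regions > len(coords):
        raise ValueError(
            f"cannot place {n_regions} regions in a brain of {len(coords)} voxels"
        )
    rng = np.random.default_rng(seed)
    centres = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    # nearest-seed assignment in voxel coordinates
    _, nearest = cKDTree(centres).query(coords)
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(coords.T)] = nearest + 1
    return AtlasVolume(labels=labels, voxel_size=voxel_size)


@dataclass
class GroundTruth:
    """What the simulator actually injected, for downstream verification."""

    active_voxel_mask: np.ndarray  # 3D boolean
    amplitude_map: np.ndarray  # 3D, percent
    dose_label: str
    spike_acquisitions: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=int)
    )

    def __post_init__(self) -> None:
        nz = self.amplitude_map != 0
        if not np.array_equal(nz, self.active_voxel_mask):
            raise ValueError("amplitude_map must be nonzero exactly on active voxels")


def _ar1_noise(
    rng: np.random.Generator, n_series: int, n_t: int, rho: float, sd: float
) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((n_series, n_t))
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    e = rng.standard_normal((n_series, n_t)) * innov_sd
    if rho == 0:
        return e
    x0 = rng.standard_normal(n_series) * sd
    out, _ = lfilter([1.0], [1.0, -rho], e, axis=1, zi=(rho * x0)[:, None])
    return out


def _response_curve(cfg: PhmriSimConfig) -> np.ndarray:
    """Unit response: 0 before onset, linear ramp, then plateau at 1."""
    t = np.arange(cfg.n_acquisitions, dtype=float)
    if cfg.ramp_length <= 0:
        return (t >= cfg.onset_acquisition).astype(float)
    return np.clip((t - cfg.onset_acquisition) / cfg.ramp_length, 0.0, 1.0)


def _nuisance_series(
    rng: np.random.Generator, n_t: int, spikes: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Plausible motion parameters and tissue-mean regressor series."""
    motion = np.cumsum(rng.standard_normal((n_t, 6)) * 1e-3, axis=0)
    motion[spikes] += rng.standard_normal((int(spikes.sum()), 6)) * 0.05
    tissue = {
        "white_matter": 1000.0 + rng.standard_normal(n_t) * 2.0,
        "csf": 1000.0 + rng.standard_normal(n_t) * 4.0,
    }
    return motion, tissue


def simulate_phmri_subject(
    atlas: AtlasVolume,
    cfg: PhmriSimConfig,
    dose: str,
    seed: int,
    subject_id: str = "",
) -> tuple[BoldScan, GroundTruth]:
    """Simulate one drug-challenge scan.

    The voxel signal model is multiplicative around a constant baseline
    level::

        s_v(t) = L * (1 + drift(t) + a_v * ramp(t) + n_v(t) + spike(t))

    where ``a_v`` is the peak fractional amplitude (the dose's percent
    amplitude / 100) in voxels of active regions and 0 elsewhere, ``ramp``
    rises linearly from injection onset to a plateau, ``n_v`` is stationary
    AR(1) noise independent across voxels, and ``spike`` is a global
    intensity deviation on motion-corrupted acquisitions (which are also
    flagged, since the pipeline scrubs by flag).
    """
    if dose not in cfg.amplitude_by_dose:
        raise KeyError(f"dose label {dose!r} absent from amplitude_by_dose")
    unknown = cfg.active_regions - set(int(i) for i in atlas.region_ids)
    if unknown:
        raise ValueError(f"active regions not in atlas: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    mask = atlas.brain_mask
    n_vox = int(mask.sum())
    n_t = cfg.n_acquisitions

    amplitude_pct = float(cfg.amplitude_by_dose[dose])
    active = np.isin(atlas.labels, list(cfg.active_regions)) & (amplitude_pct != 0)
    amp_frac = np.where(active[mask], amplitude_pct / 100.0, 0.0)

    ramp = _response_curve(cfg)
    drift = (cfg.drift_slope / 100.0) * np.arange(n_t)
    noise = _ar1_noise(rng, n_vox, n_t, cfg.ar1_coefficient, cfg.noise_sd / 100.0)

    spikes = rng.random(n_t) < cfg.motion_spike_prob
    spike_dev = np.zeros(n_t)
    if spikes.any():
        # global deviations of 2-5% with random sign
        mag = rng.uniform(0.02, 0.05, size=int(spikes.sum()))
        spike_dev[spikes] = mag * rng.choice([-1.0, 1.0], size=mag.size)

    rel = 1.0 + drift[None, :] + amp_frac[:, None] * ramp[None, :] + noise
    rel += spike_dev[None, :]
    series = cfg.baseline_level * rel

    data = np.zeros(mask.shape + (n_t,))
    data[mask] = series
    motion, tissue = _nuisance_series(rng, n_t, spikes)

    scan = BoldScan(
        data=data,
        tr_seconds=cfg.tr_seconds,
        mask=mask,
        motion_params=motion,
        outlier_flags=spikes.copy(),
        tissue_means=tissue,
        voxel_size=atlas.voxel_size,
        subject_id=subject_id,
    )
    truth = GroundTruth(
        active_voxel_mask=active,
        amplitude_map=np.where(active, amplitude_pct, 0.0),
        dose_label=dose,
        spike_acquisitions=np.flatnonzero(spikes),
    )
    return scan, truth


def simulate_resting_subject(
    atlas: AtlasVolume,
    cfg: RestingSimConfig,
    seed: int,
    subject_id: str = "",
) -> BoldScan:
    """Simulate one resting-state scan from a node covariance network.

    Region time courses are drawn jointly from ``cfg.node_covariance``
    (dimension = number of atlas regions); each voxel receives its region's
    course plus independent observation noise, all expressed as percent-scale
    fluctuations around a constant baseline level.
    """
    if cfg.node_covariance is None:
        raise ValueError("RestingSimConfig.node_covariance is required")
    cov = validate_covariance(cfg.node_covariance)
    if cov.shape[0] != atlas.n_regions:
        raise ValueError(
            f"covariance dimension {cov.shape[0]} != atlas regions {atlas.n_regions}"
        )
    rng = np.random.default_rng(seed)
    n_t = cfg.n_timepoints

    # factor the (possibly semidefinite) covariance via eigh
    w, V = np.linalg.eigh(cov)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    node_courses = L @ rng.standard_normal((cov.shape[0], n_t))

    mask = atlas.brain_mask
    labels_in = atlas.labels[mask]
    voxel_signal = node_courses[labels_in - 1]
    voxel_signal = voxel_signal + rng.standard_normal(voxel_signal.shape) * cfg.observation_noise_sd
    series = cfg.baseline_level * (1.0 + (cfg.signal_scale_pct / 100.0) * voxel_signal)

    data = np.zeros(mask.shape + (n_t,))
    data[mask] = series
    spikes = np.zeros(n_t, dtype=bool)
    motion, tissue = _nuisance_series(rng, n_t, spikes)
    return BoldScan(
        data=data,
        tr_seconds=cfg.tr_seconds,
        mask=mask,
        motion_params=motion,
        outlier_flags=spikes,
        tissue_means=tissue,
        voxel_size=atlas.voxel_size,
        subject_id=subject_id,
    )
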