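"""Digital-phantom forward model for multi-coil FID navigator cohorts.

The simulator stands in for a clinical cohort: an ellipsoidal head phantom on
a regular 3-D grid, a ring array of smooth receive-coil sensitivity profiles,
rigid 6-DOF motion trajectories typical of pediatric patients (still, slow
drift, abrupt repositioning, continuous restlessness), and a navigator
forward model

    s_j(i) = sum_x density(T_i^{-1} x) * c_j(x) * exp(i phi_j)
             + drift_j(i) + fluctuation_j(i) + noise_j(i)

with trilinear resampling of the rigidly transformed phantom.  The model
reproduces only the mechanism the motion metrics exploit — the
coil-sensitivity-weighted volume integral changing under rigid motion, on
top of slow drift, pseudo-periodic physiological fluctuation, and complex
Gaussian noise; spin history, B0 and flip-angle effects are outside its
scope.

``generate_cohort`` writes per-subject navigator CSVs plus a manifest with
ground-truth grades, emulating the acquisition of the clinical study
(TR 1.54 s, ~160 TRs over a 4.2-min scan, 32 channels) and its radiologist
grade mix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from fidnav.integration import KspaceWeighting
from fidnav.preprocess import FidnavSeries

# Acquisition defaults of the emulated protocol
DEFAULT_TR_SECONDS = 1.54
DEFAULT_N_TR_RAW = 163  # ~4.2 min of TRs; 160 retained after the steady-state trim
DEFAULT_N_CHANNELS = 32
DEFAULT_N_DISCARD = 3

#: Grade counts of the emulated 102-patient cohort, grades 1..5.
DEFAULT_GRADE_COUNTS = (3, 9, 12, 29, 49)

#: Weighted-mean-displacement bin edges (mm) mapping motion to grades 5..1.
DEFAULT_GRADE_THRESHOLDS_MM = (0.5, 1.0, 2.0, 4.0)

#: Reference lever arm converting rotations into displacement at the head surface.
DEFAULT_ROTATION_RADIUS_MM = 60.0


@dataclass
class Phantom:
    """Non-negative density on a regular isotropic 3-D grid."""

    density: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim != 3:
            raise ValueError("density must be 3-D")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate grids in mm, origin at the grid center."""
        axes = [
            (np.arange(s) - (s - 1) / 2.0) * self.spacing_mm for s in self.density.shape
        ]
        return np.meshgrid(*axes, indexing="ij")


@dataclass
class CoilArray:
    """Receive sensitivities (real, positive) and per-coil phases."""

    sensitivities: np.ndarray  # (n_channels, *grid)
    phases: np.ndarray  # (n_channels,)

    @property
    def n_channels(self) -> int:
        return self.sensitivities.shape[0]


@dataclass
class MotionTrajectory:
    """Per-TR rigid pose: translations (mm) and rotations (deg, xyz Euler)."""

    translations_mm: np.ndarray  # (n_tr, 3)
    rotations_deg: np.ndarray  # (n_tr, 3)
    profile: str = "still"

    def __post_init__(self) -> None:
        self.translations_mm = np.asarray(self.translations_mm, dtype=float)
        self.rotations_deg = np.asarray(self.rotations_deg, dtype=float)
        if self.translations_mm.shape != self.rotations_deg.shape or self.translations_mm.shape[1:] != (3,):
            raise ValueError("translations and rotations must both be (n_tr, 3)")
        if np.any(self.translations_mm[0] != 0) or np.any(self.rotations_deg[0] != 0):
            raise ValueError("pose at TR 1 must be identity")

    @property
    def n_tr(self) -> int:
        return self.translations_mm.shape[0]

    def is_identity(self, i: int) -> bool:
        return not (self.translations_mm[i].any() or self.rotations_deg[i].any())

    def scaled(self, factor: float) -> "MotionTrajectory":
        """Trajectory with all pose amplitudes scaled (small-angle linearization)."""
        return MotionTrajectory(
            self.translations_mm * factor, self.rotations_deg * factor, self.profile
        )

    def displacement_mm(self, radius_mm: float = DEFAULT_ROTATION_RADIUS_MM) -> np.ndarray:
        """Per-TR mean displacement of six surface reference points.

        Points sit at ``+-radius`` on each axis so both translations and
        rotations contribute.
        """
        pts = radius_mm * np.concatenate([np.eye(3), -np.eye(3)])
        rot = Rotation.from_euler("xyz", self.rotations_deg, degrees=True)
        disp = np.empty(self.n_tr)
        for i in range(self.n_tr):
            moved = rot[i].apply(pts) + self.translations_mm[i]
            disp[i] = np.linalg.norm(moved - pts, axis=1).mean()
        return disp


@dataclass(frozen=True)
class NoiseModel:
    """Additive disturbances, all relative to each channel's mean signal magnitude.

    ``noise_sd_rel`` — complex Gaussian SD; ``drift_rate_rel`` — maximum
    linear drift per TR; ``fluct_amp_rel`` / ``fluct_period_s`` —
    pseudo-physiological sinusoidal fluctuation (swallowing/breathing-like).
    """

    noise_sd_rel: float = 5e-4
    drift_rate_rel: float = 2e-4
    fluct_amp_rel: float = 1e-3
    fluct_period_s: float = 4.0

    def __post_init__(self) -> None:
        if self.noise_sd_rel < 0 or self.drift_rate_rel < 0 or self.fluct_amp_rel < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.fluct_period_s <= 0:
            raise ValueError("fluctuation period must be positive")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(noise_sd_rel=0.0, drift_rate_rel=0.0, fluct_amp_rel=0.0)


def make_phantom(
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    semi_axes_mm: tuple[float, float, float] = (60.0, 75.0, 65.0),
    spacing_mm: float = 6.0,
    smooth_voxels: float = 0.5,
) -> Phantom:
    """Ellipsoidal head phantom: indicator density, optionally edge-smoothed."""
    extents = [(s - 1) / 2.0 * spacing_mm for s in grid_shape]
    for ax, ext in zip(semi_axes_mm, extents):
        if ax > ext:
            raise ValueError(f"semi-axis {ax} mm exceeds grid half-extent {ext} mm")
    axes = [
        (np.arange(s) - (s - 1) / 2.0) * spacing_mm for s in grid_shape
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    if all(a == 0 for a in semi_axes_mm):
        density = np.zeros(grid_shape)
    else:
        q = sum(
            (c / a) ** 2 if a > 0 else np.where(c == 0, 0.0, np.inf)
            for c, a in zip((xx, yy, zz), semi_axes_mm)
        )
        density = (q <= 1.0).astype(float)
        if smooth_voxels > 0:
            density = ndimage.gaussian_filter(density, smooth_voxels)
    return Phantom(density=density, spacing_mm=spacing_mm)


def make_coil_array(
    phantom: Phantom,
    n_channels: int = DEFAULT_N_CHANNELS,
    ring_radius_mm: float = 110.0,
    n_rings: int = 4,
    profile_sigma_mm: float = 55.0,
    seed: int = 0,
) -> CoilArray:
    """Ring array of Gaussian sensitivity profiles around the head.

    Coil centers sit on ``n_rings`` circles of a cylinder of radius
    ``ring_radius_mm`` around the z axis, with a small seeded jitter;
    each sensitivity is an isotropic Gaussian of scale ``profile_sigma_mm``
    centered on the coil, and each coil carries a seeded random phase.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    zmax = (phantom.density.shape[2] - 1) / 2.0 * phantom.spacing_mm
    ring_z = np.linspace(-0.7 * zmax, 0.7 * zmax, n_rings)
    centers = []
    for k in range(n_channels):
        ring = k % n_rings
        idx_in_ring = k // n_rings
        per_ring = int(np.ceil(n_channels / n_rings))
        angle = 2 * np.pi * idx_in_ring / per_ring + ring * np.pi / per_ring
        angle += rng.normal(0, 0.03)
        r = ring_radius_mm * (1 + rng.normal(0, 0.02))
        centers.append(
            [r * np.cos(angle), r * np.sin(angle), ring_z[ring] + rng.normal(0, 3.0)]
        )
    centers = np.array(centers)
    xx, yy, zz = phantom.coords_mm()
    sens = np.empty((n_channels, *phantom.density.shape))
    for j, c in enumerate(centers):
        d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
        sens[j] = np.exp(-0.5 * d2 / profile_sigma_mm**2)
    phases = rng.uniform(0, 2 * np.pi, size=n_channels)
    return CoilArray(sensitivities=sens, phases=phases)


def sample_trajectory(
    profile: str,
    magnitude_mm_deg: float,
    n_tr: int,
    event_times: list[int] | None = None,
    seed: int = 0,
) -> MotionTrajectory:
    """Rigid 6-DOF trajectory of one of four pediatric motion archetypes.

    ``still`` — identity throughout; ``drift`` — linear ramp reaching
    ``magnitude`` (mm translation and deg rotation along seeded random
    directions) at the last TR; ``abrupt`` — step change(s) of ``magnitude``
    at each of ``event_times``; ``continuous`` — seeded random walk whose
    RMS excursion is ~``magnitude``.
    """
    if n_tr < 1:
        raise ValueError("n_tr must be >= 1")
    rng = np.random.default_rng(seed)
    trans = np.zeros((n_tr, 3))
    rot = np.zeros((n_tr, 3))

    def unit3() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    if profile == "still":
        pass
    elif profile == "drift":
        ramp = np.linspace(0, 1, n_tr)
        trans = np.outer(ramp, magnitude_mm_deg * unit3())
        rot = np.outer(ramp, magnitude_mm_deg * unit3())
    elif profile == "abrupt":
        if not event_times:
            event_times = [max(2, n_tr // 2)]
        for t in event_times:
            if not 2 <= t <= n_tr:
                raise ValueError(f"event time {t} outside [2, {n_tr}]")
            trans[t - 1 :] += magnitude_mm_deg * unit3()
            rot[t - 1 :] += magnitude_mm_deg * unit3()
    elif profile == "continuous":
        # mean-reverting random walk: restless subjects wander around their
        # resting pose, so excursion and per-TR speed stay coupled
        theta = 0.15
        sigma = magnitude_mm_deg * np.sqrt(2 * theta) / np.sqrt(3)
        for arr in (trans, rot):
            steps = rng.normal(0, sigma, size=(n_tr - 1, 3))
            for t in range(1, n_tr):
                arr[t] = arr[t - 1] * (1 - theta) + steps[t - 1]
    else:
        raise ValueError(f"unknown motion profile {profile!r}")
    return MotionTrajectory(trans, rot, profile=profile)


def _base_signal(phantom: Phantom, coils: CoilArray) -> np.ndarray:
    flat = phantom.density.reshape(-1)
    sens_flat = coils.sensitivities.reshape(coils.n_channels, -1)
    return (sens_flat @ flat) * np.exp(1j * coils.phases)


def _transformed_density(phantom: Phantom, t_mm: np.ndarray, r_deg: np.ndarray) -> np.ndarray:
    """Phantom density resampled under the rigid head pose (R, t), trilinear."""
    rot = Rotation.from_euler("xyz", r_deg, degrees=True).as_matrix()
    r_inv = rot.T
    shape = np.array(phantom.density.shape)
    center = (shape - 1) / 2.0
    offset = center - r_inv @ center - r_inv @ (np.asarray(t_mm) / phantom.spacing_mm)
    return ndimage.affine_transform(
        phantom.density, r_inv, offset=offset, order=1, mode="constant", cval=0.0
    )


def forward_fidnav(
    phantom: Phantom,
    coils: CoilArray,
    trajectory: MotionTrajectory,
    tr_seconds: float = DEFAULT_TR_SECONDS,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> FidnavSeries:
    """Simulate the per-TR, per-channel complex navigator signal of one scan."""
    n_tr = trajectory.n_tr
    n_c = coils.n_channels
    sens_flat = coils.sensitivities.reshape(n_c, -1)
    phase = np.exp(1j * coils.phases)
    base = _base_signal(phantom, coils)

    signal = np.empty((n_c, n_tr), dtype=complex)
    for i in range(n_tr):
        if trajectory.is_identity(i):
            signal[:, i] = base
        else:
            dens = _transformed_density(
                phantom, trajectory.translations_mm[i], trajectory.rotations_deg[i]
            )
            signal[:, i] = (sens_flat @ dens.reshape(-1)) * phase

    rng = np.random.default_rng(seed)
    mean_mag = np.abs(base)
    tr_idx = np.arange(n_tr)
    drift_rate = rng.uniform(-1, 1, size=n_c) * noise.drift_rate_rel
    signal += (mean_mag * drift_rate)[:, None] * tr_idx[None, :] * phase[:, None]
    if noise.fluct_amp_rel > 0:
        psi = rng.uniform(0, 2 * np.pi, size=n_c)
        fluct = np.sin(
            2 * np.pi * tr_idx[None, :] * tr_seconds / noise.fluct_period_s + psi[:, None]
        )
        signal += noise.fluct_amp_rel * mean_mag[:, None] * fluct * phase[:, None]
    if noise.noise_sd_rel > 0:
        sd = noise.noise_sd_rel * mean_mag.mean()
        signal += sd * (rng.normal(size=(n_c, n_tr)) + 1j * rng.normal(size=(n_c, n_tr)))
    return FidnavSeries(signal=signal, tr_seconds=tr_seconds)


def kspace_weights_from_phantom(phantom: Phantom, n_steps: int) -> KspaceWeighting:
    """Reference partition weighting from the noiseless phantom k-space.

    Plane norms of the 3-D FFT of the density along the outer phase-encoding
    axis (center plane mid-acquisition, matching a linear Cartesian
    ordering) are interpolated to ``n_steps`` acquisition steps and
    normalized to unit mean.
    """
    k = np.fft.fftshift(np.fft.fftn(phantom.density))
    norms = np.sqrt((np.abs(k) ** 2).reshape(k.shape[0], -1).sum(axis=1))
    src = np.linspace(0, 1, len(norms))
    dst = np.linspace(0, 1, n_steps)
    w = np.interp(dst, src, norms)
    return KspaceWeighting(w / w.mean(), source="noiseless phantom k-space")


def grade_from_trajectory(
    trajectory: MotionTrajectory,
    weights: KspaceWeighting,
    thresholds_mm: tuple[float, ...] = DEFAULT_GRADE_THRESHOLDS_MM,
    radius_mm: float = DEFAULT_ROTATION_RADIUS_MM,
) -> int:
    """Ground-truth image grade from the k-space-weighted mean displacement.

    The per-TR displacement of surface reference points is weighted by the
    k-space energy of the step acquired at that TR and averaged; the result
    is binned by ``thresholds_mm`` into grades 5 (below the first edge,
    negligible motion) down to 1 (above the last edge, severe motion).
    """
    if len(thresholds_mm) != 4 or np.any(np.diff(thresholds_mm) <= 0):
        raise ValueError("thresholds must be 4 strictly increasing values")
    if len(weights) != trajectory.n_tr:
        raise ValueError("weights length must equal trajectory length")
    d = _weighted_displacement(trajectory, weights, radius_mm)
    return int(5 - np.searchsorted(thresholds_mm, d, side="right"))


def _weighted_displacement(
    trajectory: MotionTrajectory, weights: KspaceWeighting, radius_mm: float
) -> float:
    disp = trajectory.displacement_mm(radius_mm)
    return float((weights.w * disp).sum() / weights.w.sum())


# Per-grade motion archetype mix: severe movers are continuously restless,
# while single abrupt repositionings and slow drifts — which impair quality
# but produce weaker per-TR signal changes — populate the moderate grades.
_GRADE_PROFILES: dict[int, list[tuple[str, float]]] = {
    5: [("still", 0.5), ("continuous", 0.5)],
    4: [("continuous", 0.7), ("drift", 0.3)],
    3: [("continuous", 0.5), ("drift", 0.25), ("abrupt", 0.25)],
    2: [("continuous", 1.0)],
    1: [("continuous", 1.0)],
}


def _target_displacement_range(
    grade: int, thresholds_mm: tuple[float, ...]
) -> tuple[float, float]:
    edges = (0.05, *thresholds_mm, 1.3 * thresholds_mm[-1])
    lo, hi = edges[5 - grade], edges[6 - grade]
    # sample from the central half of each bin: keeps grade archetypes
    # distinct and robust to resampling error at the bin edges
    margin = 0.25 * (hi - lo)
    return lo + margin, hi - margin


def _trajectory_for_grade(
    grade: int,
    n_tr: int,
    weights: KspaceWeighting,
    thresholds_mm: tuple[float, ...],
    radius_mm: float,
    rng: np.random.Generator,
) -> MotionTrajectory:
    """Sample a trajectory whose weighted displacement lands in the grade's bin."""
    profiles, probs = zip(*_GRADE_PROFILES[grade])
    profile = rng.choice(profiles, p=probs)
    if grade == 5 and profile == "still":
        return sample_trajectory("still", 0.0, n_tr, seed=int(rng.integers(2**31)))
    lo, hi = _target_displacement_range(grade, thresholds_mm)
    target = rng.uniform(lo, hi)
    # cap on the instantaneous excursion a head can plausibly reach in-coil;
    # trajectories whose rescaling would exceed it are resampled
    cap_mm = max(25.0, 3.0 * hi)
    for _ in range(20):
        event_times = None
        if profile == "abrupt":
            # events in the middle half of the scan, where enough k-space
            # weight remains for the event to plausibly degrade the image
            event_times = sorted(
                int(t) for t in rng.integers(n_tr // 4, 3 * n_tr // 4, size=rng.integers(1, 3))
            )
        traj = sample_trajectory(
            profile, 1.0, n_tr, event_times=event_times, seed=int(rng.integers(2**31))
        )
        # displacement is linear in translations and near-linear in the small
        # rotations used here, so a few rescalings converge onto the target
        ok = False
        for _ in range(4):
            d = _weighted_displacement(traj, weights, radius_mm)
            if d == 0:
                break
            if abs(d - target) / target < 0.01:
                ok = True
                break
            traj = traj.scaled(target / d)
        if ok and traj.displacement_mm(radius_mm).max() <= cap_mm:
            return traj
    return traj


def generate_cohort(
    out_dir: str | Path,
    n_subjects: int = 102,
    grade_mix: tuple[float, ...] | None = None,
    n_tr: int = DEFAULT_N_TR_RAW,
    tr_seconds: float = DEFAULT_TR_SECONDS,
    n_channels: int = DEFAULT_N_CHANNELS,
    n_discard: int = DEFAULT_N_DISCARD,
    noise: NoiseModel = NoiseModel(),
    grade_thresholds_mm: tuple[float, ...] = DEFAULT_GRADE_THRESHOLDS_MM,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (32, 32, 32),
) -> pd.DataFrame:
    """Simulate a cohort of navigator scans and write it to ``out_dir``.

    ``grade_mix`` gives target proportions for grades 1..5 (default: the
    emulated study's 3:9:12:29:49 distribution); subject counts per grade are
    apportioned by largest remainder so they sum to ``n_subjects``.  Writes
    one navigator CSV + JSON sidecar per subject and ``manifest.csv`` with
    subject id, file path, true grade, motion profile, magnitude and per-
    subject seed.  Fully reproducible from ``seed``.  Returns the manifest.
    """
    if grade_mix is None:
        grade_mix = tuple(c / sum(DEFAULT_GRADE_COUNTS) for c in DEFAULT_GRADE_COUNTS)
    grade_mix = np.asarray(grade_mix, dtype=float)
    if grade_mix.shape != (5,) or abs(grade_mix.sum() - 1.0) > 1e-9:
        raise ValueError("grade_mix must be 5 proportions summing to 1")
    raw = grade_mix * n_subjects
    counts = np.floor(raw).astype(int)
    remainder = n_subjects - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    if n_subjects < np.count_nonzero(grade_mix):
        raise ValueError("fewer subjects than nonzero grade bins")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # keep the physical head size fixed regardless of grid resolution
    spacing = 6.0 * 31.0 / (min(grid_shape) - 1)
    phantom = make_phantom(grid_shape=grid_shape, spacing_mm=spacing)
    coils = make_coil_array(phantom, n_channels=n_channels, seed=seed)
    n_steps = n_tr - n_discard
    weights = kspace_weights_from_phantom(phantom, n_steps)

    # weights for grading cover the retained TRs; the transient prefix is
    # identity motion and does not contribute
    rows = []
    sid = 0
    root_ss = np.random.SeedSequence(seed)
    grades_expanded = [g for g, c in zip(range(1, 6), counts) for _ in range(c)]
    subject_seeds = root_ss.spawn(len(grades_expanded))
    from fidnav.io import write_navigator_csv  # local import to avoid a cycle

    for grade, sseq in zip(grades_expanded, subject_seeds):
        sid += 1
        subject_id = f"S{sid:03d}"
        rng = np.random.default_rng(sseq)
        traj_body = _trajectory_for_grade(
            grade, n_steps, weights, grade_thresholds_mm, DEFAULT_ROTATION_RADIUS_MM, rng
        )
        # identity prefix over the pre-steady-state TRs that the pipeline discards
        traj = MotionTrajectory(
            np.vstack([np.zeros((n_discard, 3)), traj_body.translations_mm]),
            np.vstack([np.zeros((n_discard, 3)), traj_body.rotations_deg]),
            profile=traj_body.profile,
        )
        series = forward_fidnav(
            phantom, coils, traj, tr_seconds=tr_seconds, noise=noise,
            seed=int(rng.integers(2**31)),
        )
        series.n_steps = n_steps
        path = out_dir / f"{subject_id}.csv"
        write_navigator_csv(series, path, subject_id=subject_id)
        magnitude = float(traj_body.displacement_mm().max())
        check_grade = grade_from_trajectory(traj_body, weights, grade_thresholds_mm)
        rows.append(
            {
                "subject_id": subject_id,
                "path": path.name,
                "grade": grade,
                "grade_check": check_grade,
                "profile": traj_body.profile,
                "magnitude_mm": magnitude,
                "seed": int(sseq.entropy) if isinstance(sseq.entropy, int) else seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    params = {
        "n_subjects": n_subjects,
        "n_tr": n_tr,
        "tr_seconds": tr_seconds,
        "n_channels": n_channels,
        "n_discard": n_discard,
        "seed": seed,
        "grade_thresholds_mm": list(grade_thresholds_mm),
    }
    (out_dir / "cohort.json").write_text(json.dumps(params, indent=2))
    pd.DataFrame({"step_index": np.arange(1, n_steps + 1), "weight": weights.w}).to_csv(
        out_dir / "weights.csv", index=False
    )
    return manifest
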