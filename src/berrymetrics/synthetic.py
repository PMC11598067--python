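"""Synthetic grape bunches with occlusion, and a detector-error emulator.

The generator builds 3-D bunches of near-spherical berries so that every
stage of the validation pipeline can be exercised without images:

* berry count M uniform over a per-bunch range (default 36-76);
* berry radii from a truncated normal (default 9.5 +/- 0.45 mm, truncated
  at zero, matching the per-bunch means of the manual caliper measurements);
* berry centers packed into an ellipsoidal envelope by random sequential
  addition, with a small allowed overlap (berries in a real bunch press
  into one another);
* three views at 0/120/240 degree rotations about the vertical bunch axis,
  projected weak-perspective (single depth d for scale; per-berry depth
  orders occlusion only);
* a berry is visible in a view iff less than ``occlusion_threshold`` of its
  projected disc is covered by the union of nearer berries' discs (coverage
  estimated on a fixed deterministic polar grid).

The detector emulator perturbs ground-truth annotations with the error laws
measured for the validated counting network: count error N(-1.57, 1.9^2)
berries (rounded to an integer, floored at zero) and mean-radius error
N(0.15, 1.5^2) px.

``run_recovery_experiment`` closes the loop: estimate the total/visible
ratio R on a disjoint calibration subset, push emulated detections through
the volume and uncertainty chain, and score recovered whole-bunch volumes
against the generator's truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .camera import CameraModel, px_to_mm_factor
from .datasets import ViewAnnotation, ViewEstimate, VIEW_ANGLES_DEG
from .extrapolation import ErrorModel
from .metrics import coefficient_of_variability
from .uncertainty import (
    UncertaintySource,
    compatibility_check,
    estimator_rmse_sigma,
    propagate_power_product,
)
from .units import Quantity
from .volume import (
    RatioEstimate,
    bunch_volume_reference,
    ratio_R,
    total_volume_estimated,
    visible_volume_estimated,
    visible_volume_reference,
)

#: Default count-error law of the emulated detector, berries.
DEFAULT_COUNT_ERROR = ErrorModel(me=-1.57, sigma_e=1.9)


@dataclass(frozen=True)
class RadiusErrorModel:
    """Additive error law for the estimated mean radius, px."""

    bias_px: float = 0.15
    sd_px: float = 1.5

    def __post_init__(self) -> None:
        if self.sd_px < 0:
            raise ValueError("sd_px must be >= 0")


DEFAULT_RADIUS_ERROR = RadiusErrorModel()


class PackingError(RuntimeError):
    """Berry packing failed; retry with a larger envelope or fewer berries."""


@dataclass(frozen=True)
class SyntheticBunchParams:
    """Generator settings for one synthetic bunch.

    ``envelope`` (ellipsoid semi-axes, mm) defaults to an automatically sized
    prolate ellipsoid giving packing fraction ``packing_fraction``; real
    bunches differ in compactness and elongation, so both the packing
    fraction and the aspect ratio get a per-bunch uniform jitter
    (``packing_jitter``, ``aspect_jitter`` half-widths) which drives the
    between-image spread of the total/visible ratio R.  ``overlap_factor``
    is the allowed center-distance fraction of the radius sum (0.85 lets
    neighbouring berries press together by 15%).
    """

    n_berries_range: tuple[int, int] = (36, 76)
    r_mean_mm: float = 9.5
    r_sd_mm: float = 0.45
    envelope: Optional[tuple[float, float, float]] = None
    packing_fraction: float = 0.35
    packing_jitter: float = 0.07
    aspect: float = 1.4
    aspect_jitter: float = 0.35
    overlap_factor: float = 0.85
    occlusion_threshold: float = 0.75
    focal_px: float = 1150.0
    distance_mm: float = 500.0
    max_attempts_per_berry: int = 5000

    def __post_init__(self) -> None:
        lo, hi = self.n_berries_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad berry-count range {self.n_berries_range}")
        if self.r_mean_mm <= 0 or self.r_sd_mm < 0:
            raise ValueError("radius parameters must be positive")
        if self.r_sd_mm >= self.r_mean_mm / 3:
            raise ValueError("r_sd_mm must stay below r_mean_mm/3 to keep radii positive")
        if not 0 < self.occlusion_threshold <= 1:
            raise ValueError("occlusion_threshold must be in (0, 1]")
        if not 0 < self.overlap_factor <= 1:
            raise ValueError("overlap_factor must be in (0, 1]")
        if self.packing_jitter < 0 or self.packing_jitter >= self.packing_fraction:
            raise ValueError("packing_jitter must be in [0, packing_fraction)")
        if self.aspect_jitter < 0 or self.aspect_jitter >= self.aspect - 1.0:
            raise ValueError("aspect_jitter must keep the aspect ratio above 1")
        if self.focal_px <= 0 or self.distance_mm <= 0:
            raise ValueError("camera parameters must be positive")

    def camera(self) -> CameraModel:
        return CameraModel(focal_px=self.focal_px, distance_mm=self.distance_mm)


@dataclass
class SyntheticScene:
    """A packed 3-D bunch with its per-view visibility and true ratios R."""

    bunch_id: str
    params: SyntheticBunchParams
    seed: int
    centers_mm: np.ndarray  # (M, 3), bunch frame, z vertical
    radii_mm: np.ndarray  # (M,)
    camera: CameraModel
    visible: dict[int, np.ndarray] = field(default_factory=dict)  # view -> index array
    true_r: dict[int, float] = field(default_factory=dict)  # view -> V_total/V_visible

    @property
    def n_berries(self) -> int:
        return int(self.radii_mm.size)

    @property
    def v_total_mm3(self) -> float:
        return bunch_volume_reference(self.radii_mm)


# fixed polar grid for disc-coverage estimation: area-uniform rings
_N_RINGS, _N_ANGLES = 4, 12
_ring = np.sqrt((np.arange(_N_RINGS) + 0.5) / _N_RINGS)
_ang = 2.0 * math.pi * (np.arange(_N_ANGLES) + 0.5) / _N_ANGLES
_GRID = np.stack(
    [np.outer(_ring, np.cos(_ang)).ravel(), np.outer(_ring, np.sin(_ang)).ravel()], axis=1
)  # (48, 2) unit-disc sample points


def _rotate_z(points: np.ndarray, angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    rot = np.array([[math.cos(a), -math.sin(a), 0.0], [math.sin(a), math.cos(a), 0.0], [0.0, 0.0, 1.0]])
    return points @ rot.T


def _visible_indices(
    centers: np.ndarray, radii: np.ndarray, threshold: float
) -> np.ndarray:
    """Visibility by disc-union coverage; camera looks along +x (smaller x nearer)."""
    depth = centers[:, 0]
    proj = centers[:, 1:3]  # weak perspective: (y, z), scale irrelevant for coverage
    order = np.argsort(depth, kind="stable")
    visible = []
    for rank, i in enumerate(order):
        nearer = order[:rank]
        if nearer.size == 0:
            visible.append(i)
            continue
        pts = proj[i] + radii[i] * _GRID  # (48, 2), mm
        d2 = np.sum((pts[:, None, :] - proj[nearer][None, :, :]) ** 2, axis=2)
        covered = np.any(d2 < radii[nearer][None, :] ** 2, axis=1)
        if covered.mean() < threshold:
            visible.append(i)
    return np.sort(np.asarray(visible, dtype=int))


def _pack(
    rng: np.random.Generator,
    radii: np.ndarray,
    order: np.ndarray,
    semi: np.ndarray,
    params: SyntheticBunchParams,
) -> Optional[np.ndarray]:
    """Random sequential addition inside the ellipsoid; None if jammed."""
    centers = np.empty((radii.size, 3))
    placed: list[int] = []
    for i in order:
        r = radii[i]
        room = semi - r
        if np.any(room <= 0):
            raise PackingError(f"berry radius {r:.1f} mm exceeds envelope {semi}")
        for _ in range(params.max_attempts_per_berry):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            u = rng.uniform() ** (1.0 / 3.0)
            cand = v * u * room
            if placed:
                d = np.linalg.norm(centers[placed] - cand, axis=1)
                if np.any(d < params.overlap_factor * (radii[placed] + r)):
                    continue
            centers[i] = cand
            placed.append(i)
            break
        else:
            return None
    return centers


def generate_bunch(
    params: SyntheticBunchParams = SyntheticBunchParams(),
    seed: int = 0,
    bunch_id: str = "synthetic",
) -> SyntheticScene:
    """Generate one reproducible synthetic bunch with its three views.

    Raises :class:`PackingError` if a berry cannot be placed within the
    attempt budget (remedy: larger envelope or lower packing fraction).
    """
    rng = np.random.default_rng(seed)
    lo, hi = params.n_berries_range
    m = int(rng.integers(lo, hi + 1))
    a_trunc = (0.0 - params.r_mean_mm) / params.r_sd_mm if params.r_sd_mm > 0 else -np.inf
    if params.r_sd_mm > 0:
        radii = truncnorm.rvs(
            a_trunc, np.inf, loc=params.r_mean_mm, scale=params.r_sd_mm, size=m, random_state=rng
        )
    else:
        radii = np.full(m, params.r_mean_mm)

    if params.envelope is not None:
        ax, ay, az = params.envelope
    else:
        # per-bunch compactness/elongation jitter, then size for the packing fraction
        phi = params.packing_fraction + rng.uniform(-params.packing_jitter, params.packing_jitter)
        aspect = params.aspect + rng.uniform(-params.aspect_jitter, params.aspect_jitter)
        ax = ay = params.r_mean_mm * (m / (aspect * phi)) ** (1.0 / 3.0)
        az = aspect * ax
    semi = np.array([ax, ay, az])

    order = np.argsort(radii)[::-1]  # place large berries first
    # auto-sized envelopes relax by 5% and repack on a jam; explicit ones fail loudly
    max_relaxations = 0 if params.envelope is not None else 6
    centers = None
    for relaxation in range(max_relaxations + 1):
        centers = _pack(rng, radii, order, semi * 1.05**relaxation, params)
        if centers is not None:
            break
    if centers is None:
        raise PackingError(
            f"could not pack {m} berries after {params.max_attempts_per_berry} attempts "
            f"per berry; increase the envelope or reduce packing_fraction"
        )

    scene = SyntheticScene(
        bunch_id=bunch_id,
        params=params,
        seed=int(seed),
        centers_mm=centers,
        radii_mm=np.asarray(radii, dtype=float),
        camera=params.camera(),
    )
    v_total = scene.v_total_mm3
    for view in VIEW_ANGLES_DEG:
        idx = _view_visible(scene, view, params.occlusion_threshold)
        scene.visible[view] = idx
        v_vis = bunch_volume_reference(scene.radii_mm[idx]) if idx.size else 0.0
        scene.true_r[view] = v_total / v_vis if v_vis > 0 else math.inf
    return scene


def _view_visible(scene: SyntheticScene, view_index: int, threshold: float) -> np.ndarray:
    if view_index not in VIEW_ANGLES_DEG:
        raise ValueError(f"view_index must be in {{1,2,3}}, got {view_index}")
    rotated = _rotate_z(scene.centers_mm, VIEW_ANGLES_DEG[view_index])
    return _visible_indices(rotated, scene.radii_mm, threshold)


def project_view(
    scene: SyntheticScene, view_index: int, occlusion_threshold: Optional[float] = None
) -> ViewAnnotation:
    """Ground-truth annotation of one view: visible count and mean radius in px.

    Radii convert per the weak-perspective rule r_px = r_mm * f / d.
    """
    thr = scene.params.occlusion_threshold if occlusion_threshold is None else occlusion_threshold
    if not 0 < thr <= 1:
        raise ValueError("occlusion_threshold must be in (0, 1]")
    if occlusion_threshold is None and view_index in scene.visible:
        idx = scene.visible[view_index]
    else:
        idx = _view_visible(scene, view_index, thr)
    scale = scene.camera.focal_px / scene.camera.distance_mm
    radii_px = scene.radii_mm[idx] * scale
    return ViewAnnotation(
        bunch_id=scene.bunch_id,
        view_index=view_index,
        n_visible=int(idx.size),
        r_mean_px=float(np.mean(radii_px)),
        per_berry_radii_px=tuple(float(r) for r in radii_px),
    )


def emulate_detector(
    annotation: ViewAnnotation,
    count_err: ErrorModel = DEFAULT_COUNT_ERROR,
    radius_err: RadiusErrorModel = DEFAULT_RADIUS_ERROR,
    seed: int | np.random.Generator = 0,
) -> ViewEstimate:
    """Perturb a ground-truth annotation with the detector's error laws.

    Counts are integers: the normal count error is rounded and the result
    floored at zero.  The mean radius stays strictly positive.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_est = max(0, annotation.n_visible + int(round(rng.normal(count_err.me, count_err.sigma_e))))
    r_est = annotation.r_mean_px + rng.normal(radius_err.bias_px, radius_err.sd_px)
    r_est = max(r_est, 1e-6)
    return ViewEstimate(
        bunch_id=annotation.bunch_id,
        view_index=annotation.view_index,
        n_est=n_est,
        r_mean_est_px=float(r_est),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of a synthetic end-to-end volume-recovery experiment."""

    n_bunches: int
    n_eval_views: int
    ratio: RatioEstimate
    coverage: float  # fraction of eval views passing the k=2 compatibility check
    volume_me_mm3: float
    volume_mpe_pct: float
    volume_mpe_se_pct: float  # Monte Carlo standard error of the MPE
    mean_cov_pct: float  # mean per-bunch coefficient of variability
    table: pd.DataFrame


def run_recovery_experiment(
    n_bunches: int = 200,
    params: SyntheticBunchParams = SyntheticBunchParams(),
    count_err: ErrorModel = DEFAULT_COUNT_ERROR,
    radius_err: RadiusErrorModel = DEFAULT_RADIUS_ERROR,
    seed: int = 0,
    calib_fraction: float = 0.3,
    exact_r: bool = False,
    per_berry_reference: bool = False,
    coverage_k: float = 2.0,
) -> RecoveryReport:
    """Generate bunches, emulate detections, recover volumes, score coverage.

    The total/visible ratio R and the type-A uncertainty of the estimated
    visible pixel volume are fitted on a disjoint calibration subset
    (``calib_fraction`` of the bunches); the remaining bunches are scored.
    With ``exact_r=True`` each view uses its own true ratio, and with
    ``per_berry_reference=True`` the visible pixel volume is the per-berry
    reference sum instead of the detector's mean-radius form — together with
    zero error models this recovers every volume exactly.
    """
    if n_bunches < 2:
        raise ValueError("need at least 2 bunches (calibration + evaluation)")
    n_calib = max(1, int(round(calib_fraction * n_bunches)))
    if n_calib >= n_bunches:
        raise ValueError("calibration subset must leave at least one evaluation bunch")

    root = np.random.SeedSequence(seed)
    scene_seeds, det_seed = root.spawn(2)
    det_rng = np.random.default_rng(det_seed)
    scenes = [
        generate_bunch(params, seed=s.generate_state(1)[0] % (2**31), bunch_id=f"synth_{i:04d}")
        for i, s in enumerate(scene_seeds.spawn(n_bunches))
    ]
    calib, evalset = scenes[:n_calib], scenes[n_calib:]

    camera = params.camera()
    c = px_to_mm_factor(camera)
    scale = camera.focal_px / camera.distance_mm

    # --- calibration: ratio R and type-A sigma of the visible pixel volume
    pairs = []
    est_px, ref_px = [], []
    for scene in calib:
        for view in VIEW_ANGLES_DEG:
            ann = project_view(scene, view)
            v_vis_mm = bunch_volume_reference(scene.radii_mm[scene.visible[view]])
            pairs.append((scene.v_total_mm3, v_vis_mm))
            det = emulate_detector(ann, count_err, radius_err, seed=det_rng)
            est_px.append(visible_volume_estimated(det.n_est, det.r_mean_est_px))
            ref_px.append(visible_volume_reference(np.asarray(ann.per_berry_radii_px)))
    ratio = ratio_R(pairs)
    v_px_sigma = estimator_rmse_sigma(est_px, ref_px).sigma

    # --- evaluation
    rows = []
    for scene in evalset:
        for view in VIEW_ANGLES_DEG:
            ann = project_view(scene, view)
            det = emulate_detector(ann, count_err, radius_err, seed=det_rng)
            if per_berry_reference:
                v_vis_px = visible_volume_reference(np.asarray(ann.per_berry_radii_px))
            else:
                v_vis_px = visible_volume_estimated(det.n_est, det.r_mean_est_px)
            r_used = scene.true_r[view] if exact_r else ratio.r_mean
            r_sigma = 0.0 if exact_r else ratio.r_sigma
            v_est = total_volume_estimated(v_vis_px, c, r_used)
            v_true = scene.v_total_mm3
            err = v_est - v_true

            sources = [
                UncertaintySource("v_visible_px", Quantity(v_vis_px, v_px_sigma, "px3"), 1),
                UncertaintySource(
                    "d", Quantity(camera.distance_mm, camera.distance_sigma_mm, "mm"), 3
                ),
                UncertaintySource("f", Quantity(camera.focal_px, camera.focal_sigma_px, "px"), -3),
                UncertaintySource("R", Quantity(r_used, r_sigma, "dimensionless"), 1),
            ]
            sigma = propagate_power_product(sources).relative_sigma * v_est
            rows.append(
                {
                    "bunch_id": scene.bunch_id,
                    "view_index": view,
                    "v_true_mm3": v_true,
                    "v_est_mm3": v_est,
                    "error_mm3": err,
                    "sigma_mm3": sigma,
                    "compatible": compatibility_check(err, sigma, k=coverage_k),
                }
            )

    table = pd.DataFrame(rows)
    pct = 100.0 * table["error_mm3"] / table["v_true_mm3"]
    covs = [
        coefficient_of_variability(grp["v_est_mm3"].to_numpy())
        for _, grp in table.groupby("bunch_id")
        if len(grp) >= 2
    ]
    return RecoveryReport(
        n_bunches=n_bunches,
        n_eval_views=len(table),
        ratio=ratio,
        coverage=float(table["compatible"].mean()),
        volume_me_mm3=float(table["error_mm3"].mean()),
        volume_mpe_pct=float(pct.mean()),
        volume_mpe_se_pct=float(pct.std(ddof=1) / math.sqrt(len(pct))) if len(pct) > 1 else 0.0,
        mean_cov_pct=float(np.mean(covs)) if covs else 0.0,
        table=table,
    )
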