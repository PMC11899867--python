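"""Synthetic vessel images, two-slab volumes and study-structured cohorts.

No imaging data accompany the study this pipeline reimplements, so every
stage is exercised against simulators with known ground truth:

* ``generate_vessel_image`` draws curvature-bounded random-walk centerlines,
  thickens them to sampled calibers and renders them over a noisy
  background, returning the exact pre-noise binary mask as ground truth.
* ``generate_volume`` stacks two independent networks into the superficial
  (0-200 um) and deep (200-1000 um) slabs of a depth volume so slab
  projection recovers each network.
* ``generate_cohort`` simulates the two-group, two-eyes-per-subject cohort:
  29 diseased and 21 control subjects by default, per-cell metric means/SDs
  at the magnitudes observed for anterior-segment OCTA (e.g. temporal-deep
  VD 0.344 +- 0.09 vs 0.296 +- 0.05), ages 46.2 +- 10.8 vs 32.7 +- 6.6, and
  a subject-level random effect inducing the within-subject correlation
  between fellow eyes.

All outputs are pure functions of their seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_stats import LAYERS, METRICS, REGIONS, classify_activity
from .layers import DEEP, SUPERFICIAL, DepthLayer, EnFaceImage, OCTAVolume
from .segmentation import VesselMask

__all__ = [
    "VesselSimParams",
    "CohortSimParams",
    "TABLE_CELL_STATS",
    "generate_vessel_image",
    "generate_volume",
    "generate_cohort",
    "null_cohort_params",
    "sierpinski_carpet",
    "bar_mask",
    "line_mask",
]


@dataclass(frozen=True)
class VesselSimParams:
    """Controls for one synthetic vessel-network frame.

    Defaults emulate a 3 x 3 mm conjunctival en-face frame on a 304 x 304
    grid: ~35% vessel area from vessels of ~2 px caliber running roughly
    parallel, the near-parallel centrifugal pattern of conjunctival
    vasculature within one quadrant.
    """

    frame: tuple[int, int] = (304, 304)
    n_vessels: int = 47
    width_mean: float = 2.2  # px
    width_sd: float = 0.3
    tortuosity: float = 0.15  # SD of per-step heading increment (radians)
    target_vd: float | None = None
    noise_sd: float = 8.0  # intensity units
    background_level: float = 40.0
    vessel_level: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_level <= self.background_level:
            raise ValueError("vessel_level must exceed background_level")
        if self.width_mean < 1:
            raise ValueError("vessel widths must be >= 1 px")
        if self.target_vd is not None and self.target_vd > 0.95:
            raise ValueError("target_vd > 0.95 is unreachable")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")


def _lane_centerline(
    rng: np.random.Generator,
    lane: float,
    max_dev: float,
    n_cols: int,
    tortuosity: float,
) -> np.ndarray:
    """Curvature-bounded random-walk centerline confined to its lane.

    The heading angle performs a mean-reverting random walk (increment SD =
    tortuosity) and the resulting vertical wander reflects off +-max_dev,
    so neighbouring vessels never cross — mirroring the near-parallel
    course of conjunctival vessels within one quadrant.
    """
    theta, dev = 0.0, 0.0
    pts = np.empty((n_cols, 2))
    for x in range(n_cols):
        pts[x] = (lane + dev, x)
        theta = 0.9 * theta + rng.normal(0.0, tortuosity)
        dev += np.tan(np.clip(theta, -1.2, 1.2))
        if dev > max_dev:
            dev, theta = max_dev, -abs(theta)
        elif dev < -max_dev:
            dev, theta = -max_dev, abs(theta)
    return pts


def _stamp(mask: np.ndarray, pts: np.ndarray, radius: float) -> None:
    """Mark all pixels within ``radius`` of any centerline point."""
    rows, cols = mask.shape
    r_int = int(np.ceil(radius))
    dy, dx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    disk = (dy**2 + dx**2) <= radius**2
    offs = np.stack([dy[disk], dx[disk]], axis=1)  # (k, 2)
    centers = np.rint(pts).astype(int)
    px = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    keep = (
        (px[:, 0] >= 0) & (px[:, 0] < rows) & (px[:, 1] >= 0) & (px[:, 1] < cols)
    )
    px = px[keep]
    mask[px[:, 0], px[:, 1]] = True


def generate_vessel_image(
    p: VesselSimParams = VesselSimParams(),
) -> tuple[EnFaceImage, VesselMask]:
    """Render a vessel network; return the image and its ground-truth mask.

    Vessels are laid out in horizontal lanes with curvature-bounded wander
    (they never touch, so the true centerline length is well defined even
    at study-like densities).  The stamped tubes get one binary median
    smoothing pass to remove rasterization bumps; that smoothed mask is the
    ground truth, rendered as vessel_level over background_level plus
    Gaussian noise.  With ``target_vd`` set, the lane count is derived from
    the target area fraction instead of ``n_vessels``.
    """
    from scipy import ndimage

    rng = np.random.default_rng(p.seed)
    rows, cols = p.frame
    mask = np.zeros((rows, cols), dtype=bool)

    n = p.n_vessels
    if p.target_vd is not None:
        # lane count from the target area fraction; rasterized tubes yield
        # ~7% more area than width_mean * length, hence the correction
        n = max(int(round(p.target_vd * rows / (1.07 * p.width_mean))), 1)
    if n > 0:
        spacing = rows / n
        lanes = (np.arange(n) + 0.5) * spacing + rng.uniform(
            -0.2 * spacing, 0.2 * spacing, n
        )
        for lane in lanes:
            width = max(float(rng.normal(p.width_mean, p.width_sd)), 1.0)
            max_dev = max(spacing / 2 - width / 2 - 0.7, 0.3)
            pts = _lane_centerline(rng, lane, max_dev, cols, p.tortuosity)
            _stamp(mask, pts, radius=width / 2.0)
        mask = ndimage.median_filter(mask, size=3)

    image = np.full((rows, cols), p.background_level, dtype=float)
    image[mask] = p.vessel_level
    if p.noise_sd > 0:
        image = image + rng.normal(0.0, p.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 255.0)
    img = EnFaceImage(pixels=image, metadata={"seed": p.seed, "synthetic": True})
    return img, VesselMask(pixels=mask)


def generate_volume(
    p_superficial: VesselSimParams,
    p_deep: VesselSimParams,
    axial_spacing: float = 10.0,
    n_depth: int = 100,
    layers: tuple[DepthLayer, DepthLayer] = (SUPERFICIAL, DEEP),
) -> tuple[OCTAVolume, VesselMask, VesselMask]:
    """Stack one independent network per depth slab into an OCTA volume.

    Voxels inside a slab take the slab network's rendered intensity at
    every depth sample, so both max and mean slab projections recover that
    network's en-face image.  Returns the volume and the two ground-truth
    masks (superficial, deep).
    """
    la, lb = layers
    if la.z_max > lb.z_min and lb.z_max > la.z_min:
        raise ValueError(f"slabs {la.name!r} and {lb.name!r} overlap")
    if n_depth * axial_spacing < lb.z_max:
        raise ValueError("volume depth extent does not cover both slabs")
    if p_superficial.frame != p_deep.frame:
        raise ValueError("both networks must share the frame size")

    img_a, mask_a = generate_vessel_image(p_superficial)
    img_b, mask_b = generate_vessel_image(p_deep)

    background = min(p_superficial.background_level, p_deep.background_level)
    vox = np.full((n_depth, *p_superficial.frame), background, dtype=float)
    z = (np.arange(n_depth) + 0.5) * axial_spacing
    for layer, img in ((la, img_a), (lb, img_b)):
        idx = np.flatnonzero((z >= layer.z_min) & (z < layer.z_max))
        vox[idx] = img.pixels[None, :, :]
    vol = OCTAVolume(
        voxels=vox,
        axial_spacing=axial_spacing,
        metadata={"synthetic": True},
    )
    return vol, mask_a, mask_b


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------

#: Per-cell (mean, SD) of each metric by group, at the magnitudes observed
#: for anterior-segment OCTA in the two conjunctival quadrants and depth
#: layers (pixel units: VD fraction, VLD 1/px, VDI px, FD unitless).
TABLE_CELL_STATS: dict[tuple[str, str, str, str], tuple[float, float]] = {
    # (metric, region, layer, group): (mean, sd)
    ("vd", "nasal", "superficial", "case"): (0.341, 0.07),
    ("vd", "nasal", "superficial", "control"): (0.364, 0.06),
    ("vd", "nasal", "deep", "case"): (0.330, 0.08),
    ("vd", "nasal", "deep", "control"): (0.302, 0.06),
    ("vd", "temporal", "superficial", "case"): (0.346, 0.07),
    ("vd", "temporal", "superficial", "control"): (0.339, 0.06),
    ("vd", "temporal", "deep", "case"): (0.344, 0.09),
    ("vd", "temporal", "deep", "control"): (0.296, 0.05),
    ("vld", "nasal", "superficial", "case"): (0.165, 0.03),
    ("vld", "nasal", "superficial", "control"): (0.177, 0.03),
    ("vld", "nasal", "deep", "case"): (0.171, 0.04),
    ("vld", "nasal", "deep", "control"): (0.165, 0.03),
    ("vld", "temporal", "superficial", "case"): (0.175, 0.03),
    ("vld", "temporal", "superficial", "control"): (0.168, 0.03),
    ("vld", "temporal", "deep", "case"): (0.180, 0.04),
    ("vld", "temporal", "deep", "control"): (0.163, 0.02),
    ("vdi", "nasal", "superficial", "case"): (2.06, 0.12),
    ("vdi", "nasal", "superficial", "control"): (2.05, 0.09),
    ("vdi", "nasal", "deep", "case"): (1.92, 0.13),
    ("vdi", "nasal", "deep", "control"): (1.83, 0.11),
    ("vdi", "temporal", "superficial", "case"): (1.97, 0.14),
    ("vdi", "temporal", "superficial", "control"): (2.02, 0.13),
    ("vdi", "temporal", "deep", "case"): (1.90, 0.16),
    ("vdi", "temporal", "deep", "control"): (1.83, 0.13),
    ("fd", "nasal", "superficial", "case"): (1.85, 0.031),
    ("fd", "nasal", "superficial", "control"): (1.85, 0.033),
    ("fd", "nasal", "deep", "case"): (1.85, 0.036),
    ("fd", "nasal", "deep", "control"): (1.85, 0.032),
    ("fd", "temporal", "superficial", "case"): (1.83, 0.04),
    ("fd", "temporal", "superficial", "control"): (1.84, 0.03),
    ("fd", "temporal", "deep", "case"): (1.83, 0.04),
    ("fd", "temporal", "deep", "control"): (1.83, 0.03),
}


def _uniform_cas_probs() -> np.ndarray:
    # uniform over 0..6: P(CAS >= 3) = 4/7 ~ 0.57, close to the ~55%
    # active-eye share of the emulated cohort
    p = np.zeros(8)
    p[:7] = 1.0 / 7.0
    return p


@dataclass(frozen=True)
class CohortSimParams:
    """Study-structured cohort: two groups, two eyes per subject."""

    n_case_subjects: int = 29
    n_control_subjects: int = 21
    eyes_per_subject: int = 2
    within_subject_corr: float = 0.5
    cell_stats: Mapping[tuple[str, str, str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE_CELL_STATS)
    )
    age_mean: Mapping[str, float] = field(
        default_factory=lambda: {"case": 46.2, "control": 32.7}
    )
    age_sd: Mapping[str, float] = field(
        default_factory=lambda: {"case": 10.8, "control": 6.6}
    )
    female_p: Mapping[str, float] = field(
        default_factory=lambda: {"case": 0.41, "control": 0.38}
    )
    cas_probs: np.ndarray = field(default_factory=_uniform_cas_probs)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.within_subject_corr < 1:
            raise ValueError("within_subject_corr must be in [0, 1)")
        for (_, _, _, _), (_, sd) in self.cell_stats.items():
            if sd <= 0:
                raise ValueError("cell SDs must be positive")


def null_cohort_params(
    effect: float = 0.0,
    effect_cell: tuple[str, str, str] = ("vd", "temporal", "deep"),
    **overrides,
) -> CohortSimParams:
    """Params with identical groups except an optional mean shift.

    Both groups share every cell mean/SD, age distribution and female
    probability, so the group coefficient's true value is exactly
    ``effect`` in the ``effect_cell`` (metric, region, layer) and 0
    elsewhere — the configuration for null calibration and coverage runs.
    """
    stats = {}
    for (metric, region, layer, _), (mean, sd) in TABLE_CELL_STATS.items():
        if _ != "case":
            continue
        for group in ("case", "control"):
            m = mean
            if group == "case" and (metric, region, layer) == effect_cell:
                m = mean + effect
            stats[(metric, region, layer, group)] = (m, sd)
    base = dict(
        cell_stats=stats,
        age_mean={"case": 40.0, "control": 40.0},
        age_sd={"case": 9.0, "control": 9.0},
        female_p={"case": 0.5, "control": 0.5},
    )
    base.update(overrides)
    return CohortSimParams(**base)


def generate_cohort(p: CohortSimParams = CohortSimParams()) -> pd.DataFrame:
    """Simulate the tidy eye-level cohort table.

    One row per subject x eye x region x layer with metric columns
    (vd, vld, vdi, fd).  A shared subject-level Gaussian effect contributes
    a fraction ``within_subject_corr`` of each cell variance, inducing that
    correlation between fellow eyes; the remainder is eye-level noise.
    CAS is sampled per diseased subject and the activity label follows the
    CAS >= 3 rule; controls carry no CAS.
    """
    rng = np.random.default_rng(p.seed)
    rho = p.within_subject_corr
    eyes = ["OD", "OS"][: p.eyes_per_subject]

    rows = []
    subject_counter = 0
    for group, n_subj in (
        ("case", p.n_case_subjects),
        ("control", p.n_control_subjects),
    ):
        for _ in range(n_subj):
            subject_counter += 1
            sid = f"S{subject_counter:04d}"
            age = rng.normal(p.age_mean[group], p.age_sd[group])
            gender = "female" if rng.random() < p.female_p[group] else "male"
            if group == "case":
                cas = int(rng.choice(8, p=p.cas_probs))
                activity = classify_activity(cas)
            else:
                cas, activity = None, "none"

            # subject-level effect per metric cell, shared across eyes
            z_subj = {
                (metric, region, layer): rng.normal()
                for metric in METRICS
                for region in REGIONS
                for layer in LAYERS
            }
            for eye in eyes:
                for region in REGIONS:
                    for layer in LAYERS:
                        rec = {
                            "subject_id": sid,
                            "eye": eye,
                            "group": group,
                            "age": age,
                            "gender": gender,
                            "cas": cas,
                            "activity": activity,
                            "region": region,
                            "layer": layer,
                        }
                        for metric in METRICS:
                            mean, sd = p.cell_stats[(metric, region, layer, group)]
                            val = mean + sd * (
                                np.sqrt(rho) * z_subj[(metric, region, layer)]
                                + np.sqrt(1.0 - rho) * rng.normal()
                            )
                            rec[metric] = val
                        rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Analytic fixtures
# --------------------------------------------------------------------------


def sierpinski_carpet(order: int = 5) -> np.ndarray:
    """Boolean Sierpinski carpet of side 3**order (fractal dimension
    log 8 / log 3 ~ 1.893)."""
    carpet = np.ones((1, 1), dtype=bool)
    for _ in range(order):
        n = carpet.shape[0]
        nxt = np.zeros((3 * n, 3 * n), dtype=bool)
        for i in range(3):
            for j in range(3):
                if i == 1 and j == 1:
                    continue
                nxt[i * n : (i + 1) * n, j * n : (j + 1) * n] = carpet
        carpet = nxt
    return carpet


def bar_mask(
    length: int = 100, width: int = 5, frame: tuple[int, int] = (304, 304)
) -> np.ndarray:
    """Horizontal solid bar, centred: the analytic VDI ~ width fixture."""
    mask = np.zeros(frame, dtype=bool)
    r0 = frame[0] // 2 - width // 2
    c0 = (frame[1] - length) // 2
    mask[r0 : r0 + width, c0 : c0 + length] = True
    return mask


def line_mask(length: int = 304, frame: tuple[int, int] = (304, 304)) -> np.ndarray:
    """1-px-wide horizontal line (fractal dimension 1, VDI ~ 1).

    Full frame width by default: box counts of a short line saturate at
    large box sizes and bias the log-log slope low.
    """
    return bar_mask(length=length, width=1, frame=frame)
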