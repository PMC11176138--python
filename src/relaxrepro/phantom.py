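"""Digital leg-cross-section phantoms with tumor and contralateral muscle.

The phantom stands in for a tumor-bearing mouse hindlimb imaged in cross
section: one leg carries an osteosarcoma with intra- and extraosseous
components, the other leg provides the contralateral calf muscle used as
the signal reference for masking.  Each voxel carries latent ground-truth
decay parameters (T in ms, initial signal S0, constant offset A); tissue
values are drawn from truncated normal distributions so relaxation times
stay positive.

Iron-oxide contrast is modelled as rate addition: nanoparticle uptake adds
a non-negative per-voxel relaxation rate, 1/T_post = 1/T_pre + dR, so
post-contrast T is shortened voxel-wise and never lengthened.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage, stats

from .errors import ConfigError, ContrastStateError, DegenerateROIError

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_TUMOR",
    "LABEL_MUSCLE",
    "LABEL_BONE",
    "GeometryConfig",
    "TissueParams",
    "ContrastHeterogeneity",
    "ReaderJitter",
    "PhantomVolume",
    "ROISet",
    "make_phantom",
    "apply_contrast",
    "simulate_reader",
    "dice",
]

LABEL_BACKGROUND = 0
LABEL_TUMOR = 1
LABEL_MUSCLE = 2
LABEL_BONE = 3

# lower truncation for relaxation times (ms): keeps T strictly positive
T_FLOOR_MS = 0.1


class GeometryConfig(BaseModel):
    """Placement of the two leg cross-sections on the voxel grid.

    All coordinates are 0-based voxel indices in the (x, y) plane; the same
    2-D layout is repeated on every slice.  The tumor disc is centred on the
    tumor-bearing leg but may extend past the leg outline (extraosseous
    soft-tissue component).
    """

    shape: tuple[int, int, int] = (64, 64, 3)
    leg_radius: float = 13.0
    tumor_leg_center: tuple[float, float] = (18.0, 32.0)
    contralateral_center: tuple[float, float] = (46.0, 32.0)
    tumor_center: tuple[float, float] = (14.0, 28.0)
    tumor_radius: float = 8.0
    bone_radius: float = 2.5
    muscle_roi_radius: float = 7.0

    @model_validator(mode="after")
    def _check(self) -> "GeometryConfig":
        if any(int(s) <= 0 for s in self.shape):
            raise ConfigError(f"non-positive phantom shape {self.shape}")
        for name in ("leg_radius", "tumor_radius", "bone_radius", "muscle_roi_radius"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        return self


class TissueParams(BaseModel):
    """Mean and SD of the decay parameters for one tissue class.

    ``T_mean``/``T_sd`` are in milliseconds; ``S0``/``A`` are in arbitrary
    signal units.  SD = 0 gives a degenerate (constant) tissue.
    """

    T_mean: float
    T_sd: float = 0.0
    S0_mean: float = 100.0
    S0_sd: float = 0.0
    A_mean: float = 5.0
    A_sd: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "TissueParams":
        if self.T_mean <= 0:
            raise ConfigError("T_mean must be > 0")
        if min(self.T_sd, self.S0_sd, self.A_sd) < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.S0_mean < 0 or self.A_mean < 0:
            raise ConfigError("S0_mean and A_mean must be >= 0")
        return self


class ContrastHeterogeneity(BaseModel):
    """Shape of the per-voxel contrast-rate distribution.

    Per-voxel rate increments are gamma distributed with the configured
    ``gamma_shape`` (coefficient of variation = 1/sqrt(shape)), emulating
    heterogeneous nanoparticle uptake; ``non_tumor_fraction`` scales the
    mean increment applied to muscle and bone (systemic circulation).
    """

    gamma_shape: float = 4.0
    non_tumor_fraction: float = 0.1

    @model_validator(mode="after")
    def _check(self) -> "ContrastHeterogeneity":
        if self.gamma_shape <= 0:
            raise ConfigError("gamma_shape must be > 0")
        if not 0.0 <= self.non_tumor_fraction <= 1.0:
            raise ConfigError("non_tumor_fraction must be in [0, 1]")
        return self


class ReaderJitter(BaseModel):
    """Boundary perturbation applied to a tumor delineation.

    ``magnitude`` is the number of boundary-perturbation passes (0 = the
    reader traces the reference exactly); ``p_flip`` the probability that a
    boundary voxel is added/removed per pass; ``dice_floor`` the minimum
    acceptable overlap with the reference.
    """

    magnitude: int = 1
    p_flip: float = 0.25
    dice_floor: float = 0.7

    @model_validator(mode="after")
    def _check(self) -> "ReaderJitter":
        if self.magnitude < 0:
            raise ConfigError("magnitude must be >= 0")
        if not 0.0 <= self.p_flip <= 1.0:
            raise ConfigError("p_flip must be in [0, 1]")
        if not 0.0 <= self.dice_floor <= 1.0:
            raise ConfigError("dice_floor must be in [0, 1]")
        return self


@dataclass
class PhantomVolume:
    """Latent ground truth behind a simulated acquisition.

    Attributes
    ----------
    labels : (x, y, z) int array
        Tissue code per voxel (background/tumor/muscle/bone).
    true_T, true_S0, true_A : (x, y, z) float arrays
        Per-voxel decay parameters; ``true_T`` in ms (0 in background).
    contrast_state : {"pre", "post"}
    """

    labels: np.ndarray
    true_T: np.ndarray
    true_S0: np.ndarray
    true_A: np.ndarray
    contrast_state: str = "pre"

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    def tissue_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class ROISet:
    """Tumor and contralateral-muscle delineations for one volume."""

    tumor_mask: np.ndarray
    muscle_mask: np.ndarray
    reader_id: str = "reader0"

    def __post_init__(self) -> None:
        if self.tumor_mask.shape != self.muscle_mask.shape:
            raise ValueError("tumor and muscle masks must share a shape")
        if np.any(self.tumor_mask & self.muscle_mask):
            raise ValueError("tumor and muscle masks must be disjoint")
        if not self.tumor_mask.any() or not self.muscle_mask.any():
            raise DegenerateROIError("tumor and muscle masks must be non-empty")


def _disc(shape_xy: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    xx, yy = np.meshgrid(np.arange(shape_xy[0]), np.arange(shape_xy[1]), indexing="ij")
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Truncated-normal sample (lower-truncated, no upper bound)."""
    if sd == 0:
        return np.full(size, max(mean, lower))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def make_phantom(
    geometry: GeometryConfig,
    tissue_params: dict[str, TissueParams],
    seed: int,
) -> tuple[PhantomVolume, ROISet]:
    """Build a pre-contrast phantom and its reference ("reader 0") ROIs.

    ``tissue_params`` maps tissue names ("tumor", "muscle", "bone") to their
    parameter distributions; unlisted tissues fall back to muscle.  Voxel
    values are drawn i.i.d. from lower-truncated normals (T > 0.1 ms,
    S0 >= 0, A >= 0).  The returned ROISet matches the labels exactly:
    tumor mask = tumor voxels, muscle mask = a disc of muscle voxels in the
    contralateral calf.
    """
    geom = geometry if isinstance(geometry, GeometryConfig) else GeometryConfig(**geometry)
    nx, ny, nz = (int(s) for s in geom.shape)
    rng = np.random.default_rng(seed)

    leg_a = _disc((nx, ny), geom.tumor_leg_center, geom.leg_radius)
    leg_b = _disc((nx, ny), geom.contralateral_center, geom.leg_radius)
    tumor = _disc((nx, ny), geom.tumor_center, geom.tumor_radius)
    bone_a = _disc((nx, ny), geom.tumor_leg_center, geom.bone_radius)
    bone_b = _disc((nx, ny), geom.contralateral_center, geom.bone_radius)

    plane = np.zeros((nx, ny), dtype=np.int8)
    plane[leg_a | leg_b] = LABEL_MUSCLE
    plane[bone_a | bone_b] = LABEL_BONE
    plane[tumor] = LABEL_TUMOR  # tumor replaces underlying tissue
    labels = np.repeat(plane[:, :, None], nz, axis=2)

    true_T = np.zeros((nx, ny, nz))
    true_S0 = np.zeros((nx, ny, nz))
    true_A = np.zeros((nx, ny, nz))
    for name, code in (("tumor", LABEL_TUMOR), ("muscle", LABEL_MUSCLE), ("bone", LABEL_BONE)):
        params = tissue_params.get(name, tissue_params.get("muscle"))
        if params is None:
            raise ConfigError(f"tissue_params missing {name!r} (and no 'muscle' fallback)")
        if not isinstance(params, TissueParams):
            params = TissueParams(**params)
        mask = labels == code
        n = int(mask.sum())
        if n == 0:
            continue
        true_T[mask] = _truncnorm_draw(rng, params.T_mean, params.T_sd, T_FLOOR_MS, n)
        true_S0[mask] = _truncnorm_draw(rng, params.S0_mean, params.S0_sd, 0.0, n)
        true_A[mask] = _truncnorm_draw(rng, params.A_mean, params.A_sd, 0.0, n)

    phantom = PhantomVolume(labels=labels, true_T=true_T, true_S0=true_S0, true_A=true_A)

    muscle_roi_plane = _disc((nx, ny), geom.contralateral_center, geom.muscle_roi_radius) & (
        plane == LABEL_MUSCLE
    )
    roi = ROISet(
        tumor_mask=labels == LABEL_TUMOR,
        muscle_mask=np.repeat(muscle_roi_plane[:, :, None], nz, axis=2),
        reader_id="reader0",
    )
    return phantom, roi


def apply_contrast(
    phantom: PhantomVolume,
    delta_R_mean: float,
    heterogeneity: ContrastHeterogeneity | None = None,
    seed: int = 0,
) -> PhantomVolume:
    """Shorten relaxation times by adding per-voxel relaxation rates.

    Tumor voxels receive dR ~ Gamma(shape, mean=delta_R_mean) in 1/ms;
    muscle and bone receive the same distribution scaled by
    ``non_tumor_fraction``.  Rates only ever increase, so post-contrast T
    is voxel-wise <= pre-contrast T.
    """
    if phantom.contrast_state != "pre":
        raise ContrastStateError("contrast already applied (phantom is post-contrast)")
    if delta_R_mean < 0:
        raise ConfigError("delta_R_mean must be >= 0")
    het = heterogeneity or ContrastHeterogeneity()

    new_T = phantom.true_T.copy()
    if delta_R_mean > 0:
        rng = np.random.default_rng(seed)
        for code, mean in (
            (LABEL_TUMOR, delta_R_mean),
            (LABEL_MUSCLE, delta_R_mean * het.non_tumor_fraction),
            (LABEL_BONE, delta_R_mean * het.non_tumor_fraction),
        ):
            mask = phantom.labels == code
            n = int(mask.sum())
            if n == 0 or mean == 0:
                continue
            d_rate = rng.gamma(het.gamma_shape, mean / het.gamma_shape, size=n)
            new_T[mask] = 1.0 / (1.0 / phantom.true_T[mask] + d_rate)

    return replace(phantom, true_T=new_T, contrast_state="post")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def simulate_reader(roi: ROISet, jitter: ReaderJitter, seed: int, reader_id: str = "reader1") -> ROISet:
    """Emulate an independent reader's tumor delineation.

    The tumor boundary is perturbed slice-by-slice (readers draw 2-D ROIs):
    each pass flips inner- and outer-boundary voxels with probability
    ``p_flip``.  The muscle ROI is shared between readers (single reference
    definition in the standardized procedure).

    Raises
    ------
    DegenerateROIError
        If the perturbed mask empties or falls below ``dice_floor`` overlap
        with the input.
    """
    jit = jitter if isinstance(jitter, ReaderJitter) else ReaderJitter(**jitter)
    mask = roi.tumor_mask.copy()
    if jit.magnitude > 0 and jit.p_flip > 0:
        rng = np.random.default_rng(seed)
        struct = ndimage.generate_binary_structure(2, 1)
        for _ in range(jit.magnitude):
            for z in range(mask.shape[2]):
                sl = mask[:, :, z]
                if not sl.any():
                    continue
                outer = ndimage.binary_dilation(sl, struct) & ~sl
                inner = sl & ~ndimage.binary_erosion(sl, struct)
                add = outer & (rng.random(sl.shape) < jit.p_flip)
                remove = inner & (rng.random(sl.shape) < jit.p_flip)
                mask[:, :, z] = (sl | add) & ~remove
    # reader never annotates the reference-muscle region as tumor
    mask &= ~roi.muscle_mask

    if not mask.any():
        raise DegenerateROIError("reader jitter emptied the tumor mask")
    overlap = dice(roi.tumor_mask, mask)
    if overlap < jit.dice_floor:
        raise DegenerateROIError(
            f"reader jitter degraded overlap to Dice={overlap:.3f} < floor {jit.dice_floor}"
        )
    return ROISet(tumor_mask=mask, muscle_mask=roi.muscle_mask.copy(), reader_id=reader_id)
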