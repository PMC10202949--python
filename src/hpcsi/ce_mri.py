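"""Contrast-enhanced T1 imaging endpoint: synthetic pre/post pairs and
enhancement-volume quantification.

The geometry matches a high-resolution T1-weighted mouse-brain
acquisition: 256x256 matrix over a 20x20 mm^2 field of view, 0.8 mm
slices, giving a voxel volume of (20/256)^2 * 0.8 ~ 0.00488 mm^3.
Post-gadolinium images show blood-brain-barrier leakage as focal signal
enhancement; the endpoint is the enhancing volume in mm^3.

No segmentation procedure is standardized for this endpoint, so the
rule here is explicit and configurable: a voxel enhances when its
relative signal change exceeds the mean + k*SD of the relative change
in a normal-tissue reference region (default k = 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "T1Geometry",
    "LesionBlob",
    "T1ImagePair",
    "EnhancementResult",
    "simulate_t1_pair",
    "enhancement_volume",
    "brain_ellipse_mask",
    "lesion_blobs_for_volume",
]


@dataclass(frozen=True)
class T1Geometry:
    """Acquisition geometry of the T1-weighted scan."""

    matrix: int = 256
    fov_mm: float = 20.0
    slice_thickness_mm: float = 0.8

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.fov_mm / self.matrix) ** 2 * self.slice_thickness_mm


@dataclass(frozen=True)
class LesionBlob:
    """Circular enhancing lesion: center (row, col), radius in voxels."""

    center: tuple[float, float]
    radius_vox: float
    enhancement_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.enhancement_fraction < 0:
            raise ValueError("enhancement fraction must be >= 0")
        if self.radius_vox <= 0:
            raise ValueError("radius must be positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[0:shape[0], 0:shape[1]]
        return ((rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2
                <= self.radius_vox ** 2)


@dataclass
class T1ImagePair:
    """Pre- and post-contrast T1 images (single slice by default)."""

    pre: np.ndarray
    post: np.ndarray
    geometry: T1Geometry = field(default_factory=T1Geometry)
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pre.shape != self.post.shape:
            raise ValueError("pre and post must share a shape")
        if np.any(self.pre < 0) or np.any(self.post < 0):
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class EnhancementResult:
    """Binary enhancement segmentation and its volume."""

    mask: np.ndarray
    n_voxels: int
    volume_mm3: float
    threshold: float

    def __post_init__(self) -> None:
        if self.n_voxels != int(self.mask.sum()):
            raise ValueError("n_voxels inconsistent with mask")


def brain_ellipse_mask(shape: tuple[int, int] = (256, 256),
                       semi_axes: tuple[float, float] = (90.0, 70.0)
                       ) -> np.ndarray:
    """Elliptical brain surrogate centered in the image."""
    rr, cc = np.ogrid[0:shape[0], 0:shape[1]]
    r0, c0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return ((rr - r0) / semi_axes[0]) ** 2 + ((cc - c0) / semi_axes[1]) ** 2 <= 1.0


def lesion_blobs_for_volume(volume_mm3: float,
                            geometry: T1Geometry | None = None,
                            center: tuple[float, float] = (110.0, 128.0),
                            enhancement_fraction: float = 0.5
                            ) -> list[LesionBlob]:
    """One circular blob whose voxel count matches the requested volume."""
    geometry = geometry or T1Geometry()
    if volume_mm3 <= 0:
        return []
    n_vox = volume_mm3 / geometry.voxel_volume_mm3
    radius = max(1.0, np.sqrt(n_vox / np.pi))
    return [LesionBlob(center=center, radius_vox=radius,
                       enhancement_fraction=enhancement_fraction)]


def simulate_t1_pair(
    lesions: list[LesionBlob],
    shape: tuple[int, int] = (256, 256),
    background: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    geometry: T1Geometry | None = None,
) -> T1ImagePair:
    """Synthetic pre/post pair: post = pre with lesions scaled (1 + f).

    ``background`` defaults to a unit-intensity brain ellipse over a dim
    (0.05) exterior.  Independent Gaussian noise of SD ``noise_sigma``
    is added to both images (clipped at zero); reproducible from seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    geometry = geometry or T1Geometry()
    if background is None:
        background = np.where(brain_ellipse_mask(shape), 1.0, 0.05)
    pre = background.astype(float).copy()
    post = pre.copy()
    for blob in lesions:
        m = blob.mask(shape)
        post[m] *= (1.0 + blob.enhancement_fraction)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pre = pre + rng.normal(0.0, noise_sigma, shape)
        post = post + rng.normal(0.0, noise_sigma, shape)
    np.clip(pre, 0.0, None, out=pre)
    np.clip(post, 0.0, None, out=post)
    return T1ImagePair(pre=pre, post=post, geometry=geometry,
                       noise_sigma=noise_sigma, seed=seed)


def enhancement_volume(
    pair: T1ImagePair,
    normal_region_mask: np.ndarray,
    k_sd: float = 3.0,
    analysis_mask: np.ndarray | None = None,
    eps: float = 1e-6,
) -> EnhancementResult:
    """Threshold segmentation of contrast enhancement.

    The relative difference d = (post - pre)/max(pre, eps) is compared
    against mean_d + k_sd * SD_d of the normal-tissue region; voxels
    above threshold (within ``analysis_mask`` if given) count as
    enhancing.  Volume = count * voxel volume, exactly.
    """
    normal = np.asarray(normal_region_mask, dtype=bool)
    if normal.shape != pair.pre.shape:
        raise ValueError("normal-region mask shape mismatch")
    if not normal.any():
        raise ValueError("normal-region mask is empty")
    d = (pair.post - pair.pre) / np.maximum(pair.pre, eps)
    ref = d[normal]
    threshold = float(ref.mean() + k_sd * ref.std(ddof=1))
    enhancing = d > threshold
    if analysis_mask is not None:
        enhancing &= np.asarray(analysis_mask, dtype=bool)
    n = int(enhancing.sum())
    return EnhancementResult(
        mask=enhancing, n_voxels=n,
        volume_mm3=n * pair.geometry.voxel_volume_mm3,
        threshold=threshold,
    )
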