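"""Forward simulation of dynamic 2D CSI k-space data.

Each voxel's metabolite magnetizations (from the kinetic model) are
turned into a Lorentzian-line FID per time frame, the voxel grid is
phase-encoded by a unitary 2D spatial DFT, and i.i.d. complex Gaussian
noise is added in k-space.  One FID represents each 4-s frame (the 64
individual phase-encode excitations are not simulated; their signal
depletion is folded into the continuous RF-loss rate of the kinetic
model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .acquisition import AcquisitionParams, ResonanceTable, default_resonances, \
    ppm_to_offset_hz
from .kinetics import VoxelKinetics, magnetization_at
from .phantom import PhantomGrid

__all__ = [
    "DynamicCSIDataset",
    "synthesize_voxel_fid",
    "encode_kspace",
    "generate_dynamic_csi",
]


@dataclass
class DynamicCSIDataset:
    """Complex k-space hypercube (kx, ky, spectral point, frame) + metadata."""

    kspace: np.ndarray
    acq: AcquisitionParams
    noise_sigma: float = 0.0
    seed: int | None = None
    phantom_name: str | None = None
    ground_truth_kpl: np.ndarray | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = self.kspace
        expected = (self.acq.matrix, self.acq.matrix,
                    self.acq.n_spectral_points, self.acq.n_frames)
        if k.shape != expected:
            raise ValueError(f"kspace shape {k.shape} != {expected}")
        if not np.all(np.isfinite(k)):
            raise ValueError("kspace must be finite")

    # -- persistence --------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("kspace_real", data=self.kspace.real)
            f.create_dataset("kspace_imag", data=self.kspace.imag)
            for name, m in self.masks.items():
                f.create_dataset(f"masks/{name}", data=m.astype(np.uint8))
            if self.ground_truth_kpl is not None:
                f.create_dataset("ground_truth_kpl", data=self.ground_truth_kpl)
            g = f.create_group("acq")
            for k, v in vars(self.acq).items():
                g.attrs[k] = v
            f.attrs["noise_sigma"] = self.noise_sigma
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            if self.phantom_name is not None:
                f.attrs["phantom_name"] = self.phantom_name

    @classmethod
    def from_hdf5(cls, path) -> "DynamicCSIDataset":
        with h5py.File(path, "r") as f:
            kspace = f["kspace_real"][...] + 1j * f["kspace_imag"][...]
            acq = AcquisitionParams(**{k: (int(v) if k in
                                           ("n_spectral_points", "matrix", "n_frames")
                                           else float(v))
                                       for k, v in f["acq"].attrs.items()})
            masks = {}
            if "masks" in f:
                for name in f["masks"]:
                    masks[name] = f["masks"][name][...].astype(bool)
            gt = f["ground_truth_kpl"][...] if "ground_truth_kpl" in f else None
            return cls(
                kspace=kspace, acq=acq,
                noise_sigma=float(f.attrs.get("noise_sigma", 0.0)),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
                phantom_name=str(f.attrs["phantom_name"])
                if "phantom_name" in f.attrs else None,
                ground_truth_kpl=gt, masks=masks,
            )


def synthesize_voxel_fid(
    metabolite_mz: dict[str, float],
    resonances: ResonanceTable,
    acq: AcquisitionParams,
) -> np.ndarray:
    """Noiseless complex FID of one voxel at one frame.

    s(t_k) = sum_m Mz_m sin(theta) exp(2*pi*i f_m t_k - pi FWHM_m t_k)
    with t_k = k/SW; each line is Lorentzian by construction, centered
    at its apparent (aliased) offset.
    """
    t = acq.spectral_time_axis()
    fid = np.zeros(acq.n_spectral_points, dtype=complex)
    sin_theta = np.sin(acq.flip_angle_rad)
    for res in resonances:
        mz = float(metabolite_mz.get(res.name, 0.0))
        if mz < 0:
            raise ValueError("magnetizations must be >= 0")
        if mz == 0.0:
            continue
        f = ppm_to_offset_hz(res.ppm, acq)
        fid += mz * sin_theta * np.exp((2j * np.pi * f - np.pi * res.fwhm_hz) * t)
    return fid


def encode_kspace(voxel_fids: np.ndarray) -> np.ndarray:
    """Phase-encode a voxel grid: unitary 2D spatial DFT per (point, frame).

    Exact inverse of :func:`hpcsi.pipeline.reconstruct_voxels` (both use
    the orthonormal FFT convention, so spatial energy is preserved).
    """
    k = np.asarray(voxel_fids)
    if k.ndim < 2 or k.shape[0] != k.shape[1]:
        raise ValueError("voxel grid must be square in its two leading dims")
    return np.fft.fftn(k, axes=(0, 1), norm="ortho")


def generate_dynamic_csi(
    phantom: PhantomGrid,
    acq: AcquisitionParams | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    resonances: ResonanceTable | None = None,
) -> DynamicCSIDataset:
    """Simulate a full dynamic CSI acquisition of ``phantom``.

    Per voxel the kinetic ODEs are sampled at frame midpoints, each
    frame's magnetizations become a three-line FID, the grid is
    phase-encoded, and complex Gaussian noise of standard deviation
    ``noise_sigma`` per real/imaginary component is added to every
    k-space point.  Fully reproducible from ``seed``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    acq = acq or AcquisitionParams()
    resonances = resonances or default_resonances()
    if phantom.matrix != acq.matrix:
        raise ValueError("phantom and acquisition matrix size differ")

    frame_times = acq.frame_mid_times_s
    n = acq.matrix
    grid = np.zeros((n, n, acq.n_spectral_points, acq.n_frames), dtype=complex)

    # voxels sharing identical kinetics share one ODE solution
    cache: dict[VoxelKinetics, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i in range(n):
        for j in range(n):
            kin = phantom.kinetics[i][j]
            if kin.is_zero:
                continue
            if kin not in cache:
                cache[kin] = magnetization_at(kin, acq, frame_times)
            p, l, u = cache[kin]
            for fr in range(acq.n_frames):
                grid[i, j, :, fr] = synthesize_voxel_fid(
                    {"pyruvate": p[fr], "lactate": l[fr], "urea": u[fr]},
                    resonances, acq,
                )

    kspace = encode_kspace(grid)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        kspace = kspace + noise_sigma * (
            rng.standard_normal(kspace.shape)
            + 1j * rng.standard_normal(kspace.shape)
        )

    return DynamicCSIDataset(
        kspace=kspace, acq=acq, noise_sigma=noise_sigma, seed=seed,
        phantom_name=phantom.name, ground_truth_kpl=phantom.kpl_map(),
        masks={
            "brain": phantom.brain_mask.copy(),
            "vascular": phantom.vascular_mask.copy(),
            "roi": phantom.roi_mask.copy(),
        },
    )
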