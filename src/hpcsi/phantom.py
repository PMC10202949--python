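"""Digital phantoms: per-voxel kinetics plus brain / ROI / vascular masks.

The 8x8 grid mirrors the CSI matrix over a mouse head: a central block
of brain voxels, an inner analysis ROI standing in for the voxels
containing cortex, corpus callosum, external capsule and hippocampus,
and a ring of vascular-reference voxels (surrounding tissue containing
blood vessels) used to normalize the urea signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import VoxelKinetics

__all__ = ["PhantomGrid", "default_phantom"]

_ZERO = VoxelKinetics(pyr_delivery_amp=0.0, urea_delivery_amp=0.0)


@dataclass
class PhantomGrid:
    """Grid of voxel kinetics with the three analysis masks.

    ``kinetics`` is a nested list (matrix x matrix) of
    :class:`~hpcsi.kinetics.VoxelKinetics`.  Invariants: the ROI is a
    subset of the brain mask, the vascular reference is disjoint from
    the brain, and at least one vascular-reference voxel exists.
    """

    kinetics: list[list[VoxelKinetics]]
    brain_mask: np.ndarray
    vascular_mask: np.ndarray
    roi_mask: np.ndarray
    name: str = "phantom"

    def __post_init__(self) -> None:
        n = len(self.kinetics)
        if any(len(row) != n for row in self.kinetics):
            raise ValueError("kinetics grid must be square")
        for m in (self.brain_mask, self.vascular_mask, self.roi_mask):
            if m.shape != (n, n) or m.dtype != bool:
                raise ValueError("masks must be boolean arrays matching the grid")
        if np.any(self.roi_mask & ~self.brain_mask):
            raise ValueError("roi_mask must be a subset of brain_mask")
        if np.any(self.vascular_mask & self.brain_mask):
            raise ValueError("vascular_mask must be disjoint from brain_mask")
        if not np.any(self.vascular_mask):
            raise ValueError("at least one vascular-reference voxel required")

    @property
    def matrix(self) -> int:
        return len(self.kinetics)

    def kpl_map(self) -> np.ndarray:
        return np.array([[k.kpl for k in row] for row in self.kinetics])

    def with_scaled_delivery(self, pyr_factor: float = 1.0,
                             urea_factor: float = 1.0) -> "PhantomGrid":
        """New phantom with all delivery amplitudes rescaled.

        Models animal-to-animal variation in polarization level and
        bolus transfer time, which multiplies every metabolite signal of
        one animal and cancels in the ratio readouts.
        """
        if pyr_factor < 0 or urea_factor < 0:
            raise ValueError("delivery factors must be >= 0")
        kin = [
            [
                k.replace(pyr_delivery_amp=k.pyr_delivery_amp * pyr_factor,
                          urea_delivery_amp=k.urea_delivery_amp * urea_factor)
                for k in row
            ]
            for row in self.kinetics
        ]
        return PhantomGrid(kin, self.brain_mask.copy(), self.vascular_mask.copy(),
                           self.roi_mask.copy(), self.name)

    def with_scaled_kpl(self, factor: float, mask: np.ndarray | None = None
                        ) -> "PhantomGrid":
        """New phantom with kPL multiplied by ``factor`` on ``mask`` voxels."""
        mask = self.brain_mask if mask is None else mask
        kin = [
            [
                k.replace(kpl=k.kpl * factor) if mask[i, j] else k
                for j, k in enumerate(row)
            ]
            for i, row in enumerate(self.kinetics)
        ]
        return PhantomGrid(kin, self.brain_mask.copy(), self.vascular_mask.copy(),
                           self.roi_mask.copy(), self.name)


def default_phantom(
    kpl: float = 0.029,
    matrix: int = 8,
    brain_kin: VoxelKinetics | None = None,
    vascular_kin: VoxelKinetics | None = None,
    name: str = "default",
) -> PhantomGrid:
    """Mouse-head surrogate: 4x4 brain block, 2x4 inner ROI, vascular ring.

    Brain voxels convert pyruvate at rate ``kpl`` and receive a urea
    delivery; vascular voxels carry pyruvate and a stronger urea signal
    but no conversion; everything else is empty.
    """
    if matrix < 8:
        raise ValueError("default geometry needs matrix >= 8")
    if brain_kin is None:
        brain_kin = VoxelKinetics(kpl=kpl, pyr_delivery_amp=1.0,
                                  urea_delivery_amp=0.5)
    if vascular_kin is None:
        vascular_kin = VoxelKinetics(kpl=0.0, pyr_delivery_amp=1.5,
                                     urea_delivery_amp=1.0)

    brain = np.zeros((matrix, matrix), dtype=bool)
    brain[2:6, 2:6] = True
    roi = np.zeros_like(brain)
    roi[3:5, 2:6] = True
    vascular = np.zeros_like(brain)
    vascular[1, 2:6] = True
    vascular[6, 2:6] = True

    kin = [[_ZERO for _ in range(matrix)] for _ in range(matrix)]
    for i in range(matrix):
        for j in range(matrix):
            if brain[i, j]:
                kin[i][j] = brain_kin
            elif vascular[i, j]:
                kin[i][j] = vascular_kin
    return PhantomGrid(kin, brain, vascular, roi, name)
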