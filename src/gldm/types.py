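"""Core domain types shared across the pipeline.

A :class:`ParcelScheme` is a stand-in for a registered anatomical atlas: an
integer label volume (0 = background, 1..P = parcels) plus per-parcel
hemisphere and lobe labels.  A :class:`LesionMask` is a binary volume on the
same grid.  :class:`GroundTruth` describes the simulated deficit substrate:
the set of parcels whose damage depresses the behavioural score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: face-neighbour offsets on a 3-D grid
FACE_NEIGHBOURS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


class GridAlignmentError(ValueError):
    """A volume does not share the grid of the parcel scheme."""


class SizingError(ValueError):
    """A requested parcellation or lesion cannot fit in the grid."""


@dataclass(frozen=True)
class ParcelScheme:
    """Parcellated brain grid.

    Parameters
    ----------
    labels
        3-D integer array; 0 is background (unused by the default builder,
        which labels every voxel), 1..P are parcel ids.
    hemisphere
        Per-parcel hemisphere label (``"left"`` / ``"right"``), indexed by
        parcel id - 1.
    lobe
        Per-parcel lobe label (``"frontal"`` / ``"posterior"``).
    voxel_size_mm
        Voxel dimensions; only used for the NIfTI affine.
    """

    labels: np.ndarray
    hemisphere: tuple
    lobe: tuple
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)

    @property
    def grid_shape(self) -> tuple:
        return self.labels.shape

    @property
    def n_parcels(self) -> int:
        return len(self.hemisphere)

    @property
    def parcel_ids(self) -> np.ndarray:
        return np.arange(1, self.n_parcels + 1)

    def parcel_sizes(self) -> np.ndarray:
        """Voxel count per parcel, indexed by parcel id - 1."""
        return np.bincount(self.labels.ravel(), minlength=self.n_parcels + 1)[1:]

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Boolean voxel mask of one hemisphere (sagittal axis = axis 0)."""
        nx = self.grid_shape[0]
        mask = np.zeros(self.grid_shape, dtype=bool)
        if side == "left":
            mask[: nx // 2] = True
        elif side == "right":
            mask[nx // 2 :] = True
        else:
            raise ValueError(f"unknown side {side!r}")
        return mask

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def validate(self) -> None:
        sizes = self.parcel_sizes()
        if (sizes == 0).any():
            raise SizingError("parcel scheme contains empty parcels")
        if len(self.hemisphere) != len(self.lobe):
            raise ValueError("hemisphere/lobe label length mismatch")


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion volume aligned to a :class:`ParcelScheme` grid."""

    volume: np.ndarray
    patient_id: str

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())


@dataclass(frozen=True)
class GroundTruth:
    """Simulated deficit substrate and score model parameters.

    ``score = clamp(mu0 - effect_beta * load - age_gamma * (age - mean age)
    + eps, 0, ceiling)`` where ``load`` is the mean damage fraction over
    ``substrate_parcels`` and ``eps ~ Normal(0, noise_sd)``.
    """

    substrate_parcels: frozenset
    effect_beta: float = 30.0
    age_gamma: float = 0.2
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "substrate_parcels", frozenset(self.substrate_parcels))


def check_connected(volume: np.ndarray) -> bool:
    """True iff the nonzero voxels of ``volume`` form one face-connected set."""
    from scipy import ndimage

    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    _, n = ndimage.label(volume > 0, structure=structure)
    return n == 1
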