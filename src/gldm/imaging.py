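"""Lesion-image handling: NIfTI I/O, damage matrices, group classification.

The bridge from volumetric masks to the graph analysis is the damage matrix
(patients x parcels, entries = fraction of each parcel's voxels lesioned).
Group assignment follows the lobar rule used in focal-lesion studies: a
patient is *frontal* (or *posterior*) when at least 70% of the lesion volume
falls within frontal (posterior) parcels, and lateralised by the hemisphere
holding the majority of lesioned voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .types import GridAlignmentError, LesionMask, ParcelScheme


class EmptyLesionError(ValueError):
    """Operation requires a non-empty lesion."""


@dataclass(frozen=True)
class GroupLabel:
    """Lobar group and lesion side for one patient."""

    lobe_group: str  # {"frontal", "posterior", "excluded"}
    side: str  # {"left", "right"}


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_mask(mask: LesionMask, path, scheme: ParcelScheme) -> None:
    img = nib.Nifti1Image(mask.volume.astype(np.uint8), scheme.affine())
    nib.save(img, str(path))


def read_mask(path, scheme: ParcelScheme, patient_id: str | None = None) -> LesionMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.shape != scheme.grid_shape:
        raise GridAlignmentError(
            f"mask grid {data.shape} does not match scheme grid {scheme.grid_shape}"
        )
    if not np.allclose(img.affine, scheme.affine()):
        raise GridAlignmentError("mask affine does not match scheme affine")
    pid = patient_id if patient_id is not None else str(path)
    return LesionMask(volume=data > 0, patient_id=pid)


def write_map(volume: np.ndarray, path, scheme: ParcelScheme) -> None:
    """Write an arbitrary scalar volume on the scheme grid."""
    if volume.shape != scheme.grid_shape:
        raise GridAlignmentError("volume grid does not match scheme grid")
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), scheme.affine())
    nib.save(img, str(path))


def read_map(path, scheme: ParcelScheme) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.shape != scheme.grid_shape:
        raise GridAlignmentError("volume grid does not match scheme grid")
    return np.asarray(data, dtype=np.float64)


def write_scheme(scheme: ParcelScheme, volume_path, table_path) -> None:
    img = nib.Nifti1Image(scheme.labels.astype(np.int16), scheme.affine())
    nib.save(img, str(volume_path))
    meta = pd.DataFrame(
        {
            "parcel_id": scheme.parcel_ids,
            "hemisphere": list(scheme.hemisphere),
            "lobe": list(scheme.lobe),
        }
    )
    meta.to_csv(table_path, sep="\t", index=False)


def read_scheme(volume_path, table_path, voxel_size_mm=(2.0, 2.0, 2.0)) -> ParcelScheme:
    img = nib.load(str(volume_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    meta = pd.read_csv(table_path, sep="\t").sort_values("parcel_id")
    return ParcelScheme(
        labels=labels,
        hemisphere=tuple(meta["hemisphere"]),
        lobe=tuple(meta["lobe"]),
        voxel_size_mm=voxel_size_mm,
    )


# ---------------------------------------------------------------------------
# Damage quantification


def damage_fractions(mask: LesionMask, scheme: ParcelScheme) -> np.ndarray:
    """Fraction of each parcel's voxels covered by the lesion.

    Returns a vector of length P indexed by parcel id - 1; entries lie in
    [0, 1] and satisfy  sum_p fraction_p * |parcel p| = lesion voxel count.
    """
    if mask.volume.shape != scheme.grid_shape:
        raise GridAlignmentError("mask grid does not match scheme grid")
    sizes = scheme.parcel_sizes()
    if (sizes == 0).any():
        raise ValueError("scheme has empty parcels")
    hit = np.bincount(
        scheme.labels[mask.volume].ravel(), minlength=scheme.n_parcels + 1
    )[1:]
    return hit / sizes


def damage_matrix(masks, scheme: ParcelScheme) -> pd.DataFrame:
    """Patients x parcels damage-fraction matrix (rows in mask order)."""
    rows = [damage_fractions(m, scheme) for m in masks]
    return pd.DataFrame(
        np.array(rows) if rows else np.empty((0, scheme.n_parcels)),
        index=[m.patient_id for m in masks],
        columns=scheme.parcel_ids,
    )


def classify_patient(
    fractions: np.ndarray, scheme: ParcelScheme, threshold: float = 0.70
) -> GroupLabel:
    """Assign the lobar group and side from per-parcel damage fractions.

    The lobe share is computed over lesioned voxels (fraction x parcel size),
    so the >= threshold rule applies to the lesion volume, not to parcel
    counts.  Exactly meeting the threshold counts as membership.
    """
    fractions = np.asarray(fractions, dtype=float)
    sizes = scheme.parcel_sizes()
    vox = fractions * sizes
    total = vox.sum()
    if total <= 0:
        raise EmptyLesionError("cannot classify an empty lesion")
    lobes = np.asarray(scheme.lobe)
    hemis = np.asarray(scheme.hemisphere)
    frontal_share = vox[lobes == "frontal"].sum() / total
    posterior_share = vox[lobes == "posterior"].sum() / total
    if frontal_share >= threshold:
        lobe_group = "frontal"
    elif posterior_share >= threshold:
        lobe_group = "posterior"
    else:
        lobe_group = "excluded"
    left_vox = vox[hemis == "left"].sum()
    side = "left" if left_vox > total - left_vox else "right"
    return GroupLabel(lobe_group=lobe_group, side=side)


def binarize_damage(matrix: pd.DataFrame, tau: float = 0.5) -> pd.DataFrame:
    """Threshold damage fractions: entry = 1 iff fraction >= tau."""
    if not 0 < tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    binary = (values >= tau).astype(np.int8)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(binary, index=matrix.index, columns=matrix.columns)
    return binary
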