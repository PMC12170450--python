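"""Binary lesion masks on a regular 3-D grid with a NIfTI-style affine."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LesionMask", "check_same_grid"]

#: absolute tolerance for comparing affines of two masks
AFFINE_ATOL = 1e-6


@dataclass(frozen=True)
class LesionMask:
    """A per-subject 3-D binary volume plus its voxel-to-mm affine.

    Parameters
    ----------
    data:
        3-D boolean array; ``True`` marks lesioned voxels.
    affine:
        4x4 voxel-index -> world-mm (RAS) transform. Voxel *centers* map
        through the affine, following the NIfTI convention.
    """

    data: np.ndarray
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"lesion mask must be 3-D, got shape {data.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        object.__setattr__(self, "data", data.astype(bool))
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        """Number of lesioned voxels."""
        return int(self.data.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "LesionMask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL
        )

    def voxel_centers_mm(self, indices: np.ndarray | None = None) -> np.ndarray:
        """World-mm coordinates of voxel centers.

        Parameters
        ----------
        indices:
            (k, 3) integer voxel indices; defaults to the lesioned voxels.
        """
        if indices is None:
            indices = np.argwhere(self.data)
        indices = np.atleast_2d(np.asarray(indices))
        homog = np.c_[indices, np.ones(len(indices))]
        return (self.affine @ homog.T).T[:, :3]

    def center_of_mass_mm(self) -> np.ndarray:
        """Unweighted mean of lesioned voxel centers, in mm."""
        if self.n_voxels == 0:
            raise ValueError("center of mass undefined for an empty mask")
        return self.voxel_centers_mm().mean(axis=0)


def check_same_grid(masks: list[LesionMask]) -> None:
    """Raise ``ValueError`` unless all masks share shape and affine."""
    if not masks:
        raise ValueError("no masks supplied")
    ref = masks[0]
    for i, m in enumerate(masks[1:], start=1):
        if not ref.same_grid(m):
            raise ValueError(
                f"mask {i} grid mismatch: shape {m.shape} vs {ref.shape} "
                "or affine differs"
            )
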