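"""Scalar maps from diffusion tensors: MD, FA and the (p, q) decomposition.

A diffusion tensor is a symmetric 3x3 matrix per voxel with eigenvalues
``lam1 >= lam2 >= lam3`` (units mm^2/s).  Everything downstream uses only
rotation-invariant summaries of those eigenvalues:

* ``MD = (lam1 + lam2 + lam3) / 3`` — mean diffusivity,
* ``p  = sqrt(3) * MD`` — magnitude of the isotropic tensor component,
* ``q  = sqrt(sum_i (lam_i - MD)^2)`` — magnitude of the anisotropic
  (deviatoric) component,
* ``FA = sqrt(3/2) * q / sqrt(lam1^2 + lam2^2 + lam3^2)``.

``p`` and ``q`` are the two orthogonal legs of the tensor's Euclidean
norm, so ``p^2 + q^2 = lam1^2 + lam2^2 + lam3^2`` identically; this
identity is the main numerical self-check of the module.

Negative eigenvalues (noise or fit artefacts in upstream tensor fits)
are deliberately retained: clamping would silently bias p and q
statistics, and the cohort-level percentile clamping applied before
segmentation already suppresses outliers.  The number of affected
in-mask voxels is counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

logger = logging.getLogger(__name__)

#: order of the six unique tensor components in a 4D NIfTI file
#: (FSL lower-triangular convention).
TENSOR_COMPONENT_ORDER = ("dxx", "dxy", "dyy", "dxz", "dyz", "dzz")


@dataclass
class BrainMask:
    """Binary cerebrum mask; the single source of "cerebrum" membership.

    Voxels outside the mask are excluded from every downstream
    computation (normalisation, clustering, spectra, histograms).
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        if not self.data.any():
            raise ValueError("mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor components in mm^2/s."""

    dxx: np.ndarray
    dxy: np.ndarray
    dxz: np.ndarray
    dyy: np.ndarray
    dyz: np.ndarray
    dzz: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.components}
        if len(shapes) != 1:
            raise ValueError(f"tensor components disagree on grid shape: {shapes}")

    @property
    def components(self) -> tuple[np.ndarray, ...]:
        return (self.dxx, self.dxy, self.dxz, self.dyy, self.dyz, self.dzz)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.dxx.shape

    def as_matrices(self) -> np.ndarray:
        """Stack components into an (..., 3, 3) symmetric matrix array."""
        t = np.empty(self.grid_shape + (3, 3), dtype=np.float64)
        t[..., 0, 0] = self.dxx
        t[..., 1, 1] = self.dyy
        t[..., 2, 2] = self.dzz
        t[..., 0, 1] = t[..., 1, 0] = self.dxy
        t[..., 0, 2] = t[..., 2, 0] = self.dxz
        t[..., 1, 2] = t[..., 2, 1] = self.dyz
        return t


@dataclass
class EigenField:
    """Per-voxel diffusion-tensor eigenvalues sorted descending."""

    lam1: np.ndarray
    lam2: np.ndarray
    lam3: np.ndarray
    mask: BrainMask | None = None
    n_negative: int = field(default=0)

    def __post_init__(self) -> None:
        if not (self.lam1.shape == self.lam2.shape == self.lam3.shape):
            raise ValueError("eigenvalue volumes disagree on grid shape")
        sel = self.mask.data if self.mask is not None else slice(None)
        l1, l2, l3 = self.lam1[sel], self.lam2[sel], self.lam3[sel]
        if np.any(l1 < l2) or np.any(l2 < l3):
            raise ValueError("eigenvalues must be sorted descending at every in-mask voxel")
        self.n_negative = int(np.count_nonzero(l3 < 0))
        if self.n_negative:
            logger.warning("%d in-mask voxels carry negative eigenvalues (retained)",
                           self.n_negative)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.lam1.shape

    def stacked(self) -> np.ndarray:
        return np.stack([self.lam1, self.lam2, self.lam3], axis=-1)


@dataclass
class ScalarMap:
    """A scalar volume derived from the tensor field.

    kind is one of {"MD", "FA", "p", "q", "T2"}; units are mm^2/s for
    MD/p/q, dimensionless for FA, arbitrary for T2.
    """

    values: np.ndarray
    kind: str
    mask: BrainMask | None = None

    _UNITS = {"MD": "mm^2/s", "p": "mm^2/s", "q": "mm^2/s", "FA": "1", "T2": "a.u."}

    def __post_init__(self) -> None:
        if self.kind not in self._UNITS:
            raise ValueError(f"unknown scalar kind {self.kind!r}")

    @property
    def units(self) -> str:
        return self._UNITS[self.kind]

    def in_mask(self) -> np.ndarray:
        """Flat array of in-mask values (all values if no mask attached)."""
        if self.mask is None:
            return self.values.ravel()
        return self.values[self.mask.data]


def eigendecompose(tensors: TensorField, mask: BrainMask) -> EigenField:
    """Eigenvalues of each in-mask voxel's symmetric tensor, sorted descending.

    Out-of-mask voxels are zero.  Non-finite in-mask components raise,
    naming an offending voxel index.
    """
    if tensors.grid_shape != mask.shape:
        raise ValueError("tensor field and mask disagree on grid shape")
    m = mask.data
    for name, comp in zip(TENSOR_COMPONENT_ORDER,
                          (tensors.dxx, tensors.dxy, tensors.dyy,
                           tensors.dxz, tensors.dyz, tensors.dzz)):
        bad = ~np.isfinite(comp) & m
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(f"non-finite tensor component {name} at voxel {idx}")

    mats = tensors.as_matrices()[m]  # (n, 3, 3)
    # eigvalsh returns ascending eigenvalues for symmetric input
    lams = np.linalg.eigvalsh(mats)[:, ::-1]
    out = np.zeros(mask.shape + (3,), dtype=np.float64)
    out[m] = lams
    return EigenField(out[..., 0], out[..., 1], out[..., 2], mask=mask)


def compute_md(eig: EigenField) -> ScalarMap:
    """Mean diffusivity MD = (lam1 + lam2 + lam3) / 3."""
    md = (eig.lam1 + eig.lam2 + eig.lam3) / 3.0
    return ScalarMap(md, "MD", mask=eig.mask)


def compute_pq(eig: EigenField) -> tuple[ScalarMap, ScalarMap]:
    """Isotropic p = sqrt(3)*MD and anisotropic q = |lam - MD| per voxel."""
    md = (eig.lam1 + eig.lam2 + eig.lam3) / 3.0
    p = np.sqrt(3.0) * md
    q = np.sqrt((eig.lam1 - md) ** 2 + (eig.lam2 - md) ** 2 + (eig.lam3 - md) ** 2)
    return ScalarMap(p, "p", mask=eig.mask), ScalarMap(q, "q", mask=eig.mask)


def compute_fa(eig: EigenField) -> ScalarMap:
    """Fractional anisotropy FA = sqrt(3/2) * q / sqrt(lam1^2+lam2^2+lam3^2).

    Defined as 0 where all eigenvalues vanish.
    """
    md = (eig.lam1 + eig.lam2 + eig.lam3) / 3.0
    q2 = (eig.lam1 - md) ** 2 + (eig.lam2 - md) ** 2 + (eig.lam3 - md) ** 2
    norm2 = eig.lam1 ** 2 + eig.lam2 ** 2 + eig.lam3 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * q2 / norm2)
    fa = np.where(norm2 > 0, fa, 0.0)
    return ScalarMap(np.clip(fa, 0.0, 1.0), "FA", mask=eig.mask)


# ---------------------------------------------------------------------------
# NIfTI I/O

def load_mask(path) -> tuple[BrainMask, np.ndarray]:
    """Read a 3D 0/1 NIfTI mask; returns the mask and its affine."""
    img = nib.load(str(path))
    return BrainMask(np.asanyarray(img.dataobj) > 0), img.affine


def load_tensors(path) -> tuple[TensorField, np.ndarray]:
    """Read a 6-volume 4D NIfTI of unique tensor components.

    Volume order is the FSL lower-triangular convention
    dxx, dxy, dyy, dxz, dyz, dzz.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 6:
        raise ValueError(f"expected a 4D file with 6 volumes, got shape {data.shape}")
    dxx, dxy, dyy, dxz, dyz, dzz = (data[..., i] for i in range(6))
    zooms = img.header.get_zooms()[:3]
    return TensorField(dxx, dxy, dxz, dyy, dyz, dzz, voxel_size=tuple(zooms)), img.affine


def load_eigenvalues(path, mask: BrainMask | None = None) -> tuple[EigenField, np.ndarray]:
    """Read a 3-volume 4D NIfTI of eigenvalue maps (lam1, lam2, lam3)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(f"expected a 4D file with 3 volumes, got shape {data.shape}")
    return EigenField(data[..., 0], data[..., 1], data[..., 2], mask=mask), img.affine


def save_scalar_map(path, smap: ScalarMap, affine: np.ndarray | None = None) -> None:
    nib.save(nib.Nifti1Image(smap.values.astype(np.float64),
                             np.eye(4) if affine is None else affine), str(path))
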