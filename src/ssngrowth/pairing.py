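"""Rigid alignment of consecutive scans and cross-time nodule pairing.

Follow-up CT analysis needs the same lesion matched across exams: the
later scan is rigidly registered to the earlier one, lesion centroids
are carried through the recovered transform and matched mutually, and
fixed-size isotropic VOIs are cropped around each matched nodule.

Registration is rigid (6 degrees of freedom) through SimpleITK's
Euler3D transform with a mean-squares metric; VOI extraction resamples
to 1 mm isotropic cubes padded with -1000 HU (air) outside the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .grids import NoduleMask, VoxelGrid

__all__ = [
    "ExamPair",
    "RigidTransform",
    "Matching",
    "register_rigid",
    "pair_nodules",
    "extract_voi",
    "extract_mask_voi",
    "segment_phantom",
]


@dataclass
class ExamPair:
    """Ordered (prior, current) VOIs of one nodule.

    ``prior`` is ``None`` when only a single exam exists (the model
    then falls back to its learnable substitute embedding).
    """

    current: tuple[VoxelGrid, NoduleMask]
    prior: tuple[VoxelGrid, NoduleMask] | None = None
    interval_days: float | None = None
    subject_id: str = ""
    nodule_id: str = ""

    def __post_init__(self):
        if self.prior is not None:
            if self.interval_days is None or self.interval_days <= 0:
                raise ValueError("interval_days must be positive when a prior exists")
            if self.prior[0].shape != self.current[0].shape:
                raise ValueError("prior and current VOIs must share shape")


@dataclass
class RigidTransform:
    """Result of a rigid registration (moving -> fixed frame)."""

    translation_mm: np.ndarray  # (z, y, x) mm
    rotation_rad: np.ndarray  # Euler angles about (x, y, z), radians
    center_mm: np.ndarray  # (z, y, x) rotation centre
    success: bool
    similarity: float  # correlation of aligned moving vs fixed

    def apply(self, points_zyx: np.ndarray) -> np.ndarray:
        """Map world-mm points from the moving frame into the fixed frame."""
        pts = np.atleast_2d(np.asarray(points_zyx, float))[:, ::-1]  # -> (x,y,z)
        t = sitk.Euler3DTransform()
        t.SetCenter(tuple(self.center_mm[::-1]))
        t.SetRotation(*self.rotation_rad)
        t.SetTranslation(tuple(self.translation_mm[::-1]))
        inv = t.GetInverse()
        out = np.array([inv.TransformPoint(tuple(p)) for p in pts])
        return out[:, ::-1]


def _to_sitk(grid: VoxelGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(grid.values.astype(np.float64))
    img.SetSpacing(tuple(grid.spacing[::-1]))
    img.SetOrigin(tuple(grid.origin[::-1]))
    return img


def register_rigid(moving: VoxelGrid, fixed: VoxelGrid,
                   min_similarity: float = 0.5) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Uses moments initialization followed by gradient descent on the
    mean-squares intensity metric.  The returned ``success`` flag is
    False when the post-alignment intensity correlation falls below
    ``min_similarity`` (e.g. structureless inputs), so a bad fit is
    never reported silently.
    """
    for name, g in (("moving", moving), ("fixed", fixed)):
        if float(np.std(g.values)) < 1e-9:
            raise ValueError(f"{name} volume has (near-)constant intensity; "
                             "registration is degenerate")
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200,
        relaxationFactor=0.5)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(init, inPlace=False)
    final = reg.Execute(f_img, m_img).Downcast()
    if isinstance(final, sitk.CompositeTransform):
        final = final.GetNthTransform(0).Downcast()

    aligned = sitk.Resample(m_img, f_img, final, sitk.sitkLinear, -1000.0)
    a = sitk.GetArrayFromImage(aligned).ravel()
    b = fixed.values.ravel()
    keep = a > -999.5  # ignore padded voxels
    if keep.sum() < 10 or np.std(a[keep]) < 1e-9 or np.std(b[keep]) < 1e-9:
        sim = 0.0
    else:
        sim = float(np.corrcoef(a[keep], b[keep])[0, 1])
    return RigidTransform(
        translation_mm=np.asarray(final.GetTranslation())[::-1].copy(),
        rotation_rad=np.asarray(
            [final.GetAngleX(), final.GetAngleY(), final.GetAngleZ()]),
        center_mm=np.asarray(final.GetCenter())[::-1].copy(),
        success=sim >= min_similarity,
        similarity=sim,
    )


@dataclass
class Matching:
    """Mutual-nearest-neighbour lesion matching across two exams."""

    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    unmatched_prior: list[int] = field(default_factory=list)
    unmatched_current: list[int] = field(default_factory=list)


def pair_nodules(lesions_prior, lesions_current,
                 transform: RigidTransform | None = None,
                 gate_mm: float = 10.0) -> Matching:
    """Match lesion centroids across time by mutual nearest neighbour.

    Prior centroids (world mm, z/y/x) are mapped through ``transform``
    when given; pairs are kept when each is the other's nearest
    neighbour and their distance is within ``gate_mm``.  Unmatched
    lesions on either side are flagged, never dropped silently.
    """
    prior = np.atleast_2d(np.asarray(lesions_prior, float)) \
        if len(lesions_prior) else np.empty((0, 3))
    curr = np.atleast_2d(np.asarray(lesions_current, float)) \
        if len(lesions_current) else np.empty((0, 3))
    if transform is not None and prior.size:
        prior = transform.apply(prior)
    if prior.shape[0] == 0 or curr.shape[0] == 0:
        return Matching([], list(range(prior.shape[0])),
                        list(range(curr.shape[0])))
    d = np.linalg.norm(prior[:, None, :] - curr[None, :, :], axis=2)
    nn_p = d.argmin(axis=1)
    nn_c = d.argmin(axis=0)
    pairs, mp, mc = [], set(), set()
    for i, j in enumerate(nn_p):
        if nn_c[j] == i and d[i, j] <= gate_mm:
            pairs.append((i, int(j), float(d[i, j])))
            mp.add(i)
            mc.add(int(j))
    return Matching(
        pairs=pairs,
        unmatched_prior=[i for i in range(prior.shape[0]) if i not in mp],
        unmatched_current=[j for j in range(curr.shape[0]) if j not in mc],
    )


def _resample(values, grid: VoxelGrid, center_mm, size: int, spacing: float,
              order: int, fill: float) -> np.ndarray:
    center_idx = grid.world_to_index(center_mm)
    lo = np.any(center_idx < -0.5) or np.any(
        center_idx > np.asarray(grid.shape) - 0.5)
    if lo:
        raise ValueError("VOI centre lies outside the scan")
    offs = (np.arange(size) - (size - 1) / 2.0) * spacing
    coords_mm = [offs + c for c in np.asarray(center_mm, float)]
    zz, yy, xx = np.meshgrid(
        *[(c - o) / s for c, o, s in zip(coords_mm, grid.origin, grid.spacing)],
        indexing="ij")
    return ndimage.map_coordinates(
        values, np.stack([zz, yy, xx]), order=order, mode="constant",
        cval=fill)


def extract_voi(grid: VoxelGrid, center_mm, size: int = 32,
                spacing: float = 1.0) -> VoxelGrid:
    """Crop an isotropic cubic VOI centred on a world-mm point.

    The output is exactly ``size`` voxels per axis at ``spacing`` mm,
    linearly resampled, padded with -1000 HU (air) outside the scan.
    """
    vals = _resample(grid.values, grid, center_mm, size, spacing,
                     order=1, fill=-1000.0)
    origin = np.asarray(center_mm, float) - (size - 1) / 2.0 * spacing
    return VoxelGrid(vals, (spacing,) * 3, tuple(origin))


def extract_mask_voi(mask: NoduleMask, center_mm, size: int = 32,
                     spacing: float = 1.0) -> NoduleMask:
    """Nearest-neighbour VOI crop of a mask (background-padded)."""
    grid = VoxelGrid(mask.values.astype(np.float64), mask.spacing, mask.origin)
    vals = _resample(grid.values, grid, center_mm, size, spacing,
                     order=0, fill=0.0)
    origin = np.asarray(center_mm, float) - (size - 1) / 2.0 * spacing
    return NoduleMask(vals > 0.5, (spacing,) * 3, tuple(origin))


def segment_phantom(grid: VoxelGrid, background_hu: float = -850.0,
                    noise_sd: float = 25.0, closing_radius: int = 1,
                    threshold: float | None = None) -> NoduleMask:
    """Fixture segmenter for phantom pipelines.

    Thresholds at ``background + 3 * noise_sd`` (or an explicit
    threshold), keeps the largest connected component and applies a
    morphological closing.  This is a test fixture for synthetic data,
    not a lung lesion segmenter.
    """
    thr = background_hu + 3.0 * noise_sd if threshold is None else threshold
    fg = grid.values >= thr
    if not fg.any():
        raise ValueError("segmentation found no voxels above threshold")
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    if closing_radius > 0:
        fg = ndimage.binary_closing(
            fg, structure=ndimage.generate_binary_structure(3, 1),
            iterations=closing_radius)
    return NoduleMask(fg, grid.spacing, grid.origin)
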