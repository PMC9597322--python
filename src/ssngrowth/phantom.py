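"""Synthetic longitudinal nodule phantoms with analytic ground truth.

The simulator embeds a soft-edged ellipsoidal ground-glass lesion in
noisy lung parenchyma and grows it across 2-3 time points with known
kinetics, so that every downstream stage (measurement, pairing,
labelling, model training) can be exercised against exact ground truth.

Lesion membership is a smoothed indicator: the hard ellipsoid indicator
evaluated at voxel centres, blurred by a Gaussian of physical scale
``edge_softness`` (mm).  The ground-truth mask thresholds membership at
0.5 and the rendered attenuation blends parenchyma and lesion HU by
membership, so a threshold segmentation at the HU midpoint recovers the
mask exactly on noiseless phantoms.

Ground-truth quantities are reported twice: on the voxelized mask
(exact targets for the measurement code) and in closed form on the
continuous ellipsoid (for convergence checks).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import NoduleMask, VoxelGrid

__all__ = [
    "PhantomSpec",
    "GrowthKinetics",
    "PhantomTruth",
    "KineticsRanges",
    "CohortEffect",
    "render_phantom",
    "simulate_trajectory",
    "generate_cohort",
    "mass_mg",
]

DAYS_PER_YEAR = 365.0


def mass_mg(volume_mm3: float, mean_hu: float) -> float:
    """Nodule mass in mg: ``M = V * (A + 1000) / 1000``.

    Follows the water-calibrated convention that attenuation A (HU)
    maps linearly to physical density, with air (-1000 HU) massless.
    """
    return volume_mm3 * (mean_hu + 1000.0) / 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Static description of one synthetic nodule in its VOI.

    ``nodule_radii`` are ellipsoid semi-axes in mm, ordered (z, y, x)
    like everything else.  The initial maximal diameter must lie in the
    5-30 mm screening-inclusion window.
    """

    voi_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = -850.0
    background_noise_sd: float = 25.0
    nodule_center: tuple[float, float, float] = (24.0, 24.0, 24.0)
    nodule_radii: tuple[float, float, float] = (5.0, 5.0, 5.0)
    nodule_mean_hu: float = -650.0
    edge_softness: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.nodule_radii):
            raise ValueError("all nodule radii must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        d_max = 2.0 * max(self.nodule_radii)
        if not (5.0 <= d_max <= 30.0):
            raise ValueError(
                f"initial maximal diameter {d_max:.1f} mm outside the "
                "5-30 mm inclusion window"
            )
        if self.nodule_mean_hu < self.background_hu:
            raise ValueError("nodule attenuation must not be below background")
        if self.background_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    def with_(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GrowthKinetics:
    """Growth law for a nodule trajectory.

    radius_scale_per_year multiplies every semi-axis per 365 days;
    hu_delta_per_year drifts the lesion attenuation additively.
    ``interval_days`` holds 1 or 2 inter-exam gaps (2 or 3 exams).
    """

    radius_scale_per_year: float = 1.0
    hu_delta_per_year: float = 0.0
    interval_days: tuple[float, ...] = (365.0,)
    offset_sd_mm: float = 0.0

    def __post_init__(self):
        if self.radius_scale_per_year <= 0:
            raise ValueError("radius_scale_per_year must be positive")
        if len(self.interval_days) not in (1, 2):
            raise ValueError("interval_days must list 1 or 2 gaps (2 or 3 exams)")
        if any(d <= 0 for d in self.interval_days):
            raise ValueError("intervals must be positive")


@dataclass
class PhantomTruth:
    """Exact ground truth for one rendered time point.

    ``volume/mean_hu/mass`` are defined on the voxelized mask and the
    noiseless rendering (what a perfect measurement must reproduce to
    machine precision); the ``analytic_*`` fields are the continuous
    ellipsoid values.  ``annualized_mass_rate`` and ``growth_label``
    relate this time point to the previous one in its trajectory
    (``None`` at the first exam).
    """

    volume: float
    mean_hu: float
    mass: float
    analytic_volume: float
    analytic_mean_hu: float
    analytic_mass: float
    center: tuple[float, float, float]
    annualized_mass_rate: float | None = None
    growth_label: bool | None = None


def _membership(spec: PhantomSpec, center=None, radii=None) -> np.ndarray:
    center = np.asarray(spec.nodule_center if center is None else center, float)
    radii = np.asarray(spec.nodule_radii if radii is None else radii, float)
    shape = spec.voi_shape
    sp = np.asarray(spec.spacing, float)
    hi_world = (np.asarray(shape) - 1) * sp
    pad = np.asarray([spec.edge_softness] * 3)
    if np.any(center - radii - pad < 0) or np.any(center + radii + pad > hi_world):
        axis = "zyx"[int(np.argmax(np.maximum(radii + pad - center,
                                              center + radii + pad - hi_world)))]
        raise ValueError(f"nodule extends beyond VOI bounds along axis {axis!r}")
    zz = np.arange(shape[0]) * sp[0]
    yy = np.arange(shape[1]) * sp[1]
    xx = np.arange(shape[2]) * sp[2]
    dz = (zz - center[0]) / radii[0]
    dy = (yy - center[1]) / radii[1]
    dx = (xx - center[2]) / radii[2]
    r2 = (dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2)
    m = (r2 <= 1.0).astype(np.float64)
    if spec.edge_softness > 0:
        m = gaussian_filter(m, sigma=np.asarray([spec.edge_softness] * 3) / sp,
                            mode="constant")
    return m


def render_phantom(
    spec: PhantomSpec,
    *,
    center=None,
    radii=None,
    nodule_hu: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[VoxelGrid, NoduleMask, PhantomTruth]:
    """Render one time point of a nodule phantom.

    Returns the noisy HU grid, the ground-truth mask (membership >=
    0.5 before noise) and the exact truth record.  The keyword
    overrides exist so trajectory simulation can evolve geometry and
    attenuation without rebuilding specs.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    center = np.asarray(spec.nodule_center if center is None else center, float)
    radii = np.asarray(spec.nodule_radii if radii is None else radii, float)
    hu = spec.nodule_mean_hu if nodule_hu is None else float(nodule_hu)

    m = _membership(spec, center=center, radii=radii)
    mask = m >= 0.5
    if not mask.any():
        raise ValueError("lesion membership never reaches 0.5; nodule too soft/small")
    clean = spec.background_hu + m * (hu - spec.background_hu)
    noise = (rng.normal(0.0, spec.background_noise_sd, size=m.shape)
             if spec.background_noise_sd > 0 else 0.0)
    grid = VoxelGrid(clean + noise, spec.spacing)
    nodmask = NoduleMask(mask, spec.spacing)

    vox_vol = float(mask.sum()) * grid.voxel_volume
    vox_hu = float(clean[mask].mean())
    an_vol = 4.0 / 3.0 * np.pi * float(np.prod(radii))
    truth = PhantomTruth(
        volume=vox_vol,
        mean_hu=vox_hu,
        mass=mass_mg(vox_vol, vox_hu),
        analytic_volume=an_vol,
        analytic_mean_hu=hu,
        analytic_mass=mass_mg(an_vol, hu),
        center=tuple(center),
    )
    return grid, nodmask, truth


def simulate_trajectory(
    spec: PhantomSpec, kin: GrowthKinetics
) -> list[tuple[VoxelGrid, NoduleMask, PhantomTruth]]:
    """Render 2-3 consecutive exams of one nodule under fixed kinetics.

    Time point k scales the semi-axes by ``radius_scale_per_year``
    raised to the elapsed years and drifts the mean HU linearly; a
    small random rigid offset (SD ``offset_sd_mm``, recorded in the
    truth centre) emulates inter-scan positioning differences.
    """
    rng = np.random.default_rng(spec.seed)
    elapsed = np.concatenate([[0.0], np.cumsum(kin.interval_days)]) / DAYS_PER_YEAR
    out = []
    prev_mass = None
    for k, t in enumerate(elapsed):
        radii = np.asarray(spec.nodule_radii) * kin.radius_scale_per_year ** t
        hu = spec.nodule_mean_hu + kin.hu_delta_per_year * t
        center = np.asarray(spec.nodule_center, float)
        if k > 0 and kin.offset_sd_mm > 0:
            center = center + rng.normal(0.0, kin.offset_sd_mm, size=3)
        grid, mask, truth = render_phantom(
            spec, center=center, radii=radii, nodule_hu=hu, rng=rng
        )
        if k > 0:
            dt = kin.interval_days[k - 1]
            rate = (truth.mass - prev_mass) / prev_mass * (DAYS_PER_YEAR / dt)
            truth.annualized_mass_rate = rate
            truth.growth_label = rate >= 0.25
        prev_mass = truth.mass
        out.append((grid, mask, truth))
    return out


@dataclass(frozen=True)
class KineticsRanges:
    """Uniform sampling ranges for one class's growth kinetics."""

    radius_scale: tuple[float, float]
    hu_delta: tuple[float, float]
    init_diameter: tuple[float, float]
    init_hu: tuple[float, float]


@dataclass(frozen=True)
class CohortEffect:
    """Class-conditional generating distributions for a cohort.

    Defaults emulate the observed contrast between growing and stable
    sub-solid nodules: growers are larger and denser at baseline
    (median diameter ~10 vs ~6 mm, mean HU ~-600 vs ~-640) and gain
    both volume and attenuation, so their annualized mass rate lands
    well above the 25%/year criterion while stable nodules stay well
    below it.
    """

    growth: KineticsRanges = field(default_factory=lambda: KineticsRanges(
        radius_scale=(1.10, 1.25), hu_delta=(20.0, 60.0),
        init_diameter=(6.5, 16.0), init_hu=(-650.0, -500.0)))
    non_growth: KineticsRanges = field(default_factory=lambda: KineticsRanges(
        radius_scale=(0.97, 1.03), hu_delta=(-10.0, 10.0),
        init_diameter=(5.0, 8.0), init_hu=(-700.0, -560.0)))


@dataclass
class CohortSample:
    """One simulated nodule trajectory with full ground truth."""

    subject_id: str
    exams: list[tuple[VoxelGrid, NoduleMask, PhantomTruth]]
    interval_days: tuple[float, ...]
    y_true: float
    growth_label: bool
    spec: PhantomSpec
    kinetics: GrowthKinetics


def _draw_sample(i, is_growth, eff: CohortEffect, n_exams, interval_range,
                 voi_shape, noise_sd, offset_sd, rng) -> CohortSample:
    rng_s = np.random.default_rng(rng.integers(0, 2**31 - 1))
    rg = eff.growth if is_growth else eff.non_growth
    d = rng_s.uniform(*rg.init_diameter)
    a = d / 2.0
    radii = (a * rng_s.uniform(0.7, 1.0), a * rng_s.uniform(0.7, 1.0), a)
    hu = rng_s.uniform(*rg.init_hu)
    shape = np.asarray(voi_shape)
    center = (shape - 1) / 2.0 + rng_s.uniform(-2.0, 2.0, size=3)
    spec = PhantomSpec(
        voi_shape=tuple(int(s) for s in voi_shape),
        nodule_center=tuple(center),
        nodule_radii=radii,
        nodule_mean_hu=hu,
        background_noise_sd=noise_sd,
        # soft ground-glass margin, capped so small lesions keep a core
        edge_softness=float(min(rng_s.uniform(0.3, 1.2), min(radii) / 3.0)),
        seed=int(rng_s.integers(0, 2**31 - 1)),
    )
    kin = GrowthKinetics(
        radius_scale_per_year=float(rng_s.uniform(*rg.radius_scale)),
        hu_delta_per_year=float(rng_s.uniform(*rg.hu_delta)),
        interval_days=tuple(float(rng_s.uniform(*interval_range))
                            for _ in range(n_exams - 1)),
        offset_sd_mm=offset_sd,
    )
    exams = simulate_trajectory(spec, kin)
    truth_last = exams[-1][2]
    return CohortSample(
        subject_id=f"S{i:04d}",
        exams=exams,
        interval_days=kin.interval_days,
        y_true=truth_last.annualized_mass_rate,
        growth_label=truth_last.growth_label,
        spec=spec,
        kinetics=kin,
    )


def generate_cohort(
    n: int,
    growth_fraction: float = 0.07,
    effect: CohortEffect | None = None,
    seed: int = 0,
    *,
    n_exams: int = 3,
    interval_range: tuple[float, float] = (330.0, 430.0),
    voi_shape: tuple[int, int, int] = (48, 48, 48),
    noise_sd: float = 25.0,
    offset_sd_mm: float = 1.5,
    out_dir=None,
) -> tuple[list[CohortSample], pd.DataFrame]:
    """Generate a labelled cohort of nodule trajectories.

    The default 7% growth prevalence mirrors screening cohorts; the
    class-conditional kinetics come from :class:`CohortEffect`.  Counts
    per class are exact (stratified).  With ``out_dir`` set, volumes
    and masks are written as NIfTI and the manifest as CSV.

    Returns the samples and a manifest DataFrame (one row per
    trajectory, deterministic for fixed arguments and seed).
    """
    if n <= 0:
        raise ValueError("cohort size n must be positive")
    if not 0.0 <= growth_fraction <= 1.0:
        raise ValueError("growth_fraction must lie in [0, 1]")
    if n_exams not in (2, 3):
        raise ValueError("n_exams must be 2 or 3")
    effect = CohortEffect() if effect is None else effect
    rng = np.random.default_rng(seed)
    n_growth = int(round(n * growth_fraction))
    labels = np.array([True] * n_growth + [False] * (n - n_growth))

    samples, rows = [], []
    for i, is_growth in enumerate(labels):
        s = _draw_sample(i, bool(is_growth), effect, n_exams, interval_range,
                         voi_shape, noise_sd, offset_sd_mm, rng)
        samples.append(s)
        row = {
            "subject_id": s.subject_id,
            "n_exams": len(s.exams),
            "interval_days_last": s.interval_days[-1],
            "y_true": s.y_true,
            "growth_label": s.growth_label,
            "init_diameter_mm": 2 * max(s.spec.nodule_radii),
            "init_mean_hu": s.spec.nodule_mean_hu,
            "radius_scale_per_year": s.kinetics.radius_scale_per_year,
            "hu_delta_per_year": s.kinetics.hu_delta_per_year,
        }
        for k, (_, _, truth) in enumerate(s.exams):
            row[f"mass_mg_t{k}"] = truth.mass
        rows.append(row)
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for s in samples:
            ps = []
            for k, (grid, mask, _) in enumerate(s.exams):
                vp = out_dir / f"{s.subject_id}_t{k}_voi.nii.gz"
                mp = out_dir / f"{s.subject_id}_t{k}_mask.nii.gz"
                grid.save_nifti(vp)
                mask.save_nifti(mp)
                ps.append((vp.name, mp.name))
            paths.append(";".join(f"{v}|{m}" for v, m in ps))
        manifest = manifest.assign(files=paths)
        manifest.to_csv(out_dir / "manifest.csv", index=False, float_format="%.10g")

    return samples, manifest
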