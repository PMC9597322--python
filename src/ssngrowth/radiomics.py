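"""Hand-crafted radiomic features, LASSO selection and logistic scoring.

The feature families cover what a standard radiomics pipeline extracts
from a masked lesion: first-order intensity statistics, 3D shape
descriptors, grey-level co-occurrence (GLCM) summaries and grey-level
run-length (GLRLM) summaries.  Intensities are discretized under the
mask with a fixed 25 HU bin width before texture computation; texture
matrices aggregate the 13 unique 3D directions.

The full enumeration of features used elsewhere is not reproducible,
so this module's contract is a *documented, deterministic* set (the
count is recorded in the output metadata), not name-for-name parity
with any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.preprocessing import StandardScaler

from .grids import NoduleMask, VoxelGrid

__all__ = [
    "extract_features",
    "feature_names",
    "extract_cohort_features",
    "lasso_select",
    "fit_predict_logistic",
    "RadiomicsModel",
]

BIN_WIDTH_HU = 25.0

# the 13 unique direction vectors of a 3D 26-neighbourhood (up to sign)
_DIRECTIONS = [(0, 0, 1), (0, 1, 0), (1, 0, 0),
               (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1),
               (1, 1, 0), (1, -1, 0),
               (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)]


# ---------------------------------------------------------------- first order
def _first_order(vals: np.ndarray) -> dict[str, float]:
    v = np.asarray(vals, float)
    n = v.size
    mean = v.mean()
    p10, q1, med, q3, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    hist, _ = np.histogram(v, bins=_bin_edges(v))
    pk = hist / n
    pk = pk[pk > 0]
    return {
        "fo_mean": mean,
        "fo_median": med,
        "fo_min": v.min(),
        "fo_max": v.max(),
        "fo_range": v.max() - v.min(),
        "fo_p10": p10,
        "fo_p90": p90,
        "fo_iqr": q3 - q1,
        "fo_variance": v.var(),
        "fo_std": v.std(),
        "fo_skewness": _moment_ratio(v, 3),
        "fo_kurtosis": _moment_ratio(v, 4),
        "fo_energy": float((v ** 2).sum()),
        "fo_rms": float(np.sqrt((v ** 2).mean())),
        "fo_mad": float(np.abs(v - mean).mean()),
        "fo_robust_mad": _robust_mad(v, p10, p90),
        "fo_entropy": float(-(pk * np.log2(pk)).sum()),
        "fo_uniformity": float((pk ** 2).sum()),
    }


def _moment_ratio(v, k):
    s = v.std()
    if s < 1e-12:
        return 0.0
    return float(((v - v.mean()) ** k).mean() / s ** k)


def _robust_mad(v, p10, p90):
    sel = v[(v >= p10) & (v <= p90)]
    if sel.size == 0:
        return 0.0
    return float(np.abs(sel - sel.mean()).mean())


def _bin_edges(v):
    lo = np.floor(v.min() / BIN_WIDTH_HU) * BIN_WIDTH_HU
    hi = np.ceil(v.max() / BIN_WIDTH_HU) * BIN_WIDTH_HU
    if hi <= lo:
        hi = lo + BIN_WIDTH_HU
    return np.arange(lo, hi + BIN_WIDTH_HU / 2, BIN_WIDTH_HU)


# --------------------------------------------------------------------- shape
def _shape(mask: NoduleMask) -> dict[str, float]:
    m = mask.values
    sp = np.asarray(mask.spacing)
    volume = m.sum() * float(np.prod(sp))
    padded = np.pad(m.astype(float), 1)
    try:
        verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(sp))
        surface = float(mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        surface = 6.0 * volume ** (2 / 3)  # single-voxel fallback
    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphere_surface = 4.0 * np.pi * r_eq ** 2
    idx = np.argwhere(m) * sp
    c = idx.mean(axis=0)
    cov = np.cov((idx - c).T) if idx.shape[0] > 1 else np.zeros((3, 3))
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0, None)
    axes = 4.0 * np.sqrt(eig)  # PCA axis lengths
    d2 = ((idx[:, None, :] - idx[None, :, :]) ** 2).sum(-1) \
        if idx.shape[0] <= 400 else None
    if d2 is not None:
        max_diam = float(np.sqrt(d2.max()))
    else:  # hull-corner approximation for big masks
        from scipy.spatial import ConvexHull
        pts = idx
        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
        max_diam = float(np.sqrt(((hp[:, None] - hp[None]) ** 2).sum(-1).max()))
    return {
        "sh_volume": volume,
        "sh_surface_area": surface,
        "sh_surface_to_volume": surface / volume,
        "sh_sphericity": sphere_surface / surface,
        "sh_compactness1": volume / (np.sqrt(np.pi) * surface ** 1.5),
        "sh_compactness2": 36.0 * np.pi * volume ** 2 / surface ** 3,
        "sh_spherical_disproportion": surface / sphere_surface,
        "sh_max_diameter_3d": max_diam,
        "sh_major_axis": float(axes[0]),
        "sh_minor_axis": float(axes[1]),
        "sh_least_axis": float(axes[2]),
        "sh_elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0,
        "sh_flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0,
        "sh_equivalent_diameter": 2.0 * r_eq,
    }


# --------------------------------------------------------------------- GLCM
def _quantize(voi: VoxelGrid, mask: NoduleMask) -> tuple[np.ndarray, int]:
    vals = voi.values[mask.values]
    edges = _bin_edges(vals)
    q = np.zeros(voi.shape, dtype=np.int32)  # 0 = outside mask
    q[mask.values] = np.clip(np.digitize(voi.values[mask.values], edges), 1,
                             len(edges) - 1)
    return q, len(edges) - 1


def _glcm(q: np.ndarray, n_levels: int) -> np.ndarray:
    P = np.zeros((n_levels, n_levels))
    for dz, dy, dx in _DIRECTIONS:
        a = q
        b = np.roll(q, shift=(-dz, -dy, -dx), axis=(0, 1, 2))
        valid = np.ones_like(q, bool)
        for ax, d in zip((0, 1, 2), (dz, dy, dx)):
            if d > 0:
                sl = [slice(None)] * 3
                sl[ax] = slice(q.shape[ax] - d, None)
                valid[tuple(sl)] = False
            elif d < 0:
                sl = [slice(None)] * 3
                sl[ax] = slice(None, -d)
                valid[tuple(sl)] = False
        keep = valid & (a > 0) & (b > 0)
        np.add.at(P, (a[keep] - 1, b[keep] - 1), 1.0)
    P = P + P.T  # symmetric
    total = P.sum()
    return P / total if total > 0 else P


def _glcm_features(P: np.ndarray) -> dict[str, float]:
    n = P.shape[0]
    i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = (np.arange(1, n + 1) * px).sum()
    muy = (np.arange(1, n + 1) * py).sum()
    sx = np.sqrt(((np.arange(1, n + 1) - mux) ** 2 * px).sum())
    sy = np.sqrt(((np.arange(1, n + 1) - muy) ** 2 * py).sum())
    pxy_sum = np.zeros(2 * n - 1)  # k = i + j, 2..2n
    pxy_diff = np.zeros(n)  # k = |i - j|, 0..n-1
    np.add.at(pxy_sum, (i + j - 2).ravel(), P.ravel())
    np.add.at(pxy_diff, np.abs(i - j).ravel(), P.ravel())
    ks = np.arange(2, 2 * n + 1)
    kd = np.arange(0, n)
    nz = P > 0
    ent = float(-(P[nz] * np.log2(P[nz])).sum())
    se_nz = pxy_sum > 0
    de_nz = pxy_diff > 0
    diff_avg = (kd * pxy_diff).sum()
    corr = float((((i - mux) * (j - muy) * P).sum()) / (sx * sy)) \
        if sx > 0 and sy > 0 else 1.0
    return {
        "glcm_joint_max": float(P.max()),
        "glcm_joint_avg": float((i * P).sum()),
        "glcm_joint_entropy": ent,
        "glcm_energy": float((P ** 2).sum()),
        "glcm_contrast": float(((i - j) ** 2 * P).sum()),
        "glcm_dissimilarity": float((np.abs(i - j) * P).sum()),
        "glcm_homogeneity": float((P / (1.0 + np.abs(i - j))).sum()),
        "glcm_idm": float((P / (1.0 + (i - j) ** 2)).sum()),
        "glcm_idmn": float((P / (1.0 + ((i - j) / n) ** 2)).sum()),
        "glcm_idn": float((P / (1.0 + np.abs(i - j) / n)).sum()),
        "glcm_inverse_variance": float(
            (P[i != j] / ((i - j)[i != j] ** 2)).sum()),
        "glcm_correlation": corr,
        "glcm_autocorrelation": float((i * j * P).sum()),
        "glcm_cluster_tendency": float((((i + j) - mux - muy) ** 2 * P).sum()),
        "glcm_cluster_shade": float((((i + j) - mux - muy) ** 3 * P).sum()),
        "glcm_cluster_prominence": float((((i + j) - mux - muy) ** 4 * P).sum()),
        "glcm_sum_average": float((ks * pxy_sum).sum()),
        "glcm_sum_entropy": float(-(pxy_sum[se_nz] * np.log2(pxy_sum[se_nz])).sum()),
        "glcm_sum_variance": float(((ks - (ks * pxy_sum).sum()) ** 2 * pxy_sum).sum()),
        "glcm_diff_average": float(diff_avg),
        "glcm_diff_entropy": float(-(pxy_diff[de_nz] * np.log2(pxy_diff[de_nz])).sum()),
        "glcm_diff_variance": float(((kd - diff_avg) ** 2 * pxy_diff).sum()),
        "glcm_max_prob_contrast": float(((i - j) ** 2 * P).max()),
        "glcm_marginal_variance": float(sx ** 2),
    }


# -------------------------------------------------------------------- GLRLM
def _glrlm(q: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length matrix R[g, l-1] aggregated over the 13 directions."""
    shape = q.shape
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    max_run = int(np.ceil(np.sqrt(sum(s ** 2 for s in shape)))) + 1
    R = np.zeros((n_levels, max_run))
    flat_g = q.ravel()
    for d in _DIRECTIONS:
        dz, dy, dx = d
        # line id: project position onto two vectors orthogonal in index space
        t = zz * dz + yy * dy + xx * dx
        key1 = zz * (1 - abs(dz)) + 997 * yy * (1 - abs(dy)) \
            + 997 * 997 * xx * (1 - abs(dx))
        # disambiguate diagonal lines fully with a second key
        key2 = (yy * dz - zz * dy) + 2003 * (xx * dy - yy * dx) \
            + 2003 * 2003 * (xx * dz - zz * dx)
        order = np.lexsort((t.ravel(), key2.ravel(), key1.ravel()))
        g = flat_g[order]
        same_line = (key1.ravel()[order][1:] == key1.ravel()[order][:-1]) & \
            (key2.ravel()[order][1:] == key2.ravel()[order][:-1])
        breaks = np.nonzero(~(same_line & (g[1:] == g[:-1])))[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [g.size - 1]])
        lens = ends - starts + 1
        levels = g[starts]
        keep = levels > 0
        np.add.at(R, (levels[keep] - 1, lens[keep] - 1), 1.0)
    used = np.nonzero(R.sum(axis=0))[0]
    last = used.max() + 1 if used.size else 1
    return R[:, :last]


def _glrlm_features(R: np.ndarray) -> dict[str, float]:
    n_g, n_l = R.shape
    Nr = R.sum()
    if Nr == 0:
        return {f: 0.0 for f in _GLRLM_NAMES}
    g = np.arange(1, n_g + 1)[:, None]
    l = np.arange(1, n_l + 1)[None, :]
    rg = R.sum(axis=1)
    rl = R.sum(axis=0)
    Np = (R * l).sum()
    mu_g = ((g * R).sum()) / Nr
    mu_l = ((l * R).sum()) / Nr
    return {
        "glrlm_sre": float((rl / l.ravel() ** 2).sum() / Nr),
        "glrlm_lre": float((rl * l.ravel() ** 2).sum() / Nr),
        "glrlm_gln": float((rg ** 2).sum() / Nr),
        "glrlm_glnn": float((rg ** 2).sum() / Nr ** 2),
        "glrlm_rln": float((rl ** 2).sum() / Nr),
        "glrlm_rlnn": float((rl ** 2).sum() / Nr ** 2),
        "glrlm_rp": float(Nr / Np),
        "glrlm_lglre": float((rg / g.ravel() ** 2).sum() / Nr),
        "glrlm_hglre": float((rg * g.ravel() ** 2).sum() / Nr),
        "glrlm_srlgle": float((R / (g ** 2 * l ** 2)).sum() / Nr),
        "glrlm_srhgle": float((R * g ** 2 / l ** 2).sum() / Nr),
        "glrlm_lrlgle": float((R * l ** 2 / g ** 2).sum() / Nr),
        "glrlm_lrhgle": float((R * g ** 2 * l ** 2).sum() / Nr),
        "glrlm_glv": float(((g - mu_g) ** 2 * R).sum() / Nr),
        "glrlm_rlv": float(((l - mu_l) ** 2 * R).sum() / Nr),
        "glrlm_run_entropy": float(
            -((R[R > 0] / Nr) * np.log2(R[R > 0] / Nr)).sum()),
    }


_GLRLM_NAMES = ["glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_glnn",
                "glrlm_rln", "glrlm_rlnn", "glrlm_rp", "glrlm_lglre",
                "glrlm_hglre", "glrlm_srlgle", "glrlm_srhgle",
                "glrlm_lrlgle", "glrlm_lrhgle", "glrlm_glv", "glrlm_rlv",
                "glrlm_run_entropy"]


def extract_features(voi: VoxelGrid, mask: NoduleMask) -> pd.Series:
    """Deterministic feature vector for one masked nodule.

    Shape features depend on geometry only; first-order and texture
    features are computed from the HU values under the mask after
    fixed-bin (25 HU) discretization.
    """
    if voi.shape != mask.shape:
        raise ValueError("VOI and mask shapes differ")
    if mask.num_foreground == 0:
        raise ValueError("cannot extract features from an empty mask")
    vals = voi.values[mask.values]
    q, n_levels = _quantize(voi, mask)
    feats = {}
    feats.update(_first_order(vals))
    feats.update(_shape(mask))
    feats.update(_glcm_features(_glcm(q, n_levels)))
    feats.update(_glrlm_features(_glrlm(q, n_levels)))
    s = pd.Series(feats, dtype=float)
    if not np.all(np.isfinite(s.to_numpy())):
        bad = s.index[~np.isfinite(s.to_numpy())].tolist()
        raise RuntimeError(f"non-finite features: {bad}")
    return s


def feature_names() -> list[str]:
    """Names of the full feature set, in extraction order."""
    rng_grid = VoxelGrid(np.random.default_rng(0).normal(-650, 30, (6, 6, 6)),
                         (1, 1, 1))
    m = np.zeros((6, 6, 6), bool)
    m[1:5, 1:5, 1:5] = True
    return list(extract_features(rng_grid, NoduleMask(m, (1, 1, 1))).index)


def extract_cohort_features(vois, masks) -> pd.DataFrame:
    """Feature table: one row per nodule, fixed column order."""
    rows = [extract_features(v, m) for v, m in zip(vois, masks)]
    return pd.DataFrame(rows).reset_index(drop=True)


def lasso_select(X: pd.DataFrame, y, Cs=None, cv: int = 5,
                 seed: int = 0) -> list[str]:
    """Feature names with nonzero L1-logistic coefficients at the
    cross-validation-chosen penalty.

    Columns must be standardized by the caller or will be z-scored
    here; constant columns are dropped with a warning.
    """
    import warnings

    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("lasso_select needs both classes")
    X = X.copy()
    const = X.columns[X.std(axis=0) < 1e-12]
    if len(const):
        warnings.warn(f"dropping {len(const)} constant feature(s)")
        X = X.drop(columns=const)
    Xs = StandardScaler().fit_transform(X.to_numpy(float))
    Cs = np.logspace(-3, 2, 30) if Cs is None else np.asarray(Cs, float)
    clf = LogisticRegressionCV(
        Cs=Cs, cv=cv, penalty="l1", solver="liblinear",
        scoring="neg_log_loss", random_state=seed, max_iter=2000)
    clf.fit(Xs, y)
    coef = clf.coef_.ravel()
    return [c for c, w in zip(X.columns, coef) if abs(w) > 1e-10]


@dataclass
class RadiomicsModel:
    """LASSO-selected logistic model over radiomic features."""

    selected: list[str]
    scaler: StandardScaler
    clf: LogisticRegression

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        Xs = self.scaler.transform(X[self.selected].to_numpy(float))
        return self.clf.predict_proba(Xs)[:, 1]


def fit_predict_logistic(X_train: pd.DataFrame, y_train, X_test: pd.DataFrame,
                         selected: list[str] | None = None,
                         seed: int = 0) -> tuple[np.ndarray, RadiomicsModel]:
    """Fit a (ridge-stabilised) logistic model on selected features.

    Standardization statistics come from the training split only and
    are reused at test time.  Returns probabilistic scores for
    ``X_test`` and the fitted model.
    """
    y_train = np.asarray(y_train).astype(int)
    selected = list(X_train.columns) if selected is None else list(selected)
    if len(selected) == 0:
        raise ValueError("no features selected")
    scaler = StandardScaler().fit(X_train[selected].to_numpy(float))
    clf = LogisticRegression(C=1.0, max_iter=5000, random_state=seed)
    clf.fit(scaler.transform(X_train[selected].to_numpy(float)), y_train)
    model = RadiomicsModel(selected, scaler, clf)
    return model.predict_scores(X_test), model
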