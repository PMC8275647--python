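"""Seed-based functional connectivity and group map statistics.

A seed region (by default a 10 mm sphere in the ventromedial prefrontal
cortex, MNI (0, 44, -14)) is averaged over its voxels, correlated
against every voxel in the brain, and the Pearson coefficients are
variance-stabilized with the Fisher z transform.  Group inference on the
resulting maps uses one-sample / paired / two-sample t-tests with
voxel-level thresholding and permutation-based cluster-extent
family-wise-error correction (sign flips for one-sample and paired
designs, group-label shuffles for two-sample designs).  An optional
Benjamini-Hochberg correction over cluster p values is provided as an
alternative reading of "corrected at cluster level".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .nuisance import BOLDImage

__all__ = [
    "SphereROI",
    "SeedZMap",
    "StatMap",
    "Cluster",
    "sphere_roi",
    "seed_fc_map",
    "fisher_z",
    "group_ttest",
    "cluster_threshold",
    "SeedCorrelation",
]

#: clamp applied to |r| = 1 before atanh
R_CLAMP = 1.0 - 1e-6

#: default seed: ventromedial prefrontal cortex, MNI mm
VMPFC_CENTER = (0.0, 44.0, -14.0)


@dataclass(frozen=True)
class SphereROI:
    """A spherical region of interest on a voxel grid.

    ``indices`` holds the (n, 3) integer voxel indices whose centers lie
    within ``radius`` mm of ``center`` (inclusive boundary).
    """

    center: tuple
    radius: float
    indices: np.ndarray
    shape: tuple

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.indices.T)] = True
        return m


def sphere_roi(center, radius: float, shape, affine) -> SphereROI:
    """Voxels whose centers fall within ``radius`` mm of ``center`` (MNI mm)."""
    center = np.asarray(center, dtype=float)
    affine = np.asarray(affine, dtype=float)
    shape = tuple(int(s) for s in shape)
    ijk = np.indices(shape).reshape(3, -1).T.astype(float)
    xyz = ijk @ affine[:3, :3].T + affine[:3, 3]
    d2 = ((xyz - center) ** 2).sum(axis=1)
    inside = d2 <= radius**2 + 1e-9
    if not inside.any():
        raise ValueError(f"empty sphere: no voxel center within {radius} mm of {tuple(center)}")
    return SphereROI(tuple(center), float(radius), ijk[inside].astype(int), shape)


@dataclass
class SeedZMap:
    """Per-voxel Fisher-z seed connectivity for one subject/session.

    ``values`` is NaN at voxels flagged undefined (zero variance);
    ``clamped`` marks voxels whose |r| hit 1 and was clamped.
    """

    values: np.ndarray
    seed: SphereROI = None
    subject: str = ""
    session: str = ""
    undefined: np.ndarray = None
    clamped: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.undefined is None:
            self.undefined = ~np.isfinite(self.values)


def fisher_z(r):
    """Fisher's variance-stabilizing transform, z = atanh(r).

    |r| = 1 (within machine tolerance) is clamped to 1 - 1e-6 so the
    result stays finite; |r| > 1 is an error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    # clamp only the exact boundary; interior values map through untouched
    r = np.where(np.abs(r) >= 1.0, np.sign(r) * R_CLAMP, r)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def _corr_vs_reference(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X against ref; NaN for zero-variance rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sr = np.sqrt((rc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ rc) / (sx * sr)
    r[sx == 0] = np.nan
    return r


def seed_fc_map(bold: BOLDImage, seed: SphereROI) -> SeedZMap:
    """Fisher-z map of the seed-mean time series against every voxel.

    Voxels with zero temporal variance are flagged undefined (NaN);
    voxels perfectly correlated with the seed mean are clamped before
    the atanh and flagged.
    """
    seed_mask = seed.mask() & bold.mask
    if not seed_mask.any():
        raise ValueError("seed does not overlap the brain mask")
    seed_ts = bold.data[seed_mask].mean(axis=0)
    if np.ptp(seed_ts) == 0:
        raise ValueError("seed time series is constant")
    flat = bold.data.reshape(-1, bold.n_volumes)
    r = _corr_vs_reference(flat, seed_ts)
    clamped = np.abs(r) >= R_CLAMP
    z = np.full(r.shape, np.nan)
    ok = np.isfinite(r)
    z[ok] = np.arctanh(np.clip(r[ok], -R_CLAMP, R_CLAMP))
    z = np.where(bold.mask.reshape(-1), z, np.nan).reshape(bold.data.shape[:3])
    return SeedZMap(
        values=z,
        seed=seed,
        clamped=clamped.reshape(bold.data.shape[:3]),
    )


@dataclass
class Cluster:
    """A face-connected set of suprathreshold voxels."""

    voxels: np.ndarray  # (n, ndim) indices
    extent: int
    peak_t: float
    peak_index: tuple
    sign: int
    p_corrected: float = np.nan


@dataclass
class StatMap:
    """Voxelwise group statistic with optional cluster inference."""

    t: np.ndarray
    df: int
    p_voxel: np.ndarray
    clusters: list = field(default_factory=list)
    design: str = "one_sample"
    # payload for permutation-based cluster inference
    _data: tuple = field(default=None, repr=False)


def _as_array_stack(maps) -> np.ndarray:
    vals = [m.values if hasattr(m, "values") else np.asarray(m, dtype=float) for m in maps]
    return np.stack(vals, axis=0)


def _one_sample_t(data: np.ndarray):
    """data: (n, ...) -> t, df with degenerate voxels flagged via inf/0."""
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (sd / np.sqrt(n))
    with np.errstate(invalid="ignore"):
        t = np.where(sd == 0, np.where(m == 0, 0.0, np.sign(m) * np.inf), t)
    return t, n - 1


def _two_sample_t(a: np.ndarray, b: np.ndarray):
    """Pooled-variance two-sample t (classic SPM convention)."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore"):
        t = np.where(sp2 == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    return t, na + nb - 2


def group_ttest(maps, design: str = "one_sample", maps_b=None) -> StatMap:
    """Voxelwise group t-test on z maps.

    Parameters
    ----------
    maps : sequence of SeedZMap/CouplingMap/ndarray
        For ``one_sample``: the maps tested against zero.  For
        ``paired``: the first condition (``maps_b`` holds the matched
        second condition; the test is on ``maps - maps_b``).  For
        ``two_sample``: group A difference maps (``maps_b`` = group B),
        pooled-variance t.
    design : {"one_sample", "paired", "two_sample"}

    Notes
    -----
    Degrees of freedom are n-1 (one-sample and paired) or n1+n2-2
    (two-sample).  Voxels with zero variance and a nonzero effect are
    flagged degenerate by an infinite t.
    """
    a = _as_array_stack(maps)
    if design == "one_sample":
        if a.shape[0] < 3:
            raise ValueError("need n >= 3 maps")
        t, df = _one_sample_t(a)
        payload = ("one_sample", a)
    elif design == "paired":
        b = _as_array_stack(maps_b)
        if a.shape != b.shape:
            raise ValueError("paired design needs matched equal-length lists")
        if a.shape[0] < 3:
            raise ValueError("need n >= 3 pairs")
        t, df = _one_sample_t(a - b)
        payload = ("one_sample", a - b)
    elif design == "two_sample":
        b = _as_array_stack(maps_b)
        if a.shape[0] < 3 or b.shape[0] < 3:
            raise ValueError("need n >= 3 per group")
        t, df = _two_sample_t(a, b)
        payload = ("two_sample", a, b)
    else:
        raise ValueError(f"unknown design {design!r}")
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return StatMap(t=t, df=df, p_voxel=p, design=design, _data=payload)


def _label_clusters(mask: np.ndarray):
    """Face-connected component labeling of a boolean mask."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    labels, n = ndimage.label(mask, structure=structure)
    return labels, n


def _max_cluster_extent(tmap: np.ndarray, t_crit: float) -> int:
    best = 0
    for sign in (1, -1):
        mask = sign * tmap > t_crit
        if not mask.any():
            continue
        labels, n = _label_clusters(mask)
        if n:
            best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def cluster_threshold(
    stat: StatMap,
    voxel_p: float = 0.005,
    cluster_alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
    correction: str = "fwe",
) -> StatMap:
    """Cluster-extent inference by permutation.

    Voxels with two-sided p below ``voxel_p`` are grouped into
    face-connected clusters (positive and negative t separately).  The
    null distribution of the maximum cluster extent is built by
    permutation — sign flips of the subject maps for one-sample/paired
    designs, group-label shuffles for two-sample — and each observed
    cluster gets a family-wise-error p value
    ``(1 + #{null max >= extent}) / (1 + n_perm)``.

    ``correction="fdr"`` additionally applies Benjamini-Hochberg across
    the cluster permutation p values instead of comparing them straight
    to ``cluster_alpha``.
    """
    if stat._data is None:
        raise ValueError("StatMap lacks subject data; build it with group_ttest")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    t_crit = stats.t.ppf(1.0 - voxel_p / 2.0, stat.df)
    tmap = np.nan_to_num(stat.t, nan=0.0, posinf=1e12, neginf=-1e12)

    clusters = []
    for sign in (1, -1):
        mask = sign * tmap > t_crit
        if not mask.any():
            continue
        labels, n = _label_clusters(mask)
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            tv = tmap[labels == lab] * sign
            k = int(np.argmax(tv))
            clusters.append(
                Cluster(
                    voxels=vox,
                    extent=vox.shape[0],
                    peak_t=float(tv[k] * sign),
                    peak_index=tuple(vox[k]),
                    sign=sign,
                )
            )

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    kind = stat._data[0]
    if kind == "one_sample":
        data = stat._data[1]
        n = data.shape[0]
        flat = data.reshape(n, -1)
        ssq = (flat**2).sum(axis=0)
        chunk = 64
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            signs = rng.choice([-1.0, 1.0], size=(m, n))
            means = signs @ flat / n
            with np.errstate(invalid="ignore", divide="ignore"):
                sd = np.sqrt(np.maximum(ssq - n * means**2, 0.0) / (n - 1))
                tperm = means / (sd / np.sqrt(n))
            tperm = np.nan_to_num(tperm, nan=0.0, posinf=1e12, neginf=-1e12)
            for j in range(m):
                null_max[done + j] = _max_cluster_extent(
                    tperm[j].reshape(data.shape[1:]), t_crit
                )
            done += m
    else:  # two_sample
        a, b = stat._data[1], stat._data[2]
        pooled = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        for j in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            tp, _ = _two_sample_t(pooled[perm[:na]], pooled[perm[na:]])
            tp = np.nan_to_num(tp, nan=0.0, posinf=1e12, neginf=-1e12)
            null_max[j] = _max_cluster_extent(tp, t_crit)

    for c in clusters:
        c.p_corrected = (1 + int((null_max >= c.extent).sum())) / (1 + n_perm)
    if correction == "fdr" and clusters:
        ps = np.array([c.p_corrected for c in clusters])
        order = np.argsort(ps)
        m = ps.size
        adj = np.minimum.accumulate((ps[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        for i, k in enumerate(order):
            clusters[k].p_corrected = float(min(adj[i], 1.0))
    elif correction != "fwe":
        raise ValueError("correction must be 'fwe' or 'fdr'")

    clusters.sort(key=lambda c: -c.extent)
    out = StatMap(
        t=stat.t, df=stat.df, p_voxel=stat.p_voxel, clusters=clusters,
        design=stat.design, _data=stat._data,
    )
    out.null_max_extent_ = null_max
    out.cluster_alpha_ = cluster_alpha
    return out


class SeedCorrelation:
    """Estimator computing a seed-based Fisher-z connectivity map.

    Parameters follow the study's seed convention: a 10 mm-radius
    sphere centered on the ventromedial prefrontal cortex.  After
    :meth:`fit` the map is in ``z_map_`` and the resolved ROI in
    ``seed_``.
    """

    def __init__(self, center=VMPFC_CENTER, radius: float = 10.0):
        self.center = center
        self.radius = radius

    def get_params(self, deep: bool = True) -> dict:
        return {"center": self.center, "radius": self.radius}

    def set_params(self, **params) -> "SeedCorrelation":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, bold: BOLDImage, y=None) -> "SeedCorrelation":
        self.seed_ = sphere_roi(self.center, self.radius, bold.data.shape[:3], bold.affine)
        self.z_map_ = seed_fc_map(bold, self.seed_)
        return self

    def transform(self, bold: BOLDImage) -> np.ndarray:
        self.fit(bold)
        return self.z_map_.values
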