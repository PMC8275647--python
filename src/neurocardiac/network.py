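"""Whole-connectome construction and the network-based statistic (NBS).

Node time series are extracted from spherical parcels (10 mm diameter
by default, with at least 10 mm between centers so spheres cannot
overlap), correlated pairwise, Fisher-z transformed, and edges between
centers closer than 20 mm are discarded as potentially contaminated by
spatial smoothing.  Group comparison of connectomes uses the
network-based statistic: an edgewise t-test, a primary
component-forming threshold (default t > 4.17), connected components of
the suprathreshold graph, and permutation-based family-wise-error p
values for each component's extent (edge count).

Permutation schemes: independent within-subject condition swaps (sign
flips of the paired differences) for paired designs; group-label
shuffles for two-sample designs.  The paired null can also be
enumerated exhaustively over all 2^n sign patterns for small n.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cs_connected_components

from .connectivity import R_CLAMP, sphere_roi
from .nuisance import BOLDImage

__all__ = [
    "Parcellation",
    "ConnectivityMatrix",
    "Component",
    "NBSResult",
    "parcel_timeseries",
    "connectivity_matrix",
    "edgewise_ttest",
    "suprathreshold_components",
    "nbs",
    "NetworkBasedStatistic",
]

#: the study's component-forming threshold for paired connectome contrasts
DEFAULT_EDGE_THRESHOLD = 4.17


@dataclass
class Parcellation:
    """Spherical parcels given by labeled center coordinates (MNI mm)."""

    labels: list
    centers: np.ndarray
    radius: float = 5.0  # 10 mm diameter spheres

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if self.centers.shape[0] < 2:
            raise ValueError("need at least 2 nodes")
        if len(self.labels) != self.centers.shape[0]:
            raise ValueError("one label per center required")
        d = self.center_distances()
        off = d[~np.eye(self.n_nodes, dtype=bool)]
        if off.min() < 10.0:
            warnings.warn(
                f"minimum center distance {off.min():.1f} mm < 10 mm; "
                "spheres may overlap",
                stacklevel=2,
            )

    @property
    def n_nodes(self) -> int:
        return self.centers.shape[0]

    def center_distances(self) -> np.ndarray:
        diff = self.centers[:, None, :] - self.centers[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    @classmethod
    def from_tsv(cls, path, radius: float = 5.0) -> "Parcellation":
        df = pd.read_csv(path, sep="\t")
        required = {"label", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise ValueError(f"coordinates TSV needs columns {sorted(required)}")
        return cls(df["label"].tolist(), df[["x", "y", "z"]].to_numpy(), radius=radius)


@dataclass
class ConnectivityMatrix:
    """Node-by-node Fisher-z connectome with an edge validity mask.

    The matrix is symmetric; the diagonal is undefined; edges whose
    parcel centers lie closer than the distance cutoff (or that involve
    a constant node series) are marked invalid.
    """

    z: np.ndarray
    valid: np.ndarray
    subject: str = ""
    session: str = ""

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.z.shape[0]
        if self.z.shape != (n, n) or self.valid.shape != (n, n):
            raise ValueError("z and valid must be square and matched")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


def parcel_timeseries(bold: BOLDImage, parcellation: Parcellation):
    """Mean in-sphere time series per node: (n_nodes, t) plus empty flags."""
    shape = bold.data.shape[:3]
    out = np.full((parcellation.n_nodes, bold.n_volumes), np.nan)
    empty = np.zeros(parcellation.n_nodes, dtype=bool)
    for i, c in enumerate(parcellation.centers):
        try:
            roi = sphere_roi(c, parcellation.radius, shape, bold.affine)
        except ValueError:
            empty[i] = True
            continue
        m = roi.mask() & bold.mask
        if not m.any():
            empty[i] = True
            continue
        out[i] = bold.data[m].mean(axis=0)
    if empty.all():
        raise ValueError("all parcels empty on this grid")
    return out, empty


def connectivity_matrix(
    node_ts: np.ndarray,
    parcellation: Parcellation = None,
    min_distance: float = 20.0,
    subject: str = "",
    session: str = "",
) -> ConnectivityMatrix:
    """Pairwise Fisher-z connectome from node time series.

    Requires at least 30 time points.  When a parcellation is supplied,
    node pairs with center distance below ``min_distance`` mm are
    invalidated (short-range correlations are inflated by smoothing).
    Constant node series yield undefined, invalid edges.
    """
    node_ts = np.asarray(node_ts, dtype=float)
    n_nodes, n_t = node_ts.shape
    if n_t < 30:
        raise ValueError(f"need >= 30 time points, got {n_t}")
    sd = node_ts.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(node_ts)
    r = (r + r.T) / 2.0  # corrcoef is symmetric only up to rounding
    z = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    valid = np.ones((n_nodes, n_nodes), dtype=bool)
    np.fill_diagonal(valid, False)
    np.fill_diagonal(z, np.nan)
    bad = sd == 0
    if bad.any():
        valid[bad, :] = False
        valid[:, bad] = False
        z[bad, :] = np.nan
        z[:, bad] = np.nan
    if parcellation is not None:
        if parcellation.n_nodes != n_nodes:
            raise ValueError("parcellation size does not match node count")
        too_close = parcellation.center_distances() < min_distance
        np.fill_diagonal(too_close, False)
        valid &= ~too_close
    return ConnectivityMatrix(z=z, valid=valid, subject=subject, session=session)


# ---------------------------------------------------------------------------
# edge vectorization helpers

def _triu_indices(n: int):
    return np.triu_indices(n, k=1)


def _stack_edges(matrices):
    """Stack upper-triangle edges: (n_sub, n_edges) plus combined validity."""
    n = matrices[0].n_nodes
    iu = _triu_indices(n)
    vals = np.stack([m.z[iu] for m in matrices], axis=0)
    valid = np.logical_and.reduce([m.valid[iu] for m in matrices], axis=0)
    return vals, valid, iu


def _paired_t_vec(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (sd / np.sqrt(n))
    with np.errstate(invalid="ignore"):
        return np.where(sd == 0, np.where(m == 0, 0.0, np.sign(m) * np.inf), t)


def _paired_t_batch(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t for many sign-flip patterns at once; rows of ``signs`` are patterns."""
    n = diffs.shape[0]
    means = signs @ diffs / n
    ssq = (diffs**2).sum(axis=0)  # invariant under sign flips
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(np.maximum(ssq - n * means**2, 0.0) / (n - 1))
        t = means / (sd / np.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def _two_sample_t_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore"):
        return np.where(sp2 == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)


def edgewise_ttest(
    matrices_a,
    matrices_b,
    design: str = "paired",
    direction: str = "A>B",
):
    """Edgewise t statistics between two connectome sets.

    Returns a symmetric (n, n) t matrix (NaN on invalid edges) with the
    sign convention of ``direction``: ``"A>B"`` leaves t positive where
    A exceeds B, ``"B>A"`` negates, ``"two_sided"`` leaves the signed t
    (thresholding then uses |t|).  Edges invalid in any subject are
    excluded from the whole analysis (complete-case).
    """
    t_vec, valid, iu, _ = _edgewise_t_internal(matrices_a, matrices_b, design, direction)
    n = matrices_a[0].n_nodes
    t = np.full((n, n), np.nan)
    t[iu[0][valid], iu[1][valid]] = t_vec[valid]
    t[iu[1][valid], iu[0][valid]] = t_vec[valid]
    return t


def _edgewise_t_internal(matrices_a, matrices_b, design, direction):
    if design not in ("paired", "two_sample"):
        raise ValueError(f"unknown design {design!r}")
    if direction not in ("A>B", "B>A", "two_sided"):
        raise ValueError(f"unknown direction {direction!r}")
    a, valid_a, iu = _stack_edges(matrices_a)
    b, valid_b, _ = _stack_edges(matrices_b)
    valid = valid_a & valid_b
    if design == "paired":
        if a.shape != b.shape:
            raise ValueError("paired design needs matched equal-length lists")
        if a.shape[0] < 3:
            raise ValueError("need n >= 3 pairs")
        t = _paired_t_vec(a - b)
        payload = ("paired", a - b)
    else:
        if a.shape[0] < 3 or b.shape[0] < 3:
            raise ValueError("need n >= 3 per group")
        t = _two_sample_t_vec(a, b)
        payload = ("two_sample", a, b)
    if direction == "B>A":
        t = -t
    return t, valid, iu, payload


@dataclass
class Component:
    """A connected component of suprathreshold edges."""

    nodes: tuple
    edges: tuple  # ((i, j), ...) with i < j
    extent: int  # number of edges
    fwe_p: float = np.nan


def _components_from_edge_list(rows, cols, n_nodes):
    """Connected components of an undirected edge list (sparse labeling)."""
    if rows.size == 0:
        return []
    g = coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    _, labels = _cs_connected_components(g + g.T, directed=False)
    comps = {}
    for k in range(rows.size):
        comps.setdefault(labels[rows[k]], []).append((int(rows[k]), int(cols[k])))
    out = []
    for edge_list in comps.values():
        nodes = tuple(sorted({v for e in edge_list for v in e}))
        out.append(
            Component(nodes=nodes, edges=tuple(sorted(edge_list)), extent=len(edge_list))
        )
    out.sort(key=lambda c: (-c.extent, c.nodes))
    return out


def suprathreshold_components(t_matrix: np.ndarray, threshold: float = DEFAULT_EDGE_THRESHOLD,
                              two_sided: bool = False) -> list:
    """Connected components of the graph of edges with t above threshold.

    Singleton nodes are ignored; a component's extent is its edge count.
    """
    t_matrix = np.asarray(t_matrix, dtype=float)
    n = t_matrix.shape[0]
    iu = _triu_indices(n)
    tv = t_matrix[iu]
    with np.errstate(invalid="ignore"):
        supra = (np.abs(tv) > threshold) if two_sided else (tv > threshold)
    keep = np.flatnonzero(supra)  # NaN edges compare False, so they drop out
    return _components_from_edge_list(iu[0][keep], iu[1][keep], n)


def _max_extent(t_vec, valid, iu, n_nodes, threshold, two_sided):
    with np.errstate(invalid="ignore"):
        supra = (np.abs(t_vec) > threshold) if two_sided else (t_vec > threshold)
    supra &= valid
    if not supra.any():
        return 0
    keep = np.flatnonzero(supra)
    comps = _components_from_edge_list(iu[0][keep], iu[1][keep], n_nodes)
    return comps[0].extent if comps else 0


@dataclass
class NBSResult:
    """Outcome of a network-based-statistic comparison."""

    threshold: float
    components: list
    n_perm: int
    null_max_extent: np.ndarray
    seed: int
    design: str
    direction: str
    alpha: float = 0.05

    @property
    def significant(self) -> list:
        return [c for c in self.components if c.fwe_p < self.alpha]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "design": self.design,
            "direction": self.direction,
            "alpha": self.alpha,
            "components": [
                {
                    "nodes": list(c.nodes),
                    "edges": [list(e) for e in c.edges],
                    "extent": c.extent,
                    "fwe_p": float(c.fwe_p),
                }
                for c in self.components
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def nbs(
    matrices_a,
    matrices_b,
    design: str = "paired",
    threshold: float = DEFAULT_EDGE_THRESHOLD,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    direction: str = "A>B",
    exhaustive: bool = False,
    sign_patterns: np.ndarray = None,
) -> NBSResult:
    """Network-based statistic with permutation FWE on component extent.

    Edges with t above ``threshold`` (in the requested ``direction``)
    are grouped into connected components; each component's family-wise
    p value is the fraction of permutations whose *maximum* component
    extent reaches the observed extent, with the +1 correction
    ``(1 + count) / (1 + n_perm)`` so p is never exactly zero.

    For paired designs, ``exhaustive=True`` enumerates all ``2**n`` sign
    patterns (n <= 20) — the identity pattern is included, so the p
    value is ``count / 2**n``.  ``sign_patterns`` may supply an explicit
    (m, n) array of +-1 patterns instead of random sampling (also
    evaluated without the +1 correction, since the set is fixed).
    """
    if n_perm < 100 and not exhaustive and sign_patterns is None:
        raise ValueError("n_perm must be >= 100")
    t_vec, valid, iu, payload = _edgewise_t_internal(matrices_a, matrices_b, design, direction)
    n_nodes = matrices_a[0].n_nodes
    two_sided = direction == "two_sided"

    masked_t = np.where(valid, t_vec, np.nan)
    with np.errstate(invalid="ignore"):
        supra = (np.abs(masked_t) > threshold) if two_sided else (masked_t > threshold)
    supra = np.nan_to_num(supra).astype(bool)
    keep = np.flatnonzero(supra)
    components = _components_from_edge_list(iu[0][keep], iu[1][keep], n_nodes)

    sign_for_perm = -1.0 if direction == "B>A" else 1.0
    rng = np.random.default_rng(seed)
    plus_one = True
    if payload[0] == "paired":
        diffs = payload[1]
        n = diffs.shape[0]
        if sign_patterns is not None:
            signs = np.asarray(sign_patterns, dtype=float)
            plus_one = False
        elif exhaustive:
            if n > 20:
                raise ValueError("exhaustive enumeration limited to n <= 20 pairs")
            bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
            signs = np.where(bits == 1, 1.0, -1.0)
            plus_one = False
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        total = signs.shape[0]
        null_max = np.zeros(total, dtype=int)
        chunk = 256
        for start in range(0, total, chunk):
            tb = _paired_t_batch(diffs, signs[start : start + chunk]) * sign_for_perm
            for j in range(tb.shape[0]):
                null_max[start + j] = _max_extent(
                    tb[j], valid, iu, n_nodes, threshold, two_sided
                )
    else:
        a, b = payload[1], payload[2]
        pooled = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        null_max = np.zeros(n_perm, dtype=int)
        for j in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            tp = _two_sample_t_vec(pooled[perm[:na]], pooled[perm[na:]]) * sign_for_perm
            null_max[j] = _max_extent(tp, valid, iu, n_nodes, threshold, two_sided)
        total = n_perm

    for c in components:
        count = int((null_max >= c.extent).sum())
        c.fwe_p = (1 + count) / (1 + total) if plus_one else count / total

    return NBSResult(
        threshold=threshold, components=components, n_perm=total,
        null_max_extent=null_max, seed=seed, design=design,
        direction=direction, alpha=alpha,
    )


class NetworkBasedStatistic:
    """Estimator wrapper around :func:`nbs`.

    ``fit(matrices_a, matrices_b)`` runs the edgewise contrast,
    component extraction and permutation FWE; results land in
    ``result_``, ``components_``, ``significant_`` and ``t_matrix_``.
    """

    def __init__(self, design: str = "paired", threshold: float = DEFAULT_EDGE_THRESHOLD,
                 n_perm: int = 10000, alpha: float = 0.05, seed: int = 0,
                 direction: str = "A>B"):
        self.design = design
        self.threshold = threshold
        self.n_perm = n_perm
        self.alpha = alpha
        self.seed = seed
        self.direction = direction

    def get_params(self, deep: bool = True) -> dict:
        return {
            "design": self.design, "threshold": self.threshold,
            "n_perm": self.n_perm, "alpha": self.alpha, "seed": self.seed,
            "direction": self.direction,
        }

    def set_params(self, **params) -> "NetworkBasedStatistic":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, matrices_a, matrices_b) -> "NetworkBasedStatistic":
        self.result_ = nbs(
            matrices_a, matrices_b, design=self.design, threshold=self.threshold,
            n_perm=self.n_perm, alpha=self.alpha, seed=self.seed,
            direction=self.direction,
        )
        self.components_ = self.result_.components
        self.significant_ = self.result_.significant
        self.t_matrix_ = edgewise_ttest(
            matrices_a, matrices_b, design=self.design, direction=self.direction
        )
        return self
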