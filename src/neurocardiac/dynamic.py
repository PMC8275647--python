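"""Sliding-window co-variation of HRV and seed connectivity.

Heart-rate variability (windowed SDNN) and seed-based functional
connectivity are computed in matched sliding windows (by default 90
volumes long with a 45-volume step, i.e. 50% overlap at TR = 0.484 s —
the windows are defined in volumes; the ~45 s description is nominal).
Per subject, the windowed Fisher-z maps are regressed on the
standardized windowed-SDNN series; the per-voxel slopes are the
subject's coupling map, and the group analysis is a one-sample t-test
with cluster-extent correction.

The SDNN regressor is z-scored before the regression so slopes are
comparable across subjects; an interval belongs to a window when its
later beat falls inside the window's time span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import (
    R_CLAMP,
    SeedZMap,
    SphereROI,
    StatMap,
    _corr_vs_reference,
    cluster_threshold,
    group_ttest,
    seed_fc_map,
    sphere_roi,
)
from .nuisance import BOLDImage
from .physio import IBISeries

__all__ = [
    "WindowScheme",
    "WindowedHRV",
    "CouplingMap",
    "make_windows",
    "windowed_sdnn",
    "windowed_seed_fc",
    "windowed_node_fc",
    "coupling_regression",
    "group_coupling_test",
    "SlidingWindowCoupling",
]


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window index set over a volume series.

    Windows are half-open volume-index pairs ``[start, end)`` of equal
    ``length``, spaced ``step`` volumes apart, all inside the recording.
    """

    n_volumes: int
    length: int = 90
    step: int = 45
    tr: float = 0.484
    t0: float = 0.0

    def __post_init__(self):
        if self.n_volumes < self.length:
            raise ValueError(
                f"recording of {self.n_volumes} volumes shorter than "
                f"window length {self.length}"
            )
        if self.length < 2 or self.step < 1:
            raise ValueError("need length >= 2 and step >= 1")

    @property
    def n_windows(self) -> int:
        return (self.n_volumes - self.length) // self.step + 1

    @property
    def windows(self) -> list:
        return [
            (k * self.step, k * self.step + self.length)
            for k in range(self.n_windows)
        ]

    def window_times(self) -> np.ndarray:
        """(n_windows, 2) start/end times in seconds on the volume clock."""
        w = np.asarray(self.windows, dtype=float)
        return self.t0 + w * self.tr

    def centers(self) -> np.ndarray:
        return self.window_times().mean(axis=1)


def make_windows(n_volumes: int, length: int = 90, step: int = 45,
                 tr: float = 0.484, t0: float = 0.0) -> WindowScheme:
    """Build the sliding-window scheme; see :class:`WindowScheme`."""
    return WindowScheme(n_volumes=n_volumes, length=length, step=step, tr=tr, t0=t0)


@dataclass
class WindowedHRV:
    """Windowed SDNN aligned to a :class:`WindowScheme`.

    ``sdnn`` is NaN where a window is flagged missing (too few beats).
    """

    sdnn: np.ndarray
    n_beats: np.ndarray
    scheme: WindowScheme
    missing: np.ndarray = field(default=None)

    def __post_init__(self):
        self.sdnn = np.asarray(self.sdnn, dtype=float)
        self.n_beats = np.asarray(self.n_beats, dtype=int)
        if self.missing is None:
            self.missing = ~np.isfinite(self.sdnn)
        if self.sdnn.size != self.scheme.n_windows:
            raise ValueError("one SDNN value per window required")


def windowed_sdnn(ibi: IBISeries, scheme: WindowScheme, min_beats: int = 10) -> WindowedHRV:
    """SDNN of the inter-beat intervals falling in each sliding window.

    An interval is assigned to a window when its defining *later* beat
    time lies in ``[start*tr, end*tr)`` on the shared clock.  Windows
    with fewer than ``min_beats`` intervals are flagged missing (their
    SDNN would be dominated by sampling noise).
    """
    later_beats = ibi.beat_times[1:]
    times = scheme.window_times()
    sdnn = np.full(scheme.n_windows, np.nan)
    counts = np.zeros(scheme.n_windows, dtype=int)
    for k, (t_lo, t_hi) in enumerate(times):
        sel = (later_beats >= t_lo) & (later_beats < t_hi)
        counts[k] = int(sel.sum())
        if counts[k] >= max(min_beats, 2):
            sdnn[k] = np.std(ibi.intervals[sel], ddof=1)
    if not np.isfinite(sdnn).any():
        raise ValueError("all windows missing: too few beats per window")
    return WindowedHRV(sdnn=sdnn, n_beats=counts, scheme=scheme)


def windowed_seed_fc(bold: BOLDImage, seed: SphereROI, scheme: WindowScheme) -> list:
    """One Fisher-z seed map per window, each from that window's samples.

    Windows whose seed time series has zero variance are flagged missing
    and returned as ``None``.
    """
    maps = []
    for (s, e) in scheme.windows:
        sub = bold.with_data(bold.data[..., s:e])
        try:
            maps.append(seed_fc_map(sub, seed))
        except ValueError:
            maps.append(None)
    return maps


def windowed_node_fc(node_ts: np.ndarray, seed_index: int, scheme: WindowScheme) -> np.ndarray:
    """Windowed Fisher-z of one node against all nodes.

    Node-level counterpart of :func:`windowed_seed_fc` for (n_nodes, t)
    matrices; returns an (n_windows, n_nodes) array with NaN rows for
    windows where the seed node is constant.
    """
    node_ts = np.asarray(node_ts, dtype=float)
    out = np.full((scheme.n_windows, node_ts.shape[0]), np.nan)
    for k, (s, e) in enumerate(scheme.windows):
        seg = node_ts[:, s:e]
        ref = seg[seed_index]
        if np.ptp(ref) == 0:
            continue
        r = _corr_vs_reference(seg, ref)
        ok = np.isfinite(r)
        out[k, ok] = np.arctanh(np.clip(r[ok], -R_CLAMP, R_CLAMP))
    return out


@dataclass
class CouplingMap:
    """Per-voxel slope of windowed z on windowed (standardized) SDNN."""

    values: np.ndarray
    subject: str = ""
    n_windows_used: int = 0


def coupling_regression(window_maps, hrv: WindowedHRV, min_windows: int = 8) -> CouplingMap:
    """Subject-level regression of windowed seed maps on windowed SDNN.

    The SDNN regressor is z-scored (mean 0, SD 1 over the usable
    windows); per voxel the OLS slope with intercept is returned, so the
    slope has the units of z per SD of SDNN.  Windows missing on either
    side (flagged HRV window, zero-variance seed window, NaN map) are
    dropped pairwise.
    """
    vals = [
        (m.values if isinstance(m, SeedZMap) else (None if m is None else np.asarray(m, float)))
        for m in window_maps
    ]
    if len(vals) != hrv.scheme.n_windows:
        raise ValueError("window maps and HRV windows must align")
    usable = np.array(
        [v is not None and np.isfinite(v).all() for v in vals]
    ) & np.isfinite(hrv.sdnn)
    n_use = int(usable.sum())
    if n_use < min_windows:
        raise ValueError(f"only {n_use} usable windows; need >= {min_windows}")
    Z = np.stack([vals[k] for k in np.flatnonzero(usable)], axis=0)
    s = hrv.sdnn[usable]
    s_sd = s.std(ddof=1)
    if s_sd == 0:
        raise ValueError("windowed SDNN is constant; coupling undefined")
    s_std = (s - s.mean()) / s_sd
    # OLS slope with intercept on a standardized regressor
    Zc = Z - Z.mean(axis=0)
    beta = np.tensordot(s_std, Zc, axes=(0, 0)) / (s_std**2).sum()
    return CouplingMap(values=beta, n_windows_used=n_use)


def group_coupling_test(
    maps,
    voxel_p: float = 0.005,
    cluster_alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
    correction: str = "fwe",
) -> StatMap:
    """One-sample group test of the coupling maps with cluster correction."""
    if len(maps) < 3:
        raise ValueError("need n >= 3 subjects")
    stat = group_ttest(maps, design="one_sample")
    return cluster_threshold(
        stat, voxel_p=voxel_p, cluster_alpha=cluster_alpha,
        n_perm=n_perm, seed=seed, correction=correction,
    )


class SlidingWindowCoupling:
    """Estimator for the subject-level HRV-connectivity coupling map.

    ``fit(bold, ibi)`` slides matched windows over the cleaned BOLD
    series and the beat series, computes the windowed seed maps and
    windowed SDNN, and regresses one on the other.  Fitted attributes:
    ``scheme_``, ``seed_``, ``windowed_hrv_``, ``window_maps_``,
    ``coupling_map_``.
    """

    def __init__(self, center=(0.0, 44.0, -14.0), radius: float = 10.0,
                 length: int = 90, step: int = 45, min_beats: int = 10,
                 min_windows: int = 8):
        self.center = center
        self.radius = radius
        self.length = length
        self.step = step
        self.min_beats = min_beats
        self.min_windows = min_windows

    def get_params(self, deep: bool = True) -> dict:
        return {
            "center": self.center, "radius": self.radius, "length": self.length,
            "step": self.step, "min_beats": self.min_beats,
            "min_windows": self.min_windows,
        }

    def set_params(self, **params) -> "SlidingWindowCoupling":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, bold: BOLDImage, ibi: IBISeries) -> "SlidingWindowCoupling":
        self.scheme_ = make_windows(
            bold.n_volumes, length=self.length, step=self.step, tr=bold.tr, t0=bold.t0
        )
        self.seed_ = sphere_roi(self.center, self.radius, bold.data.shape[:3], bold.affine)
        self.windowed_hrv_ = windowed_sdnn(ibi, self.scheme_, min_beats=self.min_beats)
        self.window_maps_ = windowed_seed_fc(bold, self.seed_, self.scheme_)
        self.coupling_map_ = coupling_regression(
            self.window_maps_, self.windowed_hrv_, min_windows=self.min_windows
        )
        return self
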