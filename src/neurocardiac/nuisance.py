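"""Physiological-noise design and BOLD cleaning.

Implements the preprocessing chain applied to resting-state BOLD data
after registration: discarding initial non-steady-state volumes,
building respiratory nuisance regressors (Fourier expansions of the
respiratory phase and respiration-volume-per-time with delayed copies),
removing trends and nuisance variance by ordinary least squares,
band-pass filtering to the 0.01-0.1 Hz range of spontaneous BOLD
fluctuations, and spatial Gaussian smoothing.

The chain is deliberately sequential — regression first, then temporal
filtering, then smoothing — and each step is available both as a plain
function and through the :class:`BOLDCleaner` transformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import qr
from scipy.ndimage import gaussian_filter
from scipy.signal import butter, sosfiltfilt

from .physio import RawSignal, RespExtrema

__all__ = [
    "BOLDImage",
    "RegressorSet",
    "RVTSeries",
    "discard_initial_volumes",
    "respiratory_phase",
    "fourier_regressors",
    "compute_rvt",
    "rvt_regressors",
    "regress_nuisance",
    "bandpass",
    "bandpass_array",
    "spatial_smooth",
    "BOLDCleaner",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BOLDImage:
    """A 4-D BOLD time series with acquisition geometry.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal intensity.
    tr : float
        Repetition time in seconds (volume sampling interval).
    affine : ndarray (4, 4), optional
        Voxel-index to MNI-mm map (RAS+).  Defaults to an isotropic
        2.5 mm grid centered at the volume center.
    mask : ndarray (x, y, z) of bool, optional
        In-brain voxels; defaults to the full grid.
    t0 : float, default 0.0
        Clock time of the first retained volume (used to align physio
        traces recorded on the same clock).
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray = None
    mask: np.ndarray = None
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 volumes")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.data.shape[:3], voxel_size=2.5)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def volume_times(self) -> np.ndarray:
        """Onset time of each volume in seconds."""
        return self.t0 + np.arange(self.n_volumes) * self.tr

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def timeseries(self) -> np.ndarray:
        """In-mask voxel time series as an (n_voxels, t) view-copy."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray, t0: float = None) -> "BOLDImage":
        return replace(self, data=data, t0=self.t0 if t0 is None else t0)


def _default_affine(shape, voxel_size=2.5) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    aff[:3, 3] = -voxel_size * (np.asarray(shape) - 1) / 2.0
    return aff


@dataclass
class RegressorSet:
    """A time-locked nuisance design: one column per regressor.

    ``matrix`` is oriented (n_volumes, n_regressors) — the usual design
    matrix layout.  Columns that are constant are reported in
    ``degenerate`` unless they are labeled ``"intercept"``.
    """

    matrix: np.ndarray
    names: list
    volume_times: np.ndarray
    degenerate: list = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.volume_times = np.asarray(self.volume_times, dtype=float)
        if self.matrix.shape[0] != self.volume_times.size:
            raise ValueError("matrix rows must align with volume_times")
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("one name per column required")
        self.degenerate = [
            n
            for n, col in zip(self.names, self.matrix.T)
            if n != "intercept" and np.ptp(col) == 0
        ]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def concat(self, other: "RegressorSet") -> "RegressorSet":
        if not np.allclose(self.volume_times, other.volume_times):
            raise ValueError("cannot concat regressors on different volume grids")
        return RegressorSet(
            np.hstack([self.matrix, other.matrix]),
            list(self.names) + list(other.names),
            self.volume_times,
        )


@dataclass
class RVTSeries:
    """Respiration volume per time sampled at volume times."""

    values: np.ndarray
    volume_times: np.ndarray
    delays_applied: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.volume_times = np.asarray(self.volume_times, dtype=float)
        if self.values.size != self.volume_times.size:
            raise ValueError("RVT must be defined at every volume time")


def discard_initial_volumes(bold: BOLDImage, n: int = 20) -> BOLDImage:
    """Drop the first ``n`` volumes (magnetization steady-state period)."""
    if bold.n_volumes <= n:
        raise ValueError(
            f"recording too short: {bold.n_volumes} volumes, discard {n}"
        )
    return bold.with_data(bold.data[..., n:], t0=bold.t0 + n * bold.tr)


def respiratory_phase(
    extrema: RespExtrema,
    signal: RawSignal = None,
    volume_times: np.ndarray = None,
) -> np.ndarray:
    """Respiratory cycle phase at each volume time.

    Phase advances linearly from 0 at one inspiratory maximum to 2*pi at
    the next (wrapped to (-pi, pi], so a volume exactly at a maximum has
    phase 0).  This simple-phase construction depends only on the peak
    times, which makes it amplitude-invariant by design; the
    amplitude-histogram variant used in some retrospective-correction
    implementations is intentionally not used (determinism and
    testability — see the methods note).

    Volumes before the first or after the last detected maximum are
    assigned the phase of the nearest cycle, with a warning.
    """
    volume_times = np.asarray(volume_times, dtype=float)
    peaks = extrema.peak_times
    if peaks.size < 2:
        raise ValueError("need at least 2 respiratory maxima for phase")
    if np.any(volume_times < peaks[0]) or np.any(volume_times > peaks[-1]):
        warnings.warn(
            "volumes outside the respiratory recording span; edge volumes "
            "assigned nearest-cycle phase",
            stacklevel=2,
        )
    idx = np.clip(np.searchsorted(peaks, volume_times, side="right") - 1, 0, peaks.size - 2)
    frac = (volume_times - peaks[idx]) / (peaks[idx + 1] - peaks[idx])
    phase = 2.0 * np.pi * frac
    return np.mod(phase + np.pi, 2.0 * np.pi) - np.pi


def fourier_regressors(phase: np.ndarray, order: int = 2, volume_times=None) -> RegressorSet:
    """Fourier expansion of the respiratory phase.

    Order ``k`` contributes sin(k*phase) and cos(k*phase); the default
    order 2 yields the four low-order respiratory time series used to
    absorb signal synchronized with the respiratory cycle.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    phase = np.asarray(phase, dtype=float)
    if volume_times is None:
        volume_times = np.arange(phase.size, dtype=float)
    cols, names = [], []
    for k in range(1, order + 1):
        cols += [np.sin(k * phase), np.cos(k * phase)]
        names += [f"resp_sin{k}", f"resp_cos{k}"]
    return RegressorSet(np.column_stack(cols), names, volume_times)


def compute_rvt(extrema: RespExtrema, volume_times: np.ndarray) -> RVTSeries:
    """Respiration volume per time: breath amplitude over breath period.

    For each respiratory maximum the amplitude is the peak value minus
    the adjacent trough value (troughs linearly interpolated to the peak
    time) and the period is the local peak-to-peak interval; the
    resulting per-breath values are linearly interpolated to the volume
    times with constant extrapolation beyond the first/last breath.
    """
    volume_times = np.asarray(volume_times, dtype=float)
    pk_t, pk_a = extrema.peak_times, extrema.peak_amps
    tr_t, tr_a = extrema.trough_times, extrema.trough_amps
    if pk_t.size < 2 or tr_t.size < 1:
        raise ValueError("cannot compute RVT: insufficient extrema")
    trough_at_peak = np.interp(pk_t, tr_t, tr_a)
    # local breath period per peak: one-sided at the edges
    period = np.empty_like(pk_t)
    period[0] = pk_t[1] - pk_t[0]
    period[-1] = pk_t[-1] - pk_t[-2]
    if pk_t.size > 2:
        period[1:-1] = (pk_t[2:] - pk_t[:-2]) / 2.0
    rvt_at_peaks = (pk_a - trough_at_peak) / period
    values = np.interp(volume_times, pk_t, rvt_at_peaks)
    return RVTSeries(values, volume_times)


def rvt_regressors(
    rvt: RVTSeries, delays: tuple = (0.0, 5.0, 10.0, 15.0, 20.0)
) -> RegressorSet:
    """RVT and delayed copies as nuisance regressors.

    Column ``d`` is the RVT series evaluated at ``t - d``; times before
    the series start are edge-padded with the first defined value.  The
    default delays 0/5/10/15/20 s give the five respiration-volume
    regressors that model slow blood-oxygenation fluctuations lagging
    the breathing envelope.
    """
    delays = tuple(float(d) for d in delays)
    if any(d < 0 for d in delays):
        raise ValueError("delays must be non-negative")
    t = rvt.volume_times
    cols = [np.interp(t - d, t, rvt.values, left=rvt.values[0]) for d in delays]
    names = [f"rvt_delay{d:g}" for d in delays]
    return RegressorSet(np.column_stack(cols), names, t)


def _trend_design(n: int) -> np.ndarray:
    # intercept + Legendre-style linear and quadratic trends (orthogonal-ish)
    x = np.linspace(-1.0, 1.0, n)
    return np.column_stack([np.ones(n), x, (3.0 * x**2 - 1.0) / 2.0])


def _drop_collinear(X: np.ndarray, names: list) -> tuple[np.ndarray, list]:
    """Drop columns until the design has full column rank (pivoted QR)."""
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    _, R, piv = qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank == X.shape[1]:
        return X, list(names)
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in range(X.shape[1]) if i not in set(keep.tolist())]
    warnings.warn(f"rank-deficient design; dropped collinear columns: {dropped}", stacklevel=3)
    return X[:, keep], [names[i] for i in keep]


def regress_nuisance(
    bold: BOLDImage,
    regressors: RegressorSet = None,
    add_trends: bool = True,
) -> BOLDImage:
    """Remove trend and nuisance variance per voxel by OLS.

    The design contains an intercept, linear and quadratic trends (when
    ``add_trends``), and the supplied regressor columns (head motion,
    CSF/white-matter signal, respiratory Fourier and RVT terms, ...).
    The returned image holds the residuals, which are mean-zero and
    exactly orthogonal to every retained design column.
    """
    n_vol = bold.n_volumes
    parts, names = [], []
    if add_trends:
        parts.append(_trend_design(n_vol))
        names += ["intercept", "linear", "quadratic"]
    else:
        parts.append(np.ones((n_vol, 1)))
        names += ["intercept"]
    if regressors is not None:
        if regressors.matrix.shape[0] != n_vol:
            raise ValueError(
                f"regressor rows ({regressors.matrix.shape[0]}) must equal "
                f"bold volumes ({n_vol})"
            )
        parts.append(regressors.matrix)
        names += list(regressors.names)
    X = np.hstack(parts)
    X, _ = _drop_collinear(X, names)
    Y = bold.data.reshape(-1, n_vol).T  # (t, n_vox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T.reshape(bold.data.shape)
    return bold.with_data(resid)


def bandpass_array(x: np.ndarray, fs: float, low: float = 0.01, high: float = 0.1,
                   order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase Butterworth band-pass along ``axis`` (forward-backward)."""
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high corner {high} Hz >= Nyquist {nyq:.4g} Hz")
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=axis)


def bandpass(bold: BOLDImage, low: float = 0.01, high: float = 0.1,
             order: int = 4) -> BOLDImage:
    """Band-pass the BOLD series to the spontaneous-fluctuation band.

    A 4th-order Butterworth applied forward-backward (zero phase
    distortion); the defaults retain 0.01-0.1 Hz.
    """
    out = bandpass_array(bold.data, fs=1.0 / bold.tr, low=low, high=high, order=order)
    return bold.with_data(out)


def spatial_smooth(bold: BOLDImage, fwhm: float = 6.0) -> BOLDImage:
    """Per-volume 3-D Gaussian smoothing with the kernel size in mm."""
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return bold.with_data(bold.data.copy())
    sigma_vox = fwhm * _FWHM_TO_SIGMA / bold.voxel_sizes
    out = gaussian_filter(bold.data, sigma=(*sigma_vox, 0.0), mode="constant")
    return bold.with_data(out)


class BOLDCleaner:
    """Transformer bundling the full BOLD cleaning chain.

    Steps, in order: discard initial volumes, OLS removal of trends and
    nuisance regressors, temporal band-pass, spatial smoothing.  The
    regressor set (motion, CSF/WM, respiratory terms) is passed to
    :meth:`fit`, aligned to the *retained* volumes.

    Follows the scikit-learn estimator protocol (``get_params`` /
    ``set_params`` via duck-typed constructor parameters, fitted state in
    trailing-underscore attributes), so it composes with sklearn
    pipelines operating on :class:`BOLDImage` objects.
    """

    def __init__(self, n_discard: int = 20, low: float = 0.01, high: float = 0.1,
                 fwhm: float = 6.0, add_trends: bool = True, filter_order: int = 4):
        self.n_discard = n_discard
        self.low = low
        self.high = high
        self.fwhm = fwhm
        self.add_trends = add_trends
        self.filter_order = filter_order

    # minimal sklearn API without importing sklearn at module import time
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_discard": self.n_discard, "low": self.low, "high": self.high,
            "fwhm": self.fwhm, "add_trends": self.add_trends,
            "filter_order": self.filter_order,
        }

    def set_params(self, **params) -> "BOLDCleaner":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, bold: BOLDImage, regressors: RegressorSet = None) -> "BOLDCleaner":
        self.regressors_ = regressors
        return self

    def transform(self, bold: BOLDImage) -> BOLDImage:
        if not hasattr(self, "regressors_"):
            raise RuntimeError("BOLDCleaner must be fit before transform")
        out = discard_initial_volumes(bold, self.n_discard) if self.n_discard else bold
        out = regress_nuisance(out, self.regressors_, add_trends=self.add_trends)
        out = bandpass(out, self.low, self.high, order=self.filter_order)
        if self.fwhm:
            out = spatial_smooth(out, self.fwhm)
        return out

    def fit_transform(self, bold: BOLDImage, regressors: RegressorSet = None) -> BOLDImage:
        return self.fit(bold, regressors).transform(bold)
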