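"""Cardiac and respiratory signal processing.

Turns raw finger-pulse and respiration-belt traces into beat series,
time-domain heart-rate-variability (HRV) metrics, breathing rate, and
respiratory extrema.  Beats are located on the first derivative of the
pulse waveform, exploiting the rapid signal upstroke at pulse arrival;
an automated artifact rule replaces manual inspection of the detections,
and every replacement is flagged so a user can audit the corrections.

Conventions
-----------
* Beat times are seconds on the recording clock; inter-beat intervals
  (IBIs) are milliseconds.
* Heart rate is ``60000 / mean(IBI)`` (single convention; not the mean of
  instantaneous rates).
* SDNN uses the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

__all__ = [
    "RawSignal",
    "IBISeries",
    "HRVMetrics",
    "RespExtrema",
    "detect_pulse_peaks",
    "clean_ibi",
    "hrv_metrics",
    "detect_resp_extrema",
    "breathing_rate",
]

#: per-interval flag values
FLAG_VALID = "valid"
FLAG_CORRECTED = "corrected"


@dataclass(frozen=True)
class RawSignal:
    """A uniformly sampled physiological trace.

    Parameters
    ----------
    samples : ndarray
        Signal amplitude in arbitrary units.
    sampling_rate : float
        Sampling frequency in Hz (> 0).
    start_time : float, default 0.0
        Clock time of the first sample in seconds.  For simultaneous
        physio/fMRI recordings this aligns the trace to the scanner clock.
    channel : str
        Either ``"pulse"`` or ``"respiration"``.
    """

    samples: np.ndarray
    sampling_rate: float
    channel: str
    start_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size < 2:
            raise ValueError("signal needs at least 2 samples")
        if self.channel not in ("pulse", "respiration"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sampling_rate


@dataclass(frozen=True)
class IBISeries:
    """Beat occurrence times with the derived inter-beat intervals.

    ``intervals[i] = (beat_times[i+1] - beat_times[i]) * 1000`` always
    holds; routines that edit intervals rebuild the beat times from the
    cumulative sum so the invariant is preserved.
    """

    beat_times: np.ndarray  # s, strictly increasing
    intervals: np.ndarray  # ms, length len(beat_times) - 1
    flags: np.ndarray = field(default=None)  # per-interval

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", iv)
        if self.flags is None:
            object.__setattr__(self, "flags", np.full(iv.size, FLAG_VALID, dtype="<U9"))
        else:
            object.__setattr__(self, "flags", np.asarray(self.flags, dtype="<U9"))
        if iv.size != bt.size - 1:
            raise ValueError("intervals must have length len(beat_times) - 1")
        if np.any(np.diff(bt) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(iv <= 0):
            raise ValueError("all intervals must be positive")
        if not np.allclose(iv, np.diff(bt) * 1000.0, atol=1e-6):
            raise ValueError("intervals inconsistent with beat_times")

    @classmethod
    def from_beat_times(cls, beat_times, flags=None) -> "IBISeries":
        bt = np.asarray(beat_times, dtype=float)
        return cls(bt, np.diff(bt) * 1000.0, flags)

    @classmethod
    def from_intervals(cls, intervals_ms, t0: float = 0.0, flags=None) -> "IBISeries":
        iv = np.asarray(intervals_ms, dtype=float)
        bt = t0 + np.concatenate([[0.0], np.cumsum(iv) / 1000.0])
        return cls(bt, iv, flags)

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def n_corrected(self) -> int:
        return int(np.sum(self.flags == FLAG_CORRECTED))

    def shifted(self, dt: float) -> "IBISeries":
        """Same beats on a clock offset by ``dt`` seconds."""
        return replace(self, beat_times=self.beat_times + dt)


@dataclass(frozen=True)
class HRVMetrics:
    """Time-domain HRV summary of a recording.

    Attributes
    ----------
    hr : float
        Mean heart rate, beats per minute.
    sdnn : float
        Standard deviation of inter-beat intervals (ms) — global HRV.
    rmssd : float
        Root mean square of successive interval differences (ms) —
        short-term, vagally mediated HRV.
    n_beats : int
        Number of detected beats the metrics rest on.
    """

    hr: float
    sdnn: float
    rmssd: float
    n_beats: int


@dataclass(frozen=True)
class RespExtrema:
    """Alternating respiratory maxima (end-inspiration) and minima."""

    peak_times: np.ndarray
    trough_times: np.ndarray
    peak_amps: np.ndarray
    trough_amps: np.ndarray

    def __post_init__(self):
        for name in ("peak_times", "trough_times", "peak_amps", "trough_amps"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for t in (self.peak_times, self.trough_times):
            if np.any(np.diff(t) <= 0):
                raise ValueError("extrema times must be strictly increasing")


def detect_pulse_peaks(
    signal: RawSignal,
    min_ibi: float = 300.0,
    deriv_threshold_frac: float = 0.4,
) -> IBISeries:
    """Detect heartbeats from a pulse waveform.

    The beat fiducial is the maximum of the first derivative within each
    systolic upstroke — the steep rise at pulse arrival is the most
    reliable landmark in photoplethysmographic signals.  The detection
    threshold adapts to slow amplitude drift: a derivative peak counts as
    a beat when it exceeds ``deriv_threshold_frac`` times the rolling
    10-second maximum of the derivative.

    Parameters
    ----------
    signal : RawSignal
        Pulse channel.
    min_ibi : float, default 300
        Refractory period in ms; no two beats may be closer than this.
    deriv_threshold_frac : float, default 0.4
        Fraction of the local derivative maximum a candidate must reach.

    Returns
    -------
    IBISeries

    Raises
    ------
    TypeError
        If the signal is not a pulse channel.
    ValueError
        If no beats can be found (e.g. flat signal).
    """
    if signal.channel != "pulse":
        raise TypeError(f"expected a pulse channel, got {signal.channel!r}")
    fs = signal.sampling_rate
    x = signal.samples
    # band-limit before differentiating: the systolic upstroke lives well
    # below ~8 Hz while broadband sensor noise dominates the raw derivative
    if fs > 20.0:
        sos = butter(4, 8.0, btype="lowpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)
    deriv = np.gradient(x) * fs

    win = max(int(round(10.0 * fs)), 3)
    local_max = maximum_filter1d(deriv, size=win, mode="nearest")
    # guard: a flat signal has ~zero derivative everywhere
    global_scale = float(np.max(np.abs(deriv)))
    if global_scale <= 0 or np.max(deriv) <= 0:
        raise ValueError("no beats detected: derivative everywhere below threshold")
    height = deriv_threshold_frac * np.maximum(local_max, 1e-3 * global_scale)

    distance = max(int(round(min_ibi / 1000.0 * fs)), 1)
    idx, _ = find_peaks(deriv, distance=distance)
    idx = idx[deriv[idx] >= height[idx]]
    if idx.size < 2:
        raise ValueError("no beats detected: derivative everywhere below threshold")
    beat_times = signal.start_time + idx / fs
    return IBISeries.from_beat_times(beat_times)


def clean_ibi(
    ibi: IBISeries,
    abs_bounds: tuple[float, float] = (300.0, 2000.0),
    rel_tol: float = 0.3,
    max_invalid_frac: float = 0.2,
) -> IBISeries:
    """Flag and repair artifactual inter-beat intervals.

    An interval is invalid when it falls outside ``abs_bounds`` (ms) or
    deviates by more than ``rel_tol`` from an 11-beat running median.
    Invalid intervals are replaced by linear interpolation between the
    neighboring valid intervals and flagged ``"corrected"``.  Beat times
    are rebuilt from the corrected intervals so the series stays
    internally consistent.

    Raises
    ------
    ValueError
        If more than ``max_invalid_frac`` of the intervals are invalid —
        the recording is considered unusable, mirroring the exclusion of
        recordings whose pulse quality does not support a full analysis.
    """
    iv = ibi.intervals.copy()
    lo, hi = abs_bounds
    med = (
        pd.Series(iv)
        .rolling(window=11, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    bad = (iv < lo) | (iv > hi) | (np.abs(iv - med) > rel_tol * med)
    # the usability rule is a recording-level judgement; it is not applied
    # to very short snippets where one artifact dominates the fraction
    if iv.size >= 10 and bad.mean() > max_invalid_frac:
        raise ValueError(
            f"unusable recording: {bad.mean():.0%} of intervals invalid "
            f"(limit {max_invalid_frac:.0%})"
        )
    flags = ibi.flags.copy()
    if bad.any():
        good = ~bad
        if not good.any():
            raise ValueError("unusable recording: no valid intervals")
        iv[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), iv[good])
        flags[bad] = FLAG_CORRECTED
    return IBISeries.from_intervals(iv, t0=ibi.beat_times[0], flags=flags)


def hrv_metrics(ibi: IBISeries) -> HRVMetrics:
    """Compute HR, SDNN and RMSSD from an interval series.

    HR = 60000 / mean(IBI); SDNN = sample SD (n-1 denominator) of the
    intervals; RMSSD = sqrt(mean(successive differences squared)).

    Raises
    ------
    ValueError
        With fewer than 3 intervals ("insufficient beats").
    """
    iv = ibi.intervals
    if iv.size < 3:
        raise ValueError("insufficient beats: need at least 3 intervals")
    hr = 60000.0 / float(np.mean(iv))
    sdnn = float(np.std(iv, ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(iv) ** 2)))
    return HRVMetrics(hr=hr, sdnn=sdnn, rmssd=rmssd, n_beats=ibi.n_beats)


def detect_resp_extrema(signal: RawSignal, min_period: float = 1.5) -> RespExtrema:
    """Locate respiratory maxima and the intervening minima.

    Maxima are local peaks separated by at least ``min_period`` seconds
    with prominence of at least 10% of the signal range (which rejects
    small superimposed wiggles).  One trough — the global minimum between
    each pair of consecutive maxima — is returned per breath, so peaks
    and troughs alternate strictly.

    Raises
    ------
    ValueError
        With fewer than 2 maxima ("no breaths detected").
    """
    if signal.channel != "respiration":
        raise TypeError(f"expected a respiration channel, got {signal.channel!r}")
    x = signal.samples
    fs = signal.sampling_rate
    rng = float(np.max(x) - np.min(x))
    if rng <= 0:
        raise ValueError("no breaths detected: constant signal")
    distance = max(int(round(min_period * fs)), 1)
    pk, _ = find_peaks(x, distance=distance, prominence=0.1 * rng)
    if pk.size < 2:
        raise ValueError("no breaths detected")
    troughs = []
    for a, b in zip(pk[:-1], pk[1:]):
        troughs.append(a + int(np.argmin(x[a : b + 1])))
    tr = np.asarray(troughs, dtype=int)
    t = signal.times
    return RespExtrema(
        peak_times=t[pk],
        trough_times=t[tr],
        peak_amps=x[pk],
        trough_amps=x[tr],
    )


def breathing_rate(extrema: RespExtrema) -> float:
    """Breaths per minute: inverse of the mean interval between maxima."""
    if extrema.peak_times.size < 2:
        raise ValueError("insufficient breaths: need at least 2 maxima")
    return 60.0 / float(np.mean(np.diff(extrema.peak_times)))
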