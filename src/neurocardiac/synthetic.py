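"""Synthetic data generators for every pipeline input.

Emulates the statistical structure of simultaneous physiological and
resting-state fMRI recordings: beat-to-beat interval series with
respiratory sinus arrhythmia and a slow (Mayer-wave-like, ~0.1 Hz)
oscillation, pulse waveforms with a fast systolic upstroke, respiration
traces, BOLD node series whose seed coupling co-varies with windowed
SDNN, and paired (T1/T2) connectome cohorts with a planted connected
subnetwork effect.

Default parameters mirror the study population at baseline — heart rate
near 70 beats/min, SDNN near 54 ms, breathing rate near 16 breaths/min,
TR 0.484 s, cohorts of 15 subjects — so synthetic outputs are
plausibility-checkable against the reported group means.  Every
generator is a deterministic function of its :class:`SimConfig`
(the seed is mandatory), and each returns its ground truth alongside
the data so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .dynamic import WindowScheme, windowed_sdnn
from .network import ConnectivityMatrix
from .nuisance import bandpass_array
from .physio import IBISeries, RawSignal

__all__ = [
    "SimConfig",
    "gen_ibi_series",
    "gen_pulse_waveform",
    "gen_respiration",
    "gen_coupled_bold",
    "gen_paired_connectomes",
    "random_connected_effect",
    "gen_coordinates",
]


@dataclass(frozen=True)
class SimConfig:
    """Bundle of simulation conditions.

    Physiological defaults follow the baseline group means of the study
    population (HR ~70/min -> mean IBI ~857 ms, SDNN 54.4 ms, breathing
    rate 16/min); imaging defaults follow the acquisition (TR 0.484 s).
    """

    seed: int
    duration: float = 300.0  # s
    tr: float = 0.484
    fs_physio: float = 100.0  # Hz
    mean_ibi: float = 857.0  # ms  (~70 beats/min)
    target_sdnn: float = 54.4  # ms
    rsa_amplitude: float = 25.0  # ms, respiratory sinus arrhythmia
    slow_amplitude: float = 15.0  # ms, ~0.1 Hz oscillation
    noise_sd: float = 15.0  # ms, AR(1) beat-to-beat noise
    ar_coef: float = 0.4
    resp_rate: float = 16.0  # breaths/min
    resp_drift: float = 0.05  # fractional slow frequency drift
    resp_amp_jitter: float = 0.1  # fractional amplitude modulation
    # BOLD / coupling
    n_nodes: int = 20
    n_coupled: int = 4
    coupling_strength: float = 0.0  # kappa
    baseline_amp: float = 0.8  # static seed-coupling amplitude a
    bold_noise_sd: float = 1.0
    # connectome cohorts
    n_subjects: int = 15
    n_conn_nodes: int = 60
    effect_size: float = 1.2  # within-pair shift, in SDs of the paired diff
    n_effect_edges: int = 20
    edge_noise_sd: float = 0.1
    subject_sd: float = 0.1
    baseline_z: float = 0.25

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory (no silent nondeterminism)")
        for name in ("duration", "tr", "fs_physio", "mean_ibi", "resp_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of this config."""
        return np.random.default_rng([int(self.seed) % 2**31, int(stream)])


# stream tags (arbitrary, fixed)
_S_IBI, _S_RESP, _S_BOLD, _S_CONN, _S_COORD = 11, 23, 37, 53, 71


def gen_ibi_series(cfg: SimConfig) -> IBISeries:
    """Beat series with controllable SDNN.

    The interval sequence is mean_ibi plus respiratory sinus arrhythmia
    (a sinusoid at the breathing frequency), a slow 0.1 Hz oscillation,
    and AR(1) noise; the zero-mean part is rescaled uniformly so the
    sample SDNN equals ``target_sdnn`` exactly (component ratios are
    preserved).  Beat times are the cumulative interval sum.
    """
    if cfg.duration < 60:
        raise ValueError("duration must be >= 60 s")
    if cfg.target_sdnn == 0 and (cfg.rsa_amplitude > 0 or cfg.noise_sd > 0 or cfg.slow_amplitude > 0):
        raise ValueError(
            "infeasible target: target_sdnn 0 requires zero rsa/slow/noise amplitudes"
        )
    rng = cfg.rng(_S_IBI)
    n = int(cfg.duration * 1000.0 / cfg.mean_ibi * 1.25) + 10
    t_approx = np.arange(n) * cfg.mean_ibi / 1000.0
    f_resp = cfg.resp_rate / 60.0
    mod = cfg.rsa_amplitude * np.sin(2 * np.pi * f_resp * t_approx)
    mod = mod + cfg.slow_amplitude * np.sin(2 * np.pi * 0.1 * t_approx + rng.uniform(0, 2 * np.pi))
    if cfg.noise_sd > 0:
        eps = rng.normal(0.0, cfg.noise_sd * np.sqrt(1 - cfg.ar_coef**2), n)
        ar = np.empty(n)
        ar[0] = eps[0]
        for k in range(1, n):
            ar[k] = cfg.ar_coef * ar[k - 1] + eps[k]
        mod = mod + ar
    mod = mod - mod.mean()
    sd = mod.std(ddof=1)
    if cfg.target_sdnn > 0:
        if sd == 0:
            raise ValueError("infeasible target: no variability source enabled")
        mod = mod * (cfg.target_sdnn / sd)
    intervals = cfg.mean_ibi + mod
    if np.any(intervals <= 0):
        raise ValueError("infeasible parameters: non-positive intervals generated")
    beat_times = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
    keep = beat_times <= cfg.duration
    beat_times = beat_times[keep]
    if beat_times.size < 4:
        raise ValueError("duration too short for the requested mean interval")
    return IBISeries.from_beat_times(beat_times)


def _pulse_template(fs: float):
    """Asymmetric pulse shape: fast raised-cosine upstroke, slow decay.

    Returns the template and the sample offset of its maximum first
    derivative, so beats can be placed with the derivative maximum
    exactly on the beat time.
    """
    t_up, t_total = 0.08, 0.45
    t = np.arange(int(round(t_total * fs))) / fs
    up = t < t_up
    tpl = np.empty_like(t)
    tpl[up] = 0.5 * (1 - np.cos(np.pi * t[up] / t_up))
    tpl[~up] = np.exp(-(t[~up] - t_up) / 0.12)
    d = np.gradient(tpl)
    return tpl, int(np.argmax(d))


def gen_pulse_waveform(ibi: IBISeries, fs: float = 100.0, noise_sd: float = 0.0,
                       seed: int = 0) -> RawSignal:
    """Pulse waveform with one template per beat.

    The instant of maximum upstroke derivative coincides with each beat
    time to within one sample.  Optional additive white noise with
    standard deviation ``noise_sd`` (template peak amplitude is 1).
    """
    if fs < 50:
        raise ValueError("fs too low to resolve the systolic upstroke; need >= 50 Hz")
    tpl, d_off = _pulse_template(fs)
    start = ibi.beat_times[0] - 0.5
    n = int(np.ceil((ibi.beat_times[-1] - start + 1.0) * fs))
    x = np.zeros(n)
    for bt in ibi.beat_times:
        i0 = int(round((bt - start) * fs)) - d_off
        a, b = max(i0, 0), min(i0 + tpl.size, n)
        if b > a:
            x[a:b] += tpl[a - i0 : b - i0]
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    return RawSignal(samples=x, sampling_rate=fs, channel="pulse", start_time=start)


def gen_respiration(cfg: SimConfig):
    """Respiration trace: a sinusoid with slow drift and amplitude jitter.

    Returns ``(signal, ground_truth)`` where the ground truth holds the
    true extrema times of the generated trace.
    """
    if not 6 <= cfg.resp_rate <= 30:
        raise ValueError("resp_rate must lie in [6, 30] breaths/min")
    rng = cfg.rng(_S_RESP)
    fs = cfg.fs_physio
    n = int(cfg.duration * fs)
    t = np.arange(n) / fs
    f0 = cfg.resp_rate / 60.0
    inst_f = f0 * (1.0 + cfg.resp_drift * np.sin(2 * np.pi * t / 120.0 + rng.uniform(0, 2 * np.pi)))
    phase = 2 * np.pi * np.cumsum(inst_f) / fs
    if cfg.resp_amp_jitter > 0:
        slow = bandpass_array(rng.normal(0, 1, n), fs=fs, low=0.005, high=0.03, order=2)
        slow = slow / max(np.abs(slow).max(), 1e-12)
        amp = 1.0 + cfg.resp_amp_jitter * slow
    else:
        amp = np.ones(n)
    x = amp * np.sin(phase)
    pk, _ = find_peaks(x, distance=int(0.5 / f0 * fs))
    tr_, _ = find_peaks(-x, distance=int(0.5 / f0 * fs))
    truth = {"peak_times": t[pk], "trough_times": t[tr_]}
    sig = RawSignal(samples=x, sampling_rate=fs, channel="respiration")
    return sig, truth


def _band_noise(rng, n_series, n_t, fs):
    x = rng.normal(0.0, 1.0, (n_series, n_t))
    x = bandpass_array(x, fs=fs, low=0.01, high=0.1, order=4)
    return x / x.std(axis=1, keepdims=True)


def gen_coupled_bold(cfg: SimConfig, ibi: IBISeries, scheme: WindowScheme,
                     min_beats: int = 10):
    """BOLD node series whose seed coupling tracks windowed SDNN.

    Node 0 carries the latent seed signal ``s(t)`` (band-limited
    0.01-0.1 Hz noise).  Coupled nodes follow
    ``x_i(t) = (a + kappa * S(t)) * s(t) + noise`` where ``S`` is the
    standardized windowed-SDNN envelope of ``ibi`` interpolated to
    volume times — an amplitude-modulation mechanism chosen as the
    simplest construction whose window-wise correlation tracks SDNN (a
    modeling device, not a physiological claim).  Uncoupled nodes are
    band-limited noise.

    Returns ``(node_ts, ground_truth)`` with the coupled node indices
    and the planted static correlation of coupled nodes at ``S = 0``.
    """
    kappa = cfg.coupling_strength
    coupled = tuple(range(1, 1 + cfg.n_coupled))
    if kappa != 0 and len(coupled) == 0:
        raise ValueError("coupling_strength set but no coupled nodes requested")
    if cfg.n_nodes < 1 + cfg.n_coupled:
        raise ValueError("n_nodes too small for the requested coupled set")
    rng = cfg.rng(_S_BOLD)
    n_t = scheme.n_volumes
    fs = 1.0 / scheme.tr

    hrv = windowed_sdnn(ibi, scheme, min_beats=min_beats)
    centers = scheme.centers()
    usable = np.isfinite(hrv.sdnn)
    s_win = hrv.sdnn[usable]
    s_std = (s_win - s_win.mean()) / max(s_win.std(ddof=1), 1e-12)
    volume_times = scheme.t0 + np.arange(n_t) * scheme.tr
    envelope = np.interp(volume_times, centers[usable], s_std)

    latent = _band_noise(rng, 1, n_t, fs)[0]
    noise = _band_noise(rng, cfg.n_nodes, n_t, fs) * cfg.bold_noise_sd
    node_ts = noise.copy()
    node_ts[0] = latent + 0.1 * noise[0]
    a = cfg.baseline_amp
    for i in coupled:
        gain = a + kappa * envelope
        node_ts[i] = gain * latent + noise[i]
    static_r = a / np.sqrt(a**2 + cfg.bold_noise_sd**2)
    truth = {
        "coupled_nodes": coupled,
        "seed_node": 0,
        "kappa": kappa,
        "static_r": static_r,
        "envelope": envelope,
        "windowed_sdnn": hrv,
    }
    return node_ts, truth


def random_connected_effect(n_nodes: int, n_edges: int, rng) -> list:
    """A random tree-shaped (connected, acyclic) edge set on ``n_edges`` edges."""
    if n_edges + 1 > n_nodes:
        raise ValueError("effect tree needs n_edges + 1 <= n_nodes")
    nodes = rng.choice(n_nodes, size=n_edges + 1, replace=False)
    edges = []
    for i in range(1, n_edges + 1):
        j = int(rng.integers(0, i))
        a, b = sorted((int(nodes[i]), int(nodes[j])))
        edges.append((a, b))
    return sorted(edges)


def gen_paired_connectomes(cfg: SimConfig, effect_edges: list = None):
    """Paired (T1, T2) connectome cohorts with a planted T2 > T1 effect.

    Each subject's session matrix is a shared baseline plus a
    subject-level random deviation (common to both sessions, as in a
    within-subject design) plus independent session edge noise.  At T2
    the ``effect_edges`` gain a shift of ``effect_size`` standard
    deviations of the *paired difference* (the quantity that governs
    paired-test power).  With ``effect_size = 0`` the cohorts are an
    exchangeable null.

    Returns ``(t1_list, t2_list, ground_truth)``.
    """
    rng = cfg.rng(_S_CONN)
    n = cfg.n_conn_nodes
    iu = np.triu_indices(n, k=1)
    n_edges = iu[0].size
    if effect_edges is None and cfg.effect_size != 0:
        effect_edges = random_connected_effect(n, cfg.n_effect_edges, rng)
    effect_vec = np.zeros(n_edges)
    if effect_edges:
        lookup = {(min(a, b), max(a, b)) for a, b in effect_edges}
        for a, b in lookup:
            if not (0 <= a < n and 0 <= b < n):
                raise ValueError(f"effect edge ({a}, {b}) references unknown node")
        pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(*iu))}
        for e in lookup:
            effect_vec[pos[e]] = 1.0
    sd_diff = np.sqrt(2.0) * cfg.edge_noise_sd
    shift = cfg.effect_size * sd_diff

    baseline = rng.normal(cfg.baseline_z, 0.15, n_edges)
    t1, t2 = [], []
    for s in range(cfg.n_subjects):
        subj = rng.normal(0.0, cfg.subject_sd, n_edges)
        e1 = rng.normal(0.0, cfg.edge_noise_sd, n_edges)
        e2 = rng.normal(0.0, cfg.edge_noise_sd, n_edges)
        v1 = baseline + subj + e1
        v2 = baseline + subj + e2 + shift * effect_vec
        for vals, bucket, ses in ((v1, t1, "T1"), (v2, t2, "T2")):
            z = np.full((n, n), np.nan)
            z[iu] = vals
            z[(iu[1], iu[0])] = vals
            valid = np.ones((n, n), dtype=bool)
            np.fill_diagonal(valid, False)
            bucket.append(
                ConnectivityMatrix(z=z, valid=valid, subject=f"sub-{s:02d}", session=ses)
            )
    truth = {
        "effect_edges": sorted(effect_edges) if effect_edges else [],
        "shift": shift,
        "sd_diff": sd_diff,
    }
    return t1, t2, truth


def gen_coordinates(cfg: SimConfig, spacing: float = 14.0):
    """Synthetic MNI-like node coordinates obeying the 10 mm spacing rule.

    Nodes sit on a jittered 3-D lattice with ``spacing`` mm pitch; the
    jitter is bounded so no two centers come closer than 10 mm.
    """
    rng = cfg.rng(_S_COORD)
    n = cfg.n_conn_nodes
    side = int(np.ceil(n ** (1 / 3)))
    grid = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)]
    )[:n] * spacing
    grid = grid - grid.mean(axis=0)
    max_jitter = (spacing - 10.0) / 2.0 / np.sqrt(3.0)
    jitter = rng.uniform(-max_jitter, max_jitter, size=grid.shape)
    centers = grid + jitter
    labels = [f"node{k:03d}" for k in range(n)]
    return labels, centers
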