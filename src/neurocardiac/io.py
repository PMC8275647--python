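"""File formats: BIDS physio, NIfTI, TSV tables, JSON results.

Readers return the package's domain objects; writers emit the same
formats the readers accept, so simulated datasets round-trip through
the pipeline exactly like recorded ones.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .nuisance import BOLDImage, RegressorSet
from .physio import HRVMetrics, IBISeries, RawSignal

__all__ = [
    "read_physio",
    "write_physio",
    "read_physio_tsv",
    "load_bold",
    "save_bold",
    "load_motion_regressors",
    "write_beats",
    "read_beats",
    "write_metrics",
    "write_connectome",
    "read_connectome",
]


def read_physio(tsv_path) -> dict:
    """Read a BIDS physiological recording (``*_physio.tsv.gz`` + sidecar).

    The JSON sidecar (same stem, ``.json``) must define
    ``SamplingFrequency``, ``StartTime`` and ``Columns``.  Returns a
    dict mapping recognized column names (``pulse``/``cardiac`` and
    ``respiration``/``respiratory``) to :class:`RawSignal` objects.
    """
    tsv_path = Path(tsv_path)
    stem = tsv_path.name
    for suffix in (".tsv.gz", ".tsv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    sidecar = tsv_path.with_name(stem + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing physio sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("SamplingFrequency", "StartTime", "Columns"):
        if key not in meta:
            raise ValueError(f"malformed sidecar: missing {key!r}")
    data = pd.read_csv(tsv_path, sep="\t", header=None).to_numpy(dtype=float)
    if data.shape[1] != len(meta["Columns"]):
        raise ValueError("sidecar Columns do not match the TSV column count")
    out = {}
    for k, name in enumerate(meta["Columns"]):
        channel = {
            "pulse": "pulse", "cardiac": "pulse",
            "respiration": "respiration", "respiratory": "respiration",
        }.get(name.lower())
        if channel is None:
            continue
        out[channel] = RawSignal(
            samples=data[:, k],
            sampling_rate=float(meta["SamplingFrequency"]),
            start_time=float(meta["StartTime"]),
            channel=channel,
        )
    if not out:
        raise ValueError("no pulse or respiration column found in physio file")
    return out


def write_physio(signals: dict, tsv_path) -> None:
    """Write signals as a BIDS physio TSV(.gz) with a JSON sidecar.

    All signals must share sampling rate and start time.
    """
    tsv_path = Path(tsv_path)
    sigs = list(signals.values())
    fs = {s.sampling_rate for s in sigs}
    t0 = {s.start_time for s in sigs}
    if len(fs) != 1 or len(t0) != 1:
        raise ValueError("all channels must share SamplingFrequency and StartTime")
    n = min(s.samples.size for s in sigs)
    cols = {name: s.samples[:n] for name, s in signals.items()}
    pd.DataFrame(cols).to_csv(tsv_path, sep="\t", header=False, index=False)
    stem = tsv_path.name
    for suffix in (".tsv.gz", ".tsv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    meta = {
        "SamplingFrequency": fs.pop(),
        "StartTime": t0.pop(),
        "Columns": list(signals.keys()),
    }
    with open(tsv_path.with_name(stem + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_physio_tsv(path, channel: str, sampling_rate: float = None) -> RawSignal:
    """Read a plain 2-column (time, amplitude) TSV as one signal."""
    df = pd.read_csv(path, sep="\t", header=None)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(dt))
    return RawSignal(samples=x, sampling_rate=sampling_rate,
                     start_time=float(t[0]), channel=channel)


def load_bold(path, tr: float = None, t0: float = 0.0) -> BOLDImage:
    """Load a 4-D NIfTI; TR from the header pixdim[4] unless overridden."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr <= 0:
        raise ValueError("TR missing from header; pass tr= explicitly")
    return BOLDImage(data=data, tr=tr, affine=img.affine, t0=t0)


def save_bold(bold: BOLDImage, path) -> None:
    img = nib.Nifti1Image(bold.data, bold.affine)
    img.header.set_zooms((*bold.voxel_sizes, bold.tr))
    nib.save(img, str(path))


def load_motion_regressors(path, volume_times) -> RegressorSet:
    """Motion (and optionally CSF/WM) nuisance columns from a TSV with header."""
    df = pd.read_csv(path, sep="\t")
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != len(volume_times):
        raise ValueError(
            f"nuisance TSV has {mat.shape[0]} rows for {len(volume_times)} volumes"
        )
    return RegressorSet(mat, list(df.columns), np.asarray(volume_times, float))


def write_beats(ibi: IBISeries, path) -> None:
    """Beats TSV: onset_s, ibi_ms (of the preceding interval), flag."""
    ibi_col = np.concatenate([[np.nan], ibi.intervals])
    flag_col = np.concatenate([["first"], ibi.flags])
    pd.DataFrame(
        {"onset_s": ibi.beat_times, "ibi_ms": ibi_col, "flag": flag_col}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_beats(path) -> IBISeries:
    df = pd.read_csv(path, sep="\t")
    flags = df["flag"].to_numpy(dtype="<U9")[1:]
    return IBISeries.from_beat_times(df["onset_s"].to_numpy(dtype=float), flags=flags)


def write_metrics(metrics: HRVMetrics, path, breathing_rate: float = None,
                  n_corrected: int = None) -> None:
    payload = {
        "hr_bpm": metrics.hr,
        "sdnn_ms": metrics.sdnn,
        "rmssd_ms": metrics.rmssd,
        "n_beats": metrics.n_beats,
    }
    if breathing_rate is not None:
        payload["br_bpm"] = breathing_rate
    if n_corrected is not None:
        payload["n_corrected"] = n_corrected
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_connectome(matrix, path) -> None:
    """Dense node-by-node Fisher-z TSV; invalid edges written as NaN."""
    z = np.where(matrix.valid, matrix.z, np.nan)
    pd.DataFrame(z).to_csv(path, sep="\t", header=False, index=False,
                           float_format="%.8f")


def read_connectome(path, subject: str = "", session: str = ""):
    from .network import ConnectivityMatrix

    z = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    valid = np.isfinite(z)
    np.fill_diagonal(valid, False)
    return ConnectivityMatrix(z=z, valid=valid, subject=subject, session=session)
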