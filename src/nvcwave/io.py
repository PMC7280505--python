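"""Reading and writing the pipeline's file formats.

CSV is the portable interchange format (two-column series, margin traces,
coherence-map bundles with axis files); EDF ingestion of raw EEG — including
derived channel pairs such as C3-C4 — goes through :mod:`mne` when it is
installed.  YAML sidecars carry provenance (method, gains, filter spec,
seeds, config hash).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .aeeg import AEEGTrace
from .coherence import CoherenceMap
from .series import UniformSeries

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_edf_channel",
    "write_aeeg_csv",
    "read_aeeg_csv",
    "write_coherence_bundle",
    "write_sidecar",
    "read_sidecar",
]


def write_series_csv(path: str | Path, series: UniformSeries, value_name: str = "value") -> None:
    df = pd.DataFrame({"time_s": series.times, value_name: series.values})
    df.to_csv(path, index=False, float_format="%.10g")


def read_series_csv(path: str | Path, units: str = "") -> UniformSeries:
    """Load a two-column (time_s, value) CSV as a UniformSeries.

    The time column must be evenly spaced; the rate is recovered from it.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (time_s, value)")
    t = df.iloc[:, 0].to_numpy(float)
    v = df.iloc[:, 1].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt0 = (t[-1] - t[0]) / (t.size - 1)
    if dt0 <= 0 or np.max(np.abs(np.diff(t) - dt0)) > 1e-2 * dt0:
        raise ValueError(f"{path}: time column is not evenly spaced")
    return UniformSeries(v, rate=1.0 / float(dt0), t0=float(t[0]), units=units)


def read_edf_channel(path: str | Path, channel: str = "C3-C4") -> UniformSeries:
    """Read one EDF channel, or a two-electrode derivation written "A-B".

    Requires the optional :mod:`mne` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF input requires the optional 'mne' dependency (pip install nvcwave[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = raw.ch_names
    if channel in names:
        data = raw.get_data(picks=[channel])[0]
    elif "-" in channel:
        a, b = channel.split("-", 1)
        if a not in names or b not in names:
            raise ValueError(f"derivation {channel!r}: channels not found in {names}")
        data = raw.get_data(picks=[a])[0] - raw.get_data(picks=[b])[0]
    else:
        raise ValueError(f"channel {channel!r} not found in {names}")
    # MNE returns volts for EEG channels; the pipeline works in microvolts
    return UniformSeries(data * 1e6, rate=float(raw.info["sfreq"]), units="uV")


def write_aeeg_csv(path: str | Path, trace: AEEGTrace) -> None:
    df = pd.DataFrame(
        {"time_s": trace.uma.times, "uma_uV": trace.uma.values, "lma_uV": trace.lma.values}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_aeeg_csv(path: str | Path, method: str) -> AEEGTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    rate = 1.0 / float(t[1] - t[0])
    return AEEGTrace(
        uma=UniformSeries(df["uma_uV"].to_numpy(float), rate=rate, t0=float(t[0]), units="uV"),
        lma=UniformSeries(df["lma_uV"].to_numpy(float), rate=rate, t0=float(t[0]), units="uV"),
        method=method,
    )


def write_coherence_bundle(prefix: str | Path, cmap: CoherenceMap) -> None:
    """Write a CoherenceMap as <prefix>_r2.csv / _sig.csv / _coi.csv + axes."""
    prefix = Path(prefix)
    axes = pd.DataFrame({"scale_s": cmap.scales_s})
    axes.to_csv(f"{prefix}_scales.csv", index=False)
    pd.DataFrame({"time_s": cmap.times_s}).to_csv(f"{prefix}_times.csv", index=False)
    np.savetxt(f"{prefix}_r2.csv", cmap.r2, delimiter=",", fmt="%.6g")
    np.savetxt(f"{prefix}_coi.csv", cmap.coi_mask.astype(int), delimiter=",", fmt="%d")
    if cmap.sig_mask is not None:
        np.savetxt(f"{prefix}_sig.csv", cmap.sig_mask.astype(int), delimiter=",", fmt="%d")


def write_sidecar(path: str | Path, meta: dict[str, Any]) -> None:
    Path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_sidecar(path: str | Path) -> dict[str, Any]:
    return yaml.safe_load(Path(path).read_text())
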