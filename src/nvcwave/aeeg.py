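"""Raw EEG → amplitude-integrated EEG (aEEG) margin traces.

Two in-package conversion algorithms plus a device-ingestion path:

* ``M1`` — asymmetric equiripple FIR (rising 12 dB/decade over 2-15 Hz),
  full-wave rectification, 5th-order zero-phase Butterworth envelope, gain 2,
  then 90th/10th percentile terminal points over overlapping 15-s windows
  stepped by 4.78125 s and a smoothing pass through the terminal points.
* ``M2`` — same filter family and envelope with gain 1.631, terminal points
  over contiguous 4.78125-s epochs, and a centered 3-point moving average
  (≈15 s of support) of the terminal points.
* ``M3`` — the segmentation/margin steps of M1 applied to an externally
  computed 256 Hz aEEG amplitude series (a monitor's own conversion, which
  is not re-implemented here).

All paths emit upper/lower margin amplitudes (UMA/LMA) at one point per
1224-sample step — 256/1224 ≈ 0.209 Hz, matching the NIRS SctO2 clock —
and the bandwidth UMA − LMA that the coherence stage consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .series import UniformSeries

__all__ = [
    "FilterSpec",
    "TerminalPoints",
    "AEEGTrace",
    "FilterDesignError",
    "GAIN_M1",
    "GAIN_M2",
    "EPOCH_STEP_S",
    "M1_WINDOW_S",
    "WU_NEAT_NATIVE_STEP_S",
    "WU_NEAT_NATIVE_POINTS",
    "epoch_geometry",
    "epoch_count",
    "design_asymmetric_filter",
    "apply_fir",
    "rectify",
    "envelope",
    "apply_gain",
    "extract_terminal_points",
    "margins_m1",
    "margins_m2",
    "margins_m3",
    "bandwidth",
    "semilog_display",
]

#: Envelope gain of the M1 algorithm.
GAIN_M1 = 2.0
#: Envelope gain of the M2 (WU-NEAT-style) algorithm.
GAIN_M2 = 1.631
#: Segmentation step: 1224 samples at 256 Hz = 4.78125 s -> 0.209 Hz margins.
EPOCH_STEP_S = 1224.0 / 256.0
#: M1 sliding-window length.
M1_WINDOW_S = 15.0
#: Native WU-NEAT terminal-point step (before the 0.209 Hz re-segmentation).
WU_NEAT_NATIVE_STEP_S = 3.12
#: Native WU-NEAT moving-average width in terminal points.
WU_NEAT_NATIVE_POINTS = 5


class FilterDesignError(RuntimeError):
    """The asymmetric FIR specification could not be met."""


@dataclass(frozen=True)
class FilterSpec:
    """Asymmetric band-pass design targets.

    The desired magnitude rises at ``slope_db_per_decade`` across
    [stop_lo_hz, stop_hi_hz] (unit gain at stop_lo_hz) and is attenuated
    outside, with ``transition_hz``-wide edges.
    """

    stop_lo_hz: float = 2.0
    stop_hi_hz: float = 15.0
    slope_db_per_decade: float = 12.0
    n_taps: int = 401
    transition_hz: float = 0.5

    def validate(self, rate: float) -> None:
        if not 0 < self.stop_lo_hz < self.stop_hi_hz < rate / 2.0:
            raise ValueError(
                f"band edges ({self.stop_lo_hz}, {self.stop_hi_hz}) invalid for rate {rate}"
            )
        if self.n_taps % 2 == 0:
            raise ValueError("n_taps must be odd for a symmetric linear-phase design")
        if self.transition_hz <= 0 or self.transition_hz >= self.stop_lo_hz:
            raise ValueError("transition_hz must be in (0, stop_lo_hz)")


@dataclass(frozen=True)
class TerminalPoints:
    """Per-epoch 90th/10th percentile amplitudes (UTP/LTP) of the envelope."""

    utp: np.ndarray
    ltp: np.ndarray
    epoch_step_s: float
    epoch_len_s: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.ltp < 0) or np.any(self.utp < self.ltp):
            raise ValueError("terminal points must satisfy UTP >= LTP >= 0")

    @property
    def rate(self) -> float:
        return 1.0 / self.epoch_step_s


@dataclass(frozen=True)
class AEEGTrace:
    """Paired upper/lower margin amplitude series with the producing method."""

    uma: UniformSeries
    lma: UniformSeries
    method: str

    def __post_init__(self) -> None:
        if len(self.uma) != len(self.lma) or self.uma.rate != self.lma.rate:
            raise ValueError("uma and lma must share rate and length")
        if np.any(self.lma.values < 0) or np.any(self.uma.values < self.lma.values - 1e-12):
            raise ValueError("margins must satisfy UMA >= LMA >= 0")
        if self.method not in ("M1", "M2", "M3"):
            raise ValueError(f"unknown method tag {self.method!r}")

    @property
    def rate(self) -> float:
        return self.uma.rate


def epoch_count(n_samples: int, window: int, stride: int) -> int:
    """Number of window positions: floor((n - window)/stride) + 1."""
    if n_samples < window:
        raise ValueError(f"series of {n_samples} samples is shorter than one {window}-sample window")
    return (n_samples - window) // stride + 1


def epoch_geometry(rate: float = 256.0) -> dict[str, float]:
    """Closed-form segmentation arithmetic used throughout the pipeline."""
    step = int(round(EPOCH_STEP_S * rate))
    win = int(round(M1_WINDOW_S * rate))
    return {
        "epoch_samples": step,
        "epoch_step_s": step / rate,
        "margin_rate_hz": rate / step,
        "m1_window_samples": win,
        "m1_overlap_s": (win - step) / rate,
        "wu_neat_native_smooth_s": WU_NEAT_NATIVE_STEP_S * WU_NEAT_NATIVE_POINTS,
    }


def design_asymmetric_filter(rate: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Linear-phase FIR whose passband rises at ``slope_db_per_decade``.

    The 2-15 Hz passband is split into log-spaced sub-bands whose desired
    gains follow ``(f/stop_lo_hz)**(slope/20)`` — i.e. ``slope`` dB/decade,
    unit gain at the low edge — with zero desired response outside the band
    and ``transition_hz``-wide edges.  The taps come from a weighted
    least-squares fit (``scipy.signal.firls``), which tracks the sloped
    target without the in-band notching that equiripple exchange iterations
    exhibit on stepped-slope specifications; symmetric taps guarantee
    exactly linear phase.
    """
    spec = spec or FilterSpec()
    spec.validate(rate)
    n_seg = 24
    edges = np.geomspace(spec.stop_lo_hz, spec.stop_hi_hz, n_seg + 1)
    gains = (edges / spec.stop_lo_hz) ** (spec.slope_db_per_decade / 20.0)
    bands = [0.0, spec.stop_lo_hz - spec.transition_hz]
    desired = [0.0, 0.0]
    weight = [10.0]
    for i in range(n_seg):
        bands += [edges[i], edges[i + 1]]
        desired += [gains[i], gains[i + 1]]
        weight.append(1.0)
    bands += [spec.stop_hi_hz + spec.transition_hz, rate / 2.0]
    desired += [0.0, 0.0]
    weight.append(10.0)
    try:
        taps = signal.firls(spec.n_taps, bands, desired, weight=weight, fs=rate)
    except Exception as exc:  # pragma: no cover - scipy signals failure modes vary
        raise FilterDesignError(f"FIR design failed for {spec}: {exc}") from exc
    if not np.all(np.isfinite(taps)):
        raise FilterDesignError(f"FIR design diverged for {spec}")
    # quantify achieved ripple against the desired sloped response
    w, h = signal.freqz(taps, worN=4096, fs=rate)
    in_band = (w >= spec.stop_lo_hz * 1.05) & (w <= spec.stop_hi_hz * 0.95)
    want = (w[in_band] / spec.stop_lo_hz) ** (spec.slope_db_per_decade / 20.0)
    ripple_db = float(np.max(np.abs(20 * np.log10(np.abs(h[in_band]) / want))))
    if ripple_db > 3.0:
        raise FilterDesignError(
            f"specification unachievable with {spec.n_taps} taps: achieved in-band ripple "
            f"{ripple_db:.2f} dB (> 3 dB); increase n_taps or widen transition_hz"
        )
    return taps


def apply_fir(x: UniformSeries, taps: np.ndarray) -> UniformSeries:
    """Zero-delay application of a symmetric FIR (group delay compensated)."""
    if len(taps) % 2 != 1:
        raise ValueError("taps must have odd length")
    y = signal.oaconvolve(x.values, taps, mode="same")
    return x.with_values(y)


def rectify(x: UniformSeries) -> UniformSeries:
    """Full-wave rectification: element-wise absolute value."""
    return x.with_values(np.abs(x.values))


def envelope(x: UniformSeries, order: int = 5, cutoff_hz: float = 1.0) -> UniformSeries:
    """Zero-phase Butterworth low-pass of the rectified signal, clipped at 0.

    Forward-backward (``sosfiltfilt``) filtering doubles the effective order
    but cancels phase, so envelope features stay aligned with the raw EEG.
    The default 1 Hz cutoff smooths rectification ripple while passing the
    0.1-1.6 mHz coupling band with enormous margin.
    """
    if not 0 < cutoff_hz < x.rate / 2.0:
        raise ValueError(f"cutoff_hz {cutoff_hz} outside (0, Nyquist={x.rate / 2})")
    sos = signal.butter(order, cutoff_hz / (x.rate / 2.0), btype="lowpass", output="sos")
    return x.with_values(np.clip(signal.sosfiltfilt(sos, x.values), 0.0, None))


def apply_gain(x: UniformSeries, g: float) -> UniformSeries:
    if g <= 0:
        raise ValueError(f"gain must be positive, got {g}")
    return x.with_values(g * x.values)


def extract_terminal_points(
    env: UniformSeries,
    epoch_len_s: float = M1_WINDOW_S,
    step_s: float = EPOCH_STEP_S,
    hi_pct: float = 90.0,
    lo_pct: float = 10.0,
    _chunk: int = 4096,
) -> TerminalPoints:
    """UTP/LTP percentiles over sliding rectangular windows.

    Window and stride are fixed in integer samples (round(s * rate)) so the
    output clock never drifts; percentiles use the linear-interpolation
    convention between order statistics.
    """
    if epoch_len_s < step_s:
        raise ValueError("epoch_len_s must be >= step_s")
    window = int(round(epoch_len_s * env.rate))
    stride = int(round(step_s * env.rate))
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be at least one sample")
    n_ep = epoch_count(len(env), window, stride)
    view = np.lib.stride_tricks.sliding_window_view(env.values, window)[::stride][:n_ep]
    utp = np.empty(n_ep)
    ltp = np.empty(n_ep)
    for i in range(0, n_ep, _chunk):  # chunked: np.percentile copies its input
        block = view[i : i + _chunk]
        q = np.percentile(block, [lo_pct, hi_pct], axis=1)
        ltp[i : i + _chunk] = q[0]
        utp[i : i + _chunk] = q[1]
    return TerminalPoints(
        utp=utp,
        ltp=ltp,
        epoch_step_s=stride / env.rate,
        epoch_len_s=window / env.rate,
        t0=env.t0 + (window - 1) / (2.0 * env.rate),
    )


def _smooth_margin(x: np.ndarray, smoother: str, step_s: float) -> np.ndarray:
    if smoother == "ma3":
        # centered 3-point moving average; edges average the available points
        kernel = np.ones(3)
        num = np.convolve(x, kernel, mode="same")
        den = np.convolve(np.ones_like(x), kernel, mode="same")
        return num / den
    if smoother == "spline":
        t = np.arange(x.size) * step_s
        return CubicSpline(t[::3], x[::3])(t) if x.size > 9 else x.copy()
    if smoother == "none":
        return x.copy()
    raise ValueError(f"unknown margin smoother {smoother!r}")


def _margins(tp: TerminalPoints, method: str, smoother: str) -> AEEGTrace:
    uma = _smooth_margin(tp.utp, smoother, tp.epoch_step_s)
    lma = _smooth_margin(tp.ltp, smoother, tp.epoch_step_s)
    # spline smoothing may locally cross; restore the margin ordering invariant
    lma = np.clip(np.minimum(lma, uma), 0.0, None)
    uma = np.clip(uma, 0.0, None)
    rate = tp.rate
    return AEEGTrace(
        uma=UniformSeries(uma, rate=rate, t0=tp.t0, units="uV"),
        lma=UniformSeries(lma, rate=rate, t0=tp.t0, units="uV"),
        method=method,
    )


def margins_m1(env: UniformSeries, smoother: str = "ma3") -> AEEGTrace:
    """M1 margins: percentiles over overlapping 15-s windows stepped 4.78 s."""
    tp = extract_terminal_points(env, epoch_len_s=M1_WINDOW_S, step_s=EPOCH_STEP_S)
    return _margins(tp, "M1", smoother)


def margins_m2(env: UniformSeries, smoother: str = "ma3") -> AEEGTrace:
    """M2 margins: contiguous 4.78-s epochs, 3-point moving average (~15 s)."""
    tp = extract_terminal_points(env, epoch_len_s=EPOCH_STEP_S, step_s=EPOCH_STEP_S)
    return _margins(tp, "M2", smoother)


def margins_m3(aeeg_256: UniformSeries, smoother: str = "ma3") -> AEEGTrace:
    """Segmentation/margin steps of M1 applied to a device's 256 Hz aEEG output."""
    if np.any(aeeg_256.values < 0):
        raise ValueError("device aEEG input must be a nonnegative amplitude series")
    tp = extract_terminal_points(aeeg_256, epoch_len_s=M1_WINDOW_S, step_s=EPOCH_STEP_S)
    return _margins(tp, "M3", smoother)


def bandwidth(trace: AEEGTrace) -> UniformSeries:
    """aEEG bandwidth UMA − LMA (µV) — the series the coherence stage uses."""
    return trace.uma.with_values(np.clip(trace.uma.values - trace.lma.values, 0.0, None))


def semilog_display(v: float | np.ndarray) -> float | np.ndarray:
    """Conventional aEEG display coordinate: linear to 10 µV, log10 above.

    Maps v to v on [0, 10] and to 10*(1 + log10(v/10)) above 10, which is
    continuous and monotone (10→10, 100→20).
    """
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0):
        raise ValueError("display input must be nonnegative")
    out = np.where(arr <= 10.0, arr, 10.0 * (1.0 + np.log10(np.maximum(arr, 10.0) / 10.0)))
    return float(out) if np.isscalar(v) else out
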