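"""Synthetic paired EEG / SctO2 recordings with known neurovascular coupling.

The generator emulates long (hours-scale) neonatal monitoring sessions: a
256 Hz broadband EEG whose amplitude envelope carries slow oscillations in
the 640-10240 s band, and a cerebral tissue oxygen saturation (SctO2) series
at the NIRS device rate (nominally 0.209 Hz) that shares a configurable
fraction of those oscillations.  Because the coupling periods, strength and
seeds are known, every downstream stage (aEEG transform, wavelet coherence,
significance counting) has a ground-truth surface to test against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np
from scipy import signal

from .series import UniformSeries

__all__ = [
    "ConfigError",
    "SyntheticConfig",
    "SyntheticRecording",
    "generate_recording",
    "generate_ar1",
    "burst_suppression_carrier",
    "synthetic_device_aeeg",
    "MARGIN_STEP_S",
    "NOMINAL_SCTO2_RATE_HZ",
]

#: Margin/SctO2 step: 1224 samples at 256 Hz, the step the analysis is built around.
MARGIN_STEP_S = 1224.0 / 256.0  # 4.78125 s

#: Device-nominal SctO2 rate; exactly one sample per 4.78125 s (rounds to 0.209 Hz).
NOMINAL_SCTO2_RATE_HZ = 256.0 / 1224.0


class ConfigError(ValueError):
    """A synthetic-recording configuration field is out of its valid range."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic subject.

    Defaults describe a 20-hour continuous-background recording with a single
    shared oscillation at 3000 s, i.e. inside the 640-10240 s analysis band.

    Attributes
    ----------
    duration_s : float
        Recording length in seconds (default 72000 = 20 h).
    eeg_rate : float
        EEG sampling rate in Hz.
    scto2_rate : float
        SctO2 sampling rate in Hz.  Default is exactly 256/1224 Hz so the
        NIRS series and the aEEG margin series share one clock.
    pattern : str
        EEG background: ``"continuous"`` or ``"burst_suppression"``.
    coupling_periods_s : tuple of float
        Periods (s) of the shared slow modulation; each must be resolvable,
        i.e. lie in [2/scto2_rate, duration_s/4].
    coupling_strength : float
        In [0, 1]; the neurogenic weight of the SctO2 slow oscillation.
        SctO2 carries a constant-power mix of the shared modulation m(t)
        (weight s) and an independent vasomotion component at the same
        periods (weight 1-s), so the band coherence with the EEG envelope
        spans ~s^2/(s^2+(1-s)^2): 0 makes SctO2 statistically independent
        of the EEG envelope, 1 makes its slow oscillation fully shared.
    mod_depth : float
        Fractional depth of the EEG amplitude modulation (envelope =
        base * (1 + mod_depth * m(t)), m normalised to [-1, 1]).
    envelope_base_uV : float
        Baseline EEG envelope scale in microvolts.
    noise_sd_uV : float
        SD of additive white sensor noise on the EEG, microvolts.
    scto2_mean_pct : float
        Mean SctO2 in percent.
    scto2_coupling_amp_pct : float
        Amplitude (percent) of the shared modulation in SctO2 at strength 1.
    scto2_noise_sd_pct : float
        Stationary SD of the independent AR(1) noise added to SctO2.
    ar1_alpha : float
        Lag-1 coefficient of the SctO2 noise, in [0, 1).
    scto2_lag_s : float
        Delay of the shared modulation in SctO2 relative to the EEG envelope.
    seed : int
        Master seed; identical config implies bit-identical output.
    burst_rate_per_min, burst_len_s, suppression_ratio :
        Burst-suppression geometry, used only for that pattern.
    """

    duration_s: float = 72000.0
    eeg_rate: float = 256.0
    scto2_rate: float = NOMINAL_SCTO2_RATE_HZ
    pattern: str = "continuous"
    coupling_periods_s: tuple[float, ...] = (3000.0,)
    coupling_strength: float = 0.8
    mod_depth: float = 0.5
    envelope_base_uV: float = 25.0
    noise_sd_uV: float = 2.0
    scto2_mean_pct: float = 75.0
    scto2_coupling_amp_pct: float = 3.0
    scto2_noise_sd_pct: float = 1.5
    ar1_alpha: float = 0.8
    scto2_lag_s: float = 0.0
    seed: int = 0
    burst_rate_per_min: float = 6.0
    burst_len_s: float = 2.0
    suppression_ratio: float = 0.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "coupling_periods_s", tuple(float(p) for p in self.coupling_periods_s))

    def validate(self) -> None:
        if self.pattern not in ("continuous", "burst_suppression"):
            raise ConfigError(f"pattern: unknown value {self.pattern!r}")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ConfigError(f"coupling_strength: {self.coupling_strength} not in [0, 1]")
        if not 0.0 <= self.ar1_alpha < 1.0:
            raise ConfigError(f"ar1_alpha: {self.ar1_alpha} not in [0, 1)")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ConfigError(f"mod_depth: {self.mod_depth} not in [0, 1]")
        for name in ("duration_s", "eeg_rate", "scto2_rate", "envelope_base_uV"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be positive")
        for name in ("noise_sd_uV", "scto2_noise_sd_pct", "scto2_coupling_amp_pct"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be nonnegative")
        if self.duration_s * self.eeg_rate < 1 or self.duration_s * self.scto2_rate < 1:
            raise ConfigError("duration_s: too short for at least one sample per channel")
        lo, hi = 2.0 / self.scto2_rate, self.duration_s / 4.0
        for p in self.coupling_periods_s:
            if not lo <= p <= hi:
                raise ConfigError(
                    f"coupling_periods_s: period {p} s outside resolvable range [{lo:.1f}, {hi:.1f}] s"
                )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["coupling_periods_s"] = list(self.coupling_periods_s)
        return d


@dataclass(frozen=True)
class SyntheticRecording:
    """A generated subject: raw EEG, SctO2, and the ground truth behind them."""

    eeg: UniformSeries
    scto2: UniformSeries
    truth: dict[str, Any]

    def __post_init__(self) -> None:
        if np.any(self.scto2.values < 0) or np.any(self.scto2.values > 100):
            raise ValueError("scto2 values must lie in [0, 100]")
        span_gap = abs(self.eeg.duration - self.scto2.duration)
        if span_gap > 1.0 / self.scto2.rate + 1e-9:
            raise ValueError("eeg and scto2 must cover the same span within one SctO2 sample")


def _modulation(t: np.ndarray, periods: Sequence[float], phases: np.ndarray) -> np.ndarray:
    """Sum of unit sinusoids at the coupling periods, normalised to [-1, 1]."""
    m = np.zeros_like(t)
    for p, ph in zip(periods, phases):
        m += np.sin(2.0 * np.pi * t / p + ph)
    return m / max(len(periods), 1)


def _narrowband_vasomotion(
    t: np.ndarray, periods: Sequence[float], rng: np.random.Generator, tau_frac: float = 0.5
) -> np.ndarray:
    """Stochastic narrowband oscillation at the given periods.

    Each component is a carrier at period P whose complex amplitude drifts
    as an AR(1) with correlation time ``tau_frac * P`` — spectrally centred
    where the shared modulation lives, but phase-incoherent with it over the
    wavelet smoothing support.  Normalised to the same variance as the
    output of :func:`_modulation`.
    """
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    v = np.zeros_like(t)
    for p in periods:
        a = np.exp(-dt / (tau_frac * p))
        eps = (rng.standard_normal(t.size) + 1j * rng.standard_normal(t.size)) * np.sqrt(
            (1.0 - a * a) / 2.0
        )
        z0 = (rng.standard_normal() + 1j * rng.standard_normal()) / np.sqrt(2.0)
        z, _ = signal.lfilter([1.0], [1.0, -a], eps, zi=np.array([a * z0]))
        v += np.real(z * np.exp(2j * np.pi * t / p))
    return v / max(len(periods), 1)


def generate_ar1(n: int, alpha: float, sd: float, seed: int) -> UniformSeries:
    """First-order autoregressive noise x[t] = alpha*x[t-1] + eps[t].

    The innovation variance is sd^2 * (1 - alpha^2) and the initial state is
    drawn from the stationary distribution, so the series is stationary with
    variance sd^2 from the first sample.  This is the red-noise family used
    both for SctO2 measurement noise and for coherence-significance
    surrogates.
    """
    if not 0.0 <= alpha < 1.0:
        raise ConfigError(f"alpha: {alpha} not in [0, 1) (non-stationary)")
    if n < 2:
        raise ConfigError(f"n: need at least 2 samples, got {n}")
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, sd)
    eps = rng.standard_normal(n) * (sd * np.sqrt(1.0 - alpha * alpha))
    x, _ = signal.lfilter([1.0], [1.0, -alpha], eps, zi=np.array([alpha * x0]))
    return UniformSeries(x, rate=1.0, units="")


def ar1_batch(n: int, alpha: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """(size, n) array of independent unit-variance stationary AR(1) series."""
    if not 0.0 <= alpha < 1.0:
        raise ConfigError(f"alpha: {alpha} not in [0, 1) (non-stationary)")
    x0 = rng.standard_normal(size)
    eps = rng.standard_normal((size, n)) * np.sqrt(1.0 - alpha * alpha)
    x, _ = signal.lfilter([1.0], [1.0, -alpha], eps, axis=1, zi=(alpha * x0)[:, None])
    return x


def burst_suppression_carrier(
    duration_s: float,
    rate: float,
    burst_rate_per_min: float,
    burst_len_s: float,
    suppression_ratio: float,
    seed: int,
    ramp_s: float = 0.25,
) -> UniformSeries:
    """Discontinuous (burst-suppression-like) unit-scale broadband carrier.

    Gaussian noise whose amplitude alternates between 1 during bursts and
    ``suppression_ratio`` between them.  Burst onsets come from a seeded
    renewal process (exponential gaps shifted by the burst length so bursts
    never overlap); edges get a short cosine ramp to avoid spectral clicks.
    """
    if not 0.0 < suppression_ratio < 1.0:
        raise ConfigError(f"suppression_ratio: {suppression_ratio} not in (0, 1)")
    if burst_rate_per_min < 0 or burst_len_s < 0:
        raise ConfigError("burst geometry: rates and lengths must be nonnegative")
    duty = burst_len_s * burst_rate_per_min / 60.0
    if duty >= 1.0:
        raise ConfigError(
            f"burst geometry infeasible: duty cycle {duty:.2f} >= 1 "
            f"(burst_len_s * burst_rate_per_min / 60 must be < 1)"
        )
    n = int(round(duration_s * rate))
    rng = np.random.default_rng(seed)
    amp = np.full(n, suppression_ratio)
    if burst_rate_per_min > 0:
        mean_gap = 60.0 / burst_rate_per_min - burst_len_s
        t = float(rng.exponential(mean_gap))
        burst_n = max(int(round(burst_len_s * rate)), 1)
        while t < duration_s:
            i = int(t * rate)
            amp[i : i + burst_n] = 1.0
            t += burst_len_s + float(rng.exponential(mean_gap))
    ramp_n = int(round(ramp_s * rate))
    if ramp_n > 1:
        win = np.hanning(2 * ramp_n + 1)
        amp = signal.fftconvolve(
            np.pad(amp, ramp_n, mode="edge"), win / win.sum(), mode="same"
        )[ramp_n:-ramp_n]
    x = amp * rng.standard_normal(n)
    return UniformSeries(x, rate=rate, units="")


def generate_recording(cfg: SyntheticConfig) -> SyntheticRecording:
    """Generate one paired (raw EEG, SctO2) subject from a validated config.

    The EEG is a broadband carrier (continuous noise or burst-suppression)
    amplitude-modulated multiplicatively by a slow signal m(t) summed over
    the configured coupling periods.  SctO2's slow oscillation is a
    constant-power mix of m(t) (weight = coupling_strength, optionally
    lagged) and an independent vasomotion component at the same periods
    (weight 1 - coupling_strength), plus independent AR(1) measurement
    noise; the result is clipped to [0, 100] (clipped samples are counted
    in ``truth``).  Identical configs produce bit-identical recordings.
    """
    cfg.validate()
    ss = np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 0xA5EE])
    s_phase, s_carrier, s_sensor, s_scto2, s_vaso = ss.spawn(5)

    n_eeg = int(round(cfg.duration_s * cfg.eeg_rate))
    n_s = int(round(cfg.duration_s * cfg.scto2_rate))
    phases = np.random.default_rng(s_phase).uniform(0.0, 2.0 * np.pi, len(cfg.coupling_periods_s))

    t_eeg = np.arange(n_eeg) / cfg.eeg_rate
    m_eeg = _modulation(t_eeg, cfg.coupling_periods_s, phases)

    if cfg.pattern == "continuous":
        carrier = np.random.default_rng(s_carrier).standard_normal(n_eeg)
    else:
        carrier = burst_suppression_carrier(
            cfg.duration_s,
            cfg.eeg_rate,
            cfg.burst_rate_per_min,
            cfg.burst_len_s,
            cfg.suppression_ratio,
            seed=int(s_carrier.generate_state(1)[0] & 0x7FFFFFFF),
        ).values
    sensor = np.random.default_rng(s_sensor).standard_normal(n_eeg) * cfg.noise_sd_uV
    eeg = cfg.envelope_base_uV * (1.0 + cfg.mod_depth * m_eeg) * carrier + sensor

    t_s = np.arange(n_s) / cfg.scto2_rate
    m_s = _modulation(t_s - cfg.scto2_lag_s, cfg.coupling_periods_s, phases)
    m_vaso = _narrowband_vasomotion(t_s, cfg.coupling_periods_s, np.random.default_rng(s_vaso))
    s = cfg.coupling_strength
    norm = np.sqrt(s * s + (1.0 - s) ** 2)  # keep the oscillation power strength-independent
    noise = ar1_batch(n_s, cfg.ar1_alpha, 1, np.random.default_rng(s_scto2))[0]
    scto2 = (
        cfg.scto2_mean_pct
        + cfg.scto2_coupling_amp_pct * (s * m_s + (1.0 - s) * m_vaso) / norm
        + cfg.scto2_noise_sd_pct * noise
    )
    n_clipped = int(np.sum((scto2 < 0.0) | (scto2 > 100.0)))
    if n_clipped:
        warnings.warn(f"SctO2 clipped to [0, 100] at {n_clipped} samples", stacklevel=2)
    scto2 = np.clip(scto2, 0.0, 100.0)

    truth = {
        "config": cfg.to_dict(),
        "phases_rad": phases.tolist(),
        "modulation_scto2_rate": m_s,
        "n_scto2_clipped": n_clipped,
    }
    return SyntheticRecording(
        eeg=UniformSeries(eeg, rate=cfg.eeg_rate, units="uV"),
        scto2=UniformSeries(scto2, rate=cfg.scto2_rate, units="%"),
        truth=truth,
    )


def synthetic_device_aeeg(
    eeg: UniformSeries,
    gain: float = 1.8,
    cutoff_hz: float = 0.5,
    order: int = 2,
) -> UniformSeries:
    """Synthetic stand-in for a vendor's undisclosed 256 Hz raw-EEG→aEEG conversion.

    Used to exercise the device-ingestion path on synthetic subjects where no
    monitor export exists: band-pass (2-15 Hz Butterworth), full-wave
    rectification, a deliberately different low-pass envelope (order-2 at
    0.5 Hz) and gain, so its amplitudes differ from the in-package methods
    while the slow envelope dynamics are preserved.
    """
    nyq = eeg.rate / 2.0
    sos_bp = signal.butter(4, [2.0 / nyq, 15.0 / nyq], btype="bandpass", output="sos")
    x = signal.sosfiltfilt(sos_bp, eeg.values)
    x = np.abs(x)
    sos_lp = signal.butter(order, cutoff_hz / nyq, btype="lowpass", output="sos")
    env = np.clip(signal.sosfiltfilt(sos_lp, x), 0.0, None)
    return eeg.with_values(gain * env, units="uV")
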