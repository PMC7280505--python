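"""End-to-end orchestration: recording → aEEG per method → coherence → agreement.

A :class:`RunConfig` pins every algorithm constant (filter spec, gains,
epoch geometry, envelope cutoff, wavelet grid, surrogate count, alpha) and a
master seed from which each stochastic stage draws its own named stream, so
a run is reproducible bit for bit.  :func:`run_subject` analyses one
recording (synthetic or file-based); :func:`run_cohort` adds the
cross-subject agreement outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import aeeg, io
from .aeeg import AEEGTrace, FilterSpec
from .agreement import BlandAltmanResult, RegressionResult, bland_altman, cov_vs_pix, identity_regression
from .coherence import CoherenceMap, NVCResult, ScaleGrid, cov_across_methods, pix_total, significance_mask, wtc
from .series import UniformSeries
from .synthetic import SyntheticConfig, generate_recording, synthetic_device_aeeg

__all__ = ["RunConfig", "RunReport", "CohortResult", "run_subject", "run_cohort"]

log = logging.getLogger("nvcwave")

# named sub-stream tags hashed into the master seed (stage-level reproducibility)
_STREAMS = {"synthetic": 1, "surrogates_M1": 2, "surrogates_M2": 3, "surrogates_M3": 4}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one subject's analysis.

    Defaults are the pipeline's reference constants: 2-15 Hz asymmetric
    filter at 12 dB/decade, gains 2 (M1) and 1.631 (M2), 90th/10th
    percentiles over 15 s windows stepped 4.78125 s, the 640-10240 s wavelet
    band, 300 surrogates at alpha = 0.05.
    """

    mode: str = "synthetic"  # "synthetic" | "files"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    eeg_path: str | None = None
    scto2_path: str | None = None
    device_aeeg_path: str | None = None
    channel: str = "C3-C4"
    methods: tuple[str, ...] = ("M1", "M2", "M3")
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    gain_m1: float = aeeg.GAIN_M1
    gain_m2: float = aeeg.GAIN_M2
    envelope_cutoff_hz: float = 1.0
    envelope_order: int = 5
    smoother: str = "ma3"
    scale_lo_s: float = 640.0
    scale_hi_s: float = 10240.0
    voices_per_octave: int = 12
    n_surrogates: int = 300
    alpha: float = 0.05
    seed: int = 0
    outdir: str | None = None
    write_plots: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "methods", tuple(self.methods))
        bad = [m for m in self.methods if m not in ("M1", "M2", "M3")]
        if bad:
            raise ValueError(f"unknown methods {bad}")
        if not self.methods:
            raise ValueError("at least one method is required")
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            syn = dict(d["synthetic"])
            if "coupling_periods_s" in syn:
                syn["coupling_periods_s"] = tuple(syn["coupling_periods_s"])
            d["synthetic"] = SyntheticConfig(**syn)
        if "filter_spec" in d and isinstance(d["filter_spec"], dict):
            d["filter_spec"] = FilterSpec(**d["filter_spec"])
        if "methods" in d:
            d["methods"] = tuple(d["methods"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def stream_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([int(self.seed) & 0x7FFFFFFF, _STREAMS[stage]])
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class RunReport:
    """Per-subject outputs plus provenance for bit-identical re-runs."""

    config_hash: str
    seed: int
    traces: dict[str, AEEGTrace]
    bandwidths: dict[str, UniformSeries]
    nvc: NVCResult
    scto2_n: int
    version: str = "0.1.0"

    def summary(self) -> dict[str, Any]:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "pix_total": dict(self.nvc.pix_total),
            "cov_pct": self.nvc.cov_pct,
            "margin_samples": {m: len(t.uma) for m, t in self.traces.items()},
            "scto2_samples": self.scto2_n,
        }


@dataclass(frozen=True)
class CohortResult:
    reports: list[RunReport]
    table: pd.DataFrame  # columns: subject, method, pix_total, cov_pct
    bland_altman: dict[tuple[str, str], BlandAltmanResult]
    identity: dict[tuple[str, str], RegressionResult]
    cov_regressions: dict[str, RegressionResult]


def _load_inputs(cfg: RunConfig) -> tuple[UniformSeries, UniformSeries, UniformSeries | None]:
    """Returns (eeg, scto2, device_aeeg_or_None)."""
    if cfg.mode == "synthetic":
        rec = generate_recording(
            dataclasses.replace(cfg.synthetic, seed=cfg.stream_seed("synthetic"))
        )
        device = synthetic_device_aeeg(rec.eeg) if "M3" in cfg.methods else None
        return rec.eeg, rec.scto2, device
    if cfg.eeg_path is None and not (cfg.methods == ("M3",) and cfg.device_aeeg_path):
        raise ValueError("files mode: eeg_path is required")
    if cfg.scto2_path is None:
        raise ValueError("files mode: scto2_path is required")
    eeg = None
    if cfg.eeg_path:
        p = Path(cfg.eeg_path)
        eeg = (
            io.read_edf_channel(p, cfg.channel)
            if p.suffix.lower() == ".edf"
            else io.read_series_csv(p, units="uV")
        )
    scto2 = io.read_series_csv(cfg.scto2_path, units="%")
    device = io.read_series_csv(cfg.device_aeeg_path, units="uV") if cfg.device_aeeg_path else None
    if "M3" in cfg.methods and device is None:
        raise ValueError("files mode with M3 requires device_aeeg_path (the monitor's 256 Hz aEEG export)")
    return eeg, scto2, device


def compute_traces(
    cfg: RunConfig, eeg: UniformSeries | None, device: UniformSeries | None
) -> dict[str, AEEGTrace]:
    """Shared preprocessing then per-method margin extraction."""
    traces: dict[str, AEEGTrace] = {}
    env = None
    if {"M1", "M2"} & set(cfg.methods):
        if eeg is None:
            raise ValueError("M1/M2 require raw EEG input")
        taps = aeeg.design_asymmetric_filter(eeg.rate, cfg.filter_spec)
        filtered = aeeg.apply_fir(eeg, taps)
        rect = aeeg.rectify(filtered)
        env = aeeg.envelope(rect, order=cfg.envelope_order, cutoff_hz=cfg.envelope_cutoff_hz)
        log.info("preprocessed EEG: %d samples at %g Hz", len(eeg), eeg.rate)
    if "M1" in cfg.methods:
        traces["M1"] = aeeg.margins_m1(aeeg.apply_gain(env, cfg.gain_m1), smoother=cfg.smoother)
    if "M2" in cfg.methods:
        traces["M2"] = aeeg.margins_m2(aeeg.apply_gain(env, cfg.gain_m2), smoother=cfg.smoother)
    if "M3" in cfg.methods:
        if device is None:
            raise ValueError("M3 requires a device aEEG series")
        traces["M3"] = aeeg.margins_m3(device, smoother=cfg.smoother)
    for m, t in traces.items():
        log.info("%s margins: %d samples at %.5f Hz", m, len(t.uma), t.rate)
    return traces


def run_subject(cfg: RunConfig) -> RunReport:
    """Full single-subject analysis; see module docstring for the chain."""
    eeg, scto2, device = _load_inputs(cfg)
    traces = compute_traces(cfg, eeg, device)

    bandwidths = {m: aeeg.bandwidth(t) for m, t in traces.items()}
    n_common = min(len(scto2), *(len(b) for b in bandwidths.values()))
    scto2_c = scto2.head(n_common)

    duration = n_common / scto2.rate
    grid = ScaleGrid.band(cfg.scale_lo_s, cfg.scale_hi_s, cfg.voices_per_octave).clipped_to(duration)

    maps: dict[str, CoherenceMap] = {}
    pix: dict[str, int] = {}
    for m in cfg.methods:
        bw = bandwidths[m].head(n_common)
        try:
            cmap = wtc(scto2_c, bw, grid)
            cmap = significance_mask(
                cmap, scto2_c, bw, n_surrogates=cfg.n_surrogates, alpha=cfg.alpha,
                seed=cfg.stream_seed(f"surrogates_{m}"),
            )
        except ValueError as exc:
            raise RuntimeError(f"coherence stage failed for method {m}: {exc}") from exc
        maps[m] = cmap
        pix[m] = pix_total(cmap)
    if len(cfg.methods) >= 2:
        cov = cov_across_methods([pix[m] for m in cfg.methods])
    else:
        cov = None
        log.warning("COV unavailable: fewer than two methods requested")
    nvc = NVCResult(pix_total=pix, cov_pct=cov, maps=maps)
    report = RunReport(
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
        traces=traces,
        bandwidths=bandwidths,
        nvc=nvc,
        scto2_n=n_common,
    )
    if cfg.outdir:
        _write_subject_outputs(cfg, report)
    return report


def _write_subject_outputs(cfg: RunConfig, report: RunReport) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for m, t in report.traces.items():
        io.write_aeeg_csv(out / f"aeeg_{m}.csv", t)
    for m, cmap in report.nvc.maps.items():
        io.write_coherence_bundle(out / f"wtc_{m}", cmap)
    meta = {"config": cfg.to_dict(), "summary": report.summary()}
    io.write_sidecar(out / "report.yaml", meta)
    if cfg.write_plots:
        from . import viz

        for m, t in report.traces.items():
            viz.plot_aeeg(t, out / f"aeeg_{m}.png")
        for m, cmap in report.nvc.maps.items():
            viz.plot_coherence(cmap, out / f"wtc_{m}.png")


_PAIRS = (("M1", "M2"), ("M2", "M3"), ("M1", "M3"))


def run_cohort(cfgs: Sequence[RunConfig]) -> CohortResult:
    """Analyse several subjects on one shared grid and compare the methods.

    Raises if subjects request different wavelet grids; agreement outputs
    need at least two subjects (regressions: at least three).
    """
    if not cfgs:
        raise ValueError("empty cohort")
    grids = {(c.scale_lo_s, c.scale_hi_s, c.voices_per_octave) for c in cfgs}
    if len(grids) > 1:
        raise ValueError(f"mixed wavelet grids across subjects: {sorted(grids)}")
    reports = [run_subject(c) for c in cfgs]
    rows = []
    for i, rep in enumerate(reports):
        for m, p in rep.nvc.pix_total.items():
            rows.append({"subject": i, "method": m, "pix_total": p, "cov_pct": rep.nvc.cov_pct})
    table = pd.DataFrame(rows)

    ba: dict[tuple[str, str], BlandAltmanResult] = {}
    ident: dict[tuple[str, str], RegressionResult] = {}
    covreg: dict[str, RegressionResult] = {}
    methods = cfgs[0].methods
    if len(reports) < 2:
        log.warning("single subject: agreement section omitted")
    else:
        per_method = {m: [r.nvc.pix_total[m] for r in reports] for m in methods}
        for a, b in _PAIRS:
            if a in per_method and b in per_method:
                ba[(a, b)] = bland_altman(per_method[a], per_method[b])
                if len(reports) >= 3:
                    ident[(a, b)] = identity_regression(per_method[a], per_method[b])
        covs = [r.nvc.cov_pct for r in reports]
        if len(reports) >= 3 and all(c is not None for c in covs):
            covreg = cov_vs_pix(per_method, covs)
    return CohortResult(reports=reports, table=table, bland_altman=ba, identity=ident, cov_regressions=covreg)
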