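"""Synthetic data generators with recorded ground truth.

Every input the analysis pipeline consumes can be generated here:

* :func:`gen_mea_recording` — multichannel extracellular voltage traces:
  Gaussian noise plus biphasic spike templates at known times plus
  band-limited oscillations of known RMS amplitude.
* :func:`gen_omics_table` — log-normal LC-MS style feature tables with
  known group effects, detection-limit (lowest-signal) missingness and
  QC replicate injections of configured variability.
* :func:`gen_ocr_trace` — piecewise-plateau Seahorse oxygen-consumption
  traces with the canonical oligomycin / FCCP / rotenone-antimycin
  injection sequence.
* :func:`gen_quic_plate` — RT-QuIC ThT fluorescence plates with sigmoidal
  amplification in seeded wells.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assays import OCRTrace, QuICPlate
from .conditioning import Recording
from .errors import ConfigurationError
from .omics import FeatureTable

# --------------------------------------------------------------------------
# MEA recordings
# --------------------------------------------------------------------------

#: Representative in-band frequency (Hz) used for each named oscillation band.
DEFAULT_BAND_FREQS: dict[str, float] = {
    "delta": 2.0,
    "theta": 6.0,
    "alpha": 11.0,
    "beta": 20.0,
    "low_gamma": 40.0,
    "upper_gamma": 150.0,
}


@dataclass
class MEASimConfig:
    """Configuration of a simulated MEA recording.

    ``spike_amplitude`` is the negative-peak amplitude of the inserted
    biphasic template in multiples of ``noise_sd``. ``band_amplitudes``
    maps band names to oscillation RMS amplitudes in volts; each band is
    rendered as a sinusoid at its representative frequency
    (:data:`DEFAULT_BAND_FREQS`, overridable via ``band_freqs``).
    """

    n_channels: int = 1
    duration: float = 60.0
    fs: float = 25_000.0
    spike_rate: float = 0.0
    burst_rate: float = 0.0  # bursts per minute
    spikes_per_burst: int = 5
    intra_burst_isi: float = 0.01
    spike_amplitude: float = 8.0
    noise_sd: float = 1e-5
    band_amplitudes: Mapping[str, float] = field(default_factory=dict)
    band_freqs: Mapping[str, float] = field(default_factory=dict)
    burst_period: float | None = None  # seconds; None -> Poisson burst onsets
    seed: int = 0

    def resolved_band_freqs(self) -> dict[str, float]:
        freqs = dict(DEFAULT_BAND_FREQS)
        freqs.update(self.band_freqs)
        return freqs

    def validate(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.spike_amplitude < 0:
            raise ConfigurationError("spike_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for name, rate in (
            ("spike_rate", self.spike_rate),
            ("burst_rate", self.burst_rate),
        ):
            if rate < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.spikes_per_burst < 2:
            raise ConfigurationError("spikes_per_burst must be >= 2")
        if self.intra_burst_isi <= 0:
            raise ConfigurationError("intra_burst_isi must be > 0")
        freqs = self.resolved_band_freqs()
        for band, amp in self.band_amplitudes.items():
            if amp < 0:
                raise ConfigurationError(f"band amplitude for {band!r} must be >= 0")
            if band not in freqs:
                raise ConfigurationError(f"no frequency defined for band {band!r}")
            if amp > 0 and self.fs <= 2 * freqs[band]:
                raise ConfigurationError(
                    f"fs must exceed 2x the highest oscillation frequency "
                    f"({freqs[band]} Hz for band {band!r})"
                )


@dataclass
class MEAGroundTruth:
    """Exactly what :func:`gen_mea_recording` inserted."""

    true_spike_times: list[np.ndarray]
    true_burst_intervals: list[list[tuple[float, float]]]
    true_band_amplitudes: dict[str, float]
    true_burst_period: float | None = None


def spike_template(fs: float) -> np.ndarray:
    """Biphasic extracellular spike template, ~1 ms total width.

    Dominant negative lobe followed by a smaller positive rebound;
    normalized so the negative peak equals -1 and sits at the centre
    sample (the nominal spike time).
    """
    half = int(round(0.5e-3 * fs))
    t_ms = np.arange(-half, half + 1) / fs * 1e3
    w = -np.exp(-(((t_ms + 0.05) / 0.22) ** 2)) + 0.6 * np.exp(
        -(((t_ms - 0.30) / 0.30) ** 2)
    )
    return w / -w.min()


def _burst_onsets(
    rng: np.random.Generator, cfg: MEASimConfig, burst_len: float
) -> np.ndarray:
    lo, hi = burst_len, cfg.duration - burst_len
    if hi <= lo:
        return np.empty(0)
    if cfg.burst_period is not None:
        return np.arange(lo, hi, cfg.burst_period)
    n = rng.poisson(cfg.burst_rate / 60.0 * cfg.duration)
    onsets = np.sort(rng.uniform(lo, hi, n))
    kept: list[float] = []
    for t in onsets:  # thin to forbid overlap
        if not kept or t >= kept[-1] + burst_len:
            kept.append(t)
    return np.asarray(kept)


def gen_mea_recording(cfg: MEASimConfig) -> tuple[Recording, MEAGroundTruth]:
    """Simulate an MEA recording and return it with its ground truth.

    The trace is Gaussian noise + biphasic templates at the true spike
    times + sinusoidal oscillations at the configured band RMS
    amplitudes. Tonic spikes follow a homogeneous Poisson process; burst
    onsets are Poisson thinned to forbid overlap (or periodic when
    ``burst_period`` is set) with fixed intra-burst ISIs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    tmpl = spike_template(cfg.fs)
    half = (len(tmpl) - 1) // 2
    burst_len = (cfg.spikes_per_burst - 1) * cfg.intra_burst_isi
    freqs = cfg.resolved_band_freqs()
    amp_v = cfg.spike_amplitude * cfg.noise_sd

    traces = np.empty((cfg.n_channels, n))
    all_spikes: list[np.ndarray] = []
    all_bursts: list[list[tuple[float, float]]] = []
    margin = (half + 1) / cfg.fs
    for ch in range(cfg.n_channels):
        if cfg.noise_sd > 0:
            x = rng.normal(0.0, cfg.noise_sd, n)
        else:
            x = np.zeros(n)

        n_tonic = rng.poisson(cfg.spike_rate * cfg.duration)
        tonic = rng.uniform(margin, cfg.duration - margin, n_tonic)

        bursts: list[tuple[float, float]] = []
        burst_spikes: list[float] = []
        if cfg.burst_rate > 0 or cfg.burst_period is not None:
            for onset in _burst_onsets(rng, cfg, burst_len):
                times = onset + np.arange(cfg.spikes_per_burst) * cfg.intra_burst_isi
                burst_spikes.extend(times)
                bursts.append((float(times[0]), float(times[-1])))

        spikes = np.sort(np.concatenate([tonic, np.asarray(burst_spikes)]))
        # drop spikes closer than one template width so each inserted
        # waveform is individually resolvable in the ground truth
        if len(spikes) > 1:
            keep = np.concatenate([[True], np.diff(spikes) >= 1e-3])
            spikes = spikes[keep]
        for t in spikes:
            i = int(round(t * cfg.fs))
            x[i - half : i + half + 1] += amp_v * tmpl

        t_axis = np.arange(n) / cfg.fs
        for band, rms in cfg.band_amplitudes.items():
            if rms > 0:
                phase = rng.uniform(0.0, 2.0 * np.pi)
                x += rms * math.sqrt(2.0) * np.sin(
                    2.0 * np.pi * freqs[band] * t_axis + phase
                )

        traces[ch] = x
        all_spikes.append(spikes)
        all_bursts.append(bursts)

    rec = Recording(traces, fs=cfg.fs, protocol="organoid_mea")
    truth = MEAGroundTruth(
        true_spike_times=all_spikes,
        true_burst_intervals=all_bursts,
        true_band_amplitudes={b: a for b, a in cfg.band_amplitudes.items() if a > 0},
        true_burst_period=cfg.burst_period,
    )
    return rec, truth


# --------------------------------------------------------------------------
# Omics feature tables
# --------------------------------------------------------------------------


@dataclass
class OmicsSimConfig:
    """Configuration of a simulated LC-MS feature table.

    Signals are log-normal; group 2's per-feature means are shifted by
    ``2**true_log2fc``. Missingness censors the lowest study-sample
    signals (detection-limit behaviour). ``qc_cv`` sets the per-feature
    coefficient of variation of the QC injections; ``sample_cv`` the
    within-group biological CV.
    """

    n_per_group: int = 5
    n_features: int = 100
    group_labels: tuple[str, str] = ("DD", "DN")
    true_log2fc: Sequence[float] | float = 0.0
    missing_frac: float = 0.0
    qc_cv: Sequence[float] | float = 0.1
    n_qc: int = 4
    sample_cv: float = 0.2
    feature_class: str = "metabolite"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.missing_frac < 1.0:
            raise ConfigurationError("missing_frac must be in [0, 1)")
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        if self.n_qc < 0:
            raise ConfigurationError("n_qc must be >= 0")
        if self.sample_cv < 0:
            raise ConfigurationError("sample_cv must be >= 0")


def _cv_to_sigma_ln(cv: np.ndarray | float) -> np.ndarray | float:
    """Natural-log SD of a log-normal with the given coefficient of variation."""
    return np.sqrt(np.log1p(np.square(cv)))


def gen_omics_table(cfg: OmicsSimConfig) -> tuple[FeatureTable, pd.DataFrame]:
    """Simulate a feature table and its per-feature ground truth.

    Returns the table and a truth frame indexed by feature id with
    columns ``true_log2fc``, ``qc_cv`` and ``qc_pass_expected`` (whether
    the feature should survive a 30% QC-CV filter).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_features
    log2fc = np.broadcast_to(np.asarray(cfg.true_log2fc, dtype=float), (m,)).copy()
    qc_cv = np.broadcast_to(np.asarray(cfg.qc_cv, dtype=float), (m,)).copy()

    features = [f"F{i:04d}" for i in range(m)]
    base_ln = rng.uniform(np.log(1e3), np.log(1e6), m)  # baseline abundances
    sig_ln = _cv_to_sigma_ln(cfg.sample_cv)

    n = cfg.n_per_group
    ga, gb = cfg.group_labels
    sample_ids = [f"{ga}_{i+1}" for i in range(n)] + [f"{gb}_{i+1}" for i in range(n)]
    groups = [ga] * n + [gb] * n

    shift = np.vstack(
        [np.zeros((n, m)), np.tile(log2fc * np.log(2.0), (n, 1))]
    )
    study = np.exp(base_ln + shift + rng.normal(0.0, sig_ln, (2 * n, m)))

    # MNAR censoring: blank out the lowest missing_frac quantile of all
    # study-sample signals (QC injections are left intact)
    if cfg.missing_frac > 0:
        cut = np.quantile(study, cfg.missing_frac)
        study = np.where(study <= cut, np.nan, study)

    frames = [pd.DataFrame(study, index=sample_ids, columns=features)]
    if cfg.n_qc > 0:
        qc_ids = [f"QC_{i+1}" for i in range(cfg.n_qc)]
        qc_center = base_ln + log2fc * np.log(2.0) / 2.0  # pooled material
        qc_sig = _cv_to_sigma_ln(qc_cv)
        qc = np.exp(qc_center + rng.normal(0.0, 1.0, (cfg.n_qc, m)) * qc_sig)
        frames.append(pd.DataFrame(qc, index=qc_ids, columns=features))
        sample_ids = sample_ids + qc_ids
        groups = groups + ["QC"] * cfg.n_qc

    signal = pd.concat(frames)
    sample_meta = pd.DataFrame(
        {"group": groups, "is_qc": [g == "QC" for g in groups]}, index=sample_ids
    )
    feature_meta = pd.DataFrame(
        {
            "analyte_id": features,
            "class": [cfg.feature_class] * m,
        },
        index=features,
    )
    table = FeatureTable(signal=signal, sample_meta=sample_meta, feature_meta=feature_meta)
    truth = pd.DataFrame(
        {
            "true_log2fc": log2fc,
            "qc_cv": qc_cv,
            "qc_pass_expected": qc_cv <= 0.3,
        },
        index=features,
    )
    return table, truth


# --------------------------------------------------------------------------
# Seahorse OCR traces
# --------------------------------------------------------------------------

INJECTION_SEQUENCE = ("oligomycin", "fccp", "rotenone_antimycin")


def gen_ocr_trace(
    baseline: float,
    post_oligo: float,
    post_fccp: float,
    post_rotaa: float,
    n_reads_per_phase: int = 3,
    noise_sd: float = 0.0,
    read_interval_min: float = 6.0,
    seed: int = 0,
) -> OCRTrace:
    """Simulate a mito-stress-test OCR trace (pmol O2/min).

    Four plateaus — baseline, after oligomycin, after FCCP, after
    rotenone/antimycin A — with injections annotated midway between the
    phases' boundary readings.
    """
    levels = (baseline, post_oligo, post_fccp, post_rotaa)
    if any(v < 0 for v in levels):
        raise ConfigurationError("OCR plateau levels must be >= 0")
    if n_reads_per_phase < 1:
        raise ConfigurationError("n_reads_per_phase must be >= 1")
    rng = np.random.default_rng(seed)
    times = (np.arange(4 * n_reads_per_phase) + 1) * read_interval_min
    ocr = np.repeat(np.asarray(levels, dtype=float), n_reads_per_phase)
    if noise_sd > 0:
        ocr = ocr + rng.normal(0.0, noise_sd, ocr.shape)
    injections = [
        (float(times[k * n_reads_per_phase - 1] + read_interval_min / 2.0), label)
        for k, label in zip((1, 2, 3), INJECTION_SEQUENCE)
    ]
    return OCRTrace(times=times, ocr=ocr, injections=injections)


# --------------------------------------------------------------------------
# RT-QuIC plates
# --------------------------------------------------------------------------


def gen_quic_plate(
    n_wells: int,
    n_positive: int,
    t_lag: float = 10.0,
    t_max: float = 40.0,
    plateau: float = 200_000.0,
    baseline: float = 5_000.0,
    cadence_h: float = 0.75,
    rise_h: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "sample",
) -> tuple[QuICPlate, dict]:
    """Simulate an RT-QuIC plate read every 45 min (default cadence).

    ``n_positive`` wells follow a sigmoidal ThT rise beginning near
    ``t_lag`` hours up to ``plateau``; the rest stay at ``baseline``.
    Returns the plate and a truth dict with the seeded well indices and a
    warning flag when ``t_lag >= t_max`` (no well can cross in-window).
    """
    if n_positive > n_wells:
        raise ConfigurationError("n_positive must be <= n_wells")
    if n_wells < 1:
        raise ConfigurationError("n_wells must be >= 1")
    rng = np.random.default_rng(seed)
    n_t = int(math.floor(t_max / cadence_h)) + 1  # includes t = 0
    times = np.arange(n_t) * cadence_h

    fluor = np.full((n_wells, n_t), float(baseline))
    t50 = t_lag + 3.0 * rise_h
    sig = 1.0 / (1.0 + np.exp(-(times - t50) / rise_h))
    s0 = 1.0 / (1.0 + np.exp(-(t_lag - t50) / rise_h))
    rise = np.where(times >= t_lag, (sig - s0) / (1.0 - s0), 0.0)  # flat pre-lag
    for w in range(n_positive):
        fluor[w] = baseline + (plateau - baseline) * rise
    if noise_sd > 0:
        fluor = fluor + rng.normal(0.0, noise_sd, fluor.shape)

    truth = {
        "positive_wells": list(range(n_positive)),
        "n_positive": n_positive,
        "warning": (
            "t_lag >= t_max: no seeded well crosses within the read window"
            if (t_lag >= t_max and n_positive > 0)
            else None
        ),
    }
    plate = QuICPlate(
        fluorescence=fluor,
        times_h=times,
        replicate_map={sample_id: list(range(n_wells))},
        cadence_min=cadence_h * 60.0,
    )
    return plate, truth
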