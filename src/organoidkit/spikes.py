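"""Spike detection, burst detection and burst periodicity.

Population spikes are threshold crossings of the spike-band-conditioned
trace: events exceeding ``mean ± k·SD`` where the mean and SD come from a
baseline window at the start of the recording (30 s for organoid MEA
recordings, 10 s for multiwell plates; k = 4 by default). A burst is any
maximal group of spikes in which some 100 ms window holds at least 4
spikes. Burst periodicity is the dominant inter-burst interval estimated
from the autocorrelation of binned burst onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DataQualityError, ParameterError

#: Baseline window (s) each protocol uses for threshold estimation.
PROTOCOL_BASELINE_S = {"organoid_mea": 30.0, "multiwell": 10.0}


@dataclass(frozen=True)
class ThresholdEstimate:
    """Baseline statistics and the derived detection threshold pair."""

    mean: float
    sd: float
    k: float
    baseline_s: float

    @property
    def lower(self) -> float:
        return self.mean - self.k * self.sd

    @property
    def upper(self) -> float:
        return self.mean + self.k * self.sd


@dataclass
class SpikeTrain:
    """Detected spike times (seconds, strictly increasing) for one channel."""

    channel_id: str
    spike_times: np.ndarray
    threshold: ThresholdEstimate | None = None
    polarity: str = "both"
    dead_time: float = 0.002

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class BurstEpisode:
    """One burst: boundary spikes and member count."""

    start: float
    end: float
    n_spikes: int


@dataclass(frozen=True)
class ActivitySummary:
    spike_rate: float  # Hz
    burst_rate: float  # bursts per minute
    burst_periodicity: float | None  # seconds, None when undefined


def estimate_threshold(
    trace: np.ndarray, fs: float, baseline_s: float = 30.0, k: float = 4.0
) -> ThresholdEstimate:
    """Mean, SD and mean ± k·SD over the first ``baseline_s`` seconds."""
    trace = np.asarray(trace, dtype=float)
    n_base = int(round(baseline_s * fs))
    if trace.size < n_base:
        raise ParameterError(
            f"baseline of {baseline_s} s requested but only "
            f"{trace.size / fs:.3f} s available"
        )
    base = trace[:n_base]
    return ThresholdEstimate(
        mean=float(base.mean()), sd=float(base.std()), k=float(k),
        baseline_s=float(baseline_s),
    )


def detect_spikes(
    trace: np.ndarray,
    fs: float,
    threshold: ThresholdEstimate,
    dead_time: float = 0.002,
    polarity: str = "both",
    channel_id: str = "ch00",
) -> SpikeTrain:
    """Detect one event per threshold-crossing excursion.

    Each excursion is timestamped at its extremum; events closer than
    ``dead_time`` to the previously accepted event are suppressed so one
    biphasic waveform is never counted twice.
    """
    if dead_time <= 0:
        raise ParameterError("dead_time must be > 0")
    if polarity not in ("neg", "pos", "both"):
        raise ParameterError(f"polarity must be neg|pos|both, got {polarity!r}")
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return SpikeTrain(channel_id, np.empty(0), threshold, polarity, dead_time)
    if threshold.sd == 0:
        raise DataQualityError(
            "baseline SD is zero (flat baseline); threshold detection is degenerate"
        )
    dev = trace - threshold.mean
    lim = threshold.k * threshold.sd
    if polarity == "neg":
        mask = dev < -lim
    elif polarity == "pos":
        mask = dev > lim
    else:
        mask = np.abs(dev) > lim

    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]

    times: list[float] = []
    last = -np.inf
    for s, e in zip(starts, ends):
        peak = s + int(np.argmax(np.abs(dev[s:e])))
        t = peak / fs
        if t - last >= dead_time:
            times.append(t)
            last = t
    return SpikeTrain(channel_id, np.asarray(times), threshold, polarity, dead_time)


def detect_bursts(
    spikes: SpikeTrain | np.ndarray,
    min_spikes: int = 4,
    window_s: float = 0.1,
) -> list[BurstEpisode]:
    """Group spikes into bursts (>= ``min_spikes`` within ``window_s``).

    A window qualifies when it contains at least ``min_spikes`` spikes;
    overlapping qualifying windows merge into a single episode whose
    boundaries are its first and last member spikes.
    """
    t = spikes.spike_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    n = len(t)
    if n < min_spikes:
        return []
    if np.any(np.diff(t) < 0):
        raise ParameterError("spike times must be sorted")

    # window anchored at spike i qualifies iff spike i+min_spikes-1 fits in it
    spans: list[tuple[int, int]] = []
    for i in range(n - min_spikes + 1):
        if t[i + min_spikes - 1] - t[i] <= window_s:
            j = int(np.searchsorted(t, t[i] + window_s, side="right")) - 1
            spans.append((i, j))
    if not spans:
        return []

    merged: list[list[int]] = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= merged[-1][1]:  # shares at least one spike
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [
        BurstEpisode(start=float(t[a]), end=float(t[b]), n_spikes=b - a + 1)
        for a, b in merged
    ]


def burst_periodicity(
    episodes: list[BurstEpisode],
    bin_s: float = 0.1,
    max_lag_s: float = 10.0,
    duration: float | None = None,
) -> float | None:
    """Dominant inter-burst interval from burst-onset autocorrelation.

    Burst onsets are binned at ``bin_s`` and the unbiased autocorrelation
    evaluated to ``max_lag_s``. The returned periodicity is the lag of
    the dominant significant positive peak; for a periodic onset comb the
    peaks at the period and its multiples are statistically
    indistinguishable, so ties within 5% of the highest peak resolve to
    the smallest lag (the fundamental). Returns ``None`` for fewer than
    three episodes or when no peak clears the white-noise significance
    floor ``3/sqrt(n_bins)``.
    """
    if len(episodes) < 3:
        return None
    onsets = np.asarray([e.start for e in episodes])
    span = duration if duration is not None else float(onsets.max()) + bin_s
    n_bins = int(np.ceil(span / bin_s))
    counts, _ = np.histogram(onsets, bins=n_bins, range=(0.0, n_bins * bin_s))
    x = counts - counts.mean()
    var = float(np.dot(x, x)) / n_bins
    if var == 0:
        return None
    max_lag = min(int(round(max_lag_s / bin_s)), n_bins - 2)
    ac = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        ac[k] = float(np.dot(x[: n_bins - k], x[k:])) / (n_bins - k) / var

    peaks, _ = sps.find_peaks(ac[1:])
    peaks = peaks + 1
    floor = 3.0 / np.sqrt(n_bins)
    peaks = peaks[ac[peaks] > floor]
    if len(peaks) == 0:
        return None
    best = float(ac[peaks].max())
    lag = int(peaks[ac[peaks] >= 0.95 * best][0])
    return lag * bin_s


def activity_summary(
    st: SpikeTrain,
    episodes: list[BurstEpisode],
    duration: float,
    periodicity_kwargs: dict | None = None,
) -> ActivitySummary:
    """Spike rate (Hz), burst rate (bursts/min) and burst periodicity."""
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    kwargs = dict(periodicity_kwargs or {})
    kwargs.setdefault("duration", duration)
    return ActivitySummary(
        spike_rate=st.n_spikes / duration,
        burst_rate=len(episodes) / duration * 60.0,
        burst_periodicity=burst_periodicity(episodes, **kwargs),
    )


def match_spike_times(
    true_times: np.ndarray, detected_times: np.ndarray, tol: float = 0.002
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true events within ``tol``.

    Returns (true positives, n_true, n_detected) for recall/precision
    bookkeeping against a generator's ground truth.
    """
    true_times = np.asarray(true_times, dtype=float)
    detected_times = np.asarray(detected_times, dtype=float)
    used = np.zeros(len(detected_times), dtype=bool)
    tp = 0
    for t in true_times:
        j = int(np.searchsorted(detected_times, t))
        for jj in (j - 1, j):
            if (
                0 <= jj < len(detected_times)
                and not used[jj]
                and abs(detected_times[jj] - t) <= tol
            ):
                used[jj] = True
                tp += 1
                break
    return tp, len(true_times), len(detected_times)


def pool_spike_trains(trains: list[SpikeTrain], channel_id: str = "pooled") -> SpikeTrain:
    """Merge per-electrode trains into one population train (sorted)."""
    if not trains:
        return SpikeTrain(channel_id, np.empty(0))
    times = np.sort(np.concatenate([tr.spike_times for tr in trains]))
    return SpikeTrain(channel_id, times)
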