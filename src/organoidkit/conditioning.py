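"""Signal conditioning for extracellular recordings.

Two acquisition protocols are supported:

* ``organoid_mea`` — 60-electrode MEA recordings of cerebral organoids,
  sampled at 25 kHz. Spike-band conditioning is a 300–2500 Hz band-pass
  (4th-order Butterworth, zero-phase).
* ``multiwell`` — multiwell monolayer recordings sampled at 20 kHz.
  Spike-band conditioning is a 300 Hz high-pass (2nd-order Butterworth)
  followed by a 3500 Hz low-pass (4th-order Butterworth), zero-phase.

Oscillation analysis operates on a 1 kHz version of the signal produced by
:func:`antialias_downsample`: a linear-phase FIR low-pass applied
forward-backward before decimation, staged so that no decimation factor
exceeds 8, with the final stage passing 400 Hz and stopping 500 Hz at
>= 60 dB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ParameterError

Protocol = Literal["organoid_mea", "multiwell"]

#: Native sampling rate each acquisition protocol implies.
PROTOCOL_FS = {"organoid_mea": 25_000.0, "multiwell": 20_000.0}

#: Spike band of the organoid MEA chain (Hz).
ORGANOID_SPIKE_BAND = (300.0, 2500.0)

#: Multiwell chain: high-pass corner/order, low-pass corner/order.
MULTIWELL_HIGHPASS = (300.0, 2)
MULTIWELL_LOWPASS = (3500.0, 4)


@dataclass
class Recording:
    """A multichannel extracellular voltage recording.

    Parameters
    ----------
    samples
        channels x time array of voltages (volts).
    fs
        Sampling rate in Hz.
    protocol
        Acquisition protocol tag, ``organoid_mea`` or ``multiwell``.
    channel_ids
        One identifier per channel.
    """

    samples: np.ndarray
    fs: float
    protocol: Protocol = "organoid_mea"
    channel_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("recording contains non-finite samples")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_ids) != self.n_channels:
            raise ParameterError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Specification of one filtering stage."""

    kind: Literal["fir_lowpass", "butter_highpass", "butter_lowpass", "bandpass"]
    cutoffs: tuple[float, ...]
    order: int
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        for c in self.cutoffs:
            if not 0.0 < c < nyq:
                raise ParameterError(
                    f"cutoff {c} Hz outside (0, {nyq}) Hz for fs={fs}"
                )
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")


def _apply_sos(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def spike_band_filter(
    rec: Recording,
    protocol: Protocol | None = None,
    zero_phase: bool = True,
) -> Recording:
    """Apply the protocol's spike-band filter chain.

    ``organoid_mea``: 300–2500 Hz band-pass, 4th-order Butterworth.
    ``multiwell``: 300 Hz high-pass (order 2) then 3500 Hz low-pass
    (order 4), both Butterworth.

    Zero-phase (forward-backward) by default so event timing is preserved;
    set ``zero_phase=False`` for a single-pass, acquisition-faithful run.
    """
    protocol = protocol or rec.protocol
    if protocol not in PROTOCOL_FS:
        raise ParameterError(f"unknown protocol {protocol!r}")
    if rec.fs != PROTOCOL_FS[protocol]:
        warnings.warn(
            f"protocol {protocol} implies fs={PROTOCOL_FS[protocol]:g} Hz "
            f"but recording has fs={rec.fs:g} Hz; proceeding with the "
            "recording's rate",
            stacklevel=2,
        )
    nyq = rec.fs / 2.0
    if protocol == "organoid_mea":
        lo, hi = ORGANOID_SPIKE_BAND
        if hi >= nyq:
            raise ParameterError(f"upper cutoff {hi} Hz >= Nyquist {nyq} Hz")
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
        out = _apply_sos(sos, rec.samples, zero_phase)
    else:
        hp_c, hp_o = MULTIWELL_HIGHPASS
        lp_c, lp_o = MULTIWELL_LOWPASS
        if lp_c >= nyq:
            raise ParameterError(f"low-pass cutoff {lp_c} Hz >= Nyquist {nyq} Hz")
        sos_hp = sps.butter(hp_o, hp_c, btype="highpass", fs=rec.fs, output="sos")
        sos_lp = sps.butter(lp_o, lp_c, btype="lowpass", fs=rec.fs, output="sos")
        out = _apply_sos(sos_lp, _apply_sos(sos_hp, rec.samples, zero_phase), zero_phase)
    return replace(rec, samples=out)


def _decimation_stages(q: int, max_factor: int = 8) -> list[int]:
    """Factor an integer decimation ratio into stages of at most max_factor."""
    stages: list[int] = []
    rest = q
    for p in (8, 7, 6, 5, 4, 3, 2):
        while rest % p == 0 and rest > 1:
            stages.append(p)
            rest //= p
    if rest != 1:
        raise ParameterError(
            f"decimation ratio {q} has a prime factor > {max_factor}"
        )
    return sorted(stages, reverse=True)


def _stage_fir(fs_in: float, fs_out: float) -> np.ndarray:
    """Kaiser-window FIR passing 0.4*fs_out and stopping 0.5*fs_out at 60 dB."""
    pass_edge = 0.4 * fs_out
    stop_edge = 0.5 * fs_out
    numtaps, beta = sps.kaiserord(60.0, (stop_edge - pass_edge) / (0.5 * fs_in))
    numtaps |= 1  # odd length -> integer group delay, symmetric
    return sps.firwin(
        numtaps, (pass_edge + stop_edge) / 2.0, window=("kaiser", beta), fs=fs_in
    )


def antialias_downsample(rec: Recording, target_fs: float = 1000.0) -> Recording:
    """Anti-aliased integer-ratio downsampling (e.g. 25000 -> 1000 Hz).

    A zero-phase linear-phase FIR low-pass is applied before each
    decimation stage; the final stage passes 400 Hz and stops 500 Hz
    (>= 60 dB) when ``target_fs`` is 1000 Hz. Duration is preserved to
    within one output sample.
    """
    if target_fs >= rec.fs:
        raise ParameterError(
            f"target_fs {target_fs} Hz must be below recording fs {rec.fs} Hz"
        )
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ParameterError(
            f"target_fs {target_fs} Hz must divide fs {rec.fs} Hz evenly"
        )
    x = rec.samples
    fs = rec.fs
    for stage in _decimation_stages(q):
        fs_out = fs / stage
        taps = _stage_fir(fs, fs_out)
        padlen = min(3 * len(taps), x.shape[-1] - 1)
        x = sps.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)
        x = x[..., ::stage]
        fs = fs_out
    return replace(rec, samples=x, fs=fs)
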