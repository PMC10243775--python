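"""Deterministic signal path from a raw-rate recording to the analysis
series: segment extraction, anti-aliased decimation and zero-phase
beta-band filtering.

The default path mirrors the working resolution of the connectivity
analysis: discard the first 5 s, keep the following 55 s, decimate from
1 kHz to 50 Hz, then band-pass 13-25 Hz.  55 s at 50 Hz gives exactly
2750 samples per channel.  The whole chain is deterministic and commutes
with channel permutation.

Raw-data hygiene steps that only apply to real MEG (tSSS, ICA artefact
removal, notch filtering) are represented by identity pass-through hooks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import SensorRecording

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "extract_segment",
    "decimate_to",
    "bandpass_beta",
    "preprocess_chain",
    "artefact_cleaning_hook",
]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band in Hz; the beta band 13-25 Hz by default."""

    lo_hz: float = 13.0
    hi_hz: float = 25.0

    def validate(self, fs: float) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError(f"invalid band edges ({self.lo_hz}, {self.hi_hz})")
        if self.lo_hz >= fs / 2 or self.hi_hz > fs / 2:
            raise ValueError(
                f"band ({self.lo_hz}, {self.hi_hz}) Hz exceeds the Nyquist "
                f"frequency {fs / 2} Hz of the data")


def extract_segment(rec: SensorRecording, discard_s: float = 5.0,
                    keep_s: float = 55.0) -> SensorRecording:
    """Drop the initial ``discard_s`` seconds and keep the next ``keep_s``.

    The first output sample is the first sample at or after ``discard_s``
    (0-based index ``ceil(discard_s * fs)``); the output lasts exactly
    ``keep_s`` seconds.
    """
    start = math.ceil(discard_s * rec.fs)
    n_keep = int(round(keep_s * rec.fs))
    if start + n_keep > rec.n_samples:
        raise ValueError(
            f"recording too short: {discard_s + keep_s:g} s required "
            f"(discard {discard_s:g} + keep {keep_s:g}) but only "
            f"{rec.duration:g} s available")
    return rec.copy_with(data=rec.data[:, start:start + n_keep].copy())


def _decimation_stages(factor: int) -> list[int]:
    """Split a decimation factor into stages of at most 10 (FIR-friendly)."""
    stages = []
    while factor > 10:
        for s in (10, 8, 5, 4, 2):  # prefer larger stages
            if factor % s == 0:
                stages.append(s)
                factor //= s
                break
        else:
            raise ValueError(f"cannot factorize decimation factor {factor} "
                             "into stages <= 10")
    if factor > 1:
        stages.append(factor)
    return stages


def decimate_to(rec: SensorRecording, fs_target: float = 50.0) -> SensorRecording:
    """Decimate with an anti-alias FIR (>=40 dB stopband) to ``fs_target``.

    The original rate must be an integer multiple of the target; large
    factors are applied in cascaded stages.  Output length is
    ``floor(n * fs_target / fs)``.
    """
    ratio = rec.fs / fs_target
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"non-integer decimation factor {ratio:g} "
            f"({rec.fs:g} Hz -> {fs_target:g} Hz)")
    expected = rec.n_samples * int(round(fs_target)) // int(round(rec.fs)) \
        if float(rec.fs).is_integer() and float(fs_target).is_integer() \
        else int(rec.n_samples / factor)
    data = rec.data
    if factor > 1:
        for stage in _decimation_stages(factor):
            data = signal.decimate(data, stage, ftype="fir", axis=1,
                                   zero_phase=True)
    data = data[:, :expected].copy()
    return rec.copy_with(data=data, fs=fs_target)


def _design_beta_fir(band: BandSpec, fs: float,
                     transition_hz: float = 2.0) -> np.ndarray:
    """Linear-phase FIR for the band; Hamming design, ~3.3 fs/df taps.

    When the upper band edge sits at (or within 2% of) the Nyquist
    frequency the kernel degenerates to a high-pass at ``lo_hz`` -- no
    energy exists above Nyquist, so no upper transition band is needed.
    This is exactly the situation of a 13-25 Hz band at 50 Hz sampling.
    """
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    nyq = fs / 2.0
    if band.hi_hz >= 0.98 * nyq:
        taps = signal.firwin(numtaps, band.lo_hz, pass_zero=False, fs=fs)
    else:
        taps = signal.firwin(numtaps, [band.lo_hz, band.hi_hz],
                             pass_zero=False, fs=fs)
    return taps


def bandpass_beta(rec: SensorRecording,
                  band: BandSpec = BandSpec()) -> SensorRecording:
    """Zero-phase FIR band-pass; output length equals input length.

    The linear-phase kernel is applied forward and backward
    (``filtfilt``), which squares the magnitude response: passband ripple
    stays well under 1 dB and stopband attenuation exceeds 40 dB one
    transition width (2 Hz) beyond the band edges.
    """
    band.validate(rec.fs)
    taps = _design_beta_fir(band, rec.fs)
    logger.debug("beta FIR: %d taps at fs=%g Hz, band=(%g, %g) Hz",
                 len(taps), rec.fs, band.lo_hz, band.hi_hz)
    data = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    return rec.copy_with(data=data)


def artefact_cleaning_hook(rec: SensorRecording) -> SensorRecording:
    """Identity stand-in for raw-data cleaning (tSSS / ICA / notch).

    Synthetic recordings are generated clean, so this hook passes data
    through unchanged and logs a warning.  Real-data users should clean
    recordings with standard MEG tooling before entering the pipeline.
    """
    logger.warning("artefact cleaning hook is a pass-through on synthetic data")
    return rec.copy_with()


def preprocess_chain(
    rec: SensorRecording,
    discard_s: float = 5.0,
    keep_s: float = 55.0,
    fs_target: float = 50.0,
    band: BandSpec = BandSpec(),
) -> SensorRecording:
    """extract -> decimate -> band-pass with the default analysis settings.

    On the default path (60 s at 1 kHz in) the output has exactly
    55 s x 50 Hz = 2750 samples per channel.
    """
    out = extract_segment(rec, discard_s, keep_s)
    out = decimate_to(out, fs_target)
    return bandpass_beta(out, band)
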