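"""Raw-recording conditioning: baseline removal, FIR bandpass, re-referencing,
and non-overlapping epoch segmentation.

The canonical order, mirrored by :func:`preprocess`, is
baseline -> bandpass -> rereference -> epoch. Baseline removal and average
re-referencing are both linear projections and commute, so the fixed order is
a convention, not a numerical necessity.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Tuple

import numpy as np
import scipy.signal

from .recording import EEGRecording, EpochedData

logger = logging.getLogger(__name__)


def remove_baseline(recording: EEGRecording) -> EEGRecording:
    """Subtract each channel's mean so every channel is zero-mean."""
    if recording.n_samples < 2:
        raise ValueError("need at least 2 samples per channel to remove a baseline")
    data = recording.data - recording.data.mean(axis=1, keepdims=True)
    return recording.copy_with(data=data)


def _hamming_transition_width_hz(cutoff_hz: float) -> float:
    # conventional: a quarter of the cutoff clamped to [0.5, 2] Hz, but never
    # wider than twice the cutoff itself (a 0.1 Hz high-pass edge must still
    # reach deep attenuation by DC)
    return min(max(0.25 * cutoff_hz, 0.5), 2.0, 2.0 * cutoff_hz)


def design_bandpass_fir(
    low_hz: float, high_hz: float, sampling_rate: float
) -> np.ndarray:
    """Design a Hamming-windowed sinc bandpass FIR filter.

    The filter order follows the Hamming-window approximation
    ``N = 3.3 / (transition_width / fs)`` using the narrower of the two edge
    transition widths, forced odd so the filter has an integral group delay.
    """
    nyquist = sampling_rate / 2.0
    if not (0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low_hz < high_hz, got {low_hz}, {high_hz}")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be below the Nyquist frequency {nyquist}")
    widths = []
    if low_hz > 0:
        widths.append(_hamming_transition_width_hz(low_hz))
    widths.append(_hamming_transition_width_hz(high_hz))
    width = min(widths)
    numtaps = int(math.ceil(3.3 * sampling_rate / width))
    if numtaps % 2 == 0:
        numtaps += 1
    if low_hz > 0:
        taps = scipy.signal.firwin(
            numtaps, [low_hz, high_hz], pass_zero=False, window="hamming", fs=sampling_rate
        )
    else:
        taps = scipy.signal.firwin(
            numtaps, high_hz, pass_zero=True, window="hamming", fs=sampling_rate
        )
    return taps


def bandpass_fir(
    recording: EEGRecording, low_hz: float = 0.1, high_hz: float = 100.0
) -> EEGRecording:
    """Zero-phase Hamming-windowed sinc FIR bandpass.

    The designed filter is linear-phase (symmetric taps, odd length), so a
    single FFT convolution with its integral group delay compensated is
    exactly zero-phase — the cheap equivalent of forward-backward filtering
    without squaring the magnitude response. Edges are reflection-padded by
    half the filter length; output length equals input length.
    """
    taps = design_bandpass_fir(low_hz, high_hz, recording.sampling_rate)
    if recording.n_samples <= 3 * len(taps):
        raise ValueError(
            f"signal of {recording.n_samples} samples is too short for a "
            f"{len(taps)}-tap filter (need > 3x the filter length)"
        )
    half = (len(taps) - 1) // 2
    padded = np.pad(recording.data, ((0, 0), (half, half)), mode="reflect")
    data = scipy.signal.fftconvolve(padded, taps[None, :], mode="same", axes=1)
    data = data[:, half:-half]
    return recording.copy_with(data=data)


def rereference(
    recording: EEGRecording,
    scheme: str = "average",
    pair: Optional[Tuple[str, str]] = None,
) -> EEGRecording:
    """Re-express the recording against a new reference.

    ``scheme`` is one of ``'none'`` (identity), ``'average'`` (subtract the
    instantaneous mean over channels — the model-free stand-in for a neutral
    reference), or ``'linked_pair'`` (subtract the mean of two named channels,
    e.g. the mastoid surrogates); ``pair`` is required for ``'linked_pair'``.
    """
    if scheme == "none":
        return recording.copy_with()
    if scheme == "average":
        ref = recording.data.mean(axis=0, keepdims=True)
        return recording.copy_with(data=recording.data - ref, reference="average")
    if scheme == "linked_pair":
        if pair is None or len(pair) != 2:
            raise ValueError("linked_pair scheme requires a (label_a, label_b) pair")
        ia = recording.channel_index(pair[0])
        ib = recording.channel_index(pair[1])
        ref = 0.5 * (recording.data[ia] + recording.data[ib])
        return recording.copy_with(
            data=recording.data - ref, reference=f"linked({pair[0]},{pair[1]})"
        )
    raise ValueError(f"unknown reference scheme {scheme!r}; use none, average or linked_pair")


def segment_epochs(recording: EEGRecording, epoch_duration_s: float = 5.0) -> EpochedData:
    """Cut the recording into consecutive non-overlapping epochs.

    A trailing partial epoch is discarded; the epoch count is
    ``floor(n_samples / samples_per_epoch)``. The standard resting-state
    parameters — 300 s at 250 Hz cut into 5-s epochs — give 60 epochs of
    1,250 samples.
    """
    spe = epoch_duration_s * recording.sampling_rate
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError(
            f"epoch_duration_s * sampling_rate must be an integer, got {spe}"
        )
    spe = int(round(spe))
    if spe < 2:
        raise ValueError("epochs must contain at least 2 samples")
    n_epochs = recording.n_samples // spe
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.n_samples} samples is shorter than one "
            f"{spe}-sample epoch"
        )
    trimmed = recording.data[:, : n_epochs * spe]
    data = trimmed.reshape(recording.n_channels, n_epochs, spe).transpose(1, 0, 2)
    return EpochedData(
        data=data.copy(),
        sampling_rate=recording.sampling_rate,
        channel_labels=recording.channel_labels,
        epoch_duration_s=epoch_duration_s,
    )


def reject_epochs(epoched: EpochedData, amplitude_threshold: float) -> EpochedData:
    """Drop epochs whose absolute amplitude exceeds ``amplitude_threshold``.

    A deterministic stand-in for manual artifact rejection: any epoch in which
    any channel sample exceeds the threshold in absolute value is removed (and
    logged). Raises if every epoch would be rejected.
    """
    keep = np.max(np.abs(epoched.data), axis=(1, 2)) <= amplitude_threshold
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("rejected %d of %d epochs exceeding |%g|", n_dropped, epoched.n_epochs, amplitude_threshold)
    if not keep.any():
        raise ValueError("amplitude threshold rejected every epoch")
    return EpochedData(
        data=epoched.data[keep].copy(),
        sampling_rate=epoched.sampling_rate,
        channel_labels=epoched.channel_labels,
        epoch_duration_s=epoched.epoch_duration_s,
    )


def preprocess(
    recording: EEGRecording,
    low_hz: float = 0.1,
    high_hz: float = 100.0,
    reference_scheme: str = "average",
    reference_pair: Optional[Tuple[str, str]] = None,
    epoch_duration_s: float = 5.0,
    amplitude_threshold: Optional[float] = None,
) -> EpochedData:
    """Full conditioning chain: baseline -> bandpass -> rereference -> epoch
    (-> optional amplitude-based epoch rejection)."""
    rec = remove_baseline(recording)
    rec = bandpass_fir(rec, low_hz, high_hz)
    rec = rereference(rec, reference_scheme, reference_pair)
    epoched = segment_epochs(rec, epoch_duration_s)
    if amplitude_threshold is not None:
        epoched = reject_epochs(epoched, amplitude_threshold)
    return epoched
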