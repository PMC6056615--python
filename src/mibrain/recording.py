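"""Core data containers for multichannel EEG.

The package works on 10-20-system scalp recordings. The canonical montage here
is the 16-electrode subset Fp1/2, F3/4, F7/8, C3/4, T3/4, P3/4, O1/2, T5/6
(odd numbers over the left hemisphere, even over the right), sampled at 250 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 16 scalp loci used throughout, in fixed order (left/right interleaved).
MONTAGE_16 = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "T3", "T4", "P3", "P4", "O1", "O2", "T5", "T6",
)

#: Left/right hemisphere split of the 16-channel montage (odd = left, even = right).
LEFT_CHANNELS = frozenset({"Fp1", "F3", "F7", "C3", "T3", "P3", "O1", "T5"})
RIGHT_CHANNELS = frozenset({"Fp2", "F4", "F8", "C4", "T4", "P4", "O2", "T6"})

#: Homologous left-right electrode pairs.
HOMOLOGOUS_PAIRS = (
    ("Fp1", "Fp2"), ("F3", "F4"), ("F7", "F8"), ("C3", "C4"),
    ("T3", "T4"), ("P3", "P4"), ("O1", "O2"), ("T5", "T6"),
)

#: Frontal and parieto-occipital electrode sets used for the anterior-posterior
#: (fronto-parieto-occipital) coupling contrast.
FRONTAL_SET = frozenset({"Fp1", "Fp2", "F3", "F4", "F7", "F8"})
PARIETO_OCCIPITAL_SET = frozenset({"P3", "P4", "O1", "O2", "T5", "T6"})


@dataclass
class EEGRecording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values in microvolt-scale arbitrary units.
    sampling_rate : float
        Sampling frequency in Hz.
    channel_labels : tuple of str
        Ordered, unique 10-20 channel names, one per row of ``data``.
    reference : str
        Free-text descriptor of the reference scheme the data are expressed in.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple
    reference: str = "unknown"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in montage; valid labels: {list(self.channel_labels)}"
            ) from None

    def copy_with(self, **changes) -> "EEGRecording":
        if "data" not in changes:
            changes["data"] = self.data.copy()
        return replace(self, **changes)


@dataclass
class EpochedData:
    """Non-overlapping fixed-length epochs cut from a recording.

    ``data`` has shape (n_epochs, n_channels, samples_per_epoch) and
    ``samples_per_epoch`` must equal ``epoch_duration_s * sampling_rate``
    exactly.
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: tuple
    epoch_duration_s: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be 3-D (epochs x channels x samples)")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one epoch")
        expected = self.epoch_duration_s * self.sampling_rate
        if abs(expected - round(expected)) > 1e-9 or round(expected) != self.data.shape[2]:
            raise ValueError(
                f"samples_per_epoch {self.data.shape[2]} != epoch_duration_s * sampling_rate "
                f"({expected})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoched data contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.data.shape[2]


def hemisphere_of(label: str) -> str:
    """Return 'left' or 'right' for a 16-montage label, else raise KeyError."""
    if label in LEFT_CHANNELS:
        return "left"
    if label in RIGHT_CHANNELS:
        return "right"
    raise KeyError(
        f"channel {label!r} has no hemisphere assignment; "
        f"montage labels: {sorted(LEFT_CHANNELS | RIGHT_CHANNELS)}"
    )
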