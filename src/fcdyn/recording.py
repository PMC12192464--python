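"""Multichannel recording container and montage utilities.

A :class:`Recording` holds a channels x samples matrix together with its
sampling rate and channel labels — the in-memory form of an SEEG session
segment.  Bipolar derivation (adjacent-contact subtraction) is supported
because intracranial connectivity is conventionally computed on bipolar
channels, which suppress the common reference and far-field activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording"]


@dataclass
class Recording:
    """A block of multichannel time series.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``; rows are channels.
    fs
        Sampling rate in Hz.
    channel_labels
        Unique label per channel.  Defaults to ``ch00, ch01, ...``.
    bipolar_pairs
        Optional list of ``(anode_label, cathode_label)`` tuples; when given,
        :meth:`to_bipolar` derives ``anode - cathode`` channels.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    bipolar_pairs: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.isfinite(self.data).all():
            bad = [i for i in range(self.data.shape[0])
                   if not np.isfinite(self.data[i]).all()]
            raise ValueError(f"non-finite samples in channel rows {bad}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def slice_seconds(self, start_s: float, end_s: float) -> "Recording":
        """Half-open time slice ``[start_s, end_s)`` as a new Recording."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(end_s * self.fs))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValueError(f"slice [{start_s}, {end_s}) outside recording")
        return replace(self, data=self.data[:, i0:i1])

    def to_bipolar(self) -> "Recording":
        """Derive bipolar channels ``anode - cathode`` from ``bipolar_pairs``."""
        if not self.bipolar_pairs:
            return self
        idx = {lab: i for i, lab in enumerate(self.channel_labels)}
        rows, labels = [], []
        for anode, cathode in self.bipolar_pairs:
            if anode not in idx or cathode not in idx:
                raise KeyError(f"bipolar pair ({anode}, {cathode}) not in labels")
            rows.append(self.data[idx[anode]] - self.data[idx[cathode]])
            labels.append(f"{anode}-{cathode}")
        return Recording(np.array(rows), self.fs, labels)
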