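"""Sliding-window FC estimation and the FC-dynamics (FCD) matrix.

The session is cut into fixed-length windows (default 5 s, 50% overlap);
each window yields one fused directed FC matrix.  The FCD matrix is the
window-by-window Pearson correlation of the vectorized FC patterns — the
similarity structure in which task-specific connectivity states appear as
blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fcmeasures import (DEFAULT_BAND, DEFAULT_N_FREQS, compute_measures)
from .fusion import FusionConfig, default_config, fuse
from .recording import Recording

__all__ = ["WindowedFC", "FCDMatrix", "window_bounds", "sliding_fc", "fcd",
           "fcd_task_contrast", "MIXED_LABEL"]

logger = logging.getLogger(__name__)

MIXED_LABEL = "mixed"


@dataclass
class WindowedFC:
    """Ordered stack of per-window directed FC matrices with task labels."""

    windows: list[tuple[float, float]]
    matrices: np.ndarray           # (W, n, n), source row -> target column
    task_labels: list[str]
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.windows) != self.matrices.shape[0]:
            raise ValueError("one matrix per window required")
        if len(self.task_labels) != len(self.windows):
            raise ValueError("one task label per window required")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]

    def vectorized(self) -> np.ndarray:
        """Off-diagonal entries per window, shape (W, n*(n-1))."""
        n = self.n_channels
        off = ~np.eye(n, dtype=bool)
        return self.matrices[:, off]

    def non_mixed(self) -> "WindowedFC":
        """Subset of windows fully inside one task annotation."""
        keep = [i for i, lab in enumerate(self.task_labels) if lab != MIXED_LABEL]
        return WindowedFC(
            [self.windows[i] for i in keep],
            self.matrices[keep],
            [self.task_labels[i] for i in keep],
            self.channel_labels,
        )


@dataclass
class FCDMatrix:
    """Window x window Pearson similarity of FC patterns; symmetric, unit diag."""

    values: np.ndarray
    windows: list[tuple[float, float]]
    task_labels: list[str]


def window_bounds(duration_s: float, window_s: float,
                  overlap: float) -> list[tuple[float, float]]:
    """Half-open windows [k*hop, k*hop + window_s) fitting the session."""
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if duration_s < window_s:
        raise ValueError(
            f"session of {duration_s} s shorter than one {window_s} s window")
    hop = window_s * (1.0 - overlap)
    n_win = int(np.floor((duration_s - window_s) / hop + 1e-9)) + 1
    return [(k * hop, k * hop + window_s) for k in range(n_win)]


def label_window(bounds: tuple[float, float],
                 annotations: list[tuple[float, float, str]]) -> str:
    """Task label of the annotation covering the window, else "mixed"."""
    w0, w1 = bounds
    for a0, a1, lab in annotations:
        if a0 - 1e-9 <= w0 and w1 <= a1 + 1e-9:
            return lab
    return MIXED_LABEL


def sliding_fc(recording: Recording,
               annotations: list[tuple[float, float, str]],
               window_s: float = 5.0, overlap: float = 0.5,
               fusion_config: FusionConfig | None = None,
               order: int | str = "auto", max_order: int = 5,
               band: tuple[float, float] = DEFAULT_BAND,
               n_freqs: int = DEFAULT_N_FREQS,
               max_lag: int | None = None) -> WindowedFC:
    """Fused directed FC per sliding window over a session.

    Windows straddling a task boundary are labeled "mixed"; they stay in
    the stack (and in the FCD) but are excluded from supervised learning.
    """
    config = fusion_config if fusion_config is not None else default_config()
    bounds = window_bounds(recording.duration_s, window_s, overlap)
    matrices, labels = [], []
    for w0, w1 in bounds:
        win = recording.slice_seconds(w0, w1)
        measures = compute_measures(win, order=order, max_order=max_order,
                                    band=band, n_freqs=n_freqs, max_lag=max_lag)
        matrices.append(fuse(measures, config).values)
        labels.append(label_window((w0, w1), annotations))
    return WindowedFC(bounds, np.array(matrices), labels,
                      list(recording.channel_labels))


def fcd(wfc: WindowedFC) -> FCDMatrix:
    """FCD matrix: Pearson correlation between vectorized window FCs."""
    if wfc.n_windows < 2:
        raise ValueError("need at least 2 windows for an FCD matrix")
    vecs = wfc.vectorized()
    sd = vecs.std(axis=1)
    flat = sd < 1e-15
    if flat.any():
        logger.warning("constant FC in window(s) %s; FCD rows zeroed",
                       list(np.nonzero(flat)[0]))
    safe = vecs.copy()
    safe[flat] = np.arange(vecs.shape[1])   # placeholder, overwritten below
    values = np.corrcoef(safe)
    values[flat, :] = 0.0
    values[:, flat] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip(0.5 * (values + values.T), -1.0, 1.0)
    return FCDMatrix(values, list(wfc.windows), list(wfc.task_labels))


def fcd_task_contrast(fcdm: FCDMatrix) -> tuple[float, float]:
    """(mean within-task, mean between-task) off-diagonal FCD similarity.

    Mixed-label windows are ignored.  The gap between the two is the
    quantitative version of the block structure visible in FCD plots.
    """
    labs = np.array(fcdm.task_labels)
    keep = labs != MIXED_LABEL
    v = fcdm.values[np.ix_(keep, keep)]
    labs = labs[keep]
    same = labs[:, None] == labs[None, :]
    off = ~np.eye(len(labs), dtype=bool)
    within = float(v[same & off].mean())
    between = float(v[~same].mean())
    return within, between
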