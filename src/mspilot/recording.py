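"""Core in-memory containers shared by every pipeline stage.

The canonical layout is channels x samples (``data[i, t]`` is the potential
of channel ``i`` at sample ``t``, in microvolts).  Sensor positions are 3-D
unit vectors on the scalp sphere; they are required by the spherical-spline
interpolation and the neighbour-correlation bad-channel criterion, and are
carried along everywhere so no stage has to re-derive a montage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass
class Recording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Scalp potentials in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    positions : ndarray, shape (n_channels, 3) or None
        Unit-norm sensor positions.  ``None`` disables position-dependent
        operations (neighbour correlation, spherical splines).
    reference : str
        One of ``"mastoid"``, ``"average"``, ``"other"``.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    positions: np.ndarray | None = None
    reference: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise ValueError("a Recording needs at least 2 channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.data.shape[0], 3):
                raise ValueError("positions must be (n_channels, 3)")
            norms = np.linalg.norm(self.positions, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("positions must be unit-norm (tol 1e-6)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def copy(self, **changes) -> "Recording":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out

    def average_reference(self) -> "Recording":
        """Subtract the instantaneous channel mean from every sample."""
        data = self.data - self.data.mean(axis=0, keepdims=True)
        return self.copy(data=data, reference="average")


@dataclass
class LabelSequence:
    """Per-sample microstate class indices with bookkeeping metadata.

    ``labels`` holds class indices in ``[0, n_classes)``; ``UNLABELED``
    (-1) marks samples that could not be assigned (zero spatial variance).
    ``corr`` stores the absolute spatial correlation with the winning map
    where available.
    """

    UNLABELED = -1

    labels: np.ndarray
    fs: float
    n_classes: int
    corr: np.ndarray | None = None
    task_id: str | None = None
    stage: str | None = None
    task_type: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        ok = (self.labels == self.UNLABELED) | (
            (self.labels >= 0) & (self.labels < self.n_classes)
        )
        if not ok.all():
            raise ValueError("labels outside [0, n_classes) and not UNLABELED")
        if self.corr is not None:
            self.corr = np.asarray(self.corr, dtype=float)
            if self.corr.shape != self.labels.shape:
                raise ValueError("corr must match labels in shape")

    @property
    def n_samples(self) -> int:
        return self.labels.size


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation across channels between two topographies."""
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def run_lengths(labels: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a label sequence.

    Returns ``(values, lengths)`` such that concatenating ``values[i]``
    repeated ``lengths[i]`` times reproduces the input.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.array([], dtype=labels.dtype), np.array([], dtype=int)
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    return labels[starts], ends - starts
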