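"""Backfitting global maps to every EEG sample, and the three classic
microstate parameters (coverage, occurrence, duration).

Backfitting assigns each sample the class whose map has the highest
absolute spatial correlation with the instantaneous topography.  No
temporal smoothing of any kind is applied, so the label sequence's
temporal statistics are untouched by the assignment step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .recording import LabelSequence, Recording, run_lengths

logger = logging.getLogger(__name__)

__all__ = ["MicrostateParameters", "backfit", "microstate_parameters"]


@dataclass
class MicrostateParameters:
    """Per-class coverage, occurrence and duration of one label sequence.

    coverage : fraction of labelled time covered by the class
    occurrence : runs of the class per second
    duration : mean uninterrupted run length, ms
    n_runs : number of runs per class

    With boundary (first/last) runs included, the identity
    ``coverage_k = occurrence_k * duration_k / 1000 * (T_label / T)`` holds
    exactly; with all samples labelled it reduces to
    ``coverage_k = occurrence_k * duration_k / 1000``.
    """

    coverage: np.ndarray  # (K,)
    occurrence: np.ndarray  # (K,) per second
    duration: np.ndarray  # (K,) ms; 0 for classes that never occur
    n_runs: np.ndarray  # (K,)
    fs: float
    task_id: str | None = None
    stage: str | None = None
    task_type: str | None = None


def backfit(
    rec: Recording, global_maps: np.ndarray, fs: float | None = None
) -> LabelSequence:
    """Label every sample with the best-correlating global map.

    ``label(t) = argmax_k |corr(V_t, Γ_k)|`` with Pearson correlation
    across channels; polarity is ignored by construction.  Samples with
    zero spatial variance cannot be correlated with anything and get the
    ``UNLABELED`` sentinel (they are excluded from parameter computation).
    """
    maps = np.asarray(global_maps, dtype=float)
    if maps.shape[1] != rec.n_channels:
        raise ValueError("map channel count does not match the recording")
    X = rec.data.T  # (n_samples, n_channels)
    Xc = X - X.mean(axis=1, keepdims=True)
    Mc = maps - maps.mean(axis=1, keepdims=True)
    Mn = np.linalg.norm(Mc, axis=1)
    if np.any(Mn == 0):
        raise ValueError("a global map has zero spatial variance")
    xn = np.linalg.norm(Xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(Xc @ (Mc / Mn[:, None]).T) / xn[:, None]
    valid = xn > 0
    labels = np.full(X.shape[0], LabelSequence.UNLABELED, dtype=int)
    best = np.full(X.shape[0], np.nan)
    if valid.any():
        labels[valid] = np.argmax(corr[valid], axis=1)
        best[valid] = corr[valid, labels[valid]]
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("backfit: %d zero-variance samples left unlabeled", n_bad)
    return LabelSequence(
        labels=labels,
        fs=fs if fs is not None else rec.fs,
        n_classes=maps.shape[0],
        corr=best,
    )


def microstate_parameters(seq: LabelSequence) -> MicrostateParameters:
    """Coverage, occurrence and duration per class.

    Boundary (first and last) runs are counted like any other, which keeps
    the coverage/occurrence/duration identity exact.  Unlabeled samples
    are dropped before run-length encoding; time is measured over the full
    sequence for occurrence (events per second of analysis time) and over
    labelled samples for coverage.
    """
    K = seq.n_classes
    lab = seq.labels[seq.labels != LabelSequence.UNLABELED]
    if lab.size == 0:
        raise ValueError("no labelled samples")
    vals, lens = run_lengths(lab)
    total_seconds = seq.n_samples / seq.fs
    coverage = np.zeros(K)
    occurrence = np.zeros(K)
    duration = np.zeros(K)
    n_runs = np.zeros(K, dtype=int)
    for k in range(K):
        sel = vals == k
        n_runs[k] = int(sel.sum())
        coverage[k] = lens[sel].sum() / lab.size
        occurrence[k] = n_runs[k] / total_seconds
        if n_runs[k]:
            duration[k] = lens[sel].mean() / seq.fs * 1000.0
    return MicrostateParameters(
        coverage=coverage,
        occurrence=occurrence,
        duration=duration,
        n_runs=n_runs,
        fs=seq.fs,
        task_id=seq.task_id,
        stage=seq.stage,
        task_type=seq.task_type,
    )
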