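"""Temporal-dependency measures of microstate label sequences.

Two complementary quantities:

* a finite **entropy rate** estimate (bits/sample) from block entropies of
  the symbol sequence — short-range structure; 0 for a constant sequence,
  log2(K) for an i.i.d. uniform K-class source;
* the **Hurst exponent** by detrended fluctuation analysis (DFA) —
  long-range structure; 0.5 means uncorrelated, larger means persistent.

DFA needs a numeric sequence, so the categorical labels are first mapped
into {-1, +1}.  For K classes the mapping is not unique; following the
balanced-bipartition convention, every split assigning floor(K/2) classes
to +1 and the rest to -1 is used, and the per-partition Hurst estimates
are averaged.  For K=7 that is C(7,3) = 35 partitions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .recording import LabelSequence

__all__ = [
    "PartitionMapping",
    "DynamicsResult",
    "entropy_rate",
    "block_entropies",
    "enumerate_partitions",
    "dfa_hurst",
    "mean_hurst",
]


@dataclass(frozen=True)
class PartitionMapping:
    """Classes in ``subset`` map to +1, the complement to -1."""

    subset: frozenset
    n_classes: int

    def apply(self, labels: np.ndarray) -> np.ndarray:
        mask = np.isin(labels, list(self.subset))
        return np.where(mask, 1, -1).astype(int)


@dataclass
class DynamicsResult:
    entropy_rate: float  # bits/sample
    hurst_per_partition: list[float]
    hurst_mean: float
    k_range: tuple[int, int]
    dfa_window_sizes: np.ndarray | None = None
    partitions: list[PartitionMapping] = field(default_factory=list)


def block_entropies(
    labels: np.ndarray, n_classes: int, k_max: int, bias_correction: bool = True
) -> np.ndarray:
    """Shannon entropies H(k) of empirical k-gram distributions, k=1..k_max.

    Blocks are encoded as integers base ``n_classes``.  The naive plug-in
    entropy is biased downward once the number of distinct k-grams is
    comparable to the number of observations (inevitable at k ~ 6 for a
    7-class alphabet); with ``bias_correction`` Grassberger's digamma-based
    estimator is used instead, which stays accurate well into that regime.
    """
    from scipy.special import psi

    labels = np.asarray(labels, dtype=np.int64)
    out = np.empty(k_max)
    code = labels.copy()  # code[i] encodes labels[i:i+k], k = 1 here
    for k in range(1, k_max + 1):
        if k > 1:
            code = code[:-1] * n_classes + labels[k - 1 :]
        m = code.size
        _, counts = np.unique(code, return_counts=True)
        if counts.size == 1:  # deterministic blocks carry no uncertainty
            out[k - 1] = 0.0
            continue
        if bias_correction:
            g = psi(counts) + 0.5 * (-1.0) ** counts * (
                psi((counts + 1) / 2.0) - psi(counts / 2.0)
            )
            h_nats = math.log(m) - float(np.sum(counts * g)) / m
        else:
            p = counts / m
            h_nats = -float(np.sum(p * np.log(p)))
        out[k - 1] = h_nats / math.log(2)
    return out


def entropy_rate(
    seq: LabelSequence | np.ndarray,
    k_max: int = 6,
    n_classes: int | None = None,
    method: str = "slope",
    bias_correction: bool = True,
) -> float:
    """Finite entropy-rate estimate in bits/sample.

    ``method='slope'`` (default) fits a least-squares line to the block
    entropies H(k) over k = 1..k_max and reports its slope; for any Markov
    source H(k) is exactly affine in k, so the slope equals the true rate.
    ``method='diff'`` reports H(k_max+1) - H(k_max) instead, which
    conditions on a longer history but is noisier.

    Warns when the sequence is short relative to the k-gram space.
    """
    if isinstance(seq, LabelSequence):
        labels = seq.labels[seq.labels != LabelSequence.UNLABELED]
        K = seq.n_classes
    else:
        labels = np.asarray(seq, dtype=int)
        K = int(n_classes) if n_classes is not None else int(labels.max()) + 1
    if labels.size == 0:
        raise ValueError("empty sequence")
    if labels.size < 10 * K ** min(k_max, 4):
        warnings.warn(
            "sequence is short for the requested block length; the entropy "
            "rate estimate will be biased downward",
            stacklevel=2,
        )
    if method == "slope":
        H = block_entropies(labels, K, k_max, bias_correction)
        k = np.arange(1, k_max + 1, dtype=float)
        slope = np.polyfit(k, H, 1)[0]
        return float(max(slope, 0.0))
    if method == "diff":
        H = block_entropies(labels, K, k_max + 1, bias_correction)
        return float(max(H[-1] - H[-2], 0.0))
    raise ValueError("method must be 'slope' or 'diff'")


def enumerate_partitions(n_classes: int) -> list[PartitionMapping]:
    """All balanced bipartitions of the class set, in lexicographic order.

    The +1 subset has floor(n_classes/2) members.  For even K each split
    and its complement describe the same bipartition (DFA is sign
    invariant), so only the half containing class 0 is kept.  K=7 yields
    C(7,3) = 35 partitions.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    size = n_classes // 2
    parts = []
    for combo in itertools.combinations(range(n_classes), size):
        if n_classes % 2 == 0 and 0 not in combo:
            continue  # complement already enumerated
        parts.append(PartitionMapping(subset=frozenset(combo), n_classes=n_classes))
    return parts


def _dfa_windows(n: int, n_sizes: int = 18, min_size: int = 10) -> np.ndarray:
    max_size = n // 10
    if max_size <= min_size:
        raise ValueError("sequence too short for DFA window range")
    sizes = np.unique(
        np.round(np.geomspace(min_size, max_size, n_sizes)).astype(int)
    )
    return sizes


def dfa_hurst(
    x: np.ndarray,
    window_sizes: np.ndarray | None = None,
    order: int = 1,
    return_fluctuations: bool = False,
):
    """Hurst exponent by detrended fluctuation analysis.

    The profile is the cumulative sum of the mean-centred sequence.  For
    each window size ``s`` the profile is cut into non-overlapping windows,
    an order-``order`` polynomial trend is removed per window, and F(s) is
    the RMS of the residuals.  The estimate is the least-squares slope of
    log F(s) against log s over ~18 log-spaced sizes from 10 to n/10.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 500:
        raise ValueError("need at least 500 samples for a stable DFA estimate")
    if np.ptp(x) == 0:
        raise ValueError("constant sequence: DFA undefined")
    if window_sizes is None:
        window_sizes = _dfa_windows(n)
    profile = np.cumsum(x - x.mean())
    flucts = np.empty(len(window_sizes))
    for i, s in enumerate(window_sizes):
        n_win = n // s
        seg = profile[: n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        # least-squares polynomial detrend per window, vectorised
        V = np.vander(t, order + 1)
        coef, *_ = np.linalg.lstsq(V, seg.T, rcond=None)
        resid = seg.T - V @ coef
        flucts[i] = np.sqrt(np.mean(resid**2))
    log_s = np.log(window_sizes)
    log_f = np.log(flucts)
    h = float(np.polyfit(log_s, log_f, 1)[0])
    if return_fluctuations:
        return h, np.asarray(window_sizes), flucts
    return h


def mean_hurst(
    seq: LabelSequence | np.ndarray,
    n_classes: int | None = None,
    k_max: int = 6,
    window_sizes: np.ndarray | None = None,
    compute_entropy: bool = True,
) -> DynamicsResult:
    """Hurst exponent averaged over every balanced +/-1 partition mapping.

    Degenerate partitions (the mapped sequence is constant) are skipped
    with a warning and excluded from the mean.
    """
    if isinstance(seq, LabelSequence):
        labels = seq.labels[seq.labels != LabelSequence.UNLABELED]
        K = seq.n_classes
    else:
        labels = np.asarray(seq, dtype=int)
        K = int(n_classes) if n_classes is not None else int(labels.max()) + 1
    parts = enumerate_partitions(K)
    hursts: list[float] = []
    for p in parts:
        mapped = p.apply(labels)
        try:
            hursts.append(dfa_hurst(mapped, window_sizes=window_sizes))
        except ValueError:
            warnings.warn(
                f"partition {sorted(p.subset)} maps to a degenerate sequence; "
                "excluded from the Hurst mean",
                stacklevel=2,
            )
    er = entropy_rate(labels, k_max=k_max, n_classes=K) if compute_entropy else float("nan")
    return DynamicsResult(
        entropy_rate=er,
        hurst_per_partition=hursts,
        hurst_mean=float(np.mean(hursts)) if hursts else float("nan"),
        k_range=(1, k_max),
        dfa_window_sizes=window_sizes,
        partitions=parts,
    )
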