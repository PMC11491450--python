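"""Aggregation of per-subject/per-task microstate maps into global classes.

Because each k-means fit labels and signs its maps arbitrarily, member map
sets must be aligned before averaging.  The full-permutation procedure
searches, for each member, all K! label permutations (with the optimal
per-class sign) for the one maximising the mean absolute spatial
correlation with the current mean maps, then recomputes the mean; this
alternation is repeated until the assignments stop changing.  The aligned
global maps are finally matched one-to-one against canonical template
topographies to receive the conventional A..G labels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .recording import spatial_correlation

logger = logging.getLogger(__name__)

__all__ = ["MapSet", "Alignment", "align_full_permutation", "label_canonical"]

_MAX_K_FACTORIAL = 8  # 8! = 40320 permutations per member per sweep


@dataclass
class Alignment:
    """Per-member permutation and signs mapping member maps onto the mean."""

    permutations: list[tuple[int, ...]]
    signs: list[np.ndarray]
    objective: float  # mean |spatial corr| of aligned members with the mean
    n_iter: int
    converged: bool


@dataclass
class MapSet:
    """A collection of K-map sets sharing channel order."""

    members: list[np.ndarray]  # each (K, n_channels)

    def __post_init__(self) -> None:
        self.members = [np.asarray(m, dtype=float) for m in self.members]
        if len(self.members) < 1:
            raise ValueError("need at least one member")
        shape = self.members[0].shape
        if any(m.shape != shape for m in self.members):
            raise ValueError("all members must share K and channel count")

    @property
    def n_classes(self) -> int:
        return self.members[0].shape[0]


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed spatial correlation of every row of ``a`` with every row of ``b``."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1, keepdims=True)
    bn = np.linalg.norm(bc, axis=1, keepdims=True)
    an[an == 0] = 1.0
    bn[bn == 0] = 1.0
    return (ac / an) @ (bc / bn).T


def _best_permutation(member: np.ndarray, mean_maps: np.ndarray):
    """Exhaustive K!-search for the permutation maximising mean |corr|."""
    K = member.shape[0]
    C = _corr_matrix(mean_maps, member)  # C[k, j]: mean class k vs member map j
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = sum(abs(C[k, perm[k]]) for k in range(K))
        if score > best_score:
            best_score, best_perm = score, perm
    signs = np.sign(C[np.arange(K), best_perm])
    signs[signs == 0] = 1.0
    return best_perm, signs, best_score / K


def align_full_permutation(
    members: MapSet | list[np.ndarray], max_iter: int = 50
) -> tuple[np.ndarray, Alignment]:
    """Align member map sets and return their sign-corrected mean.

    The mean maps are initialised from the first member; each sweep
    re-aligns every member to the current mean (full K! search plus
    per-class sign) and recomputes the mean as the sign-aligned average,
    re-centred and re-normalised.  The objective (mean |corr| of members
    with the mean) is non-decreasing across sweeps; the loop stops when no
    assignment changes.
    """
    if not isinstance(members, MapSet):
        members = MapSet(members=list(members))
    if len(members.members) < 2:
        raise ValueError("alignment needs at least 2 members")
    K = members.n_classes
    if K > _MAX_K_FACTORIAL:
        raise ValueError(f"full-permutation search is limited to K <= {_MAX_K_FACTORIAL}")

    mean_maps = members.members[0].copy()
    mean_maps = _normalise(mean_maps)
    perms = [tuple(range(K)) for _ in members.members]
    signs = [np.ones(K) for _ in members.members]
    objective = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        new_perms, new_signs, scores = [], [], []
        for m in members.members:
            p, s, score = _best_permutation(m, mean_maps)
            new_perms.append(p)
            new_signs.append(s)
            scores.append(score)
        new_objective = float(np.mean(scores))
        if new_objective < objective - 1e-12:
            logger.warning("alignment objective decreased; keeping previous state")
            break
        objective = new_objective
        aligned = np.mean(
            [
                s[:, None] * m[list(p)]
                for m, p, s in zip(members.members, new_perms, new_signs)
            ],
            axis=0,
        )
        mean_maps = _normalise(aligned)
        if new_perms == perms and all(
            np.array_equal(a, b) for a, b in zip(new_signs, signs)
        ):
            perms, signs = new_perms, new_signs
            converged = True
            break
        perms, signs = new_perms, new_signs
    if not converged:
        logger.warning("alignment did not stabilise within %d sweeps", max_iter)
    return mean_maps, Alignment(
        permutations=perms,
        signs=signs,
        objective=objective,
        n_iter=it,
        converged=converged,
    )


def _normalise(maps: np.ndarray) -> np.ndarray:
    out = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return out / norms


def label_canonical(
    global_maps: np.ndarray, templates: np.ndarray, labels: tuple[str, ...] | None = None
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Order global maps A..G by optimal matching against template maps.

    Solves the one-to-one assignment maximising total absolute spatial
    correlation over the K x K score matrix (Hungarian algorithm).  Ties
    between identical candidates resolve to the lowest template index via
    the assignment solver's deterministic behaviour; exact ties are logged.

    Returns ``(ordered_maps, labels, scores)`` where ``ordered_maps[i]``
    is the global map assigned to template ``i`` (sign-aligned to it).
    """
    G = np.asarray(global_maps, dtype=float)
    T = np.asarray(templates, dtype=float)
    if G.shape != T.shape:
        raise ValueError("global maps and templates must share K and channels")
    K = G.shape[0]
    if labels is None:
        labels = tuple("ABCDEFG"[:K]) if K <= 7 else tuple(f"M{i}" for i in range(K))
    C = np.abs(_corr_matrix(T, G))  # C[i, j]: template i vs global map j
    row, col = linear_sum_assignment(-C)
    # detect exact ties for the audit trail
    for i in row:
        ties = np.isclose(C[i], C[i, col[i]], atol=1e-12).sum()
        if ties > 1:
            logger.warning(
                "template %s matches %d candidate maps equally well; "
                "lowest index kept",
                labels[i],
                ties,
            )
    signed = _corr_matrix(T, G)
    ordered = np.empty_like(G)
    scores = np.empty(K)
    for i, j in zip(row, col):
        sign = np.sign(signed[i, j]) or 1.0
        ordered[i] = sign * G[j]
        scores[i] = C[i, j]
    return ordered, list(labels), scores
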