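"""Repeated-measures statistics for fully within-subject factorial designs.

The designs of interest are 2 (TASK) x 3 (STAGE) x 5 (AREA) for theta
power, 2 x 3 x 7 (CLASS) for each microstate parameter, and 2 x 3 for the
temporal-dependency measures — all factors within-subject.

The ANOVA is computed through orthonormal within-subject contrasts: for
each effect, the Kronecker product of per-factor Helmert contrasts (for
factors in the effect) and unit-norm averaging vectors (for the rest)
projects every subject's cell means onto the effect subspace.  From the
projected scores Y (subjects x df): SS_effect = n * sum(mean(Y)^2),
SS_error = sum((Y - mean(Y))^2), F = (SS_effect/df1)/(SS_error/df2) with
df2 = df1*(n-1), and the Greenhouse-Geisser epsilon is
tr(S)^2 / (df1 * tr(S^2)) for S the sample covariance of Y.  Partial eta
squared is SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

logger = logging.getLogger(__name__)

__all__ = [
    "FactorialCube",
    "rm_anova",
    "posthoc_paired_bonferroni",
    "significance_annotation",
]


@dataclass
class FactorialCube:
    """Complete within-subject crossing: one value per subject per cell."""

    values: np.ndarray  # (n_subjects, n_cells)
    subjects: list
    factors: dict[str, list]  # factor name -> ordered levels
    cell_index: pd.MultiIndex

    @classmethod
    def from_long(
        cls,
        data: pd.DataFrame,
        dv: str,
        within: list[str],
        subject: str = "participant",
    ) -> "FactorialCube":
        """Build a cube from a tidy long table; raises on missing cells."""
        levels = {f: list(pd.unique(data[f])) for f in within}
        pivot = data.pivot_table(
            index=subject, columns=within, values=dv, aggfunc="mean", observed=True
        )
        full = pd.MultiIndex.from_product(
            [levels[f] for f in within], names=within
        )
        if len(within) == 1:
            full = full.get_level_values(0)
        pivot = pivot.reindex(columns=full)
        if pivot.isna().any().any():
            raise ValueError("incomplete design: some (subject, cell) values missing")
        if len(pivot) < 2:
            raise ValueError("need at least 2 subjects")
        cols = pivot.columns if isinstance(pivot.columns, pd.MultiIndex) else (
            pd.MultiIndex.from_arrays([pivot.columns], names=within)
        )
        return cls(
            values=pivot.to_numpy(dtype=float),
            subjects=list(pivot.index),
            factors=levels,
            cell_index=cols,
        )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def _effect_contrast(cube: FactorialCube, effect: tuple[str, ...]) -> np.ndarray:
    """Orthonormal contrast rows spanning the effect subspace."""
    mats = []
    for f in cube.factors:
        l = len(cube.factors[f])
        if f in effect:
            mats.append(helmert(l))  # (l-1, l), orthonormal rows _|_ 1
        else:
            mats.append(np.full((1, l), 1.0 / np.sqrt(l)))
    C = mats[0]
    for m in mats[1:]:
        C = np.kron(C, m)
    return C


def rm_anova(cube: FactorialCube | pd.DataFrame, **from_long_kwargs) -> pd.DataFrame:
    """Within-subject ANOVA table for every main effect and interaction.

    Returns one row per effect with sums of squares, F, uncorrected p,
    Greenhouse-Geisser epsilon, GG-corrected p (identical to uncorrected
    when the effect has a single degree of freedom, where sphericity holds
    trivially) and partial eta squared.
    """
    if isinstance(cube, pd.DataFrame):
        cube = FactorialCube.from_long(cube, **from_long_kwargs)
    n = cube.n_subjects
    names = list(cube.factors)
    rows = []
    for size in range(1, len(names) + 1):
        for effect in itertools.combinations(names, size):
            C = _effect_contrast(cube, effect)
            Y = cube.values @ C.T  # (n, df1)
            d = Y.shape[1]
            mean = Y.mean(axis=0)
            ss_eff = n * float(np.sum(mean**2))
            resid = Y - mean
            ss_err = float(np.sum(resid**2))
            df1, df2 = d, d * (n - 1)
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            F = ms_eff / ms_err if ms_err > 0 else np.inf
            p_unc = float(sps.f.sf(F, df1, df2))
            if d > 1:
                S = np.cov(Y, rowvar=False)
                tr = float(np.trace(S))
                tr2 = float(np.trace(S @ S))
                eps = tr**2 / (d * tr2) if tr2 > 0 else 1.0
                eps = float(np.clip(eps, 1.0 / d, 1.0))
            else:
                eps = 1.0
            p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps))
            rows.append(
                {
                    "effect": " * ".join(effect),
                    "ss_effect": ss_eff,
                    "ss_error": ss_err,
                    "df1": df1,
                    "df2": df2,
                    "F": F,
                    "p_unc": p_unc,
                    "gg_eps": eps,
                    "p_gg": p_gg,
                    "partial_eta_sq": ss_eff / (ss_eff + ss_err)
                    if ss_eff + ss_err > 0
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)


def total_ss_decomposition(cube: FactorialCube) -> dict[str, float]:
    """Sanity decomposition: total SS = subject SS + sum of effect/error SS."""
    Y = cube.values
    grand = Y.mean()
    total = float(np.sum((Y - grand) ** 2))
    n_cells = Y.shape[1]
    subj = n_cells * float(np.sum((Y.mean(axis=1) - grand) ** 2))
    return {"total": total, "subject": subj}


def posthoc_paired_bonferroni(
    data: pd.DataFrame,
    dv: str,
    family: str,
    per_level_of: str | None = None,
    subject: str = "participant",
) -> pd.DataFrame:
    """Two-sided paired t-tests with Bonferroni correction.

    Compares every pair of levels of ``family``, separately at each level
    of ``per_level_of`` (if given), averaging over any remaining factors
    per subject.  The Bonferroni family is the full set of comparisons
    made in this call; corrected p is raw p times the family size, capped
    at 1.
    """
    levels = list(pd.unique(data[family]))
    strata = list(pd.unique(data[per_level_of])) if per_level_of else [None]
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs) * len(strata)
    rows = []
    for stratum in strata:
        sub = data if stratum is None else data[data[per_level_of] == stratum]
        for a, b in pairs:
            xa = sub[sub[family] == a].groupby(subject)[dv].mean()
            xb = sub[sub[family] == b].groupby(subject)[dv].mean()
            common = xa.index.intersection(xb.index)
            if len(common) < 3:
                raise ValueError("fewer than 3 paired subjects")
            d = xa.loc[common].to_numpy() - xb.loc[common].to_numpy()
            if np.allclose(d, 0):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(xa.loc[common], xb.loc[common])
            p_corr = min(float(p) * m, 1.0)
            rows.append(
                {
                    per_level_of or "stratum": stratum,
                    "level_a": a,
                    "level_b": b,
                    "n": len(common),
                    "t": float(t),
                    "p_raw": float(p),
                    "p_bonf": p_corr,
                    "family_size": m,
                    "marker": significance_annotation(p_corr),
                }
            )
    out = pd.DataFrame(rows)
    if per_level_of is None:
        out = out.drop(columns=["stratum"])
    return out


def significance_annotation(p: float) -> str:
    """Conventional star markers: * p<=0.050, ** p<=0.010, *** p<=0.005."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if p <= 0.005:
        return "***"
    if p <= 0.010:
        return "**"
    if p <= 0.050:
        return "*"
    return ""
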