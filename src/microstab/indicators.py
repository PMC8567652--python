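"""Group-equalized indicator-family analysis (IndVal).

For each bacterial family and each combination of site groups (here the
four mammalian (sub-)orders), two components are computed:

* **A (specificity)** — the fraction of the family's group-equalized mean
  abundance that falls inside the combination.  Group equalization uses
  per-group means rather than pooled sums, so unequal sample counts per
  group do not bias A.
* **B (fidelity)** — the fraction of the combination's samples in which
  the family occurs at all.

The indicator statistic is ``sqrt(A * B)``.  Each family is assigned the
combination maximizing its statistic, and significance comes from
permuting the sample-to-group assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations

import numpy as np
import pandas as pd

from .tabletools import RelativeAbundanceTable, SampleMetadata

__all__ = [
    "group_combinations",
    "indval_g",
    "best_indicator",
    "IndicatorResult",
]


@dataclass
class IndicatorResult:
    family: str
    combination: tuple[str, ...]
    A: float
    B: float
    stat: float
    p: float
    permutations: int
    seed: int

    @property
    def combination_label(self) -> str:
        return " + ".join(self.combination)


def group_combinations(groups: list[str], max_order: int | None = None):
    """All non-empty group subsets of size <= ``max_order``.

    ``max_order`` defaults to one less than the number of groups (the full
    set is a trivial indicator target).  Output order is by size, then by
    group order as given — stable across runs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if max_order is None:
        max_order = len(groups) - 1
    if max_order >= len(groups):
        raise ValueError("max_order must be smaller than the number of groups")
    if max_order < 1:
        raise ValueError("max_order must be at least 1")
    out = []
    for size in range(1, max_order + 1):
        out.extend(_combinations(groups, size))
    return out


def _group_matrix(values: np.ndarray, labels: np.ndarray, groups) -> np.ndarray:
    """groups x families matrix of per-group mean abundances."""
    return np.vstack([values[labels == g].mean(axis=0) for g in groups])


def _indval_components(group_means, presence, labels, groups, combo_masks):
    """A, B and stat for every (combination, family) pair, vectorized.

    ``combo_masks`` is a boolean (n_combos x n_groups) matrix.  Families
    absent everywhere get NaN components.
    """
    total = group_means.sum(axis=0)  # per family
    with np.errstate(invalid="ignore", divide="ignore"):
        a = combo_masks @ group_means / total  # combos x families
    in_combo = combo_masks[:, np.searchsorted(groups, labels)]  # combos x samples
    b = in_combo.astype(float) @ presence / in_combo.sum(axis=1, keepdims=True)
    stat = np.sqrt(np.clip(a, 0, None) * b)
    return a, b, stat


def indval_g(
    rel_table: RelativeAbundanceTable,
    meta: SampleMetadata,
    combination,
    equalized: bool = True,
) -> pd.DataFrame:
    """A, B and sqrt(A*B) of one group combination for every family.

    With ``equalized=False`` the specificity uses pooled per-group sums
    instead of group means (the classic, sample-size-sensitive variant).
    Families absent from every sample have undefined A and are excluded.
    """
    fractions = rel_table.fractions
    samples = [s for s in fractions.index if s in meta.records.index]
    labels = meta.column("group").loc[samples].to_numpy()
    groups = np.array(sorted(pd.unique(labels)))
    combo = tuple(combination)
    unknown = [g for g in combo if g not in groups]
    if unknown:
        raise ValueError(f"unknown groups in combination: {unknown}")
    values = fractions.loc[samples].to_numpy(dtype=float)
    if not equalized:
        # pooled sums: replace means with sums in the A numerator/denominator
        group_stat = np.vstack([values[labels == g].sum(axis=0) for g in groups])
    else:
        group_stat = _group_matrix(values, labels, groups)
    mask = np.isin(groups, combo)[None, :]
    presence = (values > 0).astype(float)
    a, b, stat = _indval_components(group_stat, presence, labels, groups, mask)
    frame = pd.DataFrame(
        {"A": a[0], "B": b[0], "stat": stat[0]}, index=fractions.columns
    )
    return frame[~frame["A"].isna()]


def best_indicator(
    rel_table: RelativeAbundanceTable,
    meta: SampleMetadata,
    max_order: int | None = None,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    equalized: bool = True,
) -> list[IndicatorResult]:
    """Best-combination indicator per family with permutation significance.

    For each family, every combination of size <= ``max_order`` is scored
    and the arg-max statistic kept (ties break toward the smallest, then
    earliest combination).  The p-value permutes the sample-to-group
    assignment, recomputing the best-combination statistic each round, and
    uses the ``(b + 1)/(m + 1)`` estimator.  Results are returned for all
    families; callers select the significant set with ``p <= alpha``.
    """
    fractions = rel_table.fractions
    samples = [s for s in fractions.index if s in meta.records.index]
    labels = meta.column("group").loc[samples].to_numpy()
    groups = np.array(sorted(pd.unique(labels)))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    combos = group_combinations(list(groups), max_order)
    combo_masks = np.vstack([np.isin(groups, c) for c in combos])
    values = fractions.loc[samples].to_numpy(dtype=float)
    presence = (values > 0).astype(float)

    def best_stats(lab):
        if equalized:
            gm = _group_matrix(values, lab, groups)
        else:
            gm = np.vstack([values[lab == g].sum(axis=0) for g in groups])
        a, b, stat = _indval_components(gm, presence, lab, groups, combo_masks)
        with np.errstate(invalid="ignore"):
            best = np.nanargmax(np.where(np.isnan(stat), -np.inf, stat), axis=0)
        return a, b, stat, best

    present_anywhere = values.sum(axis=0) > 0
    a_obs, b_obs, stat_obs, best_obs = best_stats(labels)
    best_val = stat_obs[best_obs, np.arange(stat_obs.shape[1])]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(stat_obs.shape[1])
    for _ in range(permutations):
        perm = rng.permutation(labels)
        _, _, stat_p, _ = best_stats(perm)
        perm_best = np.nanmax(np.where(np.isnan(stat_p), -np.inf, stat_p), axis=0)
        exceed += perm_best >= best_val
    pvals = (exceed + 1) / (permutations + 1)

    results = []
    for j, family in enumerate(fractions.columns):
        if not present_anywhere[j]:
            continue
        k = best_obs[j]
        results.append(
            IndicatorResult(
                family=family,
                combination=combos[k],
                A=float(a_obs[k, j]),
                B=float(b_obs[k, j]),
                stat=float(stat_obs[k, j]),
                p=float(pvals[j]),
                permutations=permutations,
                seed=seed,
            )
        )
    return results


def indicator_table(results: list[IndicatorResult]) -> pd.DataFrame:
    rows = [
        {
            "family": r.family,
            "combination": r.combination_label,
            "A": r.A,
            "B": r.B,
            "stat": r.stat,
            "p": r.p,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
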