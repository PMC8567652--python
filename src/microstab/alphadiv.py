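"""Per-sample alpha diversity and non-parametric group comparison.

Three indices are computed per sample on the rarefied ASV-level table:
observed richness, the Shannon index in natural log units, and the
effective number of species (ENS), the Hill number of order one,
``exp(H)``.  Groups are compared with a tie-corrected Kruskal-Wallis test
followed by Dunn's post-hoc z-tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tabletools import FeatureTable

__all__ = [
    "richness",
    "shannon",
    "ens",
    "alpha_diversity",
    "kruskal_dunn",
    "AlphaResult",
    "GroupTestResult",
]


@dataclass
class AlphaResult:
    """Per-sample richness, Shannon (nats) and ENS, aligned on sample ID."""

    per_sample: pd.DataFrame  # columns: richness, shannon, ens

    def group_summary(self, grouping: pd.Series, spread: str = "sd") -> pd.DataFrame:
        """Median +/- spread per group for each index.

        ``spread`` is ``"sd"`` (default), ``"iqr2"`` (half the IQR) or
        ``"mad"``.
        """
        joined = self.per_sample.join(grouping.rename("group"), how="inner")
        med = joined.groupby("group").median(numeric_only=True)
        if spread == "sd":
            disp = joined.groupby("group").std(numeric_only=True, ddof=1)
        elif spread == "iqr2":
            q = joined.groupby("group").quantile([0.25, 0.75], numeric_only=True)
            disp = (q.xs(0.75, level=1) - q.xs(0.25, level=1)) / 2
        elif spread == "mad":
            disp = joined.groupby("group").agg(
                lambda s: float(np.median(np.abs(s - np.median(s))))
            )
        else:
            raise ValueError(f"unknown spread {spread!r}")
        disp.columns = [f"{c}_spread" for c in disp.columns]
        return med.join(disp)


@dataclass
class GroupTestResult:
    kw_statistic: float
    kw_p: float
    df: int
    pairwise: pd.DataFrame  # group_a, group_b, dunn_z, p_raw, p_bonferroni


def richness(counts) -> int:
    """Number of taxa with at least one read."""
    arr = np.asarray(counts)
    return int(np.count_nonzero(arr > 0))


def shannon(counts) -> float:
    """Shannon index ``-sum(p ln p)`` in nats; zero counts contribute nothing."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def ens(shannon_value: float) -> float:
    """Effective number of species: ``exp(H)`` for a Shannon index in nats."""
    return float(np.exp(shannon_value))


def alpha_diversity(table: FeatureTable) -> AlphaResult:
    counts = table.counts.to_numpy()
    rich = (counts > 0).sum(axis=1)
    h = np.array([shannon(row) for row in counts])
    df = pd.DataFrame(
        {"richness": rich, "shannon": h, "ens": np.exp(h)},
        index=table.counts.index,
    )
    return AlphaResult(df)


def _dunn_pairwise(values, labels, groups, n_pairs):
    """Dunn z-statistics on pooled mid-ranks with tie correction."""
    values = np.asarray(values, dtype=float)
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    variance_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            ra = ranks[labels == ga]
            rb = ranks[labels == gb]
            se = np.sqrt(variance_base * (1 / len(ra) + 1 / len(rb)))
            z = (ra.mean() - rb.mean()) / se
            p_raw = 2 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "dunn_z": z,
                    "p_raw": p_raw,
                    "p_bonferroni": min(1.0, p_raw * n_pairs),
                }
            )
    return pd.DataFrame(rows)


def kruskal_dunn(values, grouping, alpha: float = 0.05) -> GroupTestResult:
    """Kruskal-Wallis H across groups plus Dunn's pairwise post-hoc tests.

    ``values`` and ``grouping`` are aligned sequences (or Series sharing an
    index).  Every group needs at least two samples.
    """
    if isinstance(values, pd.Series) and isinstance(grouping, pd.Series):
        joined = pd.concat([values.rename("v"), grouping.rename("g")], axis=1).dropna()
        values, grouping = joined["v"].to_numpy(), joined["g"].to_numpy()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(grouping)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    by_group = [values[labels == g] for g in groups]
    for g, v in zip(groups, by_group):
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    h_stat, kw_p = stats.kruskal(*by_group)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise = _dunn_pairwise(values, labels, groups, n_pairs)
    return GroupTestResult(
        kw_statistic=float(h_stat),
        kw_p=float(kw_p),
        df=len(groups) - 1,
        pairwise=pairwise,
    )
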