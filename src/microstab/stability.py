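"""Coefficient-of-variation stability analysis of family abundances.

This is the sample-size sufficiency machinery: for each species and each
sufficiently abundant bacterial family, the coefficient of variation (CV,
sample standard deviation over mean) of the family's relative abundance is
computed on randomized subsets of increasing size and compared with the CV
over the species' full sample set.  The size at which the subset CVs settle
into a tolerance band around the full-data CV is the smallest sample number
that yields a stable estimate of that family's abundance.

Linear regressions of CV against species sample count, or against mean
percentage occurrence, quantify whether more samples (or higher abundance)
systematically lower the relative variability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tabletools import RelativeAbundanceTable, SampleMetadata

__all__ = [
    "cv",
    "family_stats",
    "abundance_filter",
    "subsample_stability",
    "cv_regression",
    "stabilization_size",
    "FamilyStats",
    "StabilityCurve",
    "CvRegression",
]

logger = logging.getLogger(__name__)

DEFAULT_SIZES = (3, 6, 10, 15, 20, 25)
#: families must exceed this mean relative abundance within a diet class
#: to enter the stability analysis; low-abundance families fluctuate more
#: per se and would dominate the curves otherwise
DEFAULT_ABUNDANCE_THRESHOLD = 0.07


@dataclass
class FamilyStats:
    species: str
    family: str
    n_samples: int
    mean_rel_abundance: float
    sd_rel_abundance: float
    cv: float | None  # None when the mean is zero


@dataclass
class StabilityCurve:
    species: str
    family: str
    records: list[tuple[int, int, float | None]]  # (subset size, replicate, cv)
    full_cv: float | None
    full_n: int


@dataclass
class CvRegression:
    slope: float
    intercept: float
    p_slope: float
    x_kind: str
    n_points: int


def cv(values) -> float | None:
    """Sample coefficient of variation: SD (n-1 denominator) over mean.

    Returns ``None`` when the mean is zero (all-zero data has no relative
    variability scale).  Requires at least two values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least two values")
    mean = arr.mean()
    if mean == 0:
        return None
    return float(arr.std(ddof=1) / mean)


def family_stats(
    rel_table: RelativeAbundanceTable, meta: SampleMetadata
) -> list[FamilyStats]:
    """Per-(species, family) mean, SD and CV of relative abundance.

    Species with fewer than two samples are excluded (and logged); a family
    absent from a sample counts as zero abundance there.
    """
    out: list[FamilyStats] = []
    fractions = rel_table.fractions
    for species in pd.unique(meta.column("species")):
        samples = [s for s in meta.samples_of_species(species) if s in fractions.index]
        if len(samples) < 2:
            logger.info("family_stats: species %s has < 2 samples; skipped", species)
            continue
        sub = fractions.loc[samples]
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=1)
        for family in fractions.columns:
            m, s = float(means[family]), float(sds[family])
            out.append(
                FamilyStats(
                    species=species,
                    family=family,
                    n_samples=len(samples),
                    mean_rel_abundance=m,
                    sd_rel_abundance=s,
                    cv=None if m == 0 else s / m,
                )
            )
    return out


def abundance_filter(
    rel_table: RelativeAbundanceTable,
    meta: SampleMetadata,
    diet: str,
    threshold: float = DEFAULT_ABUNDANCE_THRESHOLD,
    mode: str = "abundance",
) -> list[str]:
    """Families exceeding ``threshold`` within a diet class.

    ``mode="abundance"`` (default) keeps families whose mean relative
    abundance across all samples of the diet class is strictly greater than
    the threshold.  ``mode="prevalence"`` instead keeps families present in
    more than that fraction of the diet class's species.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    samples = [s for s in meta.samples_of_diet(diet) if s in rel_table.fractions.index]
    if not samples:
        raise ValueError(f"no samples with diet {diet!r}")
    sub = rel_table.fractions.loc[samples]
    if mode == "abundance":
        means = sub.mean(axis=0)
        return [f for f in sub.columns if means[f] > threshold]
    if mode == "prevalence":
        species = meta.column("species").loc[samples]
        present = (sub > 0).groupby(species).any()
        frac_species = present.mean(axis=0)
        return [f for f in sub.columns if frac_species[f] > threshold]
    raise ValueError(f"unknown mode {mode!r}")


def subsample_stability(
    rel_table: RelativeAbundanceTable,
    meta: SampleMetadata,
    species: str,
    families: list[str] | None = None,
    sizes: tuple[int, ...] = DEFAULT_SIZES,
    replicates: int = 3,
    seed: int = 0,
) -> dict[str, StabilityCurve]:
    """Randomized-subset CV curves for one species.

    For each subset size ``n`` and replicate, ``n`` distinct samples of the
    species are drawn uniformly without replacement (replicates are drawn
    independently and may overlap each other) and the CV of each family's
    relative abundance is computed on the subset.  Sizes exceeding the
    species' sample count are skipped with a log message.
    """
    samples = [s for s in meta.samples_of_species(species) if s in rel_table.fractions.index]
    n_total = len(samples)
    sizes = tuple(sorted(sizes))
    if n_total < min(sizes):
        raise ValueError(
            f"species {species!r} has {n_total} samples, fewer than the "
            f"smallest subset size {min(sizes)}"
        )
    if families is None:
        families = list(rel_table.fractions.columns)
    sub = rel_table.fractions.loc[samples, families]
    values = sub.to_numpy()
    rng = np.random.default_rng(seed)

    curves = {
        fam: StabilityCurve(species, fam, [], cv(values[:, j]), n_total)
        for j, fam in enumerate(families)
    }
    for n in sizes:
        if n > n_total:
            logger.info("subsample_stability: size %d exceeds %d samples of %s; skipped",
                        n, n_total, species)
            continue
        for rep in range(1, replicates + 1):
            if n == n_total:
                idx = np.arange(n_total)  # the subset is the whole set
            else:
                idx = rng.choice(n_total, size=n, replace=False)
            for j, fam in enumerate(families):
                curves[fam].records.append((n, rep, cv(values[idx, j])))
    return curves


def cv_regression(points, x_kind: str) -> CvRegression:
    """Ordinary least squares of CV on ``x`` with a two-sided slope t-test.

    ``points`` is an iterable of (x, cv) pairs; pairs with undefined CV are
    excluded (their count logged).  ``x_kind`` names the predictor:
    ``"sample-count"`` or ``"mean-abundance"``.
    """
    xs, ys, dropped = [], [], 0
    for x, y in points:
        if y is None or (isinstance(y, float) and math.isnan(y)):
            dropped += 1
            continue
        xs.append(float(x))
        ys.append(float(y))
    if dropped:
        logger.info("cv_regression: %d undefined-CV points excluded", dropped)
    if len(xs) < 3:
        raise ValueError("regression needs at least 3 points with defined CV")
    if len(set(xs)) < 2:
        raise ValueError("regression needs at least 2 distinct x values")
    res = stats.linregress(xs, ys)
    return CvRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_slope=float(res.pvalue),
        x_kind=x_kind,
        n_points=len(xs),
    )


def stabilization_size(
    curve: StabilityCurve, tol: float = 0.25, floor: float = 1e-6
) -> int | None:
    """Smallest grid size from which every replicate CV stays near the full CV.

    A subset CV is "near" when ``|cv - full_cv| <= tol * max(full_cv, floor)``.
    Returns ``None`` when no grid size satisfies the band through the end of
    the grid.
    """
    if curve.full_cv is None:
        raise ValueError("full-data CV undefined; cannot assess stabilization")
    if not curve.records:
        raise ValueError("empty stability curve")
    band = tol * max(curve.full_cv, floor)
    sizes = sorted({n for n, _, _ in curve.records})
    ok_sizes = set()
    for n in sizes:
        values = [c for nn, _, c in curve.records if nn == n]
        if all(c is not None and abs(c - curve.full_cv) <= band for c in values):
            ok_sizes.add(n)
    for i, n in enumerate(sizes):
        if all(m in ok_sizes for m in sizes[i:]):
            return n
    return None


def stability_table(curves: dict[str, StabilityCurve]) -> pd.DataFrame:
    """Tidy (species, family, n, replicate, cv) frame from a set of curves."""
    rows = []
    for fam, curve in curves.items():
        for n, rep, value in curve.records:
            rows.append(
                {
                    "species": curve.species,
                    "family": fam,
                    "n": n,
                    "replicate": rep,
                    "cv": np.nan if value is None else value,
                }
            )
        rows.append(
            {
                "species": curve.species,
                "family": fam,
                "n": curve.full_n,
                "replicate": 0,  # replicate 0 marks the full data set
                "cv": np.nan if curve.full_cv is None else curve.full_cv,
            }
        )
    return pd.DataFrame(rows)
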