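"""Core data containers and feature-table transformations.

A feature table holds non-negative integer read counts of amplicon sequence
variants (ASVs, columns) per fecal sample (rows).  Every downstream stage —
filtering, rarefaction, family aggregation, diversity, stability and
indicator analysis — consumes or produces one of the types defined here.

File formats are deliberately plain: tab-separated UTF-8 tables (samples in
rows, a ``#SampleID``-style header is tolerated), QIIME-style taxonomy
strings (``d__...; p__...; c__...; o__...; f__...; g__...``) and Newick
trees with branch lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")

#: labels that mark organelle-derived sequences anywhere in a lineage
ORGANELLE_NAMES = ("chloroplast", "mitochondria")


class TableError(ValueError):
    """Raised when a feature table or its inputs violate a contract."""


class FeatureTable:
    """Samples x taxa matrix of non-negative integer counts.

    Wraps a :class:`pandas.DataFrame` (index = sample IDs, columns = taxon
    IDs) and validates integrality, non-negativity and label uniqueness on
    construction.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise TableError("duplicate sample IDs in feature table")
        if counts.columns.has_duplicates:
            raise TableError("duplicate taxon IDs in feature table")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise TableError("feature table entries must be integers")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise TableError(
                f"negative count at sample {counts.index[i]!r}, "
                f"taxon {counts.columns[j]!r}"
            )
        self._counts = counts.astype(np.int64)

    @property
    def counts(self) -> pd.DataFrame:
        return self._counts

    @property
    def sample_ids(self) -> list[str]:
        return list(self._counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._counts.shape

    def sample_totals(self) -> pd.Series:
        return self._counts.sum(axis=1)

    def taxon_totals(self) -> pd.Series:
        return self._counts.sum(axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self._counts.equals(other._counts)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"FeatureTable({n} samples x {m} taxa)"


class RelativeAbundanceTable:
    """Row-normalized companion of :class:`FeatureTable`.

    Each row sums to one unless the source row was all-zero; such samples
    are left at zero and listed in :attr:`zero_samples`.
    """

    def __init__(self, fractions: pd.DataFrame, zero_samples: Iterable[str] = ()):
        self.fractions = fractions.astype(float)
        self.zero_samples = list(zero_samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.fractions.columns)


@dataclass(frozen=True)
class Lineage:
    """Ranked lineage from domain to genus; unknown ranks are empty strings."""

    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""

    def ranks(self) -> tuple[str, ...]:
        return (self.domain, self.phylum, self.class_, self.order, self.family, self.genus)

    def to_string(self) -> str:
        return "; ".join(p + r for p, r in zip(_RANK_PREFIXES, self.ranks()))

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        parts = [p.strip() for p in text.split(";")]
        values = ["", "", "", "", "", ""]
        for i, part in enumerate(parts[:6]):
            for prefix in _RANK_PREFIXES:
                if part.startswith(prefix):
                    part = part[len(prefix):]
                    break
            values[i] = part
        return cls(*values)


class TaxonomyMap:
    """taxon ID -> :class:`Lineage`.

    Missing taxa are tolerated by downstream filters (the taxon is kept and
    a warning is logged) so that a partial classification never silently
    deletes data.
    """

    def __init__(self, assignments: Mapping[str, Lineage]):
        self.assignments = dict(assignments)

    def get(self, taxon_id: str) -> Lineage | None:
        return self.assignments.get(taxon_id)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


class SampleMetadata:
    """sample ID -> species, (sub-)order group, diet class and zoo.

    Enforces that group is constant within a species and diet constant
    within a group, which the grouping logic of every test relies on.
    """

    COLUMNS = ("species", "group", "diet", "zoo")

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in records.columns]
        if missing:
            raise TableError(f"metadata missing columns: {missing}")
        if records.index.has_duplicates:
            raise TableError("duplicate sample IDs in metadata")
        df = records[list(self.COLUMNS)].astype(str)
        for parent, child in (("species", "group"), ("group", "diet")):
            n = df.groupby(parent)[child].nunique()
            bad = n[n > 1]
            if len(bad):
                raise TableError(
                    f"{child} is not constant within {parent} {bad.index[0]!r}"
                )
        self.records = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records.index)

    def column(self, name: str) -> pd.Series:
        return self.records[name]

    def species_of(self, sample_id: str) -> str:
        return self.records.at[sample_id, "species"]

    def samples_of_species(self, species: str) -> list[str]:
        return list(self.records.index[self.records["species"] == species])

    def samples_of_diet(self, diet: str) -> list[str]:
        return list(self.records.index[self.records["diet"] == diet])


# a rooted, branch-length-bearing tree over ASVs; scikit-bio's TreeNode is
# the in-memory representation used everywhere
PhyloTree = skbio.TreeNode


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path) -> FeatureTable:
    """Read a samples-x-taxa TSV (header = taxon IDs, first column = sample ID)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    except pd.errors.EmptyDataError as exc:
        raise TableError(f"empty feature table file: {path}") from exc
    if df.shape[1] == 0:
        raise TableError(f"feature table has no taxon columns: {path}")
    df.index = df.index.astype(str)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        try:
            values = pd.to_numeric(df[col], downcast=None)
        except (ValueError, TypeError) as exc:
            raise TableError(f"non-numeric count in column {col!r}") from exc
        if (values != np.floor(values)).any():
            row = df.index[values != np.floor(values)][0]
            raise TableError(f"non-integer count at sample {row!r}, taxon {col!r}")
        if (values < 0).any():
            row = df.index[values < 0][0]
            raise TableError(f"negative count at sample {row!r}, taxon {col!r}")
        parsed[col] = values.astype(np.int64)
    return FeatureTable(parsed)


def write_feature_table(table: FeatureTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="#SampleID")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column TSV of taxon ID and semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    lineages = {str(t): Lineage.from_string(s) for t, s in df.iloc[:, 0].items()}
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    df = pd.DataFrame(
        {"Taxon": {t: lin.to_string() for t, lin in tax.assignments.items()}}
    )
    df.to_csv(path, sep="\t", index_label="#OTU ID")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.records.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path) -> PhyloTree:
    return skbio.TreeNode.read(str(path), format="newick")


def write_tree(tree: PhyloTree, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def filter_low_abundance(table: FeatureTable, min_total: int = 10) -> FeatureTable:
    """Drop taxa whose total count over the whole data set is below ``min_total``.

    The default of 10 removes ASVs occurring fewer than 10 times in total;
    a taxon with exactly ``min_total`` reads is retained.
    """
    if min_total < 0:
        raise TableError("min_total must be >= 0")
    totals = table.taxon_totals()
    keep = totals.index[totals >= min_total]
    return FeatureTable(table.counts[keep])


def filter_organelles(table: FeatureTable, tax: TaxonomyMap) -> FeatureTable:
    """Drop taxa whose lineage names a chloroplast or mitochondrion at any rank."""
    keep = []
    for taxon in table.taxon_ids:
        lineage = tax.get(taxon)
        if lineage is None:
            logger.warning("taxon %s missing from taxonomy; kept", taxon)
            keep.append(taxon)
            continue
        ranks = [r.lower() for r in lineage.ranks()]
        if any(org in r for r in ranks for org in ORGANELLE_NAMES):
            continue
        keep.append(taxon)
    return FeatureTable(table.counts[keep])


def rarefy(table: FeatureTable, depth: int = 2300, seed: int | None = 0) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (and logged),
    mirroring the even-depth rarefaction of standard amplicon workflows.
    The multivariate hypergeometric draw makes the expected rarefied count
    of taxon *t* equal ``depth * count_t / total``.
    """
    if depth < 1:
        raise TableError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    keep = totals.index[totals >= depth]
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    if not len(keep):
        raise TableError(f"all samples have fewer than {depth} reads")
    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.shape[1]), dtype=np.int64)
    counts = table.counts.loc[keep].to_numpy()
    for i in range(len(keep)):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return FeatureTable(pd.DataFrame(out, index=keep, columns=table.taxon_ids))


def aggregate_to_family(table: FeatureTable, tax: TaxonomyMap) -> FeatureTable:
    """Sum ASV columns into family-level columns.

    ASVs without a family rank are pooled per order into
    ``unclassified_<order>`` (``unclassified_unknown`` when the order is
    empty too), so unnamed clades keep their counts.  The grand total is
    conserved.
    """
    labels = {}
    for taxon in table.taxon_ids:
        lineage = tax.get(taxon)
        if lineage is None:
            logger.warning("taxon %s missing from taxonomy; pooled as unclassified_unknown",
                           taxon)
            labels[taxon] = "unclassified_unknown"
            continue
        if lineage.family:
            labels[taxon] = lineage.family
        elif lineage.order:
            labels[taxon] = f"unclassified_{lineage.order}"
        else:
            labels[taxon] = "unclassified_unknown"
    grouped = table.counts.T.groupby(pd.Series(labels), sort=False).sum().T
    return FeatureTable(grouped)


def to_relative(table: FeatureTable) -> RelativeAbundanceTable:
    """Divide each sample row by its total; all-zero samples stay zero and are flagged."""
    totals = table.sample_totals().to_numpy().astype(float)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    fractions = table.counts.to_numpy() / safe[:, None]
    zero_samples = [s for s, z in zip(table.sample_ids, zero) if z]
    if zero_samples:
        logger.warning("to_relative: all-zero samples: %s", zero_samples)
    return RelativeAbundanceTable(
        pd.DataFrame(fractions, index=table.counts.index, columns=table.counts.columns),
        zero_samples,
    )
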