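"""Count-table data model, I/O and table-preparation rules.

The central object is :class:`FeatureTable`, an integer count matrix of
samples x features (ASVs, species or collapsed taxa).  On disk the table
uses the QIIME2/biom TSV dialect: features as rows, samples as columns,
header row starting with ``#OTU ID``; in memory it is transposed to
samples x features, the orientation every downstream analysis expects.

Table preparation follows the standard amplicon workflow: drop features
whose total count over the merged table is 1 (singletons), then level
("rarefy") every sample to a common depth set to 95% of the smallest
per-sample total, by uniform subsampling without replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ConfigurationError, EmptyTableError, ParseError, substream

logger = logging.getLogger(__name__)

#: canonical rank order for 7-rank lineages
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: closed set of oral sampling sites handled by this package
HABITATS = ("saliva", "buccal_mucosa")

#: rank prefixes used by common taxonomy exports; stripped on parse
_RANK_PREFIXES = ("k__", "d__", "p__", "c__", "o__", "f__", "g__", "s__")

UNASSIGNED = "Unassigned"


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ParseError(f"duplicate {what} id(s): {dup[:5]}")


@dataclass
class FeatureTable:
    """Integer count matrix, samples as rows and features as columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise EmptyTableError("feature table has no samples or no features")
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "feature")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError("counts must be numeric")
        if np.any(values < 0):
            bad = self.data.columns[np.any(values < 0, axis=0)][0]
            raise ParseError(f"negative count in feature {bad!r}")
        if not np.allclose(values, np.round(values)):
            bad = self.data.columns[np.any(values != np.round(values), axis=0)][0]
            raise ParseError(f"non-integer count in feature {bad!r}")
        self.data = self.data.astype(np.int64)

    # -- identifiers ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    # -- marginals ------------------------------------------------------
    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def feature_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def filter_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(sample_ids)].copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)


@dataclass
class Taxonomy:
    """Feature -> up-to-7-rank lineage; missing ranks are empty strings."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "feature")
        missing = [r for r in RANKS if r not in self.data.columns]
        for r in missing:
            self.data[r] = ""
        self.data = self.data[list(RANKS)].fillna("").astype(str)

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        return tuple(self.data.loc[feature_id])

    def __eq__(self, other) -> bool:
        return isinstance(other, Taxonomy) and self.data.equals(other.data)


@dataclass
class SampleMetadata:
    """Per-sample individual, habitat, sex and age annotations."""

    data: pd.DataFrame  # index: sample_id

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in ("individual_id", "habitat"):
            if col not in self.data.columns:
                raise ParseError(f"metadata missing required column {col!r}")
        bad = set(self.data["habitat"]) - set(HABITATS)
        if bad:
            raise ParseError(
                f"unknown habitat label(s) {sorted(bad)}; allowed: {list(HABITATS)}"
            )
        dup = self.data.duplicated(subset=["individual_id", "habitat"])
        if dup.any():
            sid = self.data.index[dup][0]
            raise ParseError(f"individual has >1 sample in one habitat (e.g. {sid!r})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.data["individual_id"].unique())

    def habitat_of(self) -> pd.Series:
        return self.data["habitat"]

    def individual_of(self) -> pd.Series:
        return self.data["individual_id"]

    def samples_for(self, habitat: str | None = None) -> list[str]:
        if habitat is None:
            return self.sample_ids
        if habitat not in HABITATS:
            raise ConfigurationError(f"unknown habitat {habitat!r}")
        return list(self.data.index[self.data["habitat"] == habitat])

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMetadata) and self.data.equals(other.data)


@dataclass
class RelativeAbundanceTable:
    """Row-normalized fractions with the same layout as FeatureTable."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "feature")
        sums = self.data.sum(axis=1).to_numpy()
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = self.data.index[np.abs(sums - 1.0) > 1e-9][0]
            raise ParseError(f"relative abundances of sample {bad!r} do not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path) -> FeatureTable:
    """Read a feature table in the ``#OTU ID`` TSV dialect.

    Comment lines before the ``#OTU ID`` header (e.g. ``# Constructed from
    biom file``) are skipped.  Columns are samples, rows are features; the
    returned table is transposed to samples x features.
    """
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = next(
        (i for i, ln in enumerate(lines) if ln.startswith("#OTU ID")), None
    )
    if header_idx is None:
        raise ParseError(f"{path}: no '#OTU ID' header line found")
    # pandas silently mangles duplicate column names, so check them first
    _check_unique(lines[header_idx].rstrip("\n").split("\t")[1:], "sample")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[header_idx:])), sep="\t", index_col=0)
    df.index.name = "#OTU ID"
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureTable(df.T)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.data.T
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> Taxonomy:
    """Read a 2-column TSV (feature id, semicolon lineage[, confidence])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: taxonomy needs at least 2 columns")
    ids = df.iloc[:, 0].astype(str)
    _check_unique(ids, "feature")
    rows = []
    for lineage in df.iloc[:, 1]:
        parts = [p.strip() for p in str(lineage).split(";")]
        parts = [
            p[3:] if p[:3].lower() in _RANK_PREFIXES else p for p in parts
        ]
        parts = (parts + [""] * len(RANKS))[: len(RANKS)]
        rows.append(parts)
    out = pd.DataFrame(rows, index=ids.to_numpy(), columns=list(RANKS))
    out.index.name = "feature_id"
    return Taxonomy(out)


def write_taxonomy(taxonomy: Taxonomy, path) -> None:
    lineage = taxonomy.data.apply(lambda r: "; ".join(r), axis=1)
    out = pd.DataFrame({"feature_id": taxonomy.data.index, "taxon": lineage.to_numpy()})
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: metadata missing 'sample_id' column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    out = metadata.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Table preparation
# ---------------------------------------------------------------------------

def remove_singletons(table: FeatureTable) -> FeatureTable:
    """Drop features whose total count across the whole table equals 1.

    "Singleton" is interpreted table-wide (total = 1 over all samples), the
    convention used when merged ASV tables are filtered after denoising, not
    per sample.
    """
    totals = table.feature_totals()
    keep = totals[totals != 1].index
    if len(keep) == 0:
        raise EmptyTableError("all features are singletons; nothing left")
    n_dropped = table.shape[1] - len(keep)
    if n_dropped:
        logger.info("remove_singletons: dropped %d singleton feature(s)", n_dropped)
    return FeatureTable(table.data[keep].copy())


def rarefaction_depth(table: FeatureTable, fraction: float = 0.95) -> int:
    """Leveling depth: ``floor(fraction * minimum per-sample total)``."""
    totals = table.sample_totals()
    if (totals <= 0).any():
        raise EmptyTableError("cannot set a rarefaction depth with empty samples")
    return int(np.floor(fraction * totals.min()))


def rarefy(table: FeatureTable, depth: int, seed: int = 0) -> FeatureTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below the depth are dropped with a warning.  A
    single seeded draw is taken (multivariate hypergeometric, i.e. exact
    uniform subsampling without replacement).
    """
    if depth <= 0:
        raise ConfigurationError(f"rarefaction depth must be positive, got {depth}")
    totals = table.sample_totals()
    keep = totals[totals >= depth].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped[:5])
    if len(keep) == 0:
        raise EmptyTableError(f"no sample reaches rarefaction depth {depth}")
    rng = substream(seed, "rarefy")
    rows = []
    for sid in keep:
        counts = table.data.loc[sid].to_numpy()
        rows.append(rng.multivariate_hypergeometric(counts, depth))
    out = pd.DataFrame(rows, index=list(keep), columns=table.data.columns)
    return FeatureTable(out)


def collapse(
    table: FeatureTable,
    taxonomy: Taxonomy,
    rank: str,
    on_missing: str = "pool",
) -> FeatureTable:
    """Sum counts over features sharing the lineage prefix up to ``rank``.

    Features unassigned at the rank, and (by default) features absent from
    the taxonomy, are pooled into an ``Unassigned`` bucket so per-sample
    totals are conserved exactly.  Groups are formed on the full lineage
    prefix; the output feature id is the taxon name at the rank, extended
    with the full prefix only when two distinct lineages share a name.
    """
    if rank not in RANKS:
        raise ConfigurationError(f"unknown rank {rank!r}; must be one of {list(RANKS)}")
    if on_missing not in ("pool", "error"):
        raise ConfigurationError("on_missing must be 'pool' or 'error'")
    depth_idx = RANKS.index(rank) + 1
    known = set(taxonomy.data.index)
    prefixes: dict[str, tuple[str, ...] | None] = {}
    n_missing = 0
    for fid in table.feature_ids:
        if fid not in known:
            if on_missing == "error":
                raise ConfigurationError(f"feature {fid!r} missing from taxonomy")
            n_missing += 1
            prefixes[fid] = None
            continue
        lin = taxonomy.lineage(fid)[:depth_idx]
        prefixes[fid] = lin if lin[-1] else None
    if n_missing:
        logger.warning("collapse: %d feature(s) missing from taxonomy pooled "
                       "into %r", n_missing, UNASSIGNED)

    # name groups by the rank value; disambiguate clashes with the prefix
    groups = sorted({p for p in prefixes.values() if p is not None})
    names = [p[-1] for p in groups]
    labels = {}
    for p, name in zip(groups, names):
        labels[p] = "; ".join(p) if names.count(name) > 1 else name
    mapping = {
        fid: (UNASSIGNED if p is None else labels[p]) for fid, p in prefixes.items()
    }
    out = table.data.T.groupby(pd.Series(mapping)).sum().T
    return FeatureTable(out)


def to_relative(table: FeatureTable) -> RelativeAbundanceTable:
    """Divide each sample row by its total."""
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise EmptyTableError(f"sample {bad!r} has zero total; cannot normalize")
    return RelativeAbundanceTable(table.data.div(totals, axis=0))
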