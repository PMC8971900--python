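"""Personal discrimination from rare unique species and the core-genus code.

Two complementary fingerprints:

* **Unique species** — among species ranked outside the top ``rank_threshold``
  (default 100) by overall mean relative abundance, species whose presence is
  confined to a single individual's samples; the discriminated fraction is
  the share of individuals owning at least one such species.
* **Microbial code** — the relative-abundance profile of each individual
  restricted to the core genera (present in every individual) and
  renormalized to sum to 1, matched against a reference panel by
  Bray-Curtis distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from ._util import ConfigurationError, OralsiteError
from .feature_table import FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class UniqueTaxaResult:
    """Per-individual unique species and the discriminated fraction."""

    per_individual: dict[str, list[str]]
    fraction: float
    rank_threshold: int
    ranking: pd.Series  # species -> rank (1 = most abundant overall)

    @property
    def discriminated(self) -> list[str]:
        return sorted(i for i, taxa in self.per_individual.items() if taxa)


def find_unique_taxa(
    table: FeatureTable,
    metadata: SampleMetadata,
    rank_threshold: int = 100,
) -> UniqueTaxaResult:
    """Identify low-abundance species confined to a single individual.

    Species are ranked by overall mean relative abundance (rank 1 = most
    abundant, ties broken by id); only species ranked strictly outside the
    threshold are candidates.  A candidate is unique to an individual when
    every sample with a positive count belongs to that individual.
    """
    ids = [s for s in table.sample_ids if s in set(metadata.sample_ids)]
    data = table.data.loc[ids]
    rel = data.div(data.sum(axis=1), axis=0)
    mean_rel = rel.mean(axis=0)
    order = sorted(mean_rel.index, key=lambda f: (-mean_rel[f], f))
    ranking = pd.Series(np.arange(1, len(order) + 1), index=order)
    effective_threshold = rank_threshold
    if len(order) <= rank_threshold:
        logger.warning("find_unique_taxa: only %d species present, all are "
                       "candidates (threshold %d)", len(order), rank_threshold)
        effective_threshold = 0
    individuals = metadata.subset(ids).individuals
    by_ind = metadata.individual_of().loc[ids]
    per_individual: dict[str, list[str]] = {i: [] for i in individuals}
    positive = data > 0
    for species in order:
        if ranking[species] <= effective_threshold:
            continue
        carriers = by_ind[positive[species]].unique()
        if len(carriers) == 1:
            per_individual[carriers[0]].append(species)
    fraction = sum(1 for taxa in per_individual.values() if taxa) / len(individuals)
    return UniqueTaxaResult(per_individual=per_individual, fraction=fraction,
                            rank_threshold=rank_threshold, ranking=ranking)


def core_taxa(table: FeatureTable, metadata: SampleMetadata) -> list[str]:
    """Taxa present (count > 0 in >= 1 sample) in every individual."""
    ids = [s for s in table.sample_ids if s in set(metadata.sample_ids)]
    presence = table.data.loc[ids] > 0
    per_ind = presence.groupby(metadata.individual_of().loc[ids]).any()
    core = per_ind.columns[per_ind.all(axis=0)]
    return sorted(core)


def individual_profiles(
    table: FeatureTable,
    metadata: SampleMetadata,
    habitat: str | None = None,
) -> pd.DataFrame:
    """Mean relative abundance per individual (individuals x taxa)."""
    ids = metadata.samples_for(habitat)
    ids = [s for s in ids if s in set(table.sample_ids)]
    if not ids:
        raise ConfigurationError("no samples for the requested habitat")
    data = table.data.loc[ids]
    rel = data.div(data.sum(axis=1), axis=0)
    return rel.groupby(metadata.individual_of().loc[ids]).mean().sort_index()


def microbial_code(
    table: FeatureTable,
    metadata: SampleMetadata,
    core: list[str],
    habitat: str | None = None,
) -> pd.DataFrame:
    """Individuals x core-taxa matrix, rows renormalized to sum to 1."""
    if not core:
        raise ConfigurationError("core taxon set is empty")
    profiles = individual_profiles(table, metadata, habitat)
    missing = [t for t in core if t not in profiles.columns]
    if missing:
        raise ConfigurationError(f"core taxa absent from table: {missing[:5]}")
    code = profiles[list(core)]
    totals = code.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise OralsiteError(f"individual {bad!r} has zero total over core taxa")
    return code.div(totals, axis=0)


def match_code(query: pd.Series, references: pd.DataFrame) -> pd.DataFrame:
    """Rank reference codes by Bray-Curtis distance to the query, best first."""
    if list(query.index) != list(references.columns):
        raise ConfigurationError("query and reference taxon orders differ")
    q = query.to_numpy(dtype=float)
    dist = {ref: float(braycurtis(q, references.loc[ref].to_numpy(dtype=float)))
            for ref in references.index}
    out = pd.DataFrame({"distance": pd.Series(dist)})
    out = out.sort_values(["distance"], kind="mergesort")
    out = out.loc[sorted(out.index, key=lambda r: (out.loc[r, "distance"], r))]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class DiscriminationReport:
    """Bundle of unique-species and microbial-code results for one habitat."""

    habitat: str | None
    unique: UniqueTaxaResult
    core: list[str]
    code: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "habitat": self.habitat,
            "rank_threshold": self.unique.rank_threshold,
            "discriminated_fraction": self.unique.fraction,
            "unique_species": {i: t for i, t in self.unique.per_individual.items() if t},
            "core_taxa": list(self.core),
            "n_core": len(self.core),
        }


def discrimination_report(
    species_table: FeatureTable,
    genus_table: FeatureTable,
    metadata: SampleMetadata,
    rank_threshold: int = 100,
    habitat: str | None = None,
) -> DiscriminationReport:
    """Run the full discrimination stage for one habitat (or pooled)."""
    if habitat is not None:
        ids = [s for s in metadata.samples_for(habitat)
               if s in set(species_table.sample_ids)]
        species_table = species_table.filter_samples(ids)
        genus_table = genus_table.filter_samples(ids)
    unique = find_unique_taxa(species_table, metadata, rank_threshold)
    core = core_taxa(genus_table, metadata)
    code = microbial_code(genus_table, metadata, core, habitat=habitat)
    return DiscriminationReport(habitat=habitat, unique=unique, core=core, code=code)
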