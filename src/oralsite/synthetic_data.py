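"""Synthetic paired saliva / buccal-mucosa community generator.

The generator emulates a paired oral-microbiome study design: each of
``n_individuals`` contributes one saliva and one buccal-mucosa sample.
Default genus profiles use the published mean relative abundances of the
ten genera that differ most between the two sites (Streptococcus-dominated
mucosa, a more even saliva) plus a set of core oral genera present in
every subject, and a long log-series tail of rare taxa so that hundreds of
low-abundance species exist.

Per-sample compositions mix three components:

* a **deterministic** habitat target over the core resident genera
  (habitat filtering; weight ``deterministic_weight``),
* an **individual** Dirichlet draw shared by both of a subject's samples
  (personal signature; weight ``individual_weight``),
* a **stochastic** habitat-specific Dirichlet draw (the remainder).

The stochastic component's mean is adjusted so the expected composition of
every habitat equals its configured profile exactly, whatever the weights.
Counts are multinomial at a per-sample read depth drawn uniformly from the
configured range.

Two alternative assembly modes support ground-truth experiments:
``neutral`` draws each local community from a Dirichlet with concentration
``Nm * p`` (so per-taxon relative abundances follow the Beta(Nm*p,
Nm*(1-p)) marginals of Sloan's neutral model), and ``filtered`` scales the
divergence between the two habitat profiles by ``filter_strength``
(0 = identical habitats, 1 = full configured divergence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ConfigurationError, substream
from .feature_table import (
    RANKS,
    FeatureTable,
    SampleMetadata,
    Taxonomy,
)

# ---------------------------------------------------------------------------
# Published study conditions
# ---------------------------------------------------------------------------

#: genus -> (saliva mean, buccal-mucosa mean) relative abundance for the ten
#: most abundant genera, which differ strongly between the two habitats
TABLE_GENUS_MEANS: dict[str, tuple[float, float]] = {
    "Streptococcus": (0.2008, 0.4961),
    "Veillonella": (0.1499, 0.1820),
    "Neisseria": (0.1609, 0.0299),
    "Haemophilus": (0.0987, 0.0712),
    "Prevotella_7": (0.0682, 0.0214),
    "Porphyromonas": (0.0488, 0.0114),
    "Gemella": (0.0181, 0.0316),
    "Fusobacterium": (0.0308, 0.0133),
    "Alloprevotella": (0.0243, 0.0147),
    "P5D1-392": (0.0069, 0.0251),
}

#: additional core oral genera (present in every subject); the study lists
#: 16 core genera of which 7 already appear above.  Their mean abundances
#: are not reported per habitat, so modest equal means are used.
EXTRA_CORE_GENUS_MEANS: dict[str, tuple[float, float]] = {
    "Rothia": (0.015, 0.015),
    "Prevotella": (0.012, 0.012),
    "Aggregatibacter": (0.008, 0.008),
    "Leptotrichia": (0.008, 0.008),
    "Actinomyces": (0.007, 0.007),
    "Granulicatella": (0.006, 0.006),
    "Lautropia": (0.004, 0.004),
    "Corynebacterium": (0.004, 0.004),
    "Capnocytophaga": (0.006, 0.006),
}

#: the 16 core oral genera found in all subjects
CORE_GENERA: tuple[str, ...] = (
    "Streptococcus", "Veillonella", "Neisseria", "Haemophilus",
    "Porphyromonas", "Gemella", "Fusobacterium", "Rothia", "Prevotella",
    "Aggregatibacter", "Leptotrichia", "Actinomyces", "Granulicatella",
    "Lautropia", "Corynebacterium", "Capnocytophaga",
)

_GENUS_PHYLUM = {
    "Streptococcus": "Firmicutes", "Veillonella": "Firmicutes",
    "Gemella": "Firmicutes", "Granulicatella": "Firmicutes",
    "Neisseria": "Proteobacteria", "Haemophilus": "Proteobacteria",
    "Aggregatibacter": "Proteobacteria", "Lautropia": "Proteobacteria",
    "Prevotella_7": "Bacteroidetes", "Prevotella": "Bacteroidetes",
    "Porphyromonas": "Bacteroidetes", "Alloprevotella": "Bacteroidetes",
    "Capnocytophaga": "Bacteroidetes",
    "Fusobacterium": "Fusobacteria", "Leptotrichia": "Fusobacteria",
    "Rothia": "Actinobacteria", "Actinomyces": "Actinobacteria",
    "Corynebacterium": "Actinobacteria",
    "P5D1-392": "Patescibacteria",
}

_RARE_PHYLA = ("Firmicutes", "Proteobacteria", "Bacteroidetes",
               "Fusobacteria", "Actinobacteria")

#: reported per-sample raw read range of the emulated study
DEFAULT_READ_RANGE: tuple[int, int] = (50_201, 199_533)

ASSEMBLY_MODES = ("dirichlet_multinomial", "neutral", "filtered")


@dataclass(frozen=True)
class HabitatProfile:
    """Mean genus composition of one habitat.

    ``means`` may sum to less than 1; the remainder is spread over the
    configured rare tail.  ``theta`` is the Dirichlet concentration
    controlling inter-individual dispersion (smaller = more variable
    subjects).  ``resident_taxa`` are the genera under strict habitat
    filtering: they receive the deterministic composition component and are
    therefore guaranteed residents of every sample.
    """

    habitat: str
    taxa: tuple[str, ...]
    means: tuple[float, ...]
    theta: float = 8.0
    resident_taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.means):
            raise ConfigurationError("taxa and means length mismatch")
        m = np.asarray(self.means, dtype=float)
        if np.any(m < 0):
            raise ConfigurationError("abundances must be >= 0")
        if m.sum() > 1 + 1e-9:
            raise ConfigurationError("named-taxon abundances must sum to <= 1")
        if not self.theta > 0:
            raise ConfigurationError("theta must be > 0")
        unknown = set(self.resident_taxa) - set(self.taxa)
        if unknown:
            raise ConfigurationError(f"resident taxa not in profile: {sorted(unknown)}")

    @property
    def mean_array(self) -> np.ndarray:
        return np.asarray(self.means, dtype=float)


def default_profiles(
    theta: float = 8.0,
) -> tuple[HabitatProfile, HabitatProfile]:
    """The study's default habitat profiles (published genus means + core)."""
    genera = {**TABLE_GENUS_MEANS, **EXTRA_CORE_GENUS_MEANS}
    taxa = tuple(genera)
    sal = tuple(v[0] for v in genera.values())
    muc = tuple(v[1] for v in genera.values())
    residents = tuple(g for g in taxa if g in CORE_GENERA)
    return (
        HabitatProfile("saliva", taxa, sal, theta, residents),
        HabitatProfile("buccal_mucosa", taxa, muc, theta, residents),
    )


def core_seeded_profiles(
    theta: float = 8.0, named_total: float = 0.98
) -> tuple[HabitatProfile, HabitatProfile]:
    """Profiles whose named genera are exactly the 16 core oral genera.

    Useful for experiments that need a known, fully guaranteed core: every
    named genus is a deterministic resident, and the published means are
    rescaled so the core carries ``named_total`` of the community, leaving
    only a sparse rare tail in which every taxon drops out of some subject.
    """
    genera = {**TABLE_GENUS_MEANS, **EXTRA_CORE_GENUS_MEANS}
    core = {g: genera[g] for g in CORE_GENERA}
    taxa = tuple(core)
    sal = np.array([v[0] for v in core.values()])
    muc = np.array([v[1] for v in core.values()])
    sal = sal * (named_total / sal.sum())
    muc = muc * (named_total / muc.sum())
    return (
        HabitatProfile("saliva", taxa, tuple(sal), theta, taxa),
        HabitatProfile("buccal_mucosa", taxa, tuple(muc), theta, taxa),
    )


def logseries_metacommunity(
    n_taxa: int = 300, x: float = 0.98, habitat: str = "saliva", theta: float = 8.0
) -> HabitatProfile:
    """A log-series rank-abundance metacommunity for neutral simulations."""
    j = np.arange(1, n_taxa + 1)
    w = x**j / j
    w = w / w.sum()
    taxa = tuple(f"T{k:04d}" for k in j)
    return HabitatProfile(habitat, taxa, tuple(w), theta)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fixes every random stream."""

    n_individuals: int = 50
    reads: tuple[int, int] = DEFAULT_READ_RANGE
    n_rare_taxa: int = 400
    rare_logseries_x: float = 0.995
    rare_tail_shape: str = "logseries"  # or "uniform"
    species_per_genus: int = 2
    unique_per_individual: int = 0
    unique_rel_abundance: float = 2e-4
    assembly_mode: str = "dirichlet_multinomial"
    individual_weight: float = 0.25
    deterministic_weight: float = 0.15
    within_individual_theta: float | None = 100.0
    filter_strength: float = 1.0
    local_community_size: int | None = None  # N of the neutral model
    migration_rate: float | None = None      # m of the neutral model
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigurationError("n_individuals must be positive")
        lo, hi = (self.reads, self.reads) if isinstance(self.reads, int) else self.reads
        if lo <= 0 or hi < lo:
            raise ConfigurationError("read range must be positive and ordered")
        if self.assembly_mode not in ASSEMBLY_MODES:
            raise ConfigurationError(
                f"assembly_mode must be one of {ASSEMBLY_MODES}")
        if not 0 <= self.individual_weight + self.deterministic_weight < 1:
            raise ConfigurationError("component weights must leave a stochastic share")
        if not 0 <= self.filter_strength <= 1:
            raise ConfigurationError("filter_strength must be in [0, 1]")
        if self.migration_rate is not None and not 0 < self.migration_rate <= 1:
            raise ConfigurationError("migration rate m must be in (0, 1]")
        if self.unique_per_individual < 0 or self.unique_rel_abundance <= 0:
            raise ConfigurationError("invalid unique-species settings")
        if self.within_individual_theta is not None and not self.within_individual_theta > 0:
            raise ConfigurationError("within_individual_theta must be > 0")
        if self.rare_tail_shape not in ("logseries", "uniform"):
            raise ConfigurationError("rare_tail_shape must be 'logseries' or 'uniform'")

    @property
    def read_range(self) -> tuple[int, int]:
        return (self.reads, self.reads) if isinstance(self.reads, int) else tuple(self.reads)

    @property
    def nm(self) -> float:
        if self.local_community_size is None or self.migration_rate is None:
            raise ConfigurationError("neutral mode needs local_community_size and migration_rate")
        return self.local_community_size * self.migration_rate


# ---------------------------------------------------------------------------
# internal: expand genus profiles to a species/ASV feature namespace
# ---------------------------------------------------------------------------

def _species_split(k: int) -> np.ndarray:
    w = 0.5 ** np.arange(k)
    return w / w.sum()


def _expand(saliva: HabitatProfile, mucosa: HabitatProfile, config: SimulationConfig):
    """Return feature ids, taxonomy, per-habitat feature-level means and the
    deterministic resident mask."""
    if saliva.taxa != mucosa.taxa:
        raise ConfigurationError("habitat profiles must share one taxon namespace")
    genera = saliva.taxa
    base = {"saliva": saliva.mean_array.copy(), "buccal_mucosa": mucosa.mean_array.copy()}

    # habitat-filter strength scales the divergence of the two profiles
    s = config.filter_strength
    if s != 1.0:
        pooled = 0.5 * (base["saliva"] + base["buccal_mucosa"])
        for h in base:
            base[h] = pooled + s * (base[h] - pooled)

    rem = {h: 1.0 - base[h].sum() for h in base}
    for h, r in rem.items():
        if r < -1e-9:
            raise ConfigurationError(f"profile means of {h} exceed 1")
    j = np.arange(1, config.n_rare_taxa + 1)
    if config.rare_tail_shape == "uniform":
        tail = np.ones_like(j, dtype=float)
    else:
        tail = config.rare_logseries_x**j / j
    tail = tail / tail.sum() if config.n_rare_taxa else tail.astype(float)

    fids, lineages, mean_rows, resident = [], [], {h: [] for h in base}, []
    split = _species_split(config.species_per_genus)
    residents = set(saliva.resident_taxa) | set(mucosa.resident_taxa)
    n = 0
    for gi, g in enumerate(genera):
        phylum = _GENUS_PHYLUM.get(g, _RARE_PHYLA[gi % len(_RARE_PHYLA)])
        for si, w in enumerate(split):
            fids.append(f"ASV_{n:04d}")
            lineages.append(("Bacteria", phylum, "", "", f"{g}aceae", g,
                             f"{g} sp{si + 1}"))
            for h in base:
                mean_rows[h].append(base[h][gi] * w)
            resident.append(g in residents)
            n += 1
    for ji in range(config.n_rare_taxa):
        g = f"Rare_{ji:03d}"
        fids.append(f"ASV_{n:04d}")
        lineages.append(("Bacteria", _RARE_PHYLA[ji % len(_RARE_PHYLA)], "", "",
                         "", g, f"{g} sp1"))
        for h in base:
            mean_rows[h].append(rem[h] * tail[ji])
        resident.append(False)
        n += 1

    tax = Taxonomy(pd.DataFrame(lineages, index=fids, columns=list(RANKS)))
    means = {h: np.asarray(v) for h, v in mean_rows.items()}
    return fids, tax, means, np.asarray(resident, dtype=bool)


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw that tolerates zero concentrations (fixed zeros)."""
    g = rng.gamma(np.maximum(alpha, 0.0))
    total = g.sum()
    if total == 0:
        raise ConfigurationError("degenerate Dirichlet: all concentrations zero")
    return g / total


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_paired_study(
    config: SimulationConfig,
    saliva: HabitatProfile | None = None,
    mucosa: HabitatProfile | None = None,
) -> tuple[FeatureTable, Taxonomy, SampleMetadata]:
    """Simulate one paired cohort: 2 samples (saliva + mucosa) per individual.

    Returns the count table, the matching taxonomy and per-sample metadata
    (individual, habitat, sex, age 20-50).  Expected habitat-mean
    compositions equal the configured profiles exactly.
    """
    if saliva is None or mucosa is None:
        d_sal, d_muc = default_profiles()
        saliva = saliva or d_sal
        mucosa = mucosa or d_muc
    if config.assembly_mode == "neutral":
        nm = config.nm  # validate early
    fids, tax, means, resident = _expand(saliva, mucosa, config)
    profiles = {"saliva": saliva, "buccal_mucosa": mucosa}
    pooled = 0.5 * (means["saliva"] + means["buccal_mucosa"])
    theta_pool = 0.5 * (saliva.theta + mucosa.theta)

    lam_det = config.deterministic_weight
    lam_ind = config.individual_weight
    lam_sto = 1.0 - lam_det - lam_ind

    det, sto_mean = {}, {}
    for h, m in means.items():
        c = np.where(resident, m, 0.0)
        if lam_det > 0 and c.sum() == 0:
            raise ConfigurationError(
                "deterministic_weight > 0 but no resident taxa are defined")
        c = c / c.sum() if c.sum() else c
        b = (m - lam_ind * pooled - lam_det * c)
        if lam_sto > 0:
            b = b / lam_sto
            if b.min() < -1e-6:
                raise ConfigurationError(
                    f"weights incompatible with the {h} profile: the "
                    "stochastic mean would be negative for some taxa")
            b = np.clip(b, 0.0, None)
            b = b / b.sum()
        det[h], sto_mean[h] = c, b

    rng_ind = substream(config.seed, "individual")
    rng_hab = {h: substream(config.seed, f"habitat/{h}") for h in means}
    rng_reads = substream(config.seed, "reads")
    rng_counts = substream(config.seed, "counts")
    rng_demo = substream(config.seed, "demographics")

    lo, hi = config.read_range
    rows, sample_ids, meta_rows = [], [], []
    for i in range(config.n_individuals):
        ind = f"I{i:03d}"
        pi = _dirichlet(rng_ind, theta_pool * pooled)
        sex = str(rng_demo.choice(["F", "M"]))
        age = int(rng_demo.integers(20, 51))
        for h in ("saliva", "buccal_mucosa"):
            if config.assembly_mode == "neutral":
                comp = _dirichlet(rng_hab[h], nm * means[h])
            else:
                theta_w = (config.within_individual_theta
                           if config.within_individual_theta is not None
                           else profiles[h].theta)
                delta = _dirichlet(rng_hab[h], theta_w * sto_mean[h])
                comp = lam_det * det[h] + lam_ind * pi + lam_sto * delta
            reads = int(rng_reads.integers(lo, hi + 1))
            rows.append(rng_counts.multinomial(reads, comp))
            sample_ids.append(f"{ind}_{h}")
            meta_rows.append((ind, h, sex, age))

    table = FeatureTable(pd.DataFrame(rows, index=sample_ids, columns=fids))
    meta = SampleMetadata(pd.DataFrame(
        meta_rows, index=sample_ids,
        columns=["individual_id", "habitat", "sex", "age"]))
    return table, tax, meta


def simulate_neutral_assembly(
    config: SimulationConfig, metacommunity: HabitatProfile
) -> FeatureTable:
    """Assemble purely neutral local communities from one metacommunity.

    Each of ``n_individuals`` local communities draws its composition from
    Dirichlet(Nm * p) — whose per-taxon marginals are the Beta(Nm*p,
    Nm*(1-p)) distributions of Sloan's neutral model — then multinomial
    reads.  Ground truth for neutral-model parameter-recovery experiments.
    """
    if config.assembly_mode != "neutral":
        raise ConfigurationError("simulate_neutral_assembly needs assembly_mode='neutral'")
    nm = config.nm
    p = metacommunity.mean_array
    p = p / p.sum()
    rng_comp = substream(config.seed, "neutral/composition")
    rng_reads = substream(config.seed, "reads")
    rng_counts = substream(config.seed, "counts")
    lo, hi = config.read_range
    rows = []
    for _ in range(config.n_individuals):
        comp = _dirichlet(rng_comp, nm * p)
        reads = int(rng_reads.integers(lo, hi + 1))
        rows.append(rng_counts.multinomial(reads, comp))
    ids = [f"S{k:03d}" for k in range(config.n_individuals)]
    return FeatureTable(pd.DataFrame(rows, index=ids, columns=list(metacommunity.taxa)))


@dataclass
class PlantedTruth:
    """Ground truth of the unique-species injection."""

    per_individual: dict[str, list[str]] = field(default_factory=dict)
    planted_fraction: float = 0.0
    warnings: list[str] = field(default_factory=list)

    @property
    def planted_taxa(self) -> list[str]:
        return sorted(t for taxa in self.per_individual.values() for t in taxa)


def inject_unique_species(
    table: FeatureTable,
    metadata: SampleMetadata,
    per_individual: int,
    rel_abundance: float = 2e-4,
    seed: int = 0,
    individuals: list[str] | int | None = None,
    rank_threshold: int = 100,
    taxonomy: Taxonomy | None = None,
) -> tuple[FeatureTable, Taxonomy | None, PlantedTruth]:
    """Plant low-abundance species each present in exactly one individual.

    For every selected individual, ``per_individual`` new features are added
    to all of that individual's samples at roughly ``rel_abundance`` of the
    sample total (at least 1 read), the reads being moved from the sample's
    most abundant feature so per-sample totals are preserved.  Returns the
    augmented table, an extended taxonomy (if one was given) and the planted
    truth; a planted taxon whose overall mean relative abundance ends up
    ranked at or inside ``rank_threshold`` is recorded as a warning.
    """
    if per_individual == 0:
        return table, taxonomy, PlantedTruth()
    rng = substream(seed, "inject_unique")
    all_inds = metadata.individuals
    if individuals is None:
        chosen = list(all_inds)
    elif isinstance(individuals, int):
        if not 0 < individuals <= len(all_inds):
            raise ConfigurationError("cannot select that many individuals")
        chosen = sorted(rng.choice(all_inds, size=individuals, replace=False))
    else:
        unknown = set(individuals) - set(all_inds)
        if unknown:
            raise ConfigurationError(f"unknown individual(s): {sorted(unknown)}")
        chosen = sorted(individuals)

    data = table.data.copy()
    truth = PlantedTruth(planted_fraction=len(chosen) / len(all_inds))
    new_cols, tax_rows = {}, []
    by_ind = metadata.individual_of()
    for ind in chosen:
        samples = [s for s in table.sample_ids if by_ind.get(s) == ind]
        taxa = []
        for k in range(per_individual):
            fid = f"unique_{ind}_{k}"
            col = np.zeros(len(data), dtype=np.int64)
            for s in samples:
                loc = data.index.get_loc(s)
                row = data.iloc[loc].to_numpy().copy()
                total = int(row.sum())
                n_reads = max(1, round(rel_abundance * total))
                if n_reads >= total:
                    raise ConfigurationError(
                        f"rel_abundance {rel_abundance} leaves no reads in {s}")
                # move reads from the most abundant features, greedily, so the
                # sample total is preserved
                remaining = n_reads
                for donor in np.argsort(row)[::-1]:
                    take = min(remaining, int(row[donor]) - 1)
                    row[donor] -= take
                    remaining -= take
                    if remaining == 0:
                        break
                data.iloc[loc] = row
                col[loc] = n_reads
            new_cols[fid] = col
            taxa.append(fid)
            tax_rows.append((fid, ("Bacteria", "", "", "", "",
                                   f"UniqueGenus_{ind}", f"Unique {ind} sp{k + 1}")))
        truth.per_individual[ind] = taxa

    out = pd.concat([data, pd.DataFrame(new_cols, index=data.index)], axis=1)
    new_table = FeatureTable(out)

    # post-hoc rank validation on the augmented table
    rel = out.div(out.sum(axis=1), axis=0)
    order = rel.mean(axis=0).sort_values(ascending=False, kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    for fid in truth.planted_taxa:
        if ranks[fid] <= rank_threshold:
            truth.warnings.append(
                f"planted taxon {fid} ranks {int(ranks[fid])} "
                f"(inside the top {rank_threshold})")

    new_tax = None
    if taxonomy is not None:
        extra = pd.DataFrame([r[1] for r in tax_rows],
                             index=[r[0] for r in tax_rows], columns=list(RANKS))
        new_tax = Taxonomy(pd.concat([taxonomy.data, extra]))
    return new_table, new_tax, truth


def write_study(table, taxonomy, metadata, out_dir) -> dict[str, str]:
    """Write the three standard inputs to a directory; returns the paths."""
    import os

    from .feature_table import write_feature_table, write_metadata, write_taxonomy

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "feature_table": os.path.join(out_dir, "feature_table.tsv"),
        "taxonomy": os.path.join(out_dir, "taxonomy.tsv"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
    }
    write_feature_table(table, paths["feature_table"])
    write_taxonomy(taxonomy, paths["taxonomy"])
    write_metadata(metadata, paths["metadata"])
    return paths
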