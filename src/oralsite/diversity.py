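"""Alpha/beta diversity, ordination and group-comparison statistics.

Alpha metrics: Shannon entropy in bits (base 2; configurable), bias-corrected
Chao1 richness, and Gini-Simpson diversity 1 - sum(p_i^2).  Beta diversity is
Bray-Curtis, D(x, y) = sum|x_i - y_i| / sum(x_i + y_i), visualized through
non-metric multidimensional scaling (Kruskal stress-1, monotone regression).
Group contrasts use Welch two-sample t-tests; age associations use Spearman
rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.diversity.alpha import simpson as _skbio_simpson
from sklearn.manifold import smacof
from statsmodels.stats.multitest import multipletests

from ._util import ConfigurationError, OralsiteError, substream
from .feature_table import FeatureTable, RelativeAbundanceTable, SampleMetadata


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or np.any(c < 0):
        raise ConfigurationError("counts must be a 1-D non-negative vector")
    if c.sum() == 0:
        raise ConfigurationError("all-zero count vector has no diversity")
    return c


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy -sum p_i log_base p_i (default: bits)."""
    return float(_skbio_shannon(_check_counts(counts), base=base))


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    return float(_skbio_chao1(_check_counts(counts), bias_corrected=True))


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum p_i^2."""
    return float(_skbio_simpson(_check_counts(counts)))


_ALPHA_METRICS = {"shannon": shannon, "chao1": chao1, "simpson": simpson}


def alpha_diversity(table: FeatureTable, metric: str = "shannon", **kwargs) -> pd.Series:
    """Per-sample alpha diversity for one metric."""
    if metric not in _ALPHA_METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; have {sorted(_ALPHA_METRICS)}")
    fn = _ALPHA_METRICS[metric]
    values = [fn(row, **kwargs) for row in table.data.to_numpy()]
    return pd.Series(values, index=table.sample_ids, name=metric)


def alpha_diversity_frame(table: FeatureTable) -> pd.DataFrame:
    """Shannon / Chao1 / Simpson per sample, one column each."""
    return pd.DataFrame({m: alpha_diversity(table, m) for m in _ALPHA_METRICS})


def bray_curtis(rel: RelativeAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities on relative abundances."""
    if len(rel.sample_ids) < 2:
        raise ConfigurationError("Bray-Curtis needs at least 2 samples")
    return beta_diversity("braycurtis", rel.data.to_numpy(), ids=rel.sample_ids)


@dataclass
class NMDSResult:
    """NMDS embedding; coordinates are defined up to rotation/reflection."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool


def _classical_mds_init(d: np.ndarray, dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(
    dm: DistanceMatrix,
    dims: int = 2,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 300,
    eps: float = 1e-6,
) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    One run starts from the classical (metric) scaling solution; additional
    random restarts guard against local minima.  The embedding with the
    lowest stress wins.
    """
    d = dm.data
    ids = list(dm.ids)
    if np.allclose(d, 0):
        coords = pd.DataFrame(np.zeros((len(ids), dims)), index=ids,
                              columns=[f"NMDS{k + 1}" for k in range(dims)])
        return NMDSResult(coords, 0.0, True)
    rng = substream(seed, "nmds")
    best = None
    inits = [_classical_mds_init(d, dims)] + [None] * n_restarts
    for init in inits:
        state = int(rng.integers(2**31))
        coords, stress, n_iter = smacof(
            d, metric=False, n_components=dims, init=init, n_init=1,
            max_iter=max_iter, eps=eps, random_state=state,
            normalized_stress=True, return_n_iter=True)
        if best is None or stress < best[1]:
            best = (coords, stress, n_iter)
    coords, stress, n_iter = best
    frame = pd.DataFrame(coords, index=ids,
                         columns=[f"NMDS{k + 1}" for k in range(dims)])
    return NMDSResult(frame, float(stress), bool(n_iter < max_iter))


@dataclass
class GroupTestResult:
    """Two-group comparison: per-level mean +/- SE and a Welch t-test."""

    factor: str
    levels: tuple[str, str]
    means: tuple[float, float]
    sems: tuple[float, float]
    statistic: float
    pvalue: float
    test_name: str = "welch_t"

    def as_dict(self) -> dict:
        return {
            "factor": self.factor,
            "levels": list(self.levels),
            "means": list(self.means),
            "sems": list(self.sems),
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "test": self.test_name,
        }


def compare_groups(
    values: pd.Series, metadata: SampleMetadata, factor: str = "habitat"
) -> GroupTestResult:
    """Welch two-sample t-test of per-sample values between two factor levels."""
    if factor not in metadata.data.columns:
        raise ConfigurationError(f"metadata has no column {factor!r}")
    labels = metadata.data.loc[values.index, factor]
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ConfigurationError(f"factor {factor!r} must have exactly 2 levels, "
                                 f"got {levels}")
    a = values[labels == levels[0]].to_numpy(dtype=float)
    b = values[labels == levels[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("each level needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupTestResult(
        factor=factor, levels=(levels[0], levels[1]),
        means=(float(a.mean()), float(b.mean())),
        sems=(float(a.std(ddof=1) / np.sqrt(len(a))),
              float(b.std(ddof=1) / np.sqrt(len(b)))),
        statistic=float(t), pvalue=float(p))


@dataclass
class SpearmanResult:
    r: float
    pvalue: float
    n: int


def spearman_age(
    values: pd.Series, metadata: SampleMetadata, by_habitat: bool = True
) -> dict[str, SpearmanResult]:
    """Spearman correlation of per-sample values against subject age."""
    if "age" not in metadata.data.columns:
        raise ConfigurationError("metadata has no 'age' column")
    groups = (sorted(metadata.data["habitat"].unique()) if by_habitat else ["all"])
    out = {}
    for g in groups:
        ids = metadata.samples_for(None if g == "all" else g)
        ids = [s for s in ids if s in values.index]
        v = values[ids].to_numpy(dtype=float)
        age = metadata.data.loc[ids, "age"].to_numpy(dtype=float)
        if len(v) < 3:
            raise ConfigurationError(f"group {g!r}: need >= 3 paired observations")
        if np.ptp(v) == 0 or np.ptp(age) == 0:
            raise OralsiteError(f"group {g!r}: constant input, correlation undefined")
        r, p = stats.spearmanr(v, age)
        out[g] = SpearmanResult(float(r), float(p), len(v))
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "ns"


def differential_abundance(
    rel: RelativeAbundanceTable,
    metadata: SampleMetadata,
    top_n: int | None = 10,
    factor: str = "habitat",
) -> pd.DataFrame:
    """Per-taxon two-group comparison of relative abundances.

    Rows are sorted by overall mean abundance (descending) and, by default,
    restricted to the top 10 taxa.  Reports group mean +/- SE, Welch t-test
    p with significance stars (** p<0.01, *** p<0.001) and, as an extension
    beyond the raw-p convention, a Benjamini-Hochberg adjusted column.
    """
    labels = metadata.data.loc[rel.data.index, factor]
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ConfigurationError(f"factor {factor!r} must have exactly 2 levels")
    overall = rel.data.mean(axis=0).sort_values(ascending=False, kind="mergesort")
    taxa = overall.index if top_n is None else overall.index[:top_n]
    rows = []
    for taxon in taxa:
        res = compare_groups(rel.data[taxon], metadata, factor)
        rows.append({
            "taxon": taxon,
            "overall_mean": float(overall[taxon]),
            f"mean_{levels[0]}": res.means[0], f"sem_{levels[0]}": res.sems[0],
            f"mean_{levels[1]}": res.means[1], f"sem_{levels[1]}": res.sems[1],
            "t": res.statistic, "pvalue": res.pvalue, "stars": _stars(res.pvalue),
        })
    out = pd.DataFrame(rows).set_index("taxon")
    out["pvalue_bh"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out
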