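"""Community-assembly inference: neutral-model fit and null-model statistics.

Sloan's neutral community model predicts the occurrence frequency of a taxon
from its mean metacommunity relative abundance p: local relative abundances
follow Beta(Nm * p, Nm * (1 - p)) with migration parameter Nm (local
community size x immigration probability), and with detection limit d the
classic expected detection frequency is

    F(p) = 1 - I_d(Nm * p, Nm * (1 - p))

where I is the regularized incomplete beta function (Beta CDF).  Because a
taxon is actually detected when at least one of R sequenced reads hits it,
the default fit uses the exact expectation of that event under binomial
read sampling,

    F(p) = 1 - E[(1 - x)^R] = 1 - B(Nm p, Nm (1 - p) + R) / B(Nm p, Nm (1 - p)),

which removes the upward bias of the hard-threshold curve at large Nm; the
threshold form remains available (``detection="threshold"``).  Nm is the
only free parameter, estimated by iteratively reweighted least squares of
observed occupancy on F(p) with binomial weights; goodness of fit is
R^2 = 1 - SSE/SST.  A 95% binomial (Wilson) band around the fitted curve
partitions taxa into those occurring more often ("above"), as often
("fit") or less often ("below") than the neutral expectation.

The null model quantifies the deterministic component of beta diversity
within a group of samples: observed mean pairwise Bray-Curtis is compared
against randomized communities that preserve each sample's richness and
read total and each taxon's occupancy (fixed-fixed presence via curveball
trades) while reassigning abundances in proportion to regional relative
abundance.  The standardized effect size is
ses.beta = (obs.beta - mean.null.beta) / sd.null.beta, and the
deterministic strength (DS, %) is the mean per-pair relative departure of
the observed dissimilarity from its null expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

from ._util import ConfigurationError, OralsiteError, substream
from .feature_table import FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------

@dataclass
class NCMFit:
    """Fitted neutral model: migration parameter, fit quality, per-taxon bands."""

    nm: float
    nm_ci: tuple[float, float]
    r_squared: float
    detection_limit: float
    n_samples: int
    taxa: pd.DataFrame  # p, freq_obs, freq_pred, ci_lower, ci_upper, partition

    def partition_counts(self) -> dict[str, int]:
        counts = self.taxa["partition"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("above", "fit", "below")}


def predicted_occupancy(
    p, nm: float, detection_limit: float, reads: float | None = None,
    detection: str = "threshold",
) -> np.ndarray:
    """Neutral expected detection frequency for metacommunity abundance p.

    ``detection="threshold"`` is the classic F(p) = 1 - BetaCDF(d; Nm p,
    Nm (1-p)); ``detection="exact"`` is the expectation of detecting >= 1 of
    ``reads`` binomially sampled reads, 1 - B(a, b + R)/B(a, b).
    """
    p = np.asarray(p, dtype=float)
    a = np.maximum(nm * p, 1e-12)
    b = np.maximum(nm * (1.0 - p), 1e-12)
    if detection == "threshold":
        return stats.beta.sf(detection_limit, a, b)
    if detection == "exact":
        if reads is None:
            reads = 1.0 / detection_limit
        return 1.0 - np.exp(gammaln(a + b) + gammaln(b + reads)
                            - gammaln(b) - gammaln(a + b + reads))
    raise ConfigurationError("detection must be 'threshold' or 'exact'")


_NM_LOG_BOUNDS = (np.log(1e-3), np.log(1e9))


def fit_ncm(
    table: FeatureTable,
    detection_limit: float | None = None,
    detection: str = "exact",
) -> NCMFit:
    """Fit Sloan's neutral model to a (rarefied) count table.

    ``detection_limit`` defaults to 1 / mean sample total — the smallest
    relative abundance observable after leveling; under the default
    ``detection="exact"`` it only sets the read depth of the detection
    model.  The fit is iteratively reweighted least squares with binomial
    weights; the parameter CI comes from the weighted large-sample
    covariance, and the per-taxon 95% band is a Wilson binomial interval
    around the fitted occupancy at the observed number of samples.
    """
    n_samples = table.shape[0]
    if n_samples < 10:
        raise ConfigurationError("neutral-model fit needs >= 10 samples")
    counts = table.data.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ConfigurationError("empty samples cannot be fitted")
    if detection_limit is None:
        detection_limit = 1.0 / totals.mean()
    reads = 1.0 / detection_limit
    rel = counts / totals[:, None]
    p = rel.mean(axis=0)
    freq = (counts > 0).mean(axis=0)
    keep = p > 0
    p, freq = p[keep], freq[keep]
    fids = np.asarray(table.feature_ids)[keep]
    if len(p) < 5:
        raise ConfigurationError("neutral-model fit needs >= 5 occurring taxa")

    def model(pp, log_nm):
        return predicted_occupancy(pp, np.exp(log_nm), detection_limit,
                                   reads=reads, detection=detection)

    # coarse grid for a starting value, then IRLS on log(Nm)
    grid = np.linspace(np.log(1.0), np.log(1e7), 40)
    sse = [np.sum((freq - model(p, g)) ** 2) for g in grid]
    x0 = np.array([grid[int(np.argmin(sse))]])
    try:
        popt, pcov = optimize.curve_fit(
            model, p, freq, p0=x0, bounds=_NM_LOG_BOUNDS, maxfev=10_000)
        for _ in range(2):
            pred = model(p, popt[0])
            sigma = np.sqrt(np.clip(pred * (1 - pred), 1e-6, None) / n_samples)
            popt, pcov = optimize.curve_fit(
                model, p, freq, p0=popt, sigma=sigma, absolute_sigma=True,
                bounds=_NM_LOG_BOUNDS, maxfev=10_000)
    except RuntimeError as err:  # pragma: no cover - optimizer pathology
        raise OralsiteError(f"neutral-model optimizer failed near "
                            f"Nm={np.exp(x0[0]):.3g}: {err}") from err
    log_nm = float(popt[0])
    nm = float(np.exp(log_nm))
    sd_log = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    nm_ci = (float(np.exp(max(log_nm - 1.96 * sd_log, -700.0))),
             float(np.exp(min(log_nm + 1.96 * sd_log, 700.0))))

    pred = model(p, log_nm)
    sst = float(np.sum((freq - freq.mean()) ** 2))
    sse_fit = float(np.sum((freq - pred) ** 2))
    r2 = 1.0 - sse_fit / sst if sst > 0 else float("nan")

    lower, upper = proportion_confint(
        np.round(pred * n_samples), n_samples, alpha=0.05, method="wilson")
    # the metacommunity abundance p is itself estimated from the same
    # samples; where the occupancy curve is steep that uncertainty dwarfs
    # the binomial noise, so propagate it through the curve (delta method)
    sd_p = rel.std(axis=0, ddof=1)[keep] / np.sqrt(n_samples)
    h = np.maximum(1e-3 * p, 1e-12)
    slope = (model(np.clip(p + h, 0, 1), log_nm)
             - model(np.clip(p - h, 0, 1), log_nm)) / (2 * h)
    widen = 1.96 * np.abs(slope) * sd_p
    lower = np.clip(lower - widen, 0.0, 1.0)
    upper = np.clip(upper + widen, 0.0, 1.0)
    partition = np.where(freq > upper, "above",
                         np.where(freq < lower, "below", "fit"))
    taxa = pd.DataFrame({
        "p": p, "freq_obs": freq, "freq_pred": pred,
        "ci_lower": lower, "ci_upper": upper, "partition": partition,
    }, index=fids)
    return NCMFit(nm=nm, nm_ci=nm_ci, r_squared=r2,
                  detection_limit=float(detection_limit),
                  n_samples=n_samples, taxa=taxa)


def partition_counts(fit: NCMFit) -> dict[str, int]:
    """Taxon counts in the above / fit / below occupancy bands."""
    return fit.partition_counts()


# ---------------------------------------------------------------------------
# Null model and deterministic strength
# ---------------------------------------------------------------------------

@dataclass
class NullModelResult:
    """Observed vs null beta diversity for one sample group."""

    group: str
    gamma: int                 # taxa with nonzero group total
    obs_mean_alpha: float      # mean per-sample richness
    obs_beta: float            # mean pairwise Bray-Curtis
    mean_null_beta: float
    sd_null_beta: float
    ses_beta: float
    ds: float                  # deterministic strength, %
    n_null: int
    seed: int
    pair_obs: np.ndarray       # condensed observed pairwise distances
    pair_null_mean: np.ndarray

    def as_row(self) -> dict:
        return {
            "group": self.group, "gamma": self.gamma,
            "obs_mean_alpha": self.obs_mean_alpha, "obs_beta": self.obs_beta,
            "mean_null_beta": self.mean_null_beta,
            "sd_null_beta": self.sd_null_beta, "ses_beta": self.ses_beta,
            "ds": self.ds, "n_null": self.n_null,
        }


def _curveball_trades(presence_sets: list[set], n_trades: int,
                      rng: np.random.Generator) -> None:
    """In-place curveball trades preserving row richness and column occupancy."""
    n = len(presence_sets)
    pairs = rng.integers(0, n, size=(n_trades, 2))
    for a, b in pairs:
        if a == b:
            continue
        sa, sb = presence_sets[a], presence_sets[b]
        only_a = list(sa - sb)
        only_b = list(sb - sa)
        if not only_a or not only_b:
            continue
        union = only_a + only_b
        rng.shuffle(union)
        new_a = set(union[: len(only_a)])
        new_b = set(union[len(only_a):])
        shared = sa & sb
        presence_sets[a] = shared | new_a
        presence_sets[b] = shared | new_b


def _bray_curtis_condensed(rel: np.ndarray) -> np.ndarray:
    return pdist(rel, metric="braycurtis")


def deterministic_strength(pair_obs: np.ndarray, pair_null_mean: np.ndarray) -> float:
    """DS (%): mean per-pair relative departure of observed dissimilarity.

    For a pair with observed dissimilarity D and null expectation N the
    selection strength is (D - N) / D when D > N (divergence beyond the
    null) and (N - D) / N otherwise (convergence below the null); pairs
    with both values zero are skipped with a warning.
    """
    d = np.asarray(pair_obs, dtype=float)
    n = np.asarray(pair_null_mean, dtype=float)
    if d.shape != n.shape:
        raise ConfigurationError("pair arrays must have matching shapes")
    usable = np.maximum(d, n) > 0
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.warning("deterministic_strength: skipped %d degenerate pair(s)",
                       n_skipped)
    if not usable.any():
        raise OralsiteError("no usable pairs for deterministic strength")
    d, n = d[usable], n[usable]
    ss = np.where(d > n, (d - n) / np.where(d > 0, d, 1.0),
                  (n - d) / np.where(n > 0, n, 1.0))
    ss = np.clip(ss, 0.0, 1.0)
    return float(100.0 * ss.mean())


def null_model(
    table: FeatureTable,
    metadata: SampleMetadata | None = None,
    group: str | None = None,
    n_null: int = 999,
    seed: int = 0,
    n_trades_per_draw: int | None = None,
) -> NullModelResult:
    """Null-model beta-diversity statistics for one group of samples.

    Null communities preserve, exactly and per draw, every sample's read
    total and richness and every taxon's occupancy count (fixed-fixed on
    presence, randomized by curveball trades along a Markov chain with
    burn-in); reads are then reassigned to each sample's present taxa by a
    multinomial proportional to regional (group-mean) relative abundance.
    """
    if group is not None:
        if metadata is None:
            raise ConfigurationError("grouping requires metadata")
        table = table.filter_samples(metadata.samples_for(group))
    if table.shape[0] < 3:
        raise ConfigurationError("null model needs >= 3 samples")
    counts = table.data.to_numpy(dtype=np.int64)
    nonzero = counts.sum(axis=0) > 0
    counts = counts[:, nonzero]
    n_samples, n_taxa = counts.shape
    totals = counts.sum(axis=1)
    gamma = int(n_taxa)
    richness = (counts > 0).sum(axis=1)
    obs_mean_alpha = float(richness.mean())

    rel = counts / totals[:, None]
    pair_obs = _bray_curtis_condensed(rel)
    obs_beta = float(pair_obs.mean())

    regional = rel.mean(axis=0)
    rng = substream(seed, "null_model")
    presence = [set(np.flatnonzero(counts[i] > 0)) for i in range(n_samples)]
    occupancy = np.zeros(n_taxa, dtype=np.int64)
    for s in presence:
        for t in s:
            occupancy[t] += 1
    if n_trades_per_draw is None:
        n_trades_per_draw = 5 * n_samples
    _curveball_trades(presence, 20 * n_samples, rng)  # burn-in

    null_betas = np.empty(n_null)
    pair_null_sum = np.zeros_like(pair_obs)
    for k in range(n_null):
        _curveball_trades(presence, n_trades_per_draw, rng)
        null_counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
        for i in range(n_samples):
            idx = np.fromiter(presence[i], dtype=np.int64)
            w = regional[idx]
            w = w / w.sum() if w.sum() > 0 else np.full(len(idx), 1.0 / len(idx))
            # one guaranteed read per present taxon keeps realized richness
            # equal to the observed richness; the rest is proportional refill
            null_counts[i, idx] = 1 + rng.multinomial(totals[i] - len(idx), w)
        # exact marginal preservation (fixed-fixed)
        assert np.array_equal(null_counts.sum(axis=1), totals)
        assert np.array_equal((null_counts > 0).sum(axis=1), richness)
        assert np.array_equal((null_counts > 0).sum(axis=0), occupancy)
        null_rel = null_counts / totals[:, None]
        pair_null = _bray_curtis_condensed(null_rel)
        pair_null_sum += pair_null
        null_betas[k] = pair_null.mean()

    mean_null = float(null_betas.mean())
    sd_null = float(null_betas.std(ddof=1))
    if sd_null == 0:
        raise OralsiteError("null beta has zero variance; ses undefined")
    ses = (obs_beta - mean_null) / sd_null
    pair_null_mean = pair_null_sum / n_null
    ds = deterministic_strength(pair_obs, pair_null_mean)
    return NullModelResult(
        group=group or "all", gamma=gamma, obs_mean_alpha=obs_mean_alpha,
        obs_beta=obs_beta, mean_null_beta=mean_null, sd_null_beta=sd_null,
        ses_beta=float(ses), ds=ds, n_null=n_null, seed=seed,
        pair_obs=pair_obs, pair_null_mean=pair_null_mean)
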