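"""Null-model partitioning of community assembly processes.

For every unordered pair of samples two statistics are computed against
null models with (by default) 1,000 randomizations:

* **βNTI** — the z-score of the observed abundance-weighted β-mean-nearest-
  taxon distance (βMNTD) against a null built by shuffling taxon labels
  across all tree tips. |βNTI| > 2 indicates deterministic selection.
* **RC** (Raup–Crick, Bray–Curtis form) — the rescaled probability in
  [−1, 1] that null-assembled communities are more dissimilar than observed.
  Null communities preserve each sample's richness and total abundance; taxa
  are drawn with probability proportional to regional occupancy and
  individuals filled proportionally to regional relative abundance.

The two are combined into the five-process classification:

====================  =============================
βNTI < −2             homogeneous selection
βNTI > +2             variable selection
|βNTI| ≤ 2, RC < −0.95  homogenizing dispersal
|βNTI| ≤ 2, RC > +0.95  dispersal limitation
|βNTI| ≤ 2, |RC| ≤ 0.95 stochastic drift (undominated)
====================  =============================

Boundary values fall to the less extreme class.  Null randomizations are
matrix-wide: each randomization draws one tip-label permutation (βNTI) or
one set of null communities (RC) shared by every pair, so all-pairs runs
scale with the number of randomizations rather than the number of pairs and
results do not depend on pair enumeration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency
from skbio import TreeNode

from .data_model import FeatureTable

logger = logging.getLogger(__name__)

PROCESSES = (
    "homogeneous_selection",
    "variable_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "drift",
)

_BC_EPS = 1e-10  # tie tolerance for Bray-Curtis comparisons (rational values)


@dataclass
class NullModelConfig:
    """Settings for the βNTI / Raup–Crick null models."""

    n_randomizations: int = 1000
    seed: int = 0
    abundance_weighted: bool = True

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be positive")
        if self.n_randomizations < 100:
            logger.warning("fewer than 100 randomizations is unreliable for "
                           "inference (got %d)", self.n_randomizations)


def patristic_matrix(tree: TreeNode, taxon_ids: list[str]) -> np.ndarray:
    """Tip-to-tip patristic distance matrix in `taxon_ids` order."""
    dm = tree.tip_tip_distances()
    missing = sorted(set(taxon_ids) - set(dm.ids))
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    idx = [dm.index(t) for t in taxon_ids]
    return dm.data[np.ix_(idx, idx)]


def _weights(counts: np.ndarray, abundance_weighted: bool) -> np.ndarray:
    """Per-taxon weights per sample: relative abundance, or 1/S unweighted."""
    counts = counts.astype(float)
    if abundance_weighted:
        return counts / counts.sum(axis=0, keepdims=True)
    pres = (counts > 0).astype(float)
    return pres / pres.sum(axis=0, keepdims=True)


def _beta_mntd_all_pairs(weights: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """βMNTD for all sample pairs given taxa×samples weights and taxa distances.

    For each sample j the nearest-taxon distance from every taxon to the
    community is ``m_j = min over taxa present in j of d(·, taxon)``; then
    βMNTD(i,j) = 0.5 (w_i·m_j + w_j·m_i).
    """
    n = weights.shape[1]
    m = np.empty((weights.shape[0], n))
    for j in range(n):
        pres = np.flatnonzero(weights[:, j] > 0)
        m[:, j] = dist[:, pres].min(axis=1)
    half = weights.T @ m  # half[i, j] = sum_t w[t, i] * m[t, j]
    return 0.5 * (half + half.T)


def beta_mntd(x, y, tree: TreeNode, taxon_ids: list[str],
              abundance_weighted: bool = True) -> float:
    """Observed βMNTD between two abundance vectors over `taxon_ids`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("both samples must be non-empty")
    dist = patristic_matrix(tree, taxon_ids)
    w = _weights(np.column_stack([x, y]), abundance_weighted)
    return float(_beta_mntd_all_pairs(w, dist)[0, 1])


def bnti_matrix(table: FeatureTable, tree: TreeNode,
                config: NullModelConfig | None = None) -> pd.DataFrame:
    """βNTI for all sample pairs (taxon-label-shuffling null)."""
    config = config or NullModelConfig()
    rng = np.random.default_rng(config.seed)
    dist = patristic_matrix(tree, table.taxon_ids)
    w = _weights(table.counts, config.abundance_weighted)
    obs = _beta_mntd_all_pairs(w, dist)
    t = w.shape[0]
    total = np.zeros_like(obs)
    total_sq = np.zeros_like(obs)
    for _ in range(config.n_randomizations):
        null = _beta_mntd_all_pairs(w[rng.permutation(t), :], dist)
        total += null
        total_sq += null * null
    mean = total / config.n_randomizations
    var = total_sq / config.n_randomizations - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    iu_r, iu_c = np.triu_indices_from(sd, k=1)
    degenerate = sd[iu_r, iu_c] < 1e-12
    if degenerate.all():
        i, j = iu_r[0], iu_c[0]
        raise ValueError(
            "null βMNTD standard deviation is zero for every pair (e.g. pair "
            f"({table.sample_ids[i]}, {table.sample_ids[j]})); shuffling tip "
            "labels does not change βMNTD — star-like phylogeny or identical "
            "taxon membership — so βNTI is undefined"
        )
    if degenerate.any():
        # isolated pairs with identical taxon membership: every null draw
        # equals the observation, so the z-score carries no evidence; 0
        logger.warning("βNTI: %d pair(s) with zero null variance set to 0",
                       int(degenerate.sum()))
    safe_sd = np.where(sd < 1e-12, 1.0, sd)
    z = np.where(sd < 1e-12, 0.0, (obs - mean) / safe_sd)
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


def bnti(x, y, tree: TreeNode, taxon_ids: list[str],
         config: NullModelConfig | None = None) -> float:
    """βNTI for a single pair of abundance vectors."""
    table = FeatureTable(np.column_stack([x, y]).astype(np.int64),
                         list(taxon_ids), ["x", "y"])
    return float(bnti_matrix(table, tree, config).iloc[0, 1])


def _null_community_counts(rng: np.random.Generator, richness: np.ndarray,
                           totals: np.ndarray, occupancy: np.ndarray,
                           pool_rel: np.ndarray) -> np.ndarray:
    """One randomization of null communities for every sample.

    Per sample: draw its observed richness worth of taxa without replacement
    with probability ∝ occupancy, then place its observed total of
    individuals — one guaranteed per drawn taxon, the remainder multinomial
    with probability ∝ regional relative abundance of the drawn taxa.
    """
    t = len(occupancy)
    n = len(richness)
    out = np.zeros((t, n), dtype=np.int64)
    logw = np.log(occupancy.astype(float))
    for j in range(n):
        s = int(richness[j])
        # Efraimidis-Spirakis: top-s Gumbel-perturbed keys = sequential
        # weighted sampling without replacement
        keys = logw + rng.gumbel(size=t)
        chosen = np.argpartition(keys, t - s)[t - s:]
        probs = pool_rel[chosen]
        probs = probs / probs.sum()
        counts = np.ones(s, dtype=np.int64)
        remaining = int(totals[j]) - s
        if remaining > 0:
            counts += rng.multinomial(remaining, probs)
        out[chosen, j] = counts
    return out


def rc_bray_matrix(table: FeatureTable,
                   config: NullModelConfig | None = None) -> pd.DataFrame:
    """Abundance-based Raup–Crick (Bray–Curtis) for all sample pairs."""
    config = config or NullModelConfig()
    rng = np.random.default_rng(config.seed)
    counts = table.counts
    if counts.sum() == 0:
        raise ValueError("empty regional pool")
    occupancy = (counts > 0).sum(axis=1)
    present = occupancy > 0
    if not present.all():
        counts = counts[present]
        occupancy = occupancy[present]
    pool_rel = counts.sum(axis=1) / counts.sum()
    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    obs = squareform(pdist(counts.T.astype(float), metric="braycurtis"))
    n = counts.shape[1]
    lt = np.zeros((n, n))
    eq = np.zeros((n, n))
    for _ in range(config.n_randomizations):
        null_counts = _null_community_counts(rng, richness, totals,
                                             occupancy, pool_rel)
        null_bc = squareform(pdist(null_counts.T.astype(float),
                                   metric="braycurtis"))
        lt += null_bc < obs - _BC_EPS
        eq += np.abs(null_bc - obs) <= _BC_EPS
    rc = 2.0 * ((lt + 0.5 * eq) / config.n_randomizations - 0.5)
    np.fill_diagonal(rc, 0.0)
    return pd.DataFrame(rc, index=table.sample_ids, columns=table.sample_ids)


def rc_bray(x, y, regional_pool: FeatureTable,
            config: NullModelConfig | None = None,
            sample_ids: tuple[str, str] | None = None) -> float:
    """RC for one pair of samples drawn from `regional_pool`'s samples.

    `x` and `y` must be columns of the pool table (the pool defines taxon
    occupancy and abundance for the null).
    """
    config = config or NullModelConfig()
    if sample_ids is not None:
        i = regional_pool.sample_ids.index(sample_ids[0])
        j = regional_pool.sample_ids.index(sample_ids[1])
    else:
        x = np.asarray(x)
        y = np.asarray(y)
        cols = regional_pool.counts.T
        try:
            i = next(k for k, c in enumerate(cols) if np.array_equal(c, x))
            j = next(k for k, c in enumerate(cols)
                     if np.array_equal(c, y) and k != i)
        except StopIteration:
            raise ValueError(
                "x and y must be samples of the regional pool") from None
    rc = rc_bray_matrix(regional_pool, config)
    return float(rc.iloc[i, j])


def classify_process(bnti_value: float, rc_value: float) -> str:
    """Map a (βNTI, RC) pair to one of the five assembly processes."""
    if np.isnan(bnti_value) or np.isnan(rc_value):
        raise ValueError("NaN input to process classification")
    if bnti_value < -2:
        return "homogeneous_selection"
    if bnti_value > 2:
        return "variable_selection"
    if rc_value > 0.95:
        return "dispersal_limitation"
    if rc_value < -0.95:
        return "homogenizing_dispersal"
    return "drift"


@dataclass
class ProcessFractions:
    """Share of each assembly process among the pairs of one condition."""

    condition: str  # all_pairs | within_site | between_site
    fractions: dict[str, float]
    counts: dict[str, int]
    n_pairs: int


@dataclass
class AssemblyResult:
    pairs: pd.DataFrame  # one row per unordered sample pair
    fractions: dict[str, ProcessFractions]
    bnti: pd.DataFrame
    rc: pd.DataFrame


def _fractions_for(pairs: pd.DataFrame, condition: str) -> ProcessFractions:
    counts = {p: int((pairs["process"] == p).sum()) for p in PROCESSES}
    n = len(pairs)
    fractions = {p: (c / n if n else 0.0) for p, c in counts.items()}
    return ProcessFractions(condition, fractions, counts, n)


def partition_assembly(table: FeatureTable, tree: TreeNode,
                       metadata: pd.DataFrame,
                       config: NullModelConfig | None = None) -> AssemblyResult:
    """Classify every sample pair and summarise process fractions.

    Fractions are reported for three conditions: all pairs, pairs from the
    same site, and pairs from different sites. Sites contributing a single
    sample appear only in the between-site condition (logged).
    """
    config = config or NullModelConfig()
    site = metadata.loc[table.sample_ids, "site"]
    singletons = site.value_counts()
    singletons = list(singletons.index[singletons == 1])
    if singletons:
        logger.info("sites with one sample contribute only between-site "
                    "pairs: %s", singletons)
    z = bnti_matrix(table, tree, config)
    rc = rc_bray_matrix(table, config)
    rows = []
    ids = table.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b = float(z.iloc[i, j])
            r = float(rc.iloc[i, j])
            rows.append({
                "sample_a": ids[i],
                "sample_b": ids[j],
                "bnti": b,
                "rc": r,
                "process": classify_process(b, r),
                "same_site": site.iloc[i] == site.iloc[j],
            })
    pairs = pd.DataFrame(rows)
    fractions = {
        "all_pairs": _fractions_for(pairs, "all_pairs"),
        "within_site": _fractions_for(pairs[pairs["same_site"]], "within_site"),
        "between_site": _fractions_for(pairs[~pairs["same_site"]], "between_site"),
    }
    return AssemblyResult(pairs, fractions, z, rc)


def compare_fractions(f_between: ProcessFractions,
                      f_within: ProcessFractions) -> pd.DataFrame:
    """Two-sample proportion test per process (chi-square, Yates-corrected).

    `delta` is fraction(between) − fraction(within): positive deltas mark
    processes whose relative importance grows when samples come from
    different sites.
    """
    if f_between.n_pairs == 0 or f_within.n_pairs == 0:
        raise ValueError("both conditions need at least one pair")
    rows = []
    for p in PROCESSES:
        a, na = f_between.counts[p], f_between.n_pairs
        b, nb = f_within.counts[p], f_within.n_pairs
        tab = np.array([[a, na - a], [b, nb - b]])
        if tab[:, 0].sum() == 0 or tab[:, 1].sum() == 0:
            chi2, pval = 0.0, 1.0
        else:
            chi2, pval, _, _ = chi2_contingency(tab, correction=True)
        rows.append({
            "process": p,
            "chi2": float(chi2),
            "p": float(pval),
            "delta": f_between.fractions[p] - f_within.fractions[p],
        })
    return pd.DataFrame(rows).set_index("process")
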