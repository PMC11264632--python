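"""Genus-level enterotype discovery.

The workflow follows the classic enterotyping recipe: collapse ASV counts to
genus-level relative abundances, compute the Jensen–Shannon distance (natural
log, square root applied so the quantity is a metric), cluster with
partitioning around medoids (PAM), pick the number of clusters k by the
Calinski–Harabasz (CH) index over k = 2..k_max, validate with mean silhouette
width, and attach principal-coordinate scores for plotting.

PAM is initialised with the deterministic BUILD phase; the seed only breaks
exact ties, so results are effectively deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import kruskal
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .data_model import FeatureTable, UNCLASSIFIED

logger = logging.getLogger(__name__)

SILHOUETTE_WEAK = 0.25  # below this mean width we flag "no strong clusters"


def collapse_to_genus(table: FeatureTable, taxonomy: pd.Series) -> pd.DataFrame:
    """Sum counts within genus and row-normalise.

    Returns a samples × genera relative-abundance DataFrame whose rows sum
    to 1. ASVs with unknown genus are pooled into an ``"unclassified"``
    bucket rather than dropped.
    """
    genera = taxonomy.reindex(table.taxon_ids).fillna(UNCLASSIFIED).to_numpy()
    df = pd.DataFrame(table.counts, index=genera, columns=table.sample_ids)
    collapsed = df.groupby(level=0).sum().T  # samples × genera
    sums = collapsed.sum(axis=1)
    if (sums == 0).any():
        raise ValueError(f"samples empty after genus collapse: "
                         f"{list(sums.index[sums == 0])}")
    return collapsed.div(sums, axis=0)


def jsd_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Jensen–Shannon distance (sqrt of JS divergence, natural log)."""
    mat = profiles.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative entries in relative-abundance profiles")
    n = mat.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jensenshannon(mat[i], mat[j])
    np.nan_to_num(out, copy=False)  # identical rows give 0/0 -> 0
    return DistanceMatrix(out, ids=[str(s) for s in profiles.index])


def pam_cluster(dm: DistanceMatrix, k: int, seed: int = 0,
                max_iter: int = 200) -> tuple[np.ndarray, list[str]]:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic BUILD initialisation followed by greedy SWAP steps until
    no swap lowers the total distance-to-medoid objective.

    Returns
    -------
    labels : array of cluster indices (0..k-1) in `dm.ids` order
    medoids : ids of the k medoid samples
    """
    d = dm.data
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)

    # BUILD: first medoid minimises total distance; each next one maximally
    # reduces the objective.
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - d, 0).sum(axis=1)
        gains[medoids] = -np.inf
        best = np.flatnonzero(gains == gains.max())
        medoids.append(int(rng.choice(best)) if len(best) > 1 else int(best[0]))
        nearest = np.minimum(nearest, d[medoids[-1]])

    def objective(meds):
        return d[np.asarray(meds)].min(axis=0).sum()

    current = objective(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                val = objective(trial)
                if val < current - 1e-12:
                    medoids, current, improved = trial, val, True
        if not improved:
            break
    labels = d[np.asarray(medoids)].argmin(axis=0)
    return labels, [dm.ids[m] for m in medoids]


def ch_index(dm: DistanceMatrix, labels) -> float:
    """Calinski–Harabasz index from a distance matrix.

    Uses the medoid-based pseudo sum-of-squares decomposition:
    within SS = squared distances to cluster medoids, total SS = squared
    distances to the overall medoid, between SS = total − within.
    """
    labels = np.asarray(labels)
    d = dm.data
    n = d.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("CH index requires at least two clusters")
    overall_medoid = int(np.argmin((d ** 2).sum(axis=1)))
    total_ss = float((d[overall_medoid] ** 2).sum())
    within_ss = 0.0
    for c in uniq:
        members = np.flatnonzero(labels == c)
        sub = d[np.ix_(members, members)] ** 2
        medoid = members[int(np.argmin(sub.sum(axis=1)))]
        within_ss += float((d[medoid, members] ** 2).sum())
    between_ss = max(total_ss - within_ss, 0.0)
    if within_ss == 0:
        logger.warning("zero within-cluster dispersion; CH index diverges")
        return float("inf")
    return (between_ss / (k - 1)) / (within_ss / (n - k))


def silhouette(dm: DistanceMatrix, labels) -> tuple[float, np.ndarray]:
    """Mean and per-sample silhouette widths; singleton clusters score 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least two clusters")
    widths = silhouette_samples(dm.data, labels, metric="precomputed")
    return float(widths.mean()), widths


@dataclass
class EnterotypeModel:
    """Result of enterotype discovery on a genus profile matrix."""

    k: int
    labels: pd.Series  # sample -> cluster index
    medoids: list[str]
    ch_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    mean_silhouette: float
    weak_structure: bool
    pcoa_scores: pd.DataFrame = field(repr=False)
    distance_matrix: DistanceMatrix = field(repr=False)


def find_enterotypes(profiles: pd.DataFrame, k_max: int = 6,
                     seed: int = 0) -> EnterotypeModel:
    """Pick k by max CH over 2..k_max; report silhouette and PCoA scores.

    When the best mean silhouette is below 0.25 the model carries a
    ``weak_structure`` flag: the CH-optimal partition should not be
    over-interpreted as discrete enterotypes.
    """
    n = profiles.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    dm = jsd_matrix(profiles)
    ch_by_k: dict[int, float] = {}
    sil_by_k: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, list[str]]] = {}
    for k in range(2, min(k_max, n - 1) + 1):
        labels, medoids = pam_cluster(dm, k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        ch_by_k[k] = ch_index(dm, labels)
        sil_by_k[k], _ = silhouette(dm, labels)
        fits[k] = (labels, medoids)
    best_k = max(ch_by_k, key=ch_by_k.get)
    labels, medoids = fits[best_k]
    mean_sil = sil_by_k[best_k]
    weak = mean_sil < SILHOUETTE_WEAK
    if weak:
        logger.warning("no strong cluster structure (mean silhouette %.3f < %.2f)",
                       mean_sil, SILHOUETTE_WEAK)
    scores = pcoa(dm, number_of_dimensions=min(3, n - 1)).samples
    scores.index = list(profiles.index)
    return EnterotypeModel(
        k=best_k,
        labels=pd.Series(labels, index=list(profiles.index), name="enterotype"),
        medoids=medoids,
        ch_by_k=ch_by_k,
        silhouette_by_k=sil_by_k,
        mean_silhouette=mean_sil,
        weak_structure=weak,
        pcoa_scores=scores,
        distance_matrix=dm,
    )


def compare_enterotypes(profiles: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-genus Kruskal–Wallis contrast between enterotypes, BH-adjusted."""
    labels = pd.Series(np.asarray(labels), index=profiles.index)
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need at least two enterotypes to compare")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("each enterotype needs at least two samples")
    rows = []
    for genus in profiles.columns:
        samples = [profiles.loc[labels == g, genus].to_numpy() for g in groups]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            h, p = 0.0, 1.0
        else:
            h, p = kruskal(*samples)
        rows.append({"genus": genus, "H": float(h), "p": float(p)})
    out = pd.DataFrame(rows).set_index("genus")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
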