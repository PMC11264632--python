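"""Rarefaction, alpha diversity (chao1, Faith's PD), Bray–Curtis, PERMANOVA.

Conventions
-----------
* Rarefaction is a single subsample without replacement at a fixed seed;
  samples below the requested depth are dropped (and logged), mirroring the
  QIIME2 ``core-metrics-phylogenetic`` behaviour at ``--p-sampling-depth``.
* chao1 is the bias-corrected form ``S_obs + F1(F1-1) / (2(F2+1))``.
* Faith's PD includes the path from the induced subtree to the tree root.
* The PERMANOVA p-value carries the +1 correction in numerator and
  denominator, so the permutation floor with 999 permutations is 0.001.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.stats.distance import permanova as _skbio_permanova
from statsmodels.stats.multitest import multipletests

from .data_model import FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_RAREFACTION_DEPTH = 4530


def rarefy(table: FeatureTable, depth: int, seed: int = 0) -> FeatureTable:
    """Subsample every sample to exactly `depth` reads without replacement.

    Samples with fewer than `depth` reads are dropped and logged; if all
    samples fall below depth this is fatal.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    cols = []
    kept_ids = []
    for j, sid in enumerate(table.sample_ids):
        if not keep[j]:
            continue
        cols.append(rng.multivariate_hypergeometric(table.counts[:, j], depth))
        kept_ids.append(sid)
    return FeatureTable(np.column_stack(cols), list(table.taxon_ids), kept_ids)


def chao1(counts) -> float:
    """Bias-corrected chao1 richness estimate for one sample."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("chao1 undefined for an all-zero sample")
    return float(_skbio_chao1(counts, bias_corrected=True))


def faith_pd(present_taxa, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity, root path included."""
    present = list(present_taxa)
    tips = [t.name for t in tree.tips()]
    missing = sorted(set(present) - set(tips))
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    counts = [1 if t in set(present) else 0 for t in tips]
    return float(_skbio_faith_pd(counts, tips, tree))


def alpha_diversity(table: FeatureTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample observed features, chao1 and (if a tree is given) Faith's PD."""
    rows = {}
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        row = {
            "observed_features": int((col > 0).sum()),
            "chao1": chao1(col),
        }
        if tree is not None:
            present = [t for t, c in zip(table.taxon_ids, col) if c > 0]
            row["faith_pd"] = faith_pd(present, tree)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least two samples")
    if (table.sample_sums() == 0).any():
        raise ValueError("zero-sum sample in Bray-Curtis input")
    data = squareform(pdist(table.counts.T.astype(float), metric="braycurtis"))
    return DistanceMatrix(data, ids=table.sample_ids)


def permanova(dm: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0) -> dict:
    """One-way PERMANOVA: pseudo-F and permutation p with +1 correction."""
    grouping = pd.Series(np.asarray(grouping), index=list(dm.ids))
    levels = grouping.unique()
    if len(levels) < 2:
        raise ValueError("grouping must have at least two groups")
    sizes = grouping.value_counts()
    if (sizes < 2).any():
        logger.warning("singleton group(s) in PERMANOVA: %s",
                       list(sizes[sizes < 2].index))
    np.random.seed(seed % (2**32))
    res = _skbio_permanova(dm, list(grouping.loc[list(dm.ids)]),
                           permutations=n_perm)
    return {"pseudo_F": float(res["test statistic"]), "p": float(res["p-value"]),
            "n_perm": n_perm}


def pairwise_permanova(dm: DistanceMatrix, grouping, n_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """All pairwise group contrasts with Benjamini–Hochberg adjustment."""
    grouping = pd.Series(np.asarray(grouping), index=list(dm.ids))
    levels = sorted(map(str, grouping.astype(str).unique()))
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            ids = grouping.index[grouping.astype(str).isin([a, b])]
            sub = dm.filter(ids)
            res = permanova(sub, grouping.loc[list(sub.ids)], n_perm=n_perm, seed=seed)
            rows.append({"group_a": a, "group_b": b, **res})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
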