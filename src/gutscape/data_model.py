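"""Core domain objects and plain-text I/O.

The pipeline's central object is a :class:`FeatureTable` — an ASV-by-sample
count matrix — linked to a rooted :class:`~skbio.TreeNode` phylogeny over the
same taxa, a per-sample metadata table, and an ASV→genus taxonomy map.
Everything downstream (rarefaction, diversity, enterotypes, assembly nulls,
environmental association) consumes the aligned bundle produced by
:func:`align_inputs`.

All matrices are indexed by id at API boundaries, never by position.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

REQUIRED_METADATA_COLUMNS = (
    "site",
    "province",
    "latitude",
    "longitude",
    "elevation",
    "annual_mean_temperature",
    "annual_precipitation",
    "population_density",
    "human_footprint",
)

#: The six environmental covariates used throughout the association analyses.
ENV_COLUMNS = (
    "latitude",
    "elevation",
    "annual_mean_temperature",
    "annual_precipitation",
    "population_density",
    "human_footprint",
)

UNCLASSIFIED = "unclassified"


class LoadError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class FeatureTable:
    """Taxa × samples matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        2-D integer array, shape ``(n_taxa, n_samples)``.
    taxon_ids, sample_ids
        Unique ordered identifiers for rows and columns.
    """

    counts: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.ndim != 2:
            raise LoadError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise LoadError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.taxon_ids)} taxa / {len(self.sample_ids)} samples"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise LoadError(f"duplicate {name} ids: {dupes}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise LoadError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            r, c = np.argwhere(self.counts < 0)[0]
            raise LoadError(
                f"negative count at taxon {self.taxon_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def filter_samples(self, keep: list[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return FeatureTable(self.counts[:, idx], list(self.taxon_ids), list(keep))

    def filter_taxa(self, keep: list[str]) -> "FeatureTable":
        idx = [self.taxon_ids.index(t) for t in keep]
        return FeatureTable(self.counts[idx, :], list(keep), list(self.sample_ids))

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized copy of the counts (per-sample proportions)."""
        sums = self.sample_sums().astype(float)
        if (sums == 0).any():
            bad = [s for s, t in zip(self.sample_ids, sums) if t == 0]
            raise LoadError(f"zero-sum samples: {bad}")
        return self.counts / sums


def read_feature_table(path) -> FeatureTable:
    """Read a dense TSV feature table (taxa rows, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise LoadError(f"{path}: empty feature table")
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df[col].to_numpy()):
            try:
                x = int(val)
            except (TypeError, ValueError):
                raise LoadError(
                    f"{path}: non-integer cell {val!r} at taxon "
                    f"{df.index[i]!r}, sample {col!r}"
                ) from None
            if x < 0:
                raise LoadError(
                    f"{path}: negative count {x} at taxon {df.index[i]!r}, "
                    f"sample {col!r}"
                )
            mat[i, j] = x
    table = FeatureTable(mat, list(df.index), list(df.columns))
    zero = table.sample_sums() == 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise LoadError(f"{path}: samples with zero total counts: {bad}")
    return table


def write_feature_table(table: FeatureTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


def read_tree(path, expected_taxa: list[str] | None = None) -> TreeNode:
    """Read a rooted Newick tree and validate tips against a taxon list.

    Missing branch lengths are a hard error (never silently zero-filled);
    `expected_taxa` absent from the tree are listed by id.
    """
    tree = TreeNode.read(str(path) if not isinstance(path, io.IOBase) else path)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise LoadError(
                f"branch without length above {node.name or 'internal node'!r}"
            )
        if node.length < 0:
            raise LoadError(f"negative branch length above {node.name!r}")
    tips = {t.name for t in tree.tips()}
    if expected_taxa is not None:
        missing = sorted(set(expected_taxa) - tips)
        if missing:
            raise LoadError(f"taxa missing from tree: {missing}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata TSV (first column sample id)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise LoadError(f"{path}: missing metadata columns: {missing}")
    if meta.index.has_duplicates:
        raise LoadError(f"{path}: duplicate sample ids in metadata")
    lat, lon = meta["latitude"], meta["longitude"]
    if (lat.abs() > 90).any() or (lon.abs() > 180).any():
        raise LoadError(f"{path}: coordinates out of range")
    if meta["site"].isna().any() or meta["province"].isna().any():
        raise LoadError(f"{path}: every sample needs a site and a province")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> pd.Series:
    """Read a two-column taxonomy TSV ("Feature ID<TAB>Taxon").

    The Taxon field may be a semicolon-delimited lineage; the genus is taken
    from the ``g__`` rank if rank prefixes are present, otherwise from the
    last (or only) field. Unknown genus is encoded as ``"unclassified"``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise LoadError(f"{path}: taxonomy needs at least two columns")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise LoadError(f"{path}: duplicate taxon ids in taxonomy")
    genera = df.iloc[:, 1].map(parse_genus)
    return pd.Series(genera.to_numpy(), index=ids.to_numpy(), name="genus")


def parse_genus(lineage: str) -> str:
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return UNCLASSIFIED
    ranks = [r.strip() for r in str(lineage).split(";") if r.strip()]
    for rank in ranks:
        if rank.startswith("g__"):
            name = rank[3:].strip()
            return name if name else UNCLASSIFIED
    if ranks and not any(r[:3] in {"d__", "k__", "p__", "c__", "o__", "f__", "s__"} for r in ranks):
        return ranks[-1]
    return UNCLASSIFIED


def write_taxonomy(tax: pd.Series, path) -> None:
    pd.DataFrame({"Feature ID": tax.index, "Taxon": ["g__" + g for g in tax.to_numpy()]}).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class AnalysisBundle:
    """Intersected, consistently ordered inputs for one analysis run."""

    table: FeatureTable
    tree: TreeNode
    metadata: pd.DataFrame
    taxonomy: pd.Series
    dropped_samples: list[str] = field(default_factory=list)
    dropped_taxa: list[str] = field(default_factory=list)
    pruned_tips: int = 0


def align_inputs(
    table: FeatureTable,
    tree: TreeNode | None,
    metadata: pd.DataFrame,
    taxonomy: pd.Series | None = None,
    require_tree: bool = True,
) -> AnalysisBundle:
    """Intersect the four inputs into one consistently ordered bundle.

    Samples without metadata are dropped with a warning; tree tips not in
    the table are pruned.  Table taxa absent from the tree are a hard error
    when ``require_tree`` (phylogenetic metrics are undefined for them) and
    a warned exclusion otherwise.
    """
    kept_samples = [s for s in table.sample_ids if s in metadata.index]
    dropped_samples = [s for s in table.sample_ids if s not in metadata.index]
    if not kept_samples:
        raise LoadError("no samples shared between table and metadata")
    if dropped_samples:
        logger.warning("dropping %d samples without metadata: %s",
                       len(dropped_samples), dropped_samples)

    dropped_taxa: list[str] = []
    pruned = 0
    kept_taxa = list(table.taxon_ids)
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = sorted(set(table.taxon_ids) - tips)
        if missing:
            if require_tree:
                raise LoadError(f"table taxa missing from tree: {missing}")
            dropped_taxa = missing
            kept_taxa = [t for t in table.taxon_ids if t in tips]
            logger.warning("excluding %d taxa absent from tree", len(missing))
        extra = tips - set(kept_taxa)
        if extra:
            pruned = len(extra)
            tree = tree.shear(kept_taxa)
            tree.prune()
            logger.info("pruned %d tree tips not in table", pruned)

    out = table.filter_samples(kept_samples)
    if kept_taxa != table.taxon_ids:
        out = out.filter_taxa(kept_taxa)
    nonzero = out.sample_sums() > 0
    if not nonzero.all():
        empty = [s for s, nz in zip(out.sample_ids, nonzero) if not nz]
        dropped_samples += empty
        out = out.filter_samples([s for s in out.sample_ids if s not in empty])
        logger.warning("dropping %d samples emptied by taxon exclusion", len(empty))

    meta = metadata.loc[out.sample_ids]
    if taxonomy is not None:
        taxonomy = taxonomy.reindex(out.taxon_ids).fillna(UNCLASSIFIED)
    return AnalysisBundle(out, tree, meta, taxonomy,
                          dropped_samples=dropped_samples,
                          dropped_taxa=dropped_taxa, pruned_tips=pruned)
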