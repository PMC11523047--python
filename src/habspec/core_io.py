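"""Reading, validation, and preprocessing of the four input artifacts.

The pipeline consumes (a) a sample-by-OTU count table (TSV or BIOM 2.1),
(b) a rooted Newick phylogeny over the OTUs, (c) per-sample metadata
(site, habitat, host species, coordinates, depth), and (d) a per-site
environmental table.  Preprocessing applies the standard metabarcoding
filters: removal of singletons and OTUs below a relative-abundance
threshold, followed by a single seeded rarefaction to a common depth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("habspec")

HABITATS = ("sediment", "gut_content", "gut_tissue")


class CommunityTable:
    """Samples x OTUs table of nonnegative integer counts.

    Wraps a pandas DataFrame (rows = samples, columns = OTUs) and enforces
    the container invariants at construction: unique ids, integral
    nonnegative counts, and no all-zero sample.
    """

    def __init__(self, data: pd.DataFrame, _validated: bool = False):
        if not _validated:
            data = _validate_community_frame(data)
        self.data = data

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other) -> bool:
        return isinstance(other, CommunityTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        n, s = self.shape
        return f"<CommunityTable: {n} samples x {s} OTUs>"

    # -- subsetting ------------------------------------------------------
    def select_samples(self, ids) -> "CommunityTable":
        return CommunityTable(self.data.loc[list(ids)], _validated=True)

    def select_otus(self, ids) -> "CommunityTable":
        return CommunityTable(self.data[list(ids)], _validated=True)

    def drop_empty_otus(self) -> "CommunityTable":
        keep = self.data.sum(axis=0) > 0
        return CommunityTable(self.data.loc[:, keep], _validated=True)

    # -- serialization ---------------------------------------------------
    def write_tsv(self, path, orientation: str = "otus") -> None:
        """Write as TSV; ``orientation='otus'`` uses the ``#OTU ID``
        rows-are-OTUs convention so the file is self-describing."""
        if orientation == "otus":
            out = self.data.T
            out.index.name = "#OTU ID"
            out.to_csv(path, sep="\t")
        elif orientation == "samples":
            out = self.data.copy()
            out.index.name = "sample_id"
            out.to_csv(path, sep="\t")
        else:
            raise ValueError(f"unknown orientation {orientation!r}")


def _validate_community_frame(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    for kind, ids in (("sample", frame.index), ("OTU", frame.columns)):
        dup = ids[ids.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate {kind} id(s): {', '.join(map(str, dup))}")
    values = frame.to_numpy()
    numeric = pd.to_numeric(values.ravel(), errors="coerce").reshape(values.shape)
    bad = np.argwhere(~np.isfinite(numeric) | (numeric < 0) | (numeric != np.round(numeric)))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"count for sample {frame.index[i]!r}, OTU {frame.columns[j]!r} is "
            f"{values[i, j]!r}: counts must be nonnegative integers"
        )
    frame = pd.DataFrame(numeric.astype(np.int64), index=frame.index, columns=frame.columns)
    empty = frame.index[frame.sum(axis=1) == 0]
    if len(empty):
        raise ValueError(f"all-zero sample(s): {', '.join(empty)}")
    return frame


def read_community_table(path, format: str = "auto", orientation: str = "auto") -> CommunityTable:
    """Read a count table from TSV or BIOM 2.1 (HDF5).

    TSV orientation is auto-detected: a leading ``#OTU ID`` cell (BIOM-TSV
    convention) implies OTUs as rows; a leading ``sample``-like keyword
    implies samples as rows; otherwise ``orientation`` must be given
    explicitly as ``'otus'`` or ``'samples'``.
    """
    path = str(path)
    if format == "auto":
        format = "biom" if path.endswith(".biom") else "tsv"
    if format == "biom":
        return _read_biom(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")

    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#") and not first.startswith("#OTU ID"):
            first = fh.readline()
    header0 = first.split("\t", 1)[0].strip()
    if orientation == "auto":
        if header0 == "#OTU ID":
            orientation = "otus"
        elif header0.lower() in {"sample", "sample_id", "sampleid", "samples", ""}:
            orientation = "samples"
        else:
            raise ValueError(
                f"cannot auto-detect orientation from leading cell {header0!r}; "
                "pass orientation='otus' or orientation='samples'"
            )
    frame = pd.read_csv(path, sep="\t", index_col=0, comment=None,
                        skiprows=lambda i: False, dtype=str)
    frame = frame[~frame.index.astype(str).str.startswith("# ")]
    if orientation == "otus":
        frame = frame.T
    return CommunityTable(frame)


def _read_biom(path) -> CommunityTable:
    """Minimal BIOM 2.1 reader: the format is an HDF5 file holding a CSR
    matrix grouped by observation plus id vectors."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        )
    frame = pd.DataFrame(mat.toarray().T, index=sample_ids, columns=obs_ids)
    return CommunityTable(frame)


def write_biom(table: CommunityTable, path) -> None:
    """Write a CommunityTable as a minimal BIOM 2.1 HDF5 file."""
    import h5py
    from scipy import sparse

    mat = sparse.csr_matrix(table.counts.T)
    with h5py.File(path, "w") as fh:
        fh.attrs["format-version"] = [2, 1]
        fh.create_dataset("observation/ids", data=np.array(table.otu_ids, dtype="S"))
        fh.create_dataset("sample/ids", data=np.array(table.sample_ids, dtype="S"))
        fh.create_dataset("observation/matrix/data", data=mat.data.astype(float))
        fh.create_dataset("observation/matrix/indices", data=mat.indices)
        fh.create_dataset("observation/matrix/indptr", data=mat.indptr)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def read_tree(path) -> TreeNode:
    """Read and validate a rooted Newick phylogeny.

    Tips must be uniquely labelled; missing branch lengths are treated as 0
    with a warning; negative lengths are an error.
    """
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if any(n is None or n == "" for n in names):
        raise ValueError("tree contains unlabelled tip(s)")
    dup = pd.Index(names)
    dup = dup[dup.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate tip label(s): {', '.join(dup)}")
    n_missing = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            if not node.is_root():
                n_missing += 1
            node.length = 0.0
        elif not np.isfinite(node.length) or node.length < 0:
            raise ValueError(f"branch length {node.length!r} at {node.name!r} is not finite and >= 0")
    if n_missing:
        logger.warning("tree: %d missing branch length(s) treated as 0", n_missing)
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Metadata / environment
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ("site", "habitat", "host_species", "latitude", "longitude", "depth")


def read_sample_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return validate_sample_frame(frame)


def validate_sample_frame(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame.index = frame.index.astype(str)
    missing = [c for c in ("site", "habitat", "latitude", "longitude") if c not in frame.columns]
    if missing:
        raise ValueError(f"sample metadata lacks column(s): {', '.join(missing)}")
    dup = frame.index[frame.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate sample id(s) in metadata: {', '.join(dup)}")
    lat = frame["latitude"].astype(float)
    lon = frame["longitude"].astype(float)
    if (lat.abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (lon.abs() > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    frame["latitude"] = lat
    frame["longitude"] = lon
    return frame


def read_env_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return validate_env_table(frame)


def validate_env_table(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame.index = frame.index.astype(str)
    dup = frame.index[frame.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate site id(s) in env table: {', '.join(dup)}")
    if frame.shape[1] < 2:
        raise ValueError("environmental table needs >= 2 variables")
    frame = frame.astype(float)
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValueError(f"missing values in environmental variable(s): {', '.join(bad)}")
    return frame


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_low_abundance(table: CommunityTable, min_rel_abund: float = 5e-5,
                         drop_singletons: bool = True) -> CommunityTable:
    """Remove singleton OTUs and OTUs below ``min_rel_abund`` of the grand
    total, computed on the whole dataset before rarefaction.

    Samples left empty by the filter are dropped with a warning.
    """
    totals = table.data.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("empty table")
    drop = totals / grand < min_rel_abund
    if drop_singletons:
        drop |= totals <= 1
    if drop.all():
        raise ValueError("abundance filter removed every OTU")
    kept = table.data.loc[:, ~drop]
    n_removed = int(drop.sum())
    if n_removed:
        logger.info("filter_low_abundance: removed %d of %d OTUs", n_removed, table.shape[1])
    empty = kept.index[kept.sum(axis=1) == 0]
    if len(empty):
        logger.warning("filter_low_abundance: dropping now-empty sample(s): %s", ", ".join(empty))
        kept = kept.drop(index=empty)
    return CommunityTable(kept, _validated=True)


def rarefy(table: CommunityTable, depth: int = 6000, seed: int | None = None,
           n_iterations: int = 1, prune_zero_otus: bool = True) -> CommunityTable:
    """Rarefy each sample to exactly ``depth`` counts by a seeded
    multivariate-hypergeometric draw (subsampling without replacement).

    Samples with fewer than ``depth`` counts are dropped with a warning.
    A single rarefaction is the default; ``n_iterations > 1`` averages
    several draws (rounded), trading exactness of the per-sample sum for
    stability of rare-taxon representation.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.data.sum(axis=1)
    shallow = totals.index[totals < depth]
    if len(shallow) == len(totals):
        raise ValueError(f"all samples have fewer than {depth} counts")
    if len(shallow):
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(shallow), depth, ", ".join(shallow))
    kept = table.data.drop(index=shallow)
    rng = np.random.default_rng(seed)
    draws = np.zeros((n_iterations,) + kept.shape, dtype=np.int64)
    counts = kept.to_numpy()
    for it in range(n_iterations):
        for i in range(counts.shape[0]):
            draws[it, i] = rng.multivariate_hypergeometric(counts[i], depth)
    out = draws[0] if n_iterations == 1 else np.round(draws.mean(axis=0)).astype(np.int64)
    result = pd.DataFrame(out, index=kept.index, columns=kept.columns)
    table = CommunityTable(result, _validated=True)
    if prune_zero_otus:
        table = table.drop_empty_otus()
    return table


# ---------------------------------------------------------------------------
# Alignment of the four artifacts
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """Validated, mutually consistent inputs."""
    table: CommunityTable
    tree: TreeNode
    samples: pd.DataFrame
    env: pd.DataFrame = field(default=None)


def align_inputs(table: CommunityTable, tree: TreeNode, samples: pd.DataFrame,
                 env: pd.DataFrame | None = None) -> Bundle:
    """Reconcile table, tree, metadata, and environment.

    The tree is pruned to the table's OTUs (patristic distances among
    retained tips are unchanged); an OTU missing from the tree is an error;
    metadata is restricted and ordered to the table's samples; every
    sample's site must appear in the environmental table.
    """
    tips = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(f"{len(missing)} table OTU(s) missing from tree: {shown}")
    if tips - set(table.otu_ids):
        tree = tree.shear(set(table.otu_ids))
        tree.prune()

    absent = [s for s in table.sample_ids if s not in samples.index]
    if absent:
        raise ValueError(f"sample(s) without metadata: {', '.join(absent[:10])}")
    samples = samples.loc[table.sample_ids]

    if env is not None:
        missing_sites = sorted(set(samples["site"]) - set(env.index))
        if missing_sites:
            raise ValueError(f"site(s) without environmental data: {', '.join(missing_sites)}")
    return Bundle(table=table, tree=tree, samples=samples, env=env)
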