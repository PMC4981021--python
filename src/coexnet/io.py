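"""Expression-collection and gene-set I/O.

The unit of analysis is one expression dataset: a normalized (log-scale)
genes x samples matrix with a replicate-group label per sample and a single
tissue label per dataset. A :class:`DatasetCollection` holds many such
datasets over a shared gene universe and is what the meta-analysis iterates
over; gene sets come in as flat GMT files restricted to that universe.

On-disk formats are deliberately plain: tab-separated matrices with a
``gene_id`` header column, a three-column sample-metadata TSV
(``sample_id``, ``replicate_group``, ``tissue``), and standard GMT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

#: Tissue label given to a dataset whose samples disagree on tissue.
MIXED_TISSUE = "mixed"

METADATA_COLUMNS = ("sample_id", "replicate_group", "tissue")


@dataclass
class ExpressionDataset:
    """One normalized expression dataset (a GEO-series analog).

    Parameters
    ----------
    dataset_id
        Unique identifier within a collection.
    values
        Genes x samples matrix of finite, already-normalized log-scale
        expression values; the index holds gene IDs, the columns sample IDs.
    replicate_group
        Categorical label per sample (index must equal ``values.columns``).
    tissue
        Dataset-level tissue label; ``"mixed"`` when the samples do not all
        share one tissue.
    """

    dataset_id: str
    values: pd.DataFrame
    replicate_group: pd.Series
    tissue: str = MIXED_TISSUE

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(
                f"dataset {self.dataset_id!r}: duplicate gene IDs {list(dupes[:5])}"
            )
        if self.values.columns.has_duplicates:
            raise InputError(f"dataset {self.dataset_id!r}: duplicate sample IDs")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise InputError(f"dataset {self.dataset_id!r}: non-numeric values")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise InputError(
                f"dataset {self.dataset_id!r}: non-finite value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        missing = self.values.columns.difference(self.replicate_group.index)
        if len(missing) > 0:
            raise InputError(
                f"dataset {self.dataset_id!r}: samples without replicate group: "
                f"{list(missing[:5])}"
            )
        self.replicate_group = self.replicate_group.reindex(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> dict[str, list[str]]:
        """Samples keyed by replicate group, in first-appearance order."""
        out: dict[str, list[str]] = {}
        for sample, grp in self.replicate_group.items():
            out.setdefault(str(grp), []).append(str(sample))
        return out


@dataclass
class DatasetCollection:
    """Ordered set of :class:`ExpressionDataset` sharing a gene universe."""

    datasets: list[ExpressionDataset] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate dataset_ids in collection")

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def __getitem__(self, dataset_id: str) -> ExpressionDataset:
        for d in self.datasets:
            if d.dataset_id == dataset_id:
                return d
        raise KeyError(dataset_id)

    @property
    def gene_universe(self) -> pd.Index:
        """Union of gene IDs across datasets, in first-appearance order."""
        seen: dict[str, None] = {}
        for d in self.datasets:
            for g in d.genes:
                seen.setdefault(g, None)
        return pd.Index(seen.keys(), name="gene_id")

    def tissues(self, include_mixed: bool = False) -> list[str]:
        """Distinct dataset tissue labels, in first-appearance order."""
        out: dict[str, None] = {}
        for d in self.datasets:
            if include_mixed or d.tissue != MIXED_TISSUE:
                out.setdefault(d.tissue, None)
        return list(out)

    def subset(self, tissue: str) -> "DatasetCollection":
        return DatasetCollection([d for d in self.datasets if d.tissue == tissue])


@dataclass
class PathwayDB:
    """Named gene sets over a gene universe (GO Biological Process analog)."""

    members: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [p for p, s in self.members.items() if not s]
        if empty:
            raise InputError(f"empty pathways after restriction: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def size(self, pathway_id: str) -> int:
        """In-universe member count m of the pathway."""
        return len(self.members[pathway_id])


def load_expression_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read a matrix TSV plus its sample-metadata TSV into a dataset.

    The dataset tissue is the samples' shared tissue label when they are
    unanimous, otherwise ``"mixed"``.
    """
    matrix_path = Path(matrix_path)
    if dataset_id is None:
        dataset_id = matrix_path.name.split(".")[0].removesuffix("_matrix")
    values = pd.read_csv(
        matrix_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    values.index = values.index.astype(str)
    values.index.name = "gene_id"
    values.columns = values.columns.astype(str)
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values[values[col].map(lambda v: not _is_number(v))]
            row = bad.index[0] if len(bad) else "?"
            raise InputError(
                f"{matrix_path}: non-numeric cell at gene {row!r}, sample {col!r}"
            )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise InputError(f"{metadata_path}: missing columns {sorted(missing_cols)}")
    meta = meta.set_index("sample_id")
    absent = values.columns.difference(meta.index)
    if len(absent) > 0:
        raise InputError(
            f"{metadata_path}: sample {absent[0]!r} missing from metadata"
        )
    meta = meta.loc[values.columns]
    sample_tissues = set(meta["tissue"])
    tissue = sample_tissues.pop() if len(sample_tissues) == 1 else MIXED_TISSUE
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=values,
        replicate_group=meta["replicate_group"],
        tissue=tissue,
    )


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_expression_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    metadata_path: str | Path,
    sample_tissue: Mapping[str, str] | None = None,
) -> None:
    """Write a dataset back to the matrix + metadata TSV pair.

    ``sample_tissue`` optionally overrides the per-sample tissue column;
    by default every sample carries the dataset-level tissue label, which
    round-trips exactly for unmixed datasets.
    """
    out = dataset.values.copy()
    out.index.name = "gene_id"
    # repr-based float formatting keeps the round trip exact at full precision
    out.to_csv(matrix_path, sep="\t", float_format=None)
    meta = pd.DataFrame(
        {
            "sample_id": dataset.samples,
            "replicate_group": dataset.replicate_group.values,
            "tissue": [
                (sample_tissue or {}).get(s, dataset.tissue) for s in dataset.samples
            ],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def load_collection(directory: str | Path) -> DatasetCollection:
    """Load every ``*_matrix.tsv`` / ``*_metadata.tsv`` pair in a directory."""
    directory = Path(directory)
    datasets = []
    for matrix_path in sorted(directory.glob("*_matrix.tsv")):
        dataset_id = matrix_path.name.removesuffix("_matrix.tsv")
        metadata_path = directory / f"{dataset_id}_metadata.tsv"
        if not metadata_path.exists():
            raise InputError(f"no metadata file for {matrix_path}")
        datasets.append(
            load_expression_dataset(matrix_path, metadata_path, dataset_id)
        )
    return DatasetCollection(datasets)


def write_collection(collection: DatasetCollection, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for d in collection:
        write_expression_dataset(
            d,
            directory / f"{d.dataset_id}_matrix.tsv",
            directory / f"{d.dataset_id}_metadata.tsv",
        )


def filter_collection(
    collection: DatasetCollection, min_samples: int
) -> DatasetCollection:
    """Keep datasets with at least ``min_samples`` samples, order preserved.

    The published corpus applied this with a floor of 12 samples per series.
    """
    if min_samples < 2:
        raise InputError(f"min_samples must be >= 2, got {min_samples}")
    return DatasetCollection(
        [d for d in collection if d.n_samples >= min_samples]
    )


def load_gene_sets(
    gmt_path: str | Path, universe: Iterable[str]
) -> PathwayDB:
    """Read a GMT file, restricting members to the gene universe.

    Pathways left empty by the restriction are dropped with a warning; the
    recorded per-pathway size m is the in-universe member count.
    """
    universe = set(universe)
    members: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{gmt_path}:{lineno}: malformed GMT line (<3 fields)"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(fields[2:]) & universe
            if not genes:
                logger.warning(
                    "pathway %s has no members in the gene universe; dropped", name
                )
                continue
            members[name] = genes
            descriptions[name] = desc
    return PathwayDB(members=members, descriptions=descriptions)


def write_gene_sets(db: PathwayDB, gmt_path: str | Path) -> None:
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for name in db:
            desc = db.descriptions.get(name, "")
            genes = "\t".join(sorted(db.members[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")
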