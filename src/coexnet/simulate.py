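"""Synthetic expression collections with known planted structure.

The generator emulates the kind of corpus the meta-analysis consumes: many
independent datasets (GEO-series analogs), each a genes x samples matrix of
log-scale expression, with replicate groups and a per-dataset tissue label.
Ground truth is planted three ways:

* background genes are i.i.d. Gaussian noise around gene-specific baselines;
* a planted partner g of a focal gene x is built as
  ``rho * z_x + sqrt(1 - rho^2) * eps`` against the standardized total
  signal z_x of the focal gene (noise plus any planted group shifts), so its
  population Pearson correlation with x is ``rho`` inside datasets matching
  the tissue restriction and 0 elsewhere — including for focal genes that
  are simultaneously planted as differentially expressed;
* a planted DE gene receives a between-replicate-group mean shift ``delta``
  in datasets matching its tissue restriction.

Randomness is organized as one global seed expanded into independent
substreams via ``numpy.random.SeedSequence`` spawn keys: key ``(0,)`` draws
the gene baselines, key ``(i + 1,)`` drives dataset ``i``. Adding datasets
therefore never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io import DatasetCollection, ExpressionDataset, write_collection

#: Tissue restriction meaning "plant in every dataset".
ALL_TISSUES = "all"

#: log2-scale baseline range typical of RMA-normalized arrays.
BASELINE_RANGE = (4.0, 12.0)


@dataclass(frozen=True)
class PlantedPartners:
    """Partner set of one focal gene with a target population correlation."""

    partners: tuple[str, ...]
    rho: float
    tissue: str = ALL_TISSUES


@dataclass(frozen=True)
class PlantedDE:
    """A between-group mean shift planted for one gene."""

    delta: float
    tissue: str = ALL_TISSUES


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic collection.

    Defaults mirror the corpus inclusion rule (every dataset has at least 12
    samples) with two replicate groups per dataset and unit noise on the
    log2 scale.
    """

    n_datasets: int = 20
    samples_per_dataset: int = 12
    n_groups_per_dataset: int = 2
    n_genes: int = 500
    focal_genes: tuple[str, ...] = ()
    tissue_labels: tuple[str, ...] | None = None  # cycled over datasets
    planted_partners: Mapping[str, PlantedPartners] = field(default_factory=dict)
    planted_de: Mapping[str, PlantedDE] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_labels is None:
            self.tissue_labels = ("root", "leaf")
        if self.noise_sd <= 0:
            raise InputError("noise_sd must be positive")
        group_size, rem = divmod(self.samples_per_dataset, self.n_groups_per_dataset)
        if rem or group_size < 2:
            raise InputError(
                "samples_per_dataset must divide into replicate groups of size >= 2"
            )
        universe = set(self.gene_ids())
        for x in self.focal_genes:
            if x not in universe:
                raise InputError(f"focal gene {x!r} outside the gene universe")
        for x, spec in self.planted_partners.items():
            if not -1 < spec.rho < 1:
                raise InputError(f"target |rho| must be < 1, got {spec.rho}")
            bad = (set(spec.partners) | {x}) - universe
            if bad:
                raise InputError(f"planted genes outside universe: {sorted(bad)[:5]}")
        for g in self.planted_de:
            if g not in universe:
                raise InputError(f"planted DE gene {g!r} outside the gene universe")

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def dataset_tissue(self, i: int) -> str:
        return self.tissue_labels[i % len(self.tissue_labels)]


def generate_collection(config: SimulationConfig) -> DatasetCollection:
    """Draw a full collection with the configured planted structure.

    Bit-identical under a fixed seed regardless of call order.
    """
    genes = config.gene_ids()
    gene_pos = {g: i for i, g in enumerate(genes)}
    root_ss = np.random.SeedSequence(config.seed)
    baseline_rng = np.random.default_rng(root_ss.spawn(1)[0])
    # spawn_key-addressed substreams: baselines from (0,), dataset i from (i+1,)
    lo, hi = BASELINE_RANGE
    baselines = baseline_rng.uniform(lo, hi, size=config.n_genes)

    group_size = config.samples_per_dataset // config.n_groups_per_dataset
    group_labels = np.repeat(
        [f"grp{j + 1}" for j in range(config.n_groups_per_dataset)], group_size
    )
    datasets = []
    for i in range(config.n_datasets):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(i + 1,))
        )
        tissue = config.dataset_tissue(i)
        z = rng.standard_normal((config.n_genes, config.samples_per_dataset))

        # DE offsets first: alternate groups shifted by delta (0, d, 0, d, ...)
        offsets = np.zeros_like(z)
        for g, spec in config.planted_de.items():
            if spec.tissue in (ALL_TISSUES, tissue):
                offsets[gene_pos[g]] = np.repeat(
                    [spec.delta * (j % 2) for j in range(config.n_groups_per_dataset)],
                    group_size,
                )
        signal = config.noise_sd * z + offsets

        # partners correlate with the focal gene's standardized TOTAL signal
        # (noise + DE offsets), so the population correlation stays rho even
        # for focal genes that are also planted DE
        for x, spec in config.planted_partners.items():
            if spec.tissue not in (ALL_TISSUES, tissue):
                continue
            sx = signal[gene_pos[x]]
            mu = offsets[gene_pos[x]].mean()
            sd = np.sqrt(config.noise_sd**2 + np.var(offsets[gene_pos[x]]))
            zx_hat = (sx - mu) / sd
            scale = np.sqrt(1.0 - spec.rho**2)
            for g in spec.partners:
                signal[gene_pos[g]] = config.noise_sd * (
                    spec.rho * zx_hat + scale * z[gene_pos[g]]
                ) + offsets[gene_pos[g]]
        values = baselines[:, None] + signal

        dataset_id = f"ds{i:03d}"
        samples = [f"{dataset_id}_s{j:02d}" for j in range(config.samples_per_dataset)]
        datasets.append(
            ExpressionDataset(
                dataset_id=dataset_id,
                values=pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                                    columns=samples),
                replicate_group=pd.Series(group_labels, index=samples),
                tissue=tissue,
            )
        )
    return DatasetCollection(datasets)


def ground_truth(config: SimulationConfig) -> pd.DataFrame:
    """Planted edges and DE genes as a long table (the simulation manifest)."""
    rows = []
    for x, spec in config.planted_partners.items():
        for g in spec.partners:
            rows.append(
                {"kind": "partner", "focal_id": x, "gene_id": g,
                 "tissue": spec.tissue, "value": spec.rho}
            )
    for g, spec in config.planted_de.items():
        rows.append(
            {"kind": "de", "focal_id": "", "gene_id": g,
             "tissue": spec.tissue, "value": spec.delta}
        )
    return pd.DataFrame(rows, columns=["kind", "focal_id", "gene_id", "tissue", "value"])


def config_from_mapping(raw: Mapping) -> SimulationConfig:
    """Build a config from the flat key-value form used in config files.

    ``planted_partners`` entries look like
    ``{"focal": ..., "partners": [...], "rho": ..., "tissue": ...}`` and
    ``planted_de`` entries like ``{"gene": ..., "delta": ..., "tissue": ...}``.
    """
    kwargs = dict(raw)
    partners = {}
    for entry in kwargs.pop("planted_partners", []) or []:
        partners[entry["focal"]] = PlantedPartners(
            partners=tuple(entry["partners"]),
            rho=float(entry["rho"]),
            tissue=entry.get("tissue", ALL_TISSUES),
        )
    de = {}
    for entry in kwargs.pop("planted_de", []) or []:
        de[entry["gene"]] = PlantedDE(
            delta=float(entry["delta"]), tissue=entry.get("tissue", ALL_TISSUES)
        )
    if "focal_genes" in kwargs:
        kwargs["focal_genes"] = tuple(kwargs["focal_genes"])
    if "tissue_labels" in kwargs and kwargs["tissue_labels"] is not None:
        kwargs["tissue_labels"] = tuple(kwargs["tissue_labels"])
    return SimulationConfig(planted_partners=partners, planted_de=de, **kwargs)


def simulate_to_directory(config: SimulationConfig, directory: str | Path
                          ) -> DatasetCollection:
    """Generate a collection, write its TSV pairs and ground-truth manifest."""
    directory = Path(directory)
    collection = generate_collection(config)
    write_collection(collection, directory)
    ground_truth(config).to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    return collection
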