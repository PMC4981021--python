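"""End-to-end orchestration: collection -> DE -> coexpression -> networks.

Stages communicate through on-disk TSVs inside the run's output directory so
each stage can be re-run and inspected independently; a JSON manifest
records the configuration, seed, per-stage row counts and runtimes. Reruns
with an identical config and seed reproduce identical outputs.

Stage order: collect, filter, de, coexpress, pathway, network, enrich.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import coexpression, diffexpr, enrichment, network, pathway, simulate
from .errors import CoexnetError, InputError
from .io import (
    DatasetCollection,
    PathwayDB,
    filter_collection,
    load_collection,
    load_gene_sets,
    write_gene_sets,
)

logger = logging.getLogger(__name__)

STAGES = ("collect", "filter", "de", "coexpress", "pathway", "network", "enrich")


@dataclass
class PipelineConfig:
    """One run's parameters; defaults follow the published analysis."""

    focal_genes: tuple[str, ...]
    input_dir: str | None = None          # load a collection from disk ...
    simulation: Mapping | None = None     # ... or generate one
    gene_sets: str | None = None          # GMT path; random sets if absent
    n_random_pathways: int = 50
    random_pathway_sizes: tuple[int, int] = (5, 30)
    min_samples: int = 12
    de_threshold: float = diffexpr.DEFAULT_Q_THRESHOLD
    top_k_genes: int = network.DEFAULT_TOP_K_GENES
    top_pathways: int = network.DEFAULT_TOP_PATHWAYS
    min_support: int = network.DEFAULT_MIN_SUPPORT
    B: int = pathway.DEFAULT_B
    rank_by_abs: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.focal_genes = tuple(self.focal_genes)
        if not self.focal_genes:
            raise InputError("focal_genes must be nonempty")
        if self.input_dir is None and self.simulation is None:
            raise InputError("config needs either input_dir or a simulation section")
        if self.seed is None:
            raise InputError("seed is mandatory")
        for name in ("min_samples", "top_k_genes", "top_pathways",
                     "min_support", "B"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be >= 1")
        if not 0 < self.de_threshold <= 1:
            raise InputError("de_threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError(f"{path}: config must be a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    status: str = "RUNNING"

    def record(self, stage: str, rows: int, seconds: float) -> None:
        self.stages.append(
            {"stage": stage, "rows": rows, "seconds": round(seconds, 3)}
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _random_pathway_db(
    universe, n_pathways: int, sizes: tuple[int, int], seed: int
) -> PathwayDB:
    """Uniform random gene sets over the universe (synthetic-run stand-in
    for a curated pathway database)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10_000,)))
    lo, hi = sizes
    genes = np.asarray(list(universe))
    members = {}
    for i in range(n_pathways):
        m = int(rng.integers(lo, hi + 1))
        draw = rng.choice(genes.size, size=min(m, genes.size), replace=False)
        members[f"RP{i:04d}"] = frozenset(genes[draw])
    return PathwayDB(members=members,
                     descriptions={p: "random gene set" for p in members})


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute all stages, writing every intermediate file under ``out_dir``.

    On a stage failure, partial outputs are kept, a ``FAILED`` marker file
    names the stage, and the error is re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config), config_hash=config.digest(), seed=config.seed
    )
    stage = "collect"
    try:
        # --- collect
        t0 = time.perf_counter()
        if config.input_dir is not None:
            collection = load_collection(config.input_dir)
        else:
            sim_cfg = simulate.config_from_mapping(
                {"seed": config.seed, **dict(config.simulation)}
            )
            collection = simulate.simulate_to_directory(sim_cfg, out / "collection")
        manifest.record("collect", len(collection), time.perf_counter() - t0)

        # --- filter
        stage = "filter"
        t0 = time.perf_counter()
        collection = filter_collection(collection, config.min_samples)
        if len(collection) == 0:
            raise InputError(
                f"no dataset has >= {config.min_samples} samples; nothing to analyze"
            )
        universe = collection.gene_universe
        missing_focal = set(config.focal_genes) - set(universe)
        if missing_focal:
            raise InputError(f"focal genes not measured: {sorted(missing_focal)[:5]}")
        manifest.record("filter", len(collection), time.perf_counter() - t0)

        # --- gene sets (needed by pathway + enrich)
        if config.gene_sets is not None:
            db = load_gene_sets(config.gene_sets, universe)
        else:
            db = _random_pathway_db(
                universe, config.n_random_pathways,
                tuple(config.random_pathway_sizes), config.seed,
            )
            write_gene_sets(db, out / "gene_sets.gmt")

        # --- de
        stage = "de"
        t0 = time.perf_counter()
        de_results = diffexpr.de_results_for_collection(
            collection, config.de_threshold
        )
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        for dataset_id, res in de_results.items():
            res.table.rename_axis("gene_id").to_csv(
                de_dir / f"{dataset_id}_de.tsv", sep="\t"
            )
        freq = diffexpr.de_frequency(list(de_results.values()), collection)
        freq.to_csv(out / "de_frequency.tsv", sep="\t", index=False)
        manifest.record("de", len(freq), time.perf_counter() - t0)

        # --- coexpress
        stage = "coexpress"
        t0 = time.perf_counter()
        focal = list(config.focal_genes)
        table_all = coexpression.average_coexpression(collection, focal, "all")
        frames = [table_all.to_frame()]
        for tissue in collection.tissues():
            frames.append(
                coexpression.average_coexpression(collection, focal, tissue)
                .to_frame()
            )
        coex_long = pd.concat(frames, ignore_index=True)
        coex_long.to_csv(out / "coexpression.tsv", sep="\t", index=False)
        manifest.record("coexpress", len(coex_long), time.perf_counter() - t0)

        # --- pathway
        stage = "pathway"
        t0 = time.perf_counter()
        scores = []
        for xi, x in enumerate(focal):
            for ti, tissue in enumerate(collection.tissues()):
                sub_seed = int(
                    np.random.SeedSequence(
                        config.seed, spawn_key=(20_000 + xi, ti)
                    ).generate_state(1)[0] % (2**31)
                )
                scores.extend(
                    pathway.score_pathways(
                        x, db, tissue, collection, de_results,
                        B=config.B, seed=sub_seed,
                    )
                )
        score_frame = pathway.scores_to_frame(scores)
        score_frame.to_csv(out / "pathway_scores.tsv", sep="\t", index=False)
        manifest.record("pathway", len(score_frame), time.perf_counter() - t0)

        # --- network
        stage = "network"
        t0 = time.perf_counter()
        gene_net = network.build_gene_network(
            table_all, focal, config.top_k_genes, config.rank_by_abs
        )
        pathway_net = network.build_pathway_network(
            scores, config.top_pathways, config.min_support
        )
        for name, net in (("gene_network", gene_net),
                          ("pathway_network", pathway_net)):
            network.export_network(net, out / f"{name}.graphml", "graphml")
            network.export_network(net, out / f"{name}.tsv", "tsv")
            network.export_network(net, out / f"{name}.sif", "sif")
        manifest.record(
            "network",
            gene_net.number_of_edges() + pathway_net.number_of_edges(),
            time.perf_counter() - t0,
        )

        # --- enrich
        stage = "enrich"
        t0 = time.perf_counter()
        members = {n for n, d in gene_net.nodes(data=True) if d["kind"] == "gene"}
        enrich_table = enrichment.enrich(
            members & set(universe), config.focal_genes, db, universe
        )
        enrich_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest.record("enrich", len(enrich_table), time.perf_counter() - t0)

        manifest.status = "COMPLETE"
        manifest.write(out / "manifest.json")
        return manifest
    except Exception as exc:
        manifest.status = f"FAILED at stage {stage}"
        manifest.write(out / "manifest.json")
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        if isinstance(exc, CoexnetError):
            raise CoexnetError(f"stage {stage}: {exc}") from exc
        raise
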