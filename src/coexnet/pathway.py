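"""Transporter-to-pathway tissue-specific coexpression with an empirical null.

A pathway score R'_{x,p} is the mean, over the pathway's member genes k, of
the tissue-stratified gene-level weights R'_{x,k} — computed over only the
tissue-matched datasets in which the focal gene x itself is differentially
expressed (the context restriction: a correlation pattern is trusted only
where x is actually responding).

Significance follows the randomization recipe: each of B replicates replaces
the pathway by m genes drawn uniformly without replacement from the gene
universe (minus x, whose self-correlation of 1 would inflate the null) and
rescores on the same restricted dataset set. The classic rule — significant
when no null score exceeds the observed one, with B = 100 — is kept as the
binary ``significant`` flag; the numeric ``empirical_p`` uses the
(exceed + 1) / (B + 1) convention so it is never zero. Ties do not count as
exceeding. Comparison is on signed scores.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coexpression import average_coexpression
from .diffexpr import DEResult
from .errors import InputError
from .io import DatasetCollection, PathwayDB

DEFAULT_B = 100


@dataclass
class PathwayScore:
    """Score of one (focal gene, pathway, tissue) triple.

    ``m`` is the pathway's in-universe size, ``m_used`` the members that had
    a defined gene-level weight and entered the mean. Null fields are None
    until :func:`permutation_null` fills them.
    """

    focal_id: str
    pathway_id: str
    tissue: str
    score: float
    m: int
    m_used: int
    n_datasets_used: int
    B: int | None = None
    null_exceed_count: int | None = None
    empirical_p: float | None = None
    significant: bool | None = None


def restricted_datasets(
    x: str,
    tissue: str,
    collection: DatasetCollection,
    de_results: Mapping[str, DEResult],
) -> DatasetCollection:
    """Tissue-matched datasets in which the focal gene is flagged DE."""
    kept = [
        d for d in collection
        if d.tissue == tissue
        and d.dataset_id in de_results
        and de_results[d.dataset_id].testable
        and de_results[d.dataset_id].is_de(x)
    ]
    return DatasetCollection(kept)


def gene_profile(
    x: str,
    tissue: str,
    collection: DatasetCollection,
    de_results: Mapping[str, DEResult],
) -> tuple[pd.Series, int]:
    """Gene-level tissue-specific weights R'_{x,k} on the restricted datasets.

    Returns the weight series over the collection's gene universe (NaN where
    undefined) and the number of datasets used. An empty restriction yields
    an all-NaN series and 0.
    """
    restricted = restricted_datasets(x, tissue, collection, de_results)
    if len(restricted) == 0:
        return pd.Series(np.nan, index=collection.gene_universe), 0
    table = average_coexpression(restricted, [x], stratum="all")
    profile = table.R.iloc[0].reindex(collection.gene_universe)
    return profile, len(restricted)


def _mean_over_members(profile: pd.Series, members: Iterable[str]) -> tuple[float, int]:
    vals = profile.reindex(list(members)).to_numpy(dtype=float)
    defined = np.isfinite(vals)
    if not defined.any():
        return float("nan"), 0
    return float(vals[defined].mean()), int(defined.sum())


def pathway_score(
    x: str,
    pathway_id: str,
    members: Iterable[str],
    tissue: str,
    collection: DatasetCollection,
    de_results: Mapping[str, DEResult],
    profile: tuple[pd.Series, int] | None = None,
) -> PathwayScore | None:
    """Score one pathway for one focal gene in one tissue.

    Members without a defined gene-level weight are dropped from the mean
    (``m_used`` < ``m``). Returns None when no dataset survives the
    restriction or no member has a defined weight.
    """
    members = sorted(set(members))
    if not members:
        raise InputError(f"pathway {pathway_id!r} is empty")
    if profile is None:
        profile = gene_profile(x, tissue, collection, de_results)
    weights, n_used = profile
    if n_used == 0:
        return None
    score, m_used = _mean_over_members(weights, members)
    if m_used == 0:
        return None
    return PathwayScore(
        focal_id=x, pathway_id=pathway_id, tissue=tissue, score=score,
        m=len(members), m_used=m_used, n_datasets_used=n_used,
    )


def permutation_null(
    x: str,
    observed: PathwayScore,
    universe: Iterable[str],
    B: int,
    seed: int | np.random.Generator,
    collection: DatasetCollection,
    de_results: Mapping[str, DEResult],
    profile: tuple[pd.Series, int] | None = None,
) -> PathwayScore:
    """Fill the null fields of an observed score with B random-set replicates.

    Each replicate draws m genes uniformly without replacement from
    ``universe`` minus the focal gene and is scored on the same restricted
    datasets (the precomputed ``profile`` may be passed to avoid recomputing
    the gene-level weights). Reproducible from ``seed``.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    pool = np.array(sorted(set(universe) - {x}))
    if observed.m > pool.size:
        raise InputError(
            f"cannot draw {observed.m} genes from a universe of {pool.size}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if profile is None:
        profile = gene_profile(x, observed.tissue, collection, de_results)
    weights, _ = profile
    pool_weights = weights.reindex(pool).to_numpy(dtype=float)
    exceed = 0
    for _ in range(B):
        draw = rng.choice(pool.size, size=observed.m, replace=False)
        vals = pool_weights[draw]
        defined = vals[np.isfinite(vals)]
        if defined.size and defined.mean() > observed.score:
            exceed += 1
    return replace(
        observed,
        B=B,
        null_exceed_count=exceed,
        empirical_p=(exceed + 1) / (B + 1),
        significant=(exceed == 0),
    )


def score_pathways(
    x: str,
    db: PathwayDB,
    tissue: str,
    collection: DatasetCollection,
    de_results: Mapping[str, DEResult],
    B: int = DEFAULT_B,
    seed: int = 0,
) -> list[PathwayScore]:
    """Score and permutation-test every pathway for one focal gene and tissue.

    The gene-level profile is computed once and shared between the observed
    scores and their nulls; per-pathway RNG substreams are spawned from
    ``seed`` keyed on a hash of the pathway ID, so results do not depend on
    pathway iteration order.
    """
    profile = gene_profile(x, tissue, collection, de_results)
    if profile[1] == 0:
        return []
    universe = collection.gene_universe
    out = []
    for pathway_id in db:
        obs = pathway_score(
            x, pathway_id, db.members[pathway_id], tissue,
            collection, de_results, profile=profile,
        )
        if obs is None:
            continue
        key = int.from_bytes(
            hashlib.sha256(pathway_id.encode()).digest()[:4], "big"
        )
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
        out.append(
            permutation_null(
                x, obs, universe, B, rng, collection, de_results, profile=profile
            )
        )
    return out


def scores_to_frame(scores: Sequence[PathwayScore]) -> pd.DataFrame:
    """Long TSV-ready table of (possibly null-tested) pathway scores."""
    rows = [
        {
            "focal_id": s.focal_id, "pathway_id": s.pathway_id, "tissue": s.tissue,
            "score": s.score, "m": s.m, "m_used": s.m_used,
            "n_datasets_used": s.n_datasets_used, "B": s.B,
            "null_exceed": s.null_exceed_count, "empirical_p": s.empirical_p,
            "significant": s.significant,
        }
        for s in scores
    ]
    return pd.DataFrame(
        rows,
        columns=["focal_id", "pathway_id", "tissue", "score", "m", "m_used",
                 "n_datasets_used", "B", "null_exceed", "empirical_p",
                 "significant"],
    )
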