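"""Hypergeometric over-representation of network members in gene sets.

The query is the set of network member genes with the focal genes removed
(the published analysis tested the neighborhood after deleting the 17
transporters themselves), tested one-sidedly for over-representation against
each pathway with the hypergeometric upper tail P(X >= a) on the measured
gene universe, then BH-adjusted across pathways.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .errors import InputError
from .io import PathwayDB

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["pathway_id", "description", "a", "q", "m", "N", "p", "q_bh"]


def enrich(
    query: Iterable[str],
    focal: Iterable[str],
    db: PathwayDB,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation rows sorted by ascending p.

    Columns: pathway_id, description, a (overlap), q (query size after focal
    removal), m (in-universe pathway size), N (universe size), p
    (hypergeometric upper tail), q_bh (BH across tested pathways).
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise InputError("query genes must lie inside the universe")
    query_prime = query - set(focal)
    if not query_prime:
        logger.warning("query is empty after removing focal genes")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    N = len(universe)
    q_size = len(query_prime)
    rows = []
    for pathway_id in db:
        members = db.members[pathway_id] & universe
        m = len(members)
        if m == 0:
            continue
        a = len(members & query_prime)
        p = float(stats.hypergeom.sf(a - 1, N, m, q_size))
        rows.append(
            {"pathway_id": pathway_id,
             "description": db.descriptions.get(pathway_id, ""),
             "a": a, "q": q_size, "m": m, "N": N, "p": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if len(out):
        out["q_bh"] = bh_fdr(out["p"])
        out = out.sort_values(["p", "pathway_id"]).reset_index(drop=True)
    else:
        out["q_bh"] = []
    return out
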