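"""Per-dataset differential expression by one-way ANOVA with BH-FDR.

Each dataset is tested on its own: for every gene, a fixed-effects one-way
ANOVA across the dataset's replicate groups asks whether between-group
variation exceeds within-group variation; Benjamini-Hochberg adjustment is
applied within the dataset's family of testable genes, and a gene is flagged
differentially expressed (DE) when its q-value falls below the threshold
(default 0.001). Cross-dataset behaviour is summarized as per-tissue DE
frequencies: the fraction of a tissue's testable datasets in which a gene
was flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io import DatasetCollection, ExpressionDataset, MIXED_TISSUE

logger = logging.getLogger(__name__)

DEFAULT_Q_THRESHOLD = 1e-3


@dataclass
class DEResult:
    """Per-gene ANOVA outcome for one dataset.

    ``table`` is indexed by gene ID with columns ``F``, ``p``, ``q``,
    ``is_DE``; untestable genes (zero total variance, or skipped) carry NaN
    statistics and ``is_DE = False``. ``testable`` is False when the dataset
    has fewer than two usable replicate groups, in which case downstream
    tallies must exclude the whole dataset.
    """

    dataset_id: str
    table: pd.DataFrame
    q_threshold: float = DEFAULT_Q_THRESHOLD
    testable: bool = True

    def is_de(self, gene: str) -> bool:
        return gene in self.table.index and bool(self.table.loc[gene, "is_DE"])


def anova_pvalue(values_by_group: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F statistic and upper-tail p-value.

    Degenerate inputs follow fixed conventions: when every group is constant
    and the means agree the statistic is 0/0 and p = 1; when within-group
    variance is zero but means differ, F is infinite and p = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise InputError("ANOVA requires at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InputError("every replicate group needs at least 2 samples")
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = np.array([g.mean() for g in groups])
    if ssw == 0.0:
        if np.ptp(means) == 0.0:
            return float("nan"), 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_flags(
    dataset: ExpressionDataset, q_threshold: float = DEFAULT_Q_THRESHOLD
) -> DEResult:
    """ANOVA every gene of a dataset across its replicate groups and flag DE.

    BH adjustment runs within the dataset over all testable genes. A dataset
    with fewer than two replicate groups of two or more samples is marked
    untestable.
    """
    groups = [
        np.flatnonzero((dataset.replicate_group == g).to_numpy())
        for g in dict.fromkeys(dataset.replicate_group)
    ]
    groups = [idx for idx in groups if idx.size >= 2]
    genes = dataset.genes
    table = pd.DataFrame(
        {"F": np.nan, "p": np.nan, "q": np.nan, "is_DE": False}, index=genes
    )
    if len(groups) < 2:
        logger.warning(
            "dataset %s has <2 usable replicate groups; untestable",
            dataset.dataset_id,
        )
        return DEResult(dataset.dataset_id, table, q_threshold, testable=False)

    values = dataset.values.to_numpy()
    blocks = [values[:, idx] for idx in groups]
    ssw = sum(((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for b in blocks)
    sst = ((values - values.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)

    testable = sst > 0
    F = np.full(len(genes), np.nan)
    p = np.full(len(genes), np.nan)
    # genes with within-group variance but possibly zero between: regular ANOVA
    regular = testable & (ssw > 0)
    if regular.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            F[regular], p[regular] = stats.f_oneway(
                *[b[regular] for b in blocks], axis=1
            )
    # variance entirely between groups: infinitely strong separation
    degenerate = testable & (ssw == 0)
    if degenerate.any():
        logger.warning(
            "dataset %s: %d genes with zero within-group variance flagged p=0",
            dataset.dataset_id, int(degenerate.sum()),
        )
        F[degenerate] = np.inf
        p[degenerate] = 0.0

    table.loc[testable, "F"] = F[testable]
    table.loc[testable, "p"] = p[testable]
    table.loc[testable, "q"] = bh_fdr(p[testable])
    table["is_DE"] = table["q"] < q_threshold
    return DEResult(dataset.dataset_id, table, q_threshold, testable=True)


def de_frequency(
    results: Sequence[DEResult],
    collection: DatasetCollection,
    tissues: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per (gene, tissue) DE frequency across a tissue's testable datasets.

    Returns a long table with columns ``gene_id``, ``tissue``, ``n_de``,
    ``n_datasets``, ``frequency``. A dataset contributes to a gene's
    denominator only if it is testable and measures the gene; tissues with
    zero testable datasets are omitted with a warning.
    """
    by_id = {r.dataset_id: r for r in results}
    unknown = set(by_id) - {d.dataset_id for d in collection}
    if unknown:
        raise InputError(f"DE results for unknown datasets: {sorted(unknown)[:5]}")
    if tissues is None:
        tissues = collection.tissues()
    rows = []
    for tissue in tissues:
        members = [
            d for d in collection
            if d.tissue == tissue and d.dataset_id in by_id
            and by_id[d.dataset_id].testable
        ]
        if not members:
            logger.warning("tissue %s has no testable datasets; omitted", tissue)
            continue
        n_de: dict[str, int] = {}
        n_total: dict[str, int] = {}
        for d in members:
            res = by_id[d.dataset_id]
            flagged = res.table["is_DE"]
            for g in d.genes:
                n_total[g] = n_total.get(g, 0) + 1
                if flagged.get(g, False):
                    n_de[g] = n_de.get(g, 0) + 1
        for g, denom in n_total.items():
            num = n_de.get(g, 0)
            rows.append(
                {"gene_id": g, "tissue": tissue, "n_de": num,
                 "n_datasets": denom, "frequency": num / denom}
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "n_de", "n_datasets", "frequency"]
    )


def de_results_for_collection(
    collection: DatasetCollection, q_threshold: float = DEFAULT_Q_THRESHOLD
) -> dict[str, DEResult]:
    """Convenience: ``de_flags`` over every dataset, keyed by dataset ID."""
    return {d.dataset_id: de_flags(d, q_threshold) for d in collection}
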