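"""Dataset-averaged and tissue-stratified Pearson coexpression.

Each dataset contributes one coexpression weight r_k per (focal gene x,
gene i) pair: the sample Pearson correlation over all of the dataset's
samples, replicate groups pooled. The meta-analytic weight R_{x,i} is the
arithmetic mean of the r_k over the datasets in which the pair is defined
(both genes present with nonzero variance); its tissue-stratified variant
R'_{x,i} averages only over datasets carrying a given tissue label. The
number of contributing datasets is recorded as the pair's support.

Weights are kept signed; whether ranking downstream uses signed or absolute
values is a network-assembly policy, not a property of the average.

``critical_pcc`` gives the smallest |r| significant at a two-sided level
alpha for a given sample size — the usual yardstick for why a fixed PCC
cutoff cannot be shared across datasets of different size (r = 0.6 is the
bar at n = 10 but 0.2 at n = 100, at alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io import DatasetCollection, ExpressionDataset

ALL_STRATUM = "all"


@dataclass
class CoexpressionTable:
    """Averaged coexpression weights for one stratum.

    ``R`` and ``support`` are focal x gene frames over the collection's
    universe; undefined pairs hold NaN weight and zero support.
    """

    R: pd.DataFrame
    support: pd.DataFrame
    stratum: str = ALL_STRATUM

    def to_frame(self) -> pd.DataFrame:
        """Long format: focal_id, gene_id, stratum, R, support (defined pairs)."""
        long = self.R.stack().rename("R").reset_index()
        long.columns = ["focal_id", "gene_id", "R"]
        sup = self.support.stack().reset_index()
        sup.columns = ["focal_id", "gene_id", "support"]
        long = long.merge(sup, on=["focal_id", "gene_id"])
        long.insert(2, "stratum", self.stratum)
        return long


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("pearson requires two equal-length vectors")
    if x.size < 3:
        raise InputError("pearson requires length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def per_dataset_correlations(
    dataset: ExpressionDataset, focal: Sequence[str]
) -> pd.DataFrame:
    """The r_k weights of one dataset: focal x gene frame of correlations.

    Computed over all samples of the dataset regardless of replicate group.
    Focal genes absent from the dataset yield all-NaN rows; zero-variance
    genes (focal or partner) yield NaN entries, which downstream averaging
    treats as missing.
    """
    values = dataset.values.to_numpy(dtype=float)
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = centered / norms[:, None]
    unit[norms == 0] = np.nan

    gene_pos = {g: i for i, g in enumerate(dataset.genes)}
    out = np.full((len(focal), len(dataset.genes)), np.nan)
    present = [(row, gene_pos[f]) for row, f in enumerate(focal) if f in gene_pos]
    if present:
        rows, pos = zip(*present)
        out[list(rows)] = np.clip(unit[list(pos)] @ unit.T, -1.0, 1.0)
    return pd.DataFrame(out, index=pd.Index(focal, name="focal_id"),
                        columns=dataset.genes)


def average_coexpression(
    collection: DatasetCollection,
    focal: Sequence[str],
    stratum: str = ALL_STRATUM,
) -> CoexpressionTable:
    """Mean per-dataset weight per (focal, gene) pair with support counts.

    ``stratum="all"`` averages over every dataset in the collection; a
    tissue label restricts to datasets carrying that label. The mean runs
    over datasets where the pair's weight is defined; pairs never defined
    get NaN and support 0.
    """
    if len(collection) == 0:
        raise InputError("empty collection")
    if stratum == ALL_STRATUM:
        datasets = list(collection)
    else:
        datasets = [d for d in collection if d.tissue == stratum]
        if not datasets:
            raise InputError(f"no datasets with tissue {stratum!r}")
    universe = collection.gene_universe
    acc = np.zeros((len(focal), len(universe)))
    count = np.zeros((len(focal), len(universe)), dtype=int)
    col_pos = {g: i for i, g in enumerate(universe)}
    for d in datasets:
        r = per_dataset_correlations(d, focal).to_numpy()
        cols = [col_pos[g] for g in d.genes]
        defined = np.isfinite(r)
        acc_cols = acc[:, cols]
        acc_cols[defined] += r[defined]
        acc[:, cols] = acc_cols
        cnt_cols = count[:, cols]
        cnt_cols[defined] += 1
        count[:, cols] = cnt_cols
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, acc / np.maximum(count, 1), np.nan)
    idx = pd.Index(focal, name="focal_id")
    return CoexpressionTable(
        R=pd.DataFrame(mean, index=idx, columns=universe),
        support=pd.DataFrame(count, index=idx, columns=universe),
        stratum=stratum,
    )


def critical_pcc(n: int, alpha: float) -> float:
    """Smallest |r| significant at two-sided level alpha for sample size n.

    Under the bivariate-normal null, t = r sqrt(n-2) / sqrt(1-r^2) follows
    Student's t with n-2 degrees of freedom; inverting at the two-sided
    critical value t* gives r* = t* / sqrt(t*^2 + n - 2).
    """
    if n < 3:
        raise InputError("critical_pcc requires n >= 3")
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")
    t_star = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return float(t_star / np.sqrt(t_star**2 + n - 2))
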