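"""Value-counting hit calling with cumulative-binomial false discovery rates.

The statistic deliberately ignores effect sizes: a replicate either crosses
a threshold or it does not, and a candidate is an shRNA that crosses in at
least *k* of *n* replicates.  This makes the call robust to outlier arrays.
Per-replicate thresholds are mean +/- one standard deviation of the
log-ratio column; the chance of a fully null shRNA crossing in >= k of n
replicates is a binomial tail, which multiplied by the number of shRNAs
tested gives the expected count of false candidates, and dividing that by
the observed count gives the FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AnnotationMap

__all__ = [
    "Thresholds",
    "CandidateSet",
    "replicate_thresholds",
    "count_exceedances",
    "binomial_tail",
    "exceedance_rates",
    "call_candidates",
    "fdr_table",
]

_DIRECTIONS = ("over", "under")


@dataclass
class Thresholds:
    """Per-replicate calling thresholds: mean +/- sample SD over all rows."""

    mean: np.ndarray
    sd: np.ndarray
    columns: list[str]

    @property
    def upper(self) -> np.ndarray:
        return self.mean + self.sd

    @property
    def lower(self) -> np.ndarray:
        return self.mean - self.sd


@dataclass
class CandidateSet:
    """shRNAs meeting a k-of-n exceedance criterion in one direction.

    ``gene_multiplicity`` counts, per gene, how many distinct significant
    shRNAs target it (only populated when an annotation is supplied).
    """

    direction: str
    k: int
    n: int
    shrnas: list[str]
    gene_multiplicity: dict[str, int] = field(default_factory=dict)

    @property
    def criterion(self) -> str:
        return f"{self.k}of{self.n}"

    def __len__(self) -> int:
        return len(self.shrnas)

    def genes(self) -> list[str]:
        return sorted(self.gene_multiplicity)


def replicate_thresholds(ratios: pd.DataFrame) -> Thresholds:
    """Mean and sample SD (ddof=1) per replicate column, over all rows.

    A constant column yields sd 0 with a warning; its thresholds collapse
    to the mean and nothing in that replicate can strictly exceed them.
    """
    if len(ratios) < 2:
        raise ValueError("need at least 2 rows to compute thresholds")
    values = ratios.to_numpy(float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn("constant replicate column: thresholds collapse to the mean")
    return Thresholds(mean=mean, sd=sd, columns=list(ratios.columns))


def count_exceedances(ratios: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Per-row counts of replicates strictly above/below the thresholds.

    Values exactly equal to a threshold count as non-exceeding.  Returns a
    DataFrame indexed like ``ratios`` with columns ``k_over``, ``k_under``
    and ``n``.
    """
    values = ratios.to_numpy(float)
    if values.shape[1] != len(thresholds.mean):
        raise ValueError("ratio matrix and thresholds have different replicate counts")
    k_over = (values > thresholds.upper).sum(axis=1)
    k_under = (values < thresholds.lower).sum(axis=1)
    return pd.DataFrame(
        {"k_over": k_over, "k_under": k_under, "n": values.shape[1]}, index=ratios.index
    )


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability p must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p))


def exceedance_rates(ratios: pd.DataFrame, thresholds: Thresholds) -> tuple[float, float]:
    """Pooled fraction of matrix cells above the upper / below the lower threshold.

    These are the per-replicate success probabilities ``p`` fed to the
    binomial null (the screen reported roughly 13% above and 14% below).
    """
    values = ratios.to_numpy(float)
    if values.shape[1] != len(thresholds.mean):
        raise ValueError("ratio matrix and thresholds have different replicate counts")
    cells = values.size
    p_over = float((values > thresholds.upper).sum() / cells)
    p_under = float((values < thresholds.lower).sum() / cells)
    return p_over, p_under


def call_candidates(
    counts: pd.DataFrame,
    k: int,
    direction: str,
    annotation: AnnotationMap | None = None,
) -> CandidateSet:
    """Select rows whose exceedance count in ``direction`` is >= k.

    With an annotation, the per-gene multiplicity (number of distinct
    significant shRNAs targeting the gene) is attached — genes found by
    more than one shRNA carry extra weight downstream.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    n = int(counts["n"].iloc[0]) if len(counts) else 0
    if len(counts) and k > n:
        raise ValueError(f"criterion k={k} exceeds replicate count n={n}")
    col = "k_over" if direction == "over" else "k_under"
    members = list(counts.index[counts[col] >= k])
    multiplicity: dict[str, int] = {}
    if annotation is not None:
        for shrna in members:
            gene = annotation.gene_of(shrna)
            if gene is not None:
                multiplicity[gene] = multiplicity.get(gene, 0) + 1
    return CandidateSet(direction=direction, k=k, n=n, shrnas=members,
                        gene_multiplicity=multiplicity)


def fdr_table(
    candidate_sets: list[CandidateSet],
    p_over: float,
    p_under: float,
    n_tested: int,
) -> pd.DataFrame:
    """Expected chance discoveries and FDR per (direction, criterion).

    ``expected = n_tested * P(X >= k)`` under the binomial null with the
    pooled exceedance rate for the direction; ``fdr = expected / found``
    (NaN when nothing was found).
    """
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    rows = []
    for cs in candidate_sets:
        p = p_over if cs.direction == "over" else p_under
        tail = binomial_tail(cs.k, cs.n, p)
        expected = n_tested * tail
        found = len(cs)
        fdr = expected / found if found > 0 else float("nan")
        rows.append(
            {
                "direction": cs.direction,
                "criterion": cs.criterion,
                "p": p,
                "p_tail": tail,
                "n_tested": n_tested,
                "expected": expected,
                "found": found,
                "fdr": fdr,
            }
        )
    return pd.DataFrame(rows)
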