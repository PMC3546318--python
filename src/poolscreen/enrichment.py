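"""GO-term enrichment among screen candidates, with a scrambled-replicate null.

Enrichment uses the same binomial machinery as hit calling: for a term
annotating ``k`` candidate genes out of ``n`` tested genes, the tail
probability P(X >= k) is computed with a background success rate ``p``
equal to the candidates' overall share of GO associations.  Because the
terms are many and correlated, the P cutoff is calibrated empirically: the
log-ratio columns are scrambled row-wise (destroying replicate concordance
while preserving each column's value multiset), the whole calling +
enrichment pipeline is re-run on each scramble, and the mean number of
null terms passing a cutoff over the observed number estimates the FDR at
that cutoff.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationMap, GoMap
from .value_counting import (
    binomial_tail,
    call_candidates,
    count_exceedances,
    replicate_thresholds,
)

__all__ = [
    "term_counts",
    "background_rate",
    "term_pvalue",
    "enrich",
    "scramble_replicates",
    "calibrate_cutoff",
]


def _weight(gene: str, weights: dict[str, int] | None) -> int:
    return 1 if weights is None else int(weights.get(gene, 1))


def term_counts(
    candidate_genes: Iterable[str],
    all_genes: Iterable[str],
    go_map: GoMap,
    min_genes: int = 3,
    weights: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-term association counts among candidates (k) and all tested genes (n).

    Only terms with ``k >= min_genes`` (default 3) are returned.  By
    default each gene contributes once per term; passing ``weights`` (e.g.
    the number of shRNAs per gene) switches the counting unit from
    distinct genes to association occurrences.
    """
    candidates = set(candidate_genes)
    universe = set(all_genes)
    stray = candidates - universe
    if stray:
        raise ValueError(f"candidate gene(s) not in the tested universe: {sorted(stray)[:5]}")
    k_by_term: dict[str, int] = {}
    n_by_term: dict[str, int] = {}
    for gene in universe:
        w = _weight(gene, weights)
        for term in go_map.terms_of(gene):
            n_by_term[term] = n_by_term.get(term, 0) + w
            if gene in candidates:
                k_by_term[term] = k_by_term.get(term, 0) + w
    rows = [
        {
            "go_id": term,
            "k": k,
            "n": n_by_term[term],
            "description": go_map.descriptions.get(term, ""),
        }
        for term, k in sorted(k_by_term.items())
        if k >= min_genes
    ]
    return pd.DataFrame(rows, columns=["go_id", "k", "n", "description"])


def background_rate(
    candidate_genes: Iterable[str],
    all_genes: Iterable[str],
    go_map: GoMap,
    weights: dict[str, int] | None = None,
) -> float:
    """Overall candidate share of GO associations.

    ``p`` = (sum over all terms of candidate associations) / (sum over all
    terms of associations among tested genes); no minimum-count filter is
    applied in either sum.
    """
    candidates = set(candidate_genes)
    universe = set(all_genes)
    stray = candidates - universe
    if stray:
        raise ValueError(f"candidate gene(s) not in the tested universe: {sorted(stray)[:5]}")
    num = sum(_weight(g, weights) * len(go_map.terms_of(g)) for g in candidates)
    den = sum(_weight(g, weights) * len(go_map.terms_of(g)) for g in universe)
    if den == 0:
        raise ValueError("no GO associations among the tested genes")
    return num / den


def term_pvalue(k: int, n: int, p: float) -> float:
    """Binomial tail P(X >= k), X ~ Binomial(n, p), for one term."""
    return binomial_tail(k, n, p)


def enrich(
    candidate_genes: Iterable[str],
    all_genes: Iterable[str],
    go_map: GoMap,
    min_genes: int = 3,
    weights: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Full per-term enrichment table with binomial tail P per term."""
    counts = term_counts(candidate_genes, all_genes, go_map, min_genes, weights)
    if counts.empty:
        counts["p_value"] = pd.Series(dtype=float)
        return counts
    p = background_rate(candidate_genes, all_genes, go_map, weights)
    counts["p_value"] = [term_pvalue(k, n, p) for k, n in zip(counts["k"], counts["n"])]
    return counts.sort_values("p_value", kind="stable").reset_index(drop=True)


def scramble_replicates(ratios: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Independently permute the row order of every replicate column.

    Each column keeps its exact value multiset, but any concordance between
    replicates — the very thing value counting measures — is destroyed.
    """
    values = ratios.to_numpy(float).copy()
    for j in range(values.shape[1]):
        values[:, j] = values[rng.permutation(values.shape[0]), j]
    return pd.DataFrame(values, index=ratios.index, columns=ratios.columns)


def _pipeline_pvalues(
    ratios: pd.DataFrame,
    annotation: AnnotationMap,
    go_map: GoMap,
    k: int,
    direction: str,
    min_genes: int,
) -> np.ndarray:
    """Candidate calling + enrichment on one (possibly scrambled) matrix."""
    thresholds = replicate_thresholds(ratios)
    counts = count_exceedances(ratios, thresholds)
    candidates = call_candidates(counts, k, direction, annotation)
    genes = candidates.genes()
    if not genes:
        return np.empty(0)
    universe = {g for s in ratios.index if (g := annotation.gene_of(s)) is not None}
    table = enrich(genes, universe, go_map, min_genes)
    return table["p_value"].to_numpy(float) if len(table) else np.empty(0)


def calibrate_cutoff(
    ratios: pd.DataFrame,
    annotation: AnnotationMap,
    go_map: GoMap,
    k: int,
    direction: str,
    cutoffs: Sequence[float],
    n_scrambles: int = 100,
    min_genes: int = 3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Estimate the enrichment FDR at each candidate P cutoff by scrambling.

    Returns a table with, per cutoff: the observed number of terms at
    ``P <= cutoff``, the mean number over ``n_scrambles`` scrambled
    re-analyses, and their ratio as the FDR (NaN when nothing is observed).
    """
    if n_scrambles < 1:
        raise ValueError("need at least one scramble")
    if any(not 0 < c < 1 for c in cutoffs):
        raise ValueError("cutoffs must lie strictly between 0 and 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = _pipeline_pvalues(ratios, annotation, go_map, k, direction, min_genes)
    null_pvals = [
        _pipeline_pvalues(
            scramble_replicates(ratios, rng), annotation, go_map, k, direction, min_genes
        )
        for _ in range(n_scrambles)
    ]
    rows = []
    for cutoff in cutoffs:
        n_obs = int((observed <= cutoff).sum())
        mean_null = float(np.mean([(pv <= cutoff).sum() for pv in null_pvals]))
        fdr = mean_null / n_obs if n_obs > 0 else float("nan")
        rows.append(
            {
                "cutoff": cutoff,
                "observed_terms": n_obs,
                "mean_null_terms": mean_null,
                "fdr": fdr,
            }
        )
    return pd.DataFrame(rows)
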