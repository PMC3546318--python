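"""Candidate prioritization: evidence flags, network degree, weighted ranking.

After hit calling, candidates are triaged by orthogonal evidence: whether
the shRNA was significant at the strictest replicate criterion, whether
the gene was hit by more than one independent shRNA, whether it belongs to
a "meaningful" enriched GO category (a user-supplied whitelist of terms
describing distinct cellular processes), how connected it is in a
protein-interaction network, and whether there is any expression evidence
for it in the relevant cell type.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = ["node_degrees", "evidence_filter", "score_and_rank", "DEFAULT_WEIGHTS"]

#: (six_of_six, multi_probe, meaningful_go, per-connection degree) weights.
#: Declared defaults for a reproducible ranking, not a claim about any
#: particular published selection.
DEFAULT_WEIGHTS: tuple[float, float, float, float] = (2.0, 1.0, 1.0, 0.25)


def node_degrees(
    network: nx.Graph,
    genes: Iterable[str],
    scope: str = "induced",
) -> dict[str, int]:
    """Undirected degree per gene; genes absent from the network get 0.

    ``scope='induced'`` (default) counts connections within the candidate
    subnetwork only — the view one gets from submitting the candidate list
    to an interaction database; ``scope='full'`` counts all neighbors.
    """
    genes = list(genes)
    if scope == "induced":
        sub = network.subgraph(genes)
        return {g: (sub.degree(g) if g in sub else 0) for g in genes}
    if scope == "full":
        return {g: (network.degree(g) if g in network else 0) for g in genes}
    raise ValueError("scope must be 'induced' or 'full'")


def evidence_filter(
    candidates: Iterable[str],
    evidence: dict[str, bool],
    provenance: dict[str, str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop candidates with explicit negative expression evidence.

    Genes flagged False are removed and listed (with provenance when
    available).  A gene missing from the table is *retained* with a
    warning: unknown is not the same as not expressed.
    """
    kept: list[str] = []
    removed = []
    for gene in candidates:
        flag = evidence.get(gene)
        if flag is None:
            warnings.warn(f"no expression evidence entry for {gene!r}; retained")
            kept.append(gene)
        elif flag:
            kept.append(gene)
        else:
            removed.append(
                {"gene": gene, "provenance": (provenance or {}).get(gene, "")}
            )
    return kept, pd.DataFrame(removed, columns=["gene", "provenance"])


def score_and_rank(
    candidates: pd.DataFrame,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """Weighted evidence score and deterministic ranking.

    ``candidates`` needs columns ``gene``, ``six_of_six``, ``multi_probe``,
    ``meaningful_go`` (booleans) and ``degree`` (int).  The score is
    ``w1*six_of_six + w2*multi_probe + w3*meaningful_go + w4*degree``;
    ranking is by descending score with ties broken alphabetically by gene
    symbol, so the output is reproducible from its inputs.
    """
    w1, w2, w3, w4 = (float(w) for w in weights)
    out = candidates.copy()
    out["score"] = (
        w1 * out["six_of_six"].astype(float)
        + w2 * out["multi_probe"].astype(float)
        + w3 * out["meaningful_go"].astype(float)
        + w4 * out["degree"].astype(float)
    )
    out = out.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = out.index + 1
    return out
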