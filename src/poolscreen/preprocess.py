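"""Probe-level quality filtering, ln-ratio computation and probe collapsing.

The screen readout is a two-color array: the green channel measures each
shRNA's abundance at the start of the culture, the red channel at the end.
Preprocessing removes unreliable probes, forms the natural-log ratio
``ln(red/green)`` per probe and replicate, and averages sibling probes of
the same shRNA into one row per shRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotationMap, ProbeTable

__all__ = [
    "FilterReport",
    "filter_probes",
    "compute_log_ratios",
    "collapse_probes",
    "preprocess_screen",
]


@dataclass
class FilterReport:
    """Counts of probes removed by each quality rule.

    Each probe is counted once, under the first rule it violates; the rules
    are applied in the order low-intensity, unannotated, multimapping.
    """

    n_input: int
    n_low_intensity: int
    n_unannotated: int
    n_multimapping: int
    n_remaining: int

    def __post_init__(self) -> None:
        removed = self.n_low_intensity + self.n_unannotated + self.n_multimapping
        if self.n_input != removed + self.n_remaining:
            raise ValueError("filter report counts do not reconcile")


def filter_probes(
    table: ProbeTable,
    annotation: AnnotationMap,
    min_green: float = 200.0,
    min_fail_arrays: int = 3,
) -> tuple[ProbeTable, FilterReport]:
    """Remove low-confidence probes before ratio analysis.

    Three rules, applied in order:

    1. low intensity — green signal below ``min_green`` in at least
       ``min_fail_arrays`` of the replicates (defaults 200 and 3 of 6);
    2. unannotated — no probe->shRNA mapping available;
    3. multimapping — probe matches more than one shRNA sequence.
    """
    if min_green <= 0 or min_fail_arrays <= 0:
        raise ValueError("thresholds must be positive")
    n = len(table)
    if n == 0:
        return table, FilterReport(0, 0, 0, 0, 0)

    low = (table.green < min_green).sum(axis=1) >= min_fail_arrays
    status = table.probe_ids.map(annotation.status).to_numpy()
    unann = ~low & (status == "unannotated")
    multi = ~low & ~unann & (status == "multimap")
    keep = ~(low | unann | multi)

    report = FilterReport(
        n_input=n,
        n_low_intensity=int(low.sum()),
        n_unannotated=int(unann.sum()),
        n_multimapping=int(multi.sum()),
        n_remaining=int(keep.sum()),
    )
    return table.subset(keep), report


def compute_log_ratios(table: ProbeTable) -> pd.DataFrame:
    """Per-probe, per-replicate natural-log ratio ``ln(red/green)``.

    Both channels must be strictly positive — run after filtering.  The
    result is a DataFrame indexed by probe id with columns ``rep_1..rep_n``.
    """
    green, red = table.green, table.red
    bad = ~((green > 0) & (red > 0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive signal for probe {table.probe_ids.iloc[i]!r} in replicate {j + 1}"
        )
    ratios = np.log(red / green)
    cols = [f"rep_{j + 1}" for j in range(table.n_replicates)]
    return pd.DataFrame(ratios, index=pd.Index(table.probe_ids, name="id"), columns=cols)


def collapse_probes(ratios: pd.DataFrame, annotation: AnnotationMap) -> pd.DataFrame:
    """Average sibling probes of the same shRNA, per replicate.

    Every probe must resolve to exactly one shRNA (filter first).  shRNAs
    whose probes were all removed upstream are simply absent from the
    output.  A probe that failed filtering does not contribute even if its
    sibling passed: the mean is over surviving probes only.
    """
    try:
        shrnas = [annotation.shrna_of(p) for p in ratios.index]
    except KeyError as exc:
        raise ValueError(f"cannot collapse: {exc.args[0]}") from exc
    collapsed = ratios.groupby(pd.Index(shrnas, name="id"), sort=True).mean()
    return collapsed


def preprocess_screen(
    table: ProbeTable,
    annotation: AnnotationMap,
    min_green: float = 200.0,
    min_fail_arrays: int = 3,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter, log-ratio and collapse in one call.

    Returns the shRNA-level log-ratio matrix and the filter report — the
    standard entry point from raw probe signals to the calling statistic.
    """
    filtered, report = filter_probes(table, annotation, min_green, min_fail_arrays)
    ratios = compute_log_ratios(filtered)
    return collapse_probes(ratios, annotation), report
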