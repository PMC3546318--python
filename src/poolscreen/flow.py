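"""Internal-standard competition proliferation assay, from events to fold change.

A knockdown line carrying a fluorescent reporter is mixed 1:1 with
untransduced cells and the mixture cultured for weeks.  Because both
populations share every plate, split and trypsinization, the ratio of
fluorescent to non-fluorescent cells cancels handling noise and reports
the knockdown's relative growth rate directly.  This module gates debris
out of tabular flow-cytometry event lists, splits the fluorescence
histogram at the valley between the negative and positive modes, tracks
the positive:negative odds over time, and summarizes the percent decrease.
A small helper implements relative qPCR quantification (2^-ddCt) used to
confirm the knockdown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "GateError",
    "ValleyError",
    "DdctResult",
    "gate_events",
    "split_at_valley",
    "ratio_series",
    "percent_decrease",
    "summarize_decrease",
    "delta_delta_ct",
]


class GateError(ValueError):
    """The scatter gate left no events."""


class ValleyError(ValueError):
    """No two-mode structure found; supply a manual boundary."""


def gate_events(
    events: pd.DataFrame,
    ssc_min: float,
    fsc_range: tuple[float, float] | None = None,
    ssc_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Keep events above the side-scatter debris threshold and inside the gate.

    The gate parameters are recorded in ``result.attrs["gate"]`` so exactly
    the same gate can be reapplied to every sample of a measurement day.
    Raises :class:`GateError` if nothing survives.
    """
    mask = events["ssc"] > ssc_min
    if ssc_range is not None:
        mask &= events["ssc"].between(*ssc_range)
    if fsc_range is not None:
        mask &= events["fsc"].between(*fsc_range)
    gated = events.loc[mask].reset_index(drop=True)
    if gated.empty:
        raise GateError("scatter gate removed all events")
    gated.attrs["gate"] = {"ssc_min": ssc_min, "fsc_range": fsc_range, "ssc_range": ssc_range}
    return gated


def split_at_valley(
    intensities: np.ndarray | pd.Series,
    n_bins: int = 256,
    smoothing_bandwidth: float = 3.0,
    fixed_boundary: float | None = None,
) -> tuple[float, float]:
    """Fraction of fluorescence-positive events and the boundary used.

    With ``fixed_boundary`` the fraction is simply the share of events
    above it — this is how a boundary "chosen once" is reapplied across a
    time course.  Otherwise the intensities are log10-transformed, binned
    into ``n_bins``, smoothed with a Gaussian kernel of
    ``smoothing_bandwidth`` bins, and the boundary is placed at the
    histogram minimum between the two highest modes.  A histogram without
    two modes raises :class:`ValleyError` advising a manual boundary.
    """
    x = np.asarray(intensities, float)
    if x.size < 2:
        raise ValueError("need at least 2 events")
    if fixed_boundary is not None:
        return float(np.mean(x > fixed_boundary)), float(fixed_boundary)

    positive = x[x > 0]
    if positive.size == 0:
        raise ValleyError("all intensities are zero; supply a manual boundary")
    log_x = np.log10(np.clip(x, positive.min(), None))
    counts, edges = np.histogram(log_x, bins=n_bins)
    smooth = gaussian_filter1d(counts.astype(float), sigma=smoothing_bandwidth)

    # a mode must be a substantial, well-separated peak, not a shoulder
    # ripple: require prominence of 10% of the tallest peak and a spacing
    # of several smoothing bandwidths
    peaks, props = find_peaks(
        smooth,
        prominence=0.10 * smooth.max(),
        distance=max(int(4 * smoothing_bandwidth), 1),
    )
    if len(peaks) < 2:
        raise ValleyError(
            "fluorescence histogram is unimodal; supply fixed_boundary manually"
        )
    order = np.argsort(props["prominences"])[::-1]
    lo, hi = sorted(int(peaks[i]) for i in order[:2])
    valley_region = smooth[lo : hi + 1]
    depth = valley_region.min()
    if hi - lo < 2 or depth > 0.6 * min(smooth[lo], smooth[hi]):
        raise ValleyError(
            "no clear valley between the two highest modes; "
            "supply fixed_boundary manually"
        )
    # middle of the minimal plateau, so an empty gap splits at its center
    at_min = np.flatnonzero(valley_region == depth)
    valley = lo + int(at_min[(len(at_min) - 1) // 2])
    centers = 0.5 * (edges[:-1] + edges[1:])
    boundary = float(10 ** centers[valley])
    return float(np.mean(x > boundary)), boundary


def ratio_series(samples: Sequence[tuple[float, float]]) -> pd.DataFrame:
    """Build the competition time series from (time, fraction_positive) pairs.

    Per time point ``t`` (hours): the positive fraction ``f``, the odds
    ``R = f/(1-f)``, ``log2(R)``, and the normalized decrease
    ``D = 1 - R(t)/R(0)`` in percent.  A 1:1 starting mix has R(0)=1 and
    log2 R(0)=0.  Time points with f=1 have undefined odds and are flagged
    with NaN.  Requires t=0 with 0 < f(0) < 1.
    """
    frame = pd.DataFrame(sorted(samples), columns=["time", "fraction"])
    if not ((frame["fraction"] >= 0) & (frame["fraction"] <= 1)).all():
        raise ValueError("fractions must lie in [0, 1]")
    if 0.0 not in frame["time"].values:
        raise ValueError("the series must include a t=0 sample")
    f0 = float(frame.loc[frame["time"] == 0.0, "fraction"].iloc[0])
    if not 0.0 < f0 < 1.0:
        raise ValueError("f(0) must lie strictly between 0 and 1")
    f = frame["fraction"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(f < 1.0, f / (1.0 - f), np.nan)
    r0 = f0 / (1.0 - f0)
    frame["odds"] = odds
    with np.errstate(divide="ignore", invalid="ignore"):
        frame["log2_ratio"] = np.log2(odds)
    frame["decrease_pct"] = 100.0 * (1.0 - odds / r0)
    return frame


def percent_decrease(series: pd.DataFrame, t: float) -> float:
    """The normalized decrease D(t), in percent, at one time point."""
    match = series.loc[series["time"] == t, "decrease_pct"]
    if match.empty:
        raise ValueError(f"time point {t} not present in the series")
    return float(match.iloc[0])


def summarize_decrease(series_list: Sequence[pd.DataFrame], t: float) -> tuple[float, float]:
    """Mean and sample SD of D(t) across replicate series.

    With a single series the SD is reported as NaN (not computable).
    """
    values = np.array([percent_decrease(s, t) for s in series_list], float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


@dataclass
class DdctResult:
    """Relative expression by the 2^-ddCt method."""

    dct_sample: float
    dct_calibrator: float
    ddct: float
    fold: float


def delta_delta_ct(
    ct_target_sample,
    ct_ref_sample,
    ct_target_cal,
    ct_ref_cal,
) -> DdctResult:
    """Relative expression of a target gene, reference-normalized.

    Inputs may be scalars or replicate arrays (e.g. qPCR triplicates),
    which are averaged.  ``ddCt = (Ct_target - Ct_ref)_sample -
    (Ct_target - Ct_ref)_calibrator`` and the fold change is ``2^-ddCt``;
    a fold of 0.1 corresponds to 10-fold silencing.
    """
    vals = [np.mean(np.asarray(v, float)) for v in
            (ct_target_sample, ct_ref_sample, ct_target_cal, ct_ref_cal)]
    if not all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    dct_sample = vals[0] - vals[1]
    dct_cal = vals[2] - vals[3]
    ddct = dct_sample - dct_cal
    return DdctResult(
        dct_sample=float(dct_sample),
        dct_calibrator=float(dct_cal),
        ddct=float(ddct),
        fold=float(2.0 ** (-ddct)),
    )
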