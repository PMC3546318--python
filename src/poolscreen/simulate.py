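"""Synthetic pooled-screen and competition-assay data with known ground truth.

The screen generator emulates a two-week pooled culture of ~6,796 shRNAs
read out on a two-color array with two probes per shRNA and six
replicates.  Growth is deterministic-exponential in each shRNA's fitness;
stochasticity enters through per-replicate biological noise, multinomial
sampling at the sequencing/hybridization depth, and per-probe measurement
noise.  Everything needed to verify recovery — per-shRNA fitness, gene
assignments, decoy labels — is returned as ground truth.

The flow generator emulates the internal-standard competition assay: a
fluorescent and a non-fluorescent population whose mixing fraction evolves
logistically with the fitness difference, plus sub-threshold debris.

``poisson_representation`` is the screen-design calculator: at a given
number of transduced cells, how many cells carry each shRNA on average,
and what is the lowest per-shRNA clone count any library member is
expected to reach under Poisson statistics.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AnnotationMap, ProbeTable

__all__ = [
    "SimScreenParams",
    "SimFlowParams",
    "SimTruth",
    "RepresentationReport",
    "simulate_screen",
    "simulate_flow",
    "simulate_go_map",
    "mixing_fraction",
    "poisson_representation",
    "child_rng",
]


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-purpose random stream derived from one master seed.

    Streams are keyed by a label hash, so any component can be re-run in
    isolation and reproduce exactly the draws it would see in a full run.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _mixture_normal(
    rng: np.random.Generator,
    size,
    sigma: float,
    contam_frac: float,
    contam_scale: float,
) -> np.ndarray:
    """Scale-contaminated normal noise: heavier-tailed than Gaussian.

    A small fraction of draws come from a ``contam_scale``-times wider
    normal.  Heavy tails push the sample SD up relative to the central
    mass, so the fraction of values beyond one SD falls below the Gaussian
    15.9% — mirroring the 13–14% threshold-exceedance rates typical of
    array log-ratios.
    """
    base = rng.normal(0.0, sigma, size)
    wide = rng.random(size) < contam_frac
    base[wide] *= contam_scale
    return base


@dataclass
class SimScreenParams:
    """Study conditions for the simulated pooled screen.

    Defaults describe a library of 6,796 shRNAs (two array probes each,
    ~3 shRNAs per gene), six replicate cultures of ~14 population
    doublings, a small minority of shRNAs with real fitness effects, and
    noise calibrated so that null log-ratios have SD near 1 with roughly
    13–14% of cells beyond one SD of their replicate mean.
    """

    n_shrna: int = 6796
    probes_per_shrna: int = 2
    n_replicates: int = 6
    shrnas_per_gene: int = 3
    generations: float = 14.0
    frac_negative: float = 0.01
    s_negative: float = -0.25
    frac_positive: float = 0.005
    s_positive: float = 0.25
    depth: int = 2_000_000
    abundance_sd: float = 0.5
    sigma_growth: float = 0.9
    sigma_measure: float = 0.2
    contam_frac: float = 0.05
    contam_scale: float = 3.0
    probe_offset_sd: float = 0.3
    signal_scale: float = 5.0
    background: float = 5.0
    normalize: bool = True
    frac_low_intensity: float = 0.05
    frac_unannotated: float = 0.002
    frac_multimap: float = 0.017
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_negative + self.frac_positive > 1:
            raise ValueError("fitness fractions must sum to at most 1")
        if self.frac_low_intensity + self.frac_unannotated + self.frac_multimap > 1:
            raise ValueError("decoy fractions must sum to at most 1")
        for name in ("n_shrna", "probes_per_shrna", "n_replicates", "depth",
                     "generations", "signal_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data.

    ``shrnas`` has one row per shRNA (id, gene, fitness); ``probes`` one
    row per emitted probe (id, shRNA, label), where label is ``real``,
    ``low_intensity``, ``unannotated`` or ``multimap``.
    """

    shrnas: pd.DataFrame
    probes: pd.DataFrame
    seed: int
    params: SimScreenParams | None = None
    counts_t0: np.ndarray | None = None   # shRNA x replicate sampled counts, start
    counts_end: np.ndarray | None = None  # shRNA x replicate sampled counts, end


def _assign_fitness(params: SimScreenParams, rng: np.random.Generator) -> np.ndarray:
    s = np.zeros(params.n_shrna)
    n_neg = int(round(params.frac_negative * params.n_shrna))
    n_pos = int(round(params.frac_positive * params.n_shrna))
    picks = rng.choice(params.n_shrna, size=n_neg + n_pos, replace=False)
    s[picks[:n_neg]] = params.s_negative
    s[picks[n_neg:]] = params.s_positive
    return s


def simulate_screen(
    params: SimScreenParams | None = None,
) -> tuple[ProbeTable, AnnotationMap, SimTruth]:
    """Generate a probe table, annotation map and ground truth for one screen.

    Model: initial abundances are log-normal around uniform; each shRNA's
    end abundance is ``a0 * exp(s * g)`` times a per-replicate biological
    noise factor; both time points are sampled multinomially at the
    configured depth per replicate; each probe reports its shRNA's counts
    times a fixed per-probe hybridization efficiency and per-cell
    measurement noise on both channels.  Decoy probes (dim, unannotated,
    multimapping) are appended per the configured fractions.
    """
    p = params or SimScreenParams()
    n, n_rep = p.n_shrna, p.n_replicates

    if p.depth / n < 20:
        expected_zero = n * np.exp(-p.depth / n)
        warnings.warn(
            f"sampling depth {p.depth} is shallow for {n} shRNAs; "
            f"~{expected_zero:.0f} zero counts expected per replicate"
        )

    fitness = _assign_fitness(p, child_rng(p.seed, "fitness"))
    shrna_ids = np.array([f"SH{i + 1:05d}" for i in range(n)])
    genes = np.array([f"GENE{i // p.shrnas_per_gene + 1:05d}" for i in range(n)])

    rng_ab = child_rng(p.seed, "abundance")
    w0 = np.exp(rng_ab.normal(0.0, p.abundance_sd, n))
    w0 /= w0.sum()

    rng_growth = child_rng(p.seed, "growth")
    bio = _mixture_normal(rng_growth, (n, n_rep), p.sigma_growth, p.contam_frac, p.contam_scale)
    w_end = w0[:, None] * np.exp(fitness[:, None] * p.generations + bio)
    w_end /= w_end.sum(axis=0, keepdims=True)

    rng_counts = child_rng(p.seed, "counts")
    c0 = np.stack([rng_counts.multinomial(p.depth, w0) for _ in range(n_rep)], axis=1)
    c1 = np.stack([rng_counts.multinomial(p.depth, w_end[:, r]) for r in range(n_rep)], axis=1)

    # probe readout: both probes of an shRNA see the same counts
    n_probes = n * p.probes_per_shrna
    rng_probe = child_rng(p.seed, "probes")
    offsets = np.exp(rng_probe.normal(0.0, p.probe_offset_sd, n_probes))
    probe_shrna_idx = np.repeat(np.arange(n), p.probes_per_shrna)
    rng_meas = child_rng(p.seed, "measurement")
    eps_g = _mixture_normal(rng_meas, (n_probes, n_rep), p.sigma_measure,
                            p.contam_frac, p.contam_scale)
    eps_r = _mixture_normal(rng_meas, (n_probes, n_rep), p.sigma_measure,
                            p.contam_frac, p.contam_scale)
    # additive scanner background keeps signals positive even at zero counts;
    # a fully depleted shRNA then reads out at background, i.e. a strongly
    # negative ratio, as on a real array
    bg_g = p.background * np.exp(rng_meas.normal(0.0, 0.3, (n_probes, n_rep)))
    bg_r = p.background * np.exp(rng_meas.normal(0.0, 0.3, (n_probes, n_rep)))
    green = p.signal_scale * c0[probe_shrna_idx] * offsets[:, None] * np.exp(eps_g) + bg_g
    red = p.signal_scale * c1[probe_shrna_idx] * offsets[:, None] * np.exp(eps_r) + bg_r
    if p.normalize:
        # emulate upstream two-color normalization: center each replicate's
        # log-ratio distribution at zero (median-based, lowess-like)
        correction = np.median(np.log(red / green), axis=0)
        red = red * np.exp(-correction)[None, :]

    probe_ids = np.array(
        [f"PR{i + 1:05d}_{j + 1}" for i in range(n) for j in range(p.probes_per_shrna)]
    )
    probe_rows = [
        {"probe_id": pid, "shrna_id": shrna_ids[si], "label": "real"}
        for pid, si in zip(probe_ids, probe_shrna_idx)
    ]
    ann_rows = [
        (pid, shrna_ids[si], genes[si]) for pid, si in zip(probe_ids, probe_shrna_idx)
    ]

    # decoys
    rng_decoy = child_rng(p.seed, "decoys")
    extra_green, extra_red, extra_ids = [], [], []
    n_low = int(round(p.frac_low_intensity * n_probes))
    n_unann = int(round(p.frac_unannotated * n_probes))
    n_multi = int(round(p.frac_multimap * n_probes))
    median_signal = float(np.median(green)) if n_probes else 1000.0

    for i in range(n_low):
        pid = f"PRLOW{i + 1:04d}"
        sig = 80.0 * np.exp(rng_decoy.normal(0.0, 0.5, (2, n_rep)))
        extra_ids.append(pid)
        extra_green.append(sig[0])
        extra_red.append(sig[1])
        dummy = f"SHLOW{i + 1:04d}"
        probe_rows.append({"probe_id": pid, "shrna_id": dummy, "label": "low_intensity"})
        ann_rows.append((pid, dummy, f"GENELOW{i + 1:04d}"))
    for i in range(n_unann):
        pid = f"PRUNK{i + 1:04d}"
        sig = median_signal * np.exp(rng_decoy.normal(0.0, 0.5, (2, n_rep)))
        extra_ids.append(pid)
        extra_green.append(sig[0])
        extra_red.append(sig[1])
        probe_rows.append({"probe_id": pid, "shrna_id": "", "label": "unannotated"})
    for i in range(n_multi):
        pid = f"PRMUL{i + 1:04d}"
        sig = median_signal * np.exp(rng_decoy.normal(0.0, 0.5, (2, n_rep)))
        extra_ids.append(pid)
        extra_green.append(sig[0])
        extra_red.append(sig[1])
        a, b = rng_decoy.choice(n, size=2, replace=False)
        probe_rows.append({"probe_id": pid, "shrna_id": shrna_ids[a], "label": "multimap"})
        ann_rows.append((pid, shrna_ids[a], genes[a]))
        ann_rows.append((pid, shrna_ids[b], genes[b]))

    all_ids = np.concatenate([probe_ids, np.array(extra_ids, dtype=object)]) \
        if extra_ids else probe_ids
    all_green = np.vstack([green] + [np.atleast_2d(g) for g in extra_green]) \
        if extra_green else green
    all_red = np.vstack([red] + [np.atleast_2d(r) for r in extra_red]) \
        if extra_red else red

    frame = pd.DataFrame({"probe_id": all_ids})
    for j in range(n_rep):
        frame[f"green_{j + 1}"] = all_green[:, j]
    for j in range(n_rep):
        frame[f"red_{j + 1}"] = all_red[:, j]
    table = ProbeTable(frame, n_rep)

    probe_to_shrnas: dict[str, set[str]] = {}
    shrna_to_gene: dict[str, str] = {}
    for pid, shrna, gene in ann_rows:
        probe_to_shrnas.setdefault(pid, set()).add(shrna)
        shrna_to_gene.setdefault(shrna, gene)
    annotation = AnnotationMap(probe_to_shrnas, shrna_to_gene)

    truth = SimTruth(
        shrnas=pd.DataFrame(
            {"shrna_id": shrna_ids, "gene_symbol": genes, "fitness": fitness}
        ),
        probes=pd.DataFrame(probe_rows),
        seed=p.seed,
        params=p,
        counts_t0=c0,
        counts_end=c1,
    )
    return table, annotation, truth


def simulate_go_map(
    genes: Sequence[str],
    n_terms: int = 150,
    terms_per_gene: int = 4,
    planted: dict[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> "GoMap":
    """Random GO association map over a gene universe, optionally with
    planted term/gene blocks.

    Each gene receives ``terms_per_gene`` distinct random terms; entries of
    ``planted`` (term id -> genes) are added on top, letting tests and
    power studies construct terms genuinely enriched in a chosen gene set.
    """
    from .io import GoMap

    rng = child_rng(seed, "go-map")
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    gene_to_terms: dict[str, set[str]] = {}
    for gene in genes:
        picks = rng.choice(n_terms, size=min(terms_per_gene, n_terms), replace=False)
        gene_to_terms[gene] = {term_ids[i] for i in picks}
    if planted:
        for term, members in planted.items():
            for gene in members:
                gene_to_terms.setdefault(gene, set()).add(term)
    descriptions = {t: f"simulated process {t[3:]}" for t in term_ids}
    if planted:
        descriptions.update({t: f"planted process {t}" for t in planted})
    return GoMap(gene_to_terms, descriptions)


@dataclass
class SimFlowParams:
    """Study conditions for the simulated competition assay.

    Defaults describe a 1:1 starting mix followed for two weeks with
    measurements every 2–3 days, 10,000 gated events per sample, and a
    fitness deficit for the fluorescent line such that its odds roughly
    halve per week (~54% odds decrease at 168 h).
    """

    p0: float = 0.5
    fitness: float = -0.00462  # per hour, log-odds slope of the fluorescent line
    times: Sequence[float] = (0.0, 48.0, 96.0, 168.0, 240.0, 336.0)
    events_per_sample: int = 10_000
    debris_frac: float = 0.10
    neg_log_mean: float = 1.0   # log10 intensity of the non-fluorescent mode
    pos_log_mean: float = 2.5   # log10 intensity of the fluorescent mode
    log_sd: float = 0.25
    ssc_threshold: float = 200.0
    seed: int = 0


def mixing_fraction(p0: float, s: float, t: float) -> float:
    """Positive fraction after time t: logistic growth of the odds.

    ``f(t) = p0 e^{st} / (p0 e^{st} + 1 - p0)``; the odds are multiplied
    by ``e^{st}`` while the fraction stays in [0, 1].
    """
    num = p0 * np.exp(s * t)
    return float(num / (num + (1.0 - p0)))


def simulate_flow(
    params: SimFlowParams | None = None,
) -> tuple[dict[float, pd.DataFrame], pd.DataFrame]:
    """Generate per-time-point flow event tables and the true fractions.

    Each table holds one event per row with ``ssc``, ``fsc`` and ``fl``
    columns; intact cells sit above the SSC threshold, debris below it.
    Fluorescence intensities are log-normal around the negative or
    positive mode.
    """
    p = params or SimFlowParams()
    rng = child_rng(p.seed, "flow")
    tables: dict[float, pd.DataFrame] = {}
    truth_rows = []
    n_debris = int(round(p.events_per_sample * p.debris_frac))
    n_cells = p.events_per_sample - n_debris
    for t in p.times:
        f_true = mixing_fraction(p.p0, p.fitness, t)
        n_pos = int(rng.binomial(n_cells, f_true))
        n_neg = n_cells - n_pos
        fl = np.concatenate(
            [
                10 ** rng.normal(p.pos_log_mean, p.log_sd, n_pos),
                10 ** rng.normal(p.neg_log_mean, p.log_sd, n_neg),
                10 ** rng.normal(0.5, 0.3, n_debris),
            ]
        )
        ssc = np.concatenate(
            [
                np.clip(rng.normal(500.0, 80.0, n_cells), p.ssc_threshold + 1.0, None),
                np.clip(rng.normal(80.0, 40.0, n_debris), 1.0, p.ssc_threshold - 1.0),
            ]
        )
        fsc = np.concatenate(
            [
                np.clip(rng.normal(400.0, 60.0, n_cells), 1.0, None),
                np.clip(rng.normal(60.0, 20.0, n_debris), 1.0, None),
            ]
        )
        order = rng.permutation(p.events_per_sample)
        tables[t] = pd.DataFrame({"ssc": ssc[order], "fsc": fsc[order], "fl": fl[order]})
        truth_rows.append(
            {"time": t, "f_true": f_true, "n_pos": n_pos, "n_cells": n_cells,
             "n_debris": n_debris}
        )
    return tables, pd.DataFrame(truth_rows)


@dataclass
class RepresentationReport:
    """Library coverage at a given number of transduced cells."""

    mean_per_shrna: float
    min_expected_clones: int


def poisson_representation(transduced_cells: float, n_shrna: int) -> RepresentationReport:
    """Poisson bound on the worst-represented library member.

    With ``transduced_cells`` cells spread over ``n_shrna`` constructs the
    mean clone count per shRNA is ``lambda = cells / n_shrna``.  The
    report's ``min_expected_clones`` is the largest count ``c`` such that
    fewer than one shRNA is expected below it, i.e.
    ``n_shrna * P(X < c; lambda) < 1`` — no library member is expected to
    be represented by fewer clones than this.
    """
    if transduced_cells < 0 or n_shrna <= 0:
        raise ValueError("inputs must be non-negative (cells) and positive (shRNAs)")
    lam = transduced_cells / n_shrna
    c = 0
    while True:
        below = sps.poisson.cdf(c, lam)  # P(X < c + 1) = P(X <= c)
        if n_shrna * below >= 1.0:
            break
        c += 1
    return RepresentationReport(mean_per_shrna=float(lam), min_expected_clones=c)
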