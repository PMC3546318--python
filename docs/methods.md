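# Methods

## The screen model and its statistic

The unit of analysis is the shRNA × replicate matrix of natural-log
two-color ratios `r_ij = ln(red/green)`, formed after three probe-level
quality rules applied in order (a probe is counted once, under the first
rule it violates): (1) green signal below `min_green` (default 200
fluorescence units) in at least `min_fail_arrays` (default 3) of the
replicates; (2) no probe→shRNA annotation; (3) probe matching more than
one shRNA.  Sibling probes of one shRNA are then averaged per replicate;
a probe that failed filtering does not contribute even if its sibling
passed.  Replicate count is a parameter (default 6) taken from the data
everywhere downstream.

Hit calling is by value counting.  Per replicate the thresholds are
`mean ± SD` of that column over all rows; the sample SD (ddof = 1) is
used, the conventional estimator at six replicates.  Exceedance is strict
(`>` / `<`): a value exactly at a threshold does not count — ties are
measure-zero in continuous data and "exceeds" is read literally.  The
chance probability of crossing, `p_over`/`p_under`, is pooled over all
matrix cells rather than computed per replicate.  For a k-of-n criterion
the expected chance candidate count is `N · P(X ≥ k)` with
`X ~ Binomial(n, p)`, computed through the regularized survival function
(scipy) and verified against exhaustive 2^n enumeration to 1e-12;
`FDR = expected / found`, reported as NaN when nothing is found.
Thresholds and rates are computed on the collapsed shRNA-level matrix;
probe-level thresholds are available by simply running the statistic on
the uncollapsed matrix.  Effect-size ranking by mean log-change is
deliberately out of scope — insensitivity to outliers is the method's
point.

## Enrichment and its scramble null

GO enrichment reuses the binomial tail: for a term annotating `k`
candidate genes out of `n` tested genes, `P(X ≥ k)` with a background rate
`p` = (sum of candidate associations over all terms) / (sum of all
associations over all terms); no minimum-count filter enters the sums, but
only terms with `k ≥ 3` are reported.  Counting is by distinct genes (a
gene contributes at most once to a term's `k` and `n`); counting
association occurrences instead — weighting a gene by its shRNA count —
is available through the `weights` argument.  No propagation to GO
ancestor terms is performed.

Because terms are many and correlated, the P cutoff is calibrated
empirically: every replicate column's rows are permuted independently,
which preserves each column's exact value multiset (and hence the marginal
exceedance rates) while destroying the cross-replicate concordance that
value counting measures.  The full calling + enrichment pipeline is re-run
per scramble and `FDR(cutoff) = mean null term count / observed term
count`.  The default is 100 scrambles with a recorded seed (tests and the
acceptance script use fewer, 4 per screen over many screens, trading
per-screen precision for seed coverage).  Note a consequence of
preserving marginals: when the data contain real hits, scrambled runs
still produce candidate lists of comparable size, so at loose cutoffs the
estimated FDR is conservative; the calibration is most informative at
stringent cutoffs (the 0.005 neighborhood).

## Prioritization

The final triage is a transparent weighted score over per-gene evidence:
strictest-criterion significance, multi-shRNA support, membership in a
user-supplied whitelist of "meaningful" GO terms (no automatic semantics —
what counts as a distinct cellular process is a judgment call), and
network degree, by default within the induced candidate subnetwork (the
view an interaction database returns for a submitted gene list; whole-
network degree is a switch).  Default weights (2, 1, 1, 0.25 per
connection) are declared package defaults for reproducibility, not a claim
about any published selection, which was qualitative.  Genes with explicit
negative expression evidence are excluded; genes *missing* from the
evidence table are retained with a warning — unknown is not unexpressed.
Ranking is a stable descending sort with alphabetical tie-break, so it is
a deterministic function of its inputs.

## Competition assay

Events are gated by a side-scatter threshold (plus optional rectangular
SSC/FSC bounds) recorded so the same gate can be reapplied across a
measurement day.  The fluorescence histogram is built over log10 intensity
in 256 bins, smoothed with a Gaussian kernel of 3 bins, and split at the
minimum between the two most prominent peaks (scipy `find_peaks`,
prominence ≥ 10% of the tallest peak, spacing ≥ 4 bandwidths); the
boundary sits at the center of the minimal plateau, so perfectly separated
populations split at the gap's middle.  A histogram without two such peaks
raises an error advising a manual boundary, and a `fixed_boundary` chosen
once can be reapplied to all later samples — the intended workflow.

The decrease is defined on the odds `R(t) = f/(1−f)`, not the raw
fraction: with an internal standard the odds are the quantity proportional
to the transduced population's relative size, and `log2 R(t)` is linear in
time under constant fitness.  `D(t) = 1 − R(t)/R(0)` in percent; the
fraction-based alternative is trivially recoverable from the series table,
which reports `f`, `R`, `log2 R` and `D` side by side.  Samples where
`f = 1` have undefined odds and are flagged NaN rather than dropped.
ΔΔCt quantification averages replicate Ct values and reports
`fold = 2^(−ΔΔCt)`.

## The simulator

The screen generator emulates the study conditions it is meant to test:
6,796 shRNAs (~3 per gene, giving ~2,300 genes), two probes per shRNA,
six replicates, ~14 population doublings.  Growth is
deterministic-exponential in fitness — final abundance
`∝ a_i0 · exp(s_i · g)` — with stochasticity entering at three points:
per-replicate biological noise on end abundance, multinomial sampling of
both time points at depth 2×10⁶ reads per replicate (counts therefore sum
to the depth exactly), and per-probe measurement noise on each channel.
Initial abundances are log-normal (SD 0.5) around uniform.  Both noise
sources are scale-contaminated normals (5% of draws at 3× width): heavy
tails push the sample SD up relative to the central mass, so the fraction
of cells beyond one SD falls to ~13%, matching the 13–14% rates typical of
array log-ratios, while the null column SD lands near 1.05–1.15 with
`σ_growth = 0.9` and `σ_measure = 0.2`.  Each probe carries a fixed
log-normal hybridization efficiency (SD 0.3) applied to both channels —
it cancels in the ratio, as two-color designs intend.  An additive scanner
background (~5 units) keeps signals positive even at zero sampled counts,
so a fully depleted shRNA reads out at background level.  Because the
input to the real pipeline is normalization software output, the generator
median-centers each replicate's log-ratio by rescaling the red channel;
per-replicate means then sit within a few hundredths of zero.  Signal
scale is set so the median green signal is ~1,300 units.

Fitness defaults plant 1% of shRNAs at `s = −0.25` per doubling and 0.5%
at `+0.25` — over 14 doublings a ±3.5 log-unit shift, i.e. a strong hit —
with the remainder neutral; `g` and `|s|` were calibrated once so that a
strong effect yields 6of6 calls at the default noise.  Decoy probes are
injected at the scale seen on real arrays: 5% dim probes (log-normal
around 80 units, removed by the intensity rule), 0.2% unannotated, 1.7%
multimapping.  All randomness derives from one master seed through
labeled child streams (CRC32-keyed `SeedSequence` spawn keys), so each
component can be re-run in isolation and reproduce its draws bitwise.

The flow generator mixes two log-normal intensity populations (log10
means 1.0 and 2.5, SD 0.25) plus 10% sub-threshold debris, 10,000 events
per sample, with the positive fraction following
`f(t) = p0·e^{st} / (p0·e^{st} + 1−p0)`.  The default fitness
(−0.00462 h⁻¹) halves the fluorescent line's odds roughly weekly, the
scale of a clearly detrimental knockdown.

What the simulator does **not** emulate: array spatial artifacts and dye
bias (assumed removed upstream), PCR sequence bias, per-cell branching
stochasticity (growth is abundance-level), cross-population interactions
in the competition assay, and instrument compensation.  Passing tests
therefore demonstrate the statistics' correctness and calibration under a
faithful abundance-sampling model, not robustness to every artifact of
real arrays or cytometers.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline at the native
6,796-shRNA scale: 200 all-neutral screens for null calibration, 50
screens per effect size for power, 25–50 screens with 4 scrambles each for
the enrichment FDR (the power-surface grid uses 1,200 shRNAs at reduced
depth, since power is a per-shRNA property).  The binomial tail is
validated to 1e-12 against full 2^n enumeration for n ≤ 12.  Degenerate
inputs are handled explicitly: constant replicate columns warn and
collapse thresholds to the mean; empty candidate sets make FDRs NaN
("not computable") rather than zero; zero-association GO universes and
all-debris gates are errors.

## Known limitations

The value-counting FDR is an expected-false-discovery ratio, not a
q-value, and can exceed 1.  The scramble FDR's conservatism at loose
cutoffs is described above.  Valley splitting assumes two populations;
strongly overlapping modes (< ~2 SD apart on log intensity) are reported
as unimodal and need a manual boundary.  The prioritization score makes a
qualitative workflow reproducible but its weights are conventions, not
fitted quantities.
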