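# Methods

## The recognition model

The package treats RecA homology recognition as a two-stage kinetic filter.
A 20-nt interaction between the presynaptic filament's initiating strand and
an incoming duplex is summarized by its registration-aligned match pattern —
a boolean vector over positions, no indels, no register sliding, no
mismatch-identity weighting. The rapid initial test accepts the interaction
iff at least one window of M contiguous base pairs contains fewer than j
mismatches; the statistic N_{M bp with <j} counts such windows (n − M + 1
windows in an n-nt alignment). The test is deliberately simplistic:
position within the window and the chemical identity of a mismatch are
ignored, matching the hypothesis that the initial test reads only local
contiguity of Watson–Crick pairing.

For single-mismatched-triplet 20-mers the geometry is summarized by k, the
distance from the triplet's central base to the nearest duplex end, and m,
the longest contiguous match run; these satisfy m = 19 − k, which the code
asserts and the tests verify exhaustively over all 18 admissible centers.

## Background statistics

Accidental matches between unrelated sequences are modeled as iid Bernoulli
with p = 1/4 (uniform base composition; p is configurable for GC-skewed
genomes). All binomial quantities are computed from closed-form terms
(math.comb with fsum accumulation) — no Gaussian or Poisson approximation
anywhere. The probability that a random pattern passes the (M, <j) test is
computed by two independent exact routes:

- **enumeration** — all 2^n patterns, binomially weighted (n ≤ 24; the
  default n = 20 takes about a second);
- **dynamic programme** — a transfer matrix over the last M − 1 position
  outcomes (2^(M−1) states); mass is deleted the moment a completed window
  passes, so the surviving total is the rejection probability. Valid for
  any n, bounded at M ≤ 22 by the state space.

The two routes agree to 1e-12 across the tested (n, M, j) grid. The
headline rejection probability is computed for the full 20-nt interaction
(any of the 13 windows may pass), the stricter reading of "base pairings
rejected"; the single-window reading is recoverable by setting n = M.

## The synthetic panel

The oligonucleotide sequences behind the published panel are not publicly
deposited, so the panel ships as named mismatch-position sets chosen once to
satisfy every published constraint and documented in
`patterns.DEFAULT_PANEL_MISMATCHES`:

- match totals implied by each name (hom 20, het 0, triplet and isolated
  patterns 17, mis4 16, mis5 15, mis6 14, 12/20, 10/20, and the 5/20
  background sequence from pcDNA3);
- longest-run values m: tr 3′/tr 5′ = 17, tr c3′/tr c5′ = 14, tr m = 9,
  3i = 5 (three isolated mismatches every 5–6 bases), 1+2 = 10, 2+1 = 8;
- mis4's four passing 8-bp windows starting exactly at {1, 4, 5, 6};
- N_{8 bp with <2} = 0 for every sparser distributed pattern;
- identical 8-bp window profiles for the two 15/20 sequences (their
  mismatches sit on the same period-4 lattice, offset toward opposite ends).

"5/20" and "pcDNA3" name the same distributed-match 20-mer, so the default
simulation panel drops the alias and holds 18 sequences. A YAML override
can substitute the true sequences at any time; every statistic is recomputed
from positions, nothing is hard-wired to the defaults.
`sequences_from_pattern` materializes concrete (synthetic) base sequences
realizing any pattern for FASTA round-trip tests.

## Fluorescence synthesis and reduction

The generator emulates donor-emission time courses in two geometries:
quench-down (free ssDNA binding to the filament, or protein-free annealing —
emission falls as the acceptor approaches) and recover-up (strand exchange
with a labeled outgoing strand — emission rises as the strand is displaced).
Each trace approaches its plateau single-exponentially with iid Gaussian
readout noise:

    F(t) = F_inf + (F_start − F_inf) exp(−t/τ) + ε,  ε ~ N(0, σ²)

Defaults: 0.5-s integration over 30 min (3601 samples), τ = 30 s so
equilibration completes by ~100 s, F0 = 100 a.u., a fully quenched floor of
5% of F0 (the homologous binding curve loses ~95% of the initial emission).
The plateau follows the generative signal model

    g(pattern) = s_het + (1 − s_het) · N_{M,<j}(pattern) / (n − M + 1)

with s_het = 0.1 (the heterologous baseline is ~10% of the homologous
change) and optional per-name overrides (e.g. pinning the 5/20 background
sequence to the ~20% level seen in the binding geometry). Panel simulation
derives one child seed per trace from the root seed, so a panel is a pure
function of (panel, model, config, seed).

Reduction fits the three-parameter exponential by least squares
(scipy.optimize.curve_fit; initialization F_inf ← tail mean, F0 ← first
sample, τ ← half-change time; relative tolerance 1e-8). A tail-mean
estimate (final 10% of samples) is always computed alongside and serves as
the fallback when the fit fails or the trace is flat; flat traces report the
constant level with τ flagged unidentifiable. Plateaus are normalized
against the measured homologous and heterologous references,
v = (F_inf − F_het)/(F_hom − F_het), which orients both geometries to
hom = 1 / het = 0 (the quench-down sign flip is absorbed by the negative
denominator); values slightly outside [0, 1] from noise are clipped to
[−0.1, 1.1] and flagged. Note the anchoring means v recovers the
de-baselined signal (g − s_het)/(1 − s_het), exactly N/(n−M+1) under the
default model — the σ = 0 round trip reproduces it to better than 1e-6.

Not modeled, by design: photophysics (Förster radius, quantum yields),
photobleaching drift, instrument response, and the slow second phase seen
for the 5/20 background sequence in the binding geometry (its emission
keeps drifting through the observation window; a single exponential cannot
represent that). The functional form of the published curve fits is not
stated anywhere, so the single exponential is this package's own modeling
choice; consequences of these simplifications are that passing round-trip
tests demonstrate internal consistency of the pipeline, not fidelity to any
particular instrument.

## The (M, j) scan

For each cell of the grid (default M = 4..20, j = 1..3) the panel's
normalized signals are compared with N_{M,<j} via (a) the Pearson
product-moment correlation ("correlation" is never specified further in the
source analyses; Spearman is available behind a flag) and (b) the mean
square deviation after per-vector min-max normalization to [0, 1]
(configurable to max-only scaling). Cells whose N vector is constant
across the panel carry no information and are flagged invalid rather than
scored. Best cells are the argmax of r and the argmin of MSD over valid
cells, ties broken toward smaller M then smaller j; ranked lists are
returned for inspection.

The seeded parameter-recovery study perturbs the noiseless 18-sequence
panel signals with Gaussian noise (σ = 0.05 on the normalized scale —
comparable to the 2–8% assay variation of the underlying measurements),
rescans the grid, and scores a replicate as recovered when the
best-by-correlation cell has j = 2 and M ∈ [6, 10]. With 100 replicates
recovery is essentially complete and concentrated on (8, 2); the study runs
in about a second.

## Numerical choices and edge cases

- Window counts use a cumulative-sum difference; the test suite checks it
  against a naive double loop over the whole catalog × M ∈ [1, 20] ×
  j ∈ [1, 4] and over random patterns (hypothesis, derandomized).
- Binomial tails sum the upper-tail terms with fsum; tail + CDF = 1 is
  asserted to 1e-12.
- The ambiguity base N never matches (conservative); U maps to T; input is
  case-insensitive. Gaps are rejected — the analysis is registration-only.
- Pearson r is clipped to [−1, 1] against rounding; zero-variance vectors
  yield NaN at cell level, never an exception at grid level.
- Fits whose plateau lands outside the observed emission range (± 3 RMS)
  are rejected to the tail-mean fallback.

## Problem sizes

Defaults throughout are the study conditions themselves: n = 20, the 2^20
enumeration, 13 windows, an 18-sequence panel, 3601 samples per trace, 100
recovery replicates. The full test suite runs in well under a minute; the
acceptance script in a few seconds.
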