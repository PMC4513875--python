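# recascan

Sliding-window mismatch statistics and model selection for RecA-mediated
homology recognition.

## The problem

When a RecA presynaptic filament searches a bacterial genome for a sequence
homologous to its initiating ssDNA, almost every 20-nt interaction it samples
is unrelated sequence. Under uniform base composition two unrelated 20-mers
still agree at 20/4 = 5 positions on average, and about one interaction in
five carries exactly five accidental matches — so a recognition system that
scored only total matches would drown in background. A kinetic
two-step model resolves this: a rapid initial test accepts an interaction
only if it contains at least one window of *M* contiguous base pairs with
fewer than *j* mismatches, and only accepted interactions go on to the
slower, triplet-by-triplet strand-exchange extension.

The central statistic is

> *N*<sub>*M* bp with &lt;*j*</sub> — the number of distinct contiguous
> *M*-bp windows of a registration-aligned pair containing fewer than *j*
> mismatches (a 20-nt alignment has 21 − *M* such windows; 13 for *M* = 8).

`recascan` implements, as a tested pipeline over a synthetic data layer:

- **`patterns`** — match/mismatch profiles of aligned pairs (FASTA in), plus
  a 20-nt panel emulating the experimental oligonucleotide sets (terminal and
  central mismatched triplets, isolated mismatches, distributed matches down
  to the 5/20 background level);
- **`windows`** — the per-window mismatch census and *N*<sub>*M* bp with &lt;*j*</sub>;
- **`background`** — exact Binomial(*n*, 1/4) statistics of accidental
  matches and the exact probability that a random pattern passes the initial
  test (exhaustive 2²⁰ enumeration, cross-checked against a transfer-matrix
  dynamic programme to 10⁻¹²);
- **`fret`** / **`curves`** — a seeded generator of donor-emission
  time courses whose plateaus follow the window statistic, and the
  exponential plateau fit + hom/het-anchored normalization that turns traces
  back into signals;
- **`scan`** — the (M, j) model-selection grid: Pearson correlation and
  normalized mean-square deviation between panel signals and
  *N*<sub>*M* bp with &lt;*j*</sub>, with best-cell selection and a seeded
  parameter-recovery study.

## Worked example

```python
>>> import recascan as rs
>>> panel = rs.panel_catalog()
>>> prof = rs.window_mismatch_counts(panel["mis4"], 8)
>>> list(prof.counts)
[1, 2, 2, 1, 1, 1, 2, 2, 2, 2, 2, 2, 2]
>>> prof.n_passing(2), prof.passing_starts(2)
(4, (1, 4, 5, 6))
```

The 16/20-match sequence mis4 contains four 8-bp windows with fewer than two
mismatches, starting at positions 1, 4, 5 and 6 — it passes the initial
test. Every sparser distributed-match pattern in the panel (15/20 down to
5/20) has *N*<sub>8 bp with &lt;2</sub> = 0 and is rejected.

```python
>>> model = rs.BackgroundModel(n=20, p_match=0.25)
>>> rs.expected_matches(model)
5.0
>>> rs.match_count_pmf(model, 5)
0.2023311518569244
>>> rs.tail_prob_more_than(model, 14)
3.813027433352545e-06
>>> p = rs.initial_test_pass_probability(model, rs.WindowParams(8, 2))
>>> 1 - p
0.9968571969275217
```

A random 20-nt interaction carries five accidental matches on average,
exceeds fourteen with probability 3.8 × 10⁻⁶, and is rejected by the
8-bp/one-mismatch initial test 99.7% of the time — the sparsity of
accidental matches lets the initial test discard almost the whole genome
without forming a detectable 20-bp product.

The numbered scripts under `analysis/` run the full narrative: panel census,
background statistics, trace simulation, plateau fitting and the (M, j)
scan, writing their tables under `results/`. Running them in order prints,
at the end of `05_model_scan.py` and `06_parameter_recovery.py`:

```
Best cell by correlation: M=8, j=2; by MSD: M=8, j=2.
j=1 column peaks at r=0.939 — poor at every M.
100% of 100 noisy panels recovered j=2 with M in [6, 10].
```

i.e. the scan re-identifies the 8-bp/one-mismatch test from the simulated
fluorescence panel, a zero-tolerance test fits poorly at every window
length, and recovery is stable under signal noise.

There is also a CLI (`recascan profile|windows|background|simulate|process|scan`)
wrapping the same functions; `recascan windows -M 8 -j 2 --out windows.tsv`
reproduces the panel census from the shell.

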