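"""Statistics of accidental matches between unrelated sequences.

Under a uniform base composition two unrelated sequences agree at each
aligned position independently with probability 1/4, so the number of
accidental matches in a 20-nt interaction is Binomial(20, 1/4): five
matches on average, more than fourteen with probability below 3e-5.
This module evaluates that model exactly (closed-form binomial terms, no
Gaussian or Poisson approximation) and computes the exact probability
that a random match pattern passes the initial M-bp/<j-mismatch window
test — the quantity behind the claim that an 8-bp test tolerating one
mismatch rejects the vast majority of genomic base pairings.

Two independent routes compute the pass probability: exhaustive
enumeration of all 2^n binomially weighted patterns (n <= 24) and a
transfer-matrix dynamic programme over the last M-1 position outcomes
(any n); they agree to 1e-12 and are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .windows import WindowParams

__all__ = [
    "BackgroundModel",
    "BackgroundParameterError",
    "EnumerationCapabilityError",
    "expected_matches",
    "match_count_pmf",
    "tail_prob_more_than",
    "initial_test_pass_probability",
    "completion_time",
    "ENUMERATION_MAX_N",
]

ENUMERATION_MAX_N = 24
_DP_MAX_M = 22


class BackgroundParameterError(ValueError):
    """Model or query parameter outside its valid range."""


class EnumerationCapabilityError(ValueError):
    """Problem too large for exhaustive enumeration; use the DP route."""


@dataclass(frozen=True)
class BackgroundModel:
    """Bernoulli model of accidental matches over an n-nt interaction.

    ``p_match`` defaults to 1/4 (uniform base composition); raise it for
    GC-skewed genomes.
    """

    n: int = 20
    p_match: float = 0.25

    def __post_init__(self) -> None:
        if self.n < 1:
            raise BackgroundParameterError(f"n={self.n} must be >= 1")
        if not 0.0 <= self.p_match <= 1.0:
            raise BackgroundParameterError(f"p_match={self.p_match} outside [0, 1]")


def expected_matches(model: BackgroundModel) -> float:
    """Mean number of accidental matches, n * p (20/4 = 5 by default)."""
    return model.n * model.p_match


def match_count_pmf(model: BackgroundModel, k: int) -> float:
    """P(X = k): exact binomial term C(n,k) p^k (1-p)^(n-k)."""
    if not 0 <= k <= model.n:
        raise BackgroundParameterError(f"k={k} out of range 0..{model.n}")
    p = model.p_match
    return math.comb(model.n, k) * p**k * (1.0 - p) ** (model.n - k)


def tail_prob_more_than(model: BackgroundModel, k: int) -> float:
    """P(X > k) by exact summation of the binomial terms above k.

    ``k = -1`` is accepted as the lower edge (P(X > -1) = 1).
    """
    if not -1 <= k <= model.n:
        raise BackgroundParameterError(f"k={k} out of range -1..{model.n}")
    # sum the smaller tail for accuracy when it is the upper one
    upper = math.fsum(match_count_pmf(model, i) for i in range(k + 1, model.n + 1))
    return upper


def _pattern_weights(n: int, p: float) -> np.ndarray:
    """Probability of every 2^n match pattern (bit i set = match at i)."""
    codes = np.arange(1 << n, dtype=np.uint32)
    nbytes = 4
    k = (
        np.unpackbits(codes.view(np.uint8).reshape(-1, nbytes), axis=1, bitorder="little")
        .sum(axis=1)
        .astype(np.float64)
    )
    return p**k * (1.0 - p) ** (n - k)


def _pass_probability_enumeration(model: BackgroundModel, params: WindowParams) -> float:
    n, M, j = model.n, params.M, params.j
    if n > ENUMERATION_MAX_N:
        raise EnumerationCapabilityError(
            f"n={n} exceeds the 2^n enumeration bound ({ENUMERATION_MAX_N}); "
            "use method='dp'"
        )
    codes = np.arange(1 << n, dtype=np.uint32)
    weights = _pattern_weights(n, model.p_match)
    window_mask = np.uint32((1 << M) - 1)
    passes = np.zeros(codes.shape, dtype=bool)
    for start in range(n - M + 1):
        window = (codes >> np.uint32(start)) & window_mask
        matches = (
            np.unpackbits(window.view(np.uint8).reshape(-1, 4), axis=1, bitorder="little")
            .sum(axis=1)
            .astype(np.int64)
        )
        passes |= (M - matches) < j
    return float(weights[passes].sum())


def _pass_probability_dp(model: BackgroundModel, params: WindowParams) -> float:
    """P(at least one passing window) via a transfer matrix on the last M-1 outcomes.

    Tracks the probability mass of patterns with no passing window so far,
    resolved by the trailing M-1 match/mismatch outcomes; mass is removed
    the moment a completed window holds fewer than j mismatches.  The
    surviving total is the rejection probability.
    """
    n, M, j = model.n, params.M, params.j
    p = model.p_match
    if M > _DP_MAX_M:
        raise BackgroundParameterError(
            f"M={M} exceeds the DP state-space bound ({_DP_MAX_M})"
        )
    if M == 1:
        # a 1-bp window passes iff it is a match (j >= 1 always accepts 0 mismatches)
        return float(1.0 - (1.0 - p) ** n) if j == 1 else 1.0

    n_states = 1 << (M - 1)
    state_mask = n_states - 1
    states = np.arange(n_states, dtype=np.int64)
    match_counts = np.array(
        [bin(s).count("1") for s in range(n_states)], dtype=np.int64
    )

    # probability of each length-(M-1) prefix, none of which completes a window
    prob = (
        p**match_counts * (1.0 - p) ** (M - 1 - match_counts)
        if n >= M - 1
        else None
    )
    if n < M:
        return 0.0  # no window fits: the test can never pass
    assert prob is not None

    next_state_mismatch = (states << 1) & state_mask
    next_state_match = next_state_mismatch | 1
    for _ in range(M - 1, n):
        window_matches_if_match = match_counts + 1  # completed M-window, new base matches
        window_matches_if_mismatch = match_counts
        ok_match = (M - window_matches_if_match) >= j  # window does NOT pass
        ok_mismatch = (M - window_matches_if_mismatch) >= j
        new_prob = np.zeros_like(prob)
        np.add.at(new_prob, next_state_match[ok_match], prob[ok_match] * p)
        np.add.at(
            new_prob, next_state_mismatch[ok_mismatch], prob[ok_mismatch] * (1.0 - p)
        )
        prob = new_prob
    return float(1.0 - math.fsum(prob))


def initial_test_pass_probability(
    model: BackgroundModel,
    params: WindowParams,
    method: str = "auto",
) -> float:
    """Exact probability that a random pattern passes the (M, <j) window test.

    ``method`` is ``"enumeration"`` (exhaustive over 2^n patterns,
    n <= 24), ``"dp"`` (transfer-matrix dynamic programme, any n), or
    ``"auto"`` (enumeration when feasible).  The rejection probability is
    one minus the returned value.
    """
    if params.j > params.M:
        return 1.0  # every window trivially passes
    if params.M > model.n:
        return 0.0
    if method == "auto":
        method = "enumeration" if model.n <= ENUMERATION_MAX_N else "dp"
    if method == "enumeration":
        return _pass_probability_enumeration(model, params)
    if method == "dp":
        return _pass_probability_dp(model, params)
    raise BackgroundParameterError(f"unknown method {method!r}")


def completion_time(length_nt: int, rate_bp_per_s: float) -> float:
    """Time for strand exchange to traverse a homologous region.

    Exchange progresses through homology at roughly 6 bp/s, so a 20-nt
    interaction completes in under 4 s.
    """
    if rate_bp_per_s <= 0:
        raise BackgroundParameterError(f"rate {rate_bp_per_s} bp/s must be positive")
    if length_nt < 0:
        raise BackgroundParameterError(f"length {length_nt} nt must be non-negative")
    return length_nt / rate_bp_per_s
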