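"""Sliding-window mismatch census: the initial-homology-test statistic.

The working model of RecA homology recognition is that an interaction is
accepted by a rapid initial test iff the 20-nt alignment contains at least
one window of M contiguous base pairs with fewer than j mismatches.  The
statistic N_{M bp with <j} counts such windows; a 20-nt alignment holds
21 - M distinct windows (13 for M = 8).  The test is deliberately
simplistic: it is insensitive to mismatch identity and to position within
the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .patterns import MatchPattern

__all__ = [
    "WindowParams",
    "WindowProfile",
    "WindowParameterError",
    "window_mismatch_counts",
    "count_passing_windows",
    "passes_initial_test",
    "panel_window_table",
]


class WindowParameterError(ValueError):
    """Window length or tolerance outside its valid range."""


@dataclass(frozen=True)
class WindowParams:
    """Initial-test parameters: window length M and mismatch tolerance j.

    A window passes iff it contains strictly fewer than j mismatches, so
    j = 2 accepts windows with 0 or 1 mismatch.
    """

    M: int
    j: int

    def __post_init__(self) -> None:
        if self.M < 1:
            raise WindowParameterError(f"window length M={self.M} must be >= 1")
        if self.j < 1:
            raise WindowParameterError(f"tolerance j={self.j} must be >= 1")


@dataclass(frozen=True)
class WindowProfile:
    """Per-start mismatch counts for one pattern at one window length.

    ``counts[i]`` is the number of mismatches in the window whose first
    base sits at 1-based position ``starts[i] = i + 1``.
    """

    name: str
    M: int
    counts: np.ndarray

    @property
    def starts(self) -> np.ndarray:
        return np.arange(1, len(self.counts) + 1)

    def n_passing(self, j: int) -> int:
        """N_{M bp with <j}: windows with strictly fewer than j mismatches."""
        if j < 1:
            raise WindowParameterError(f"tolerance j={j} must be >= 1")
        return int((self.counts < j).sum())

    def passing_starts(self, j: int) -> tuple[int, ...]:
        """1-based start positions of the passing windows."""
        return tuple(int(s) for s in self.starts[self.counts < j])


def window_mismatch_counts(pattern: MatchPattern, M: int) -> WindowProfile:
    """Mismatch count of every contiguous M-bp window of the pattern.

    Returns the n - M + 1 counts in start order (21 - M windows for the
    20-nt panel).
    """
    n = pattern.n
    if not 1 <= M <= n:
        raise WindowParameterError(f"window length M={M} out of range 1..{n}")
    mism = (~pattern.is_match).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(mism)))
    counts = cum[M:] - cum[:-M]
    return WindowProfile(name=pattern.name, M=M, counts=counts)


def count_passing_windows(pattern: MatchPattern, params: WindowParams) -> int:
    """N_{M bp with <j} for one pattern."""
    return window_mismatch_counts(pattern, params.M).n_passing(params.j)


def passes_initial_test(pattern: MatchPattern, params: WindowParams) -> bool:
    """True iff at least one M-bp window holds fewer than j mismatches."""
    return count_passing_windows(pattern, params) >= 1


def panel_window_table(
    panel: Mapping[str, MatchPattern] | Iterable[MatchPattern],
    M: int,
    j: int,
) -> pd.DataFrame:
    """Window census of a whole panel as a tidy table.

    One row per pattern with its per-start mismatch counts, N_{M bp with <j}
    and the passing start positions; TSV-serializable.
    """
    patterns = list(panel.values()) if isinstance(panel, Mapping) else list(panel)
    rows = []
    for pat in patterns:
        prof = window_mismatch_counts(pat, M)
        rows.append(
            {
                "name": pat.name,
                "n": pat.n,
                "matches": pat.matches,
                "M": M,
                "j": j,
                "counts": ",".join(str(c) for c in prof.counts),
                "N_pass": prof.n_passing(j),
                "passing_starts": ",".join(str(s) for s in prof.passing_starts(j)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "n", "matches", "M", "j", "counts", "N_pass", "passing_starts"],
    )
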