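"""Model selection over the (M, j) grid of initial-test parameters.

For every candidate window length M and tolerance j, the panel's
normalized equilibrium signals are compared with the window statistic
N_{M bp with <j} via the Pearson correlation and the mean-square
deviation of min-max-normalized values.  The best-fitting cell
identifies the initial test the data support; with the default panel a
window of 6-10 bp tolerating one mismatch fits best, while j = 1
(no-mismatch) tests fit poorly at every M.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .patterns import MatchPattern
from .windows import WindowParams, count_passing_windows

__all__ = [
    "ScanGrid",
    "ScanResult",
    "ScanError",
    "correlation",
    "msd_normalized",
    "scan_grid",
    "best_parameters",
    "DEFAULT_M_RANGE",
    "DEFAULT_J_RANGE",
]

DEFAULT_M_RANGE = range(4, 21)
DEFAULT_J_RANGE = range(1, 4)


class ScanError(ValueError):
    """Scan inputs or grid unusable."""


def correlation(signals: Sequence[float], n_values: Sequence[float]) -> float:
    """Pearson product-moment correlation of signals against N values.

    Returns NaN when either vector has zero variance (the grid flags the
    cell invalid rather than raising).
    """
    x = np.asarray(signals, dtype=float)
    y = np.asarray(n_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ScanError("signals and N values must be equal-length 1-D vectors")
    if x.size < 3:
        raise ScanError(f"need >= 3 panel members, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def _minmax(v: np.ndarray, mode: str) -> np.ndarray | None:
    if mode == "minmax":
        lo, hi = v.min(), v.max()
        if hi - lo == 0.0:
            return None
        return (v - lo) / (hi - lo)
    if mode == "max":
        hi = np.abs(v).max()
        if hi == 0.0:
            return None
        return v / hi
    raise ScanError(f"unknown normalization mode {mode!r}")


def msd_normalized(
    signals: Sequence[float],
    n_values: Sequence[float],
    mode: str = "minmax",
) -> float:
    """Mean-square deviation after per-vector normalization to [0, 1].

    Both vectors are min-max scaled (or scaled by their max with
    ``mode="max"``) before the mean of squared differences is taken;
    a constant vector makes the cell undefined (NaN).
    """
    x = np.asarray(signals, dtype=float)
    y = np.asarray(n_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ScanError("signals and N values must be equal-length 1-D vectors")
    xn = _minmax(x, mode)
    yn = _minmax(y, mode)
    if xn is None or yn is None:
        return float("nan")
    return float(np.mean((xn - yn) ** 2))


@dataclass(frozen=True)
class ScanGrid:
    """Correlation and MSD for every (M, j) cell, as a tidy frame.

    Columns: M, j, r, msd, valid.  Cells whose N vector is constant
    across the panel are flagged invalid and excluded from selection.
    """

    table: pd.DataFrame

    def cell(self, M: int, j: int) -> pd.Series:
        sub = self.table[(self.table["M"] == M) & (self.table["j"] == j)]
        if sub.empty:
            raise ScanError(f"cell (M={M}, j={j}) not in grid")
        return sub.iloc[0]


@dataclass(frozen=True)
class ScanResult:
    """Selected initial-test parameters and the ranked grid."""

    best_by_r: tuple[int, int]
    best_by_msd: tuple[int, int]
    ranked_by_r: pd.DataFrame
    ranked_by_msd: pd.DataFrame
    grid: ScanGrid


def scan_grid(
    signals: Mapping[str, float],
    panel: Mapping[str, MatchPattern],
    M_range: Sequence[int] = DEFAULT_M_RANGE,
    j_range: Sequence[int] = DEFAULT_J_RANGE,
    msd_mode: str = "minmax",
    method: str = "pearson",
) -> ScanGrid:
    """Fill the (M, j) grid from panel signals and patterns.

    ``signals`` and ``panel`` are joined on name (every signal needs a
    pattern); order is irrelevant.  ``method`` may be ``"pearson"``
    (default) or ``"spearman"`` (rank correlation).
    """
    Ms, js = list(M_range), list(j_range)
    if not Ms or not js:
        raise ScanError("empty M or j range")
    names = list(signals.keys())
    if len(names) < 3:
        raise ScanError(f"need >= 3 panel members, got {len(names)}")
    missing = [nm for nm in names if nm not in panel]
    if missing:
        raise ScanError(f"signals without panel patterns: {missing}")
    sig = np.array([signals[nm] for nm in names], dtype=float)
    if method == "spearman":
        sig_for_r = rankdata(sig)
    elif method == "pearson":
        sig_for_r = sig
    else:
        raise ScanError(f"unknown correlation method {method!r}")

    rows = []
    for M in Ms:
        for j in js:
            params = WindowParams(M, j)
            N = np.array(
                [count_passing_windows(panel[nm], params) for nm in names],
                dtype=float,
            )
            if np.ptp(N) == 0.0:
                rows.append({"M": M, "j": j, "r": np.nan, "msd": np.nan, "valid": False})
                continue
            N_for_r = rankdata(N) if method == "spearman" else N
            r = correlation(sig_for_r, N_for_r)
            msd = msd_normalized(sig, N, mode=msd_mode)
            valid = bool(np.isfinite(r) and np.isfinite(msd))
            rows.append({"M": M, "j": j, "r": r, "msd": msd, "valid": valid})
    return ScanGrid(table=pd.DataFrame(rows, columns=["M", "j", "r", "msd", "valid"]))


def best_parameters(grid: ScanGrid) -> ScanResult:
    """Select the best (M, j) by correlation and by MSD.

    Ties are broken toward smaller M, then smaller j.  Invalid cells
    never win; an all-invalid grid raises :class:`ScanError`.
    """
    valid = grid.table[grid.table["valid"]].copy()
    if valid.empty:
        raise ScanError("no valid cells in scan grid")
    by_r = valid.sort_values(["r", "M", "j"], ascending=[False, True, True]).reset_index(
        drop=True
    )
    by_msd = valid.sort_values(["msd", "M", "j"], ascending=[True, True, True]).reset_index(
        drop=True
    )
    best_r = (int(by_r.iloc[0]["M"]), int(by_r.iloc[0]["j"]))
    best_msd = (int(by_msd.iloc[0]["M"]), int(by_msd.iloc[0]["j"]))
    return ScanResult(
        best_by_r=best_r,
        best_by_msd=best_msd,
        ranked_by_r=by_r,
        ranked_by_msd=by_msd,
        grid=grid,
    )
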