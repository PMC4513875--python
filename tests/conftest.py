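import numpy as np
import pytest

from recascan.patterns import MatchPattern, panel_catalog


@pytest.fixture(scope="session")
def catalog() -> dict[str, MatchPattern]:
    return panel_catalog()


@pytest.fixture(scope="session")
def mis4(catalog) -> MatchPattern:
    return catalog["mis4"]


def naive_window_counts(pattern: MatchPattern, M: int) -> list[int]:
    """Independent double-loop oracle for per-window mismatch counts."""
    n = pattern.n
    counts = []
    for start in range(n - M + 1):
        c = 0
        for pos in range(start, start + M):
            if not pattern.is_match[pos]:
                c += 1
        counts.append(c)
    return counts


def naive_passing_windows(pattern: MatchPattern, M: int, j: int) -> int:
    return sum(1 for c in naive_window_counts(pattern, M) if c < j)
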