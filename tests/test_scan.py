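"""The (M, j) model-selection scan: correlation, MSD and best-cell choice."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from recascan.experiments import (
    default_panel,
    noiseless_panel_signals,
    parameter_recovery,
    scan_panel,
)
from recascan.scan import (
    ScanError,
    best_parameters,
    correlation,
    msd_normalized,
    scan_grid,
)
from recascan.windows import WindowParams, count_passing_windows


class TestCorrelation:
    def test_proportional_vectors_correlate_perfectly(self):
        n = [0, 4, 9, 13]
        assert correlation([0.1 + 0.9 * v / 13 for v in n], n) == pytest.approx(1.0)

    def test_negated_vectors_anticorrelate(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert correlation([-v for v in x], x) == pytest.approx(-1.0)

    def test_agrees_with_scipy_pearsonr_oracle(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=18)
        y = rng.permutation(np.arange(18.0))
        assert correlation(x, y) == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)

    def test_zero_variance_vector_is_undefined_not_fatal(self):
        assert np.isnan(correlation([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]))

    def test_too_short_input_rejected(self):
        with pytest.raises(ScanError):
            correlation([1.0, 2.0], [3.0, 4.0])


class TestMsdNormalized:
    def test_identical_shapes_have_zero_deviation(self):
        x = [0.0, 1.0, 2.0, 4.0]
        assert msd_normalized(x, [10 * v for v in x]) == pytest.approx(0.0)

    def test_complementary_binary_vectors_deviate_maximally(self):
        assert msd_normalized([0, 1, 0, 1], [1, 0, 1, 0]) == pytest.approx(1.0)

    def test_worked_four_element_case(self):
        # min-max: x -> [0, 1/3, 2/3, 1], y -> [0, 1, 1/2, 1/4]
        # squared diffs: 0, 4/9, 1/36, 9/16 -> mean = 149/576
        x = [1.0, 2.0, 3.0, 4.0]
        y = [0.0, 4.0, 2.0, 1.0]
        assert msd_normalized(x, y) == pytest.approx(149 / 576, rel=1e-12)

    def test_constant_vector_is_undefined(self):
        assert np.isnan(msd_normalized([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]))


class TestScanGrid:
    def test_noiseless_panel_peaks_exactly_at_8_2(self):
        signals = noiseless_panel_signals()
        result = scan_panel(signals)
        assert result.best_by_r == (8, 2)
        assert result.best_by_msd == (8, 2)
        cell = result.grid.cell(8, 2)
        assert cell["r"] == pytest.approx(1.0, abs=1e-12)
        assert cell["msd"] == pytest.approx(0.0, abs=1e-12)

    def test_no_mismatch_tolerance_fits_poorly_at_every_M(self):
        signals = noiseless_panel_signals()
        grid = scan_panel(signals).grid.table
        r_8_2 = float(grid.query("M == 8 and j == 2")["r"].iloc[0])
        j1 = grid.query("j == 1 and valid")
        assert (j1["r"] < r_8_2 - 0.05).all()

    def test_grid_matches_per_cell_recomputation_on_toy_panel(self, catalog):
        panel = {k: catalog[k] for k in ("hom", "mis4", "3i")}
        signals = {"hom": 0.95, "mis4": 0.30, "3i": 0.70}
        grid = scan_grid(signals, panel, range(4, 11), range(1, 4)).table
        for row in grid.itertuples():
            N = [
                count_passing_windows(panel[nm], WindowParams(row.M, row.j))
                for nm in signals
            ]
            if len(set(N)) == 1:
                assert not row.valid
                continue
            expect_r = correlation(list(signals.values()), N)
            expect_msd = msd_normalized(list(signals.values()), N)
            assert row.r == pytest.approx(expect_r, abs=1e-12)
            assert row.msd == pytest.approx(expect_msd, abs=1e-12)

    def test_scan_is_permutation_invariant_in_panel_order(self):
        signals = noiseless_panel_signals()
        panel = default_panel()
        fwd = scan_grid(signals, panel).table
        shuffled = dict(reversed(list(signals.items())))
        rev = scan_grid(shuffled, panel).table
        assert np.allclose(fwd["r"].to_numpy(), rev["r"].to_numpy(), equal_nan=True)
        assert np.allclose(fwd["msd"].to_numpy(), rev["msd"].to_numpy(), equal_nan=True)

    def test_monotone_transform_of_signals_keeps_the_peak(self):
        # a saturating monotone distortion must leave (8,2) within 1e-9 of the max r
        signals = noiseless_panel_signals()
        distorted = {k: 1.0 - np.exp(-3.0 * v) for k, v in signals.items()}
        result = scan_panel(distorted)
        grid = result.grid.table
        r_star = float(grid.query("M == 8 and j == 2")["r"].iloc[0])
        assert r_star >= grid["r"].max(skipna=True) - 1e-9

    def test_empty_ranges_rejected(self):
        with pytest.raises(ScanError):
            scan_grid(noiseless_panel_signals(), default_panel(), [], [1, 2])


class TestBestParameters:
    def test_tie_breaks_toward_smaller_M_then_smaller_j(self):
        import pandas as pd

        from recascan.scan import ScanGrid

        table = pd.DataFrame(
            [
                {"M": 9, "j": 2, "r": 0.9, "msd": 0.1, "valid": True},
                {"M": 8, "j": 2, "r": 0.9, "msd": 0.1, "valid": True},
                {"M": 8, "j": 3, "r": 0.9, "msd": 0.1, "valid": True},
            ]
        )
        result = best_parameters(ScanGrid(table))
        assert result.best_by_r == (8, 2)
        assert result.best_by_msd == (8, 2)

    def test_invalid_cells_never_win(self):
        import pandas as pd

        from recascan.scan import ScanGrid

        table = pd.DataFrame(
            [
                {"M": 4, "j": 1, "r": np.nan, "msd": np.nan, "valid": False},
                {"M": 8, "j": 2, "r": 0.5, "msd": 0.3, "valid": True},
            ]
        )
        assert best_parameters(ScanGrid(table)).best_by_r == (8, 2)

    def test_all_invalid_grid_rejected(self):
        import pandas as pd

        from recascan.scan import ScanGrid

        table = pd.DataFrame([{"M": 4, "j": 1, "r": np.nan, "msd": np.nan, "valid": False}])
        with pytest.raises(ScanError):
            best_parameters(ScanGrid(table))


class TestParameterRecovery:
    def test_noisy_panels_recover_the_8bp_one_mismatch_test(self):
        # 100 panels at sigma = 0.05: the best cell should sit at j = 2,
        # M in [6, 10] in at least 95% of replicates
        study = parameter_recovery(n_replicates=100, sigma=0.05, seed=20)
        assert study.recovery_rate >= 0.95
        assert set(study.replicates.columns) >= {"best_M", "best_j", "recovered"}
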