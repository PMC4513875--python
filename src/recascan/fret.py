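"""Synthetic donor-emission time courses for the sequence panel.

Generates fluorescence-versus-time traces emulating the three FRET
geometries used to probe homology recognition: complementary-ssDNA
binding to the presynaptic filament and protein-free annealing (both
quench the fluorescein donor as the rhodamine acceptor approaches) and
strand exchange with a labeled outgoing strand (donor emission recovers
as the outgoing strand is displaced).

The generative model ties each pattern's equilibrium plateau to the
window statistic: the true normalized signal is

    g(pattern) = s_het + (1 - s_het) * N_{M bp with <j} / (n - M + 1)

with per-sequence overrides available to emulate measured levels (the
heterologous baseline is ~10% of the homologous change; the pcDNA3
5/20-match sequence reaches ~20% in the binding geometry).  Traces decay
(or recover) single-exponentially to the plateau with iid Gaussian
readout noise; sampling defaults to 0.5-s integration over 30 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .patterns import MatchPattern
from .windows import WindowParams, count_passing_windows

__all__ = [
    "SimConfig",
    "PanelSignalModel",
    "FluorescenceTrace",
    "SimulationParameterError",
    "simulate_trace",
    "panel_signal",
    "simulate_panel",
    "QUENCH_DOWN",
    "RECOVER_UP",
]

QUENCH_DOWN = "quench-down"
RECOVER_UP = "recover-up"

#: Fraction of the initial donor emission left when fully quenched; the
#: homologous binding curve loses ~95% of the initial fluorescence.
_FLOOR_FRACTION = 0.05


class SimulationParameterError(ValueError):
    """Simulation configuration outside its valid range."""


@dataclass(frozen=True)
class SimConfig:
    """Trace-generation settings for one experimental geometry.

    ``geometry`` is ``"quench-down"`` (binding/annealing: emission falls
    from F0 toward the plateau) or ``"recover-up"`` (strand exchange with
    a labeled outgoing strand: emission rises from the quenched floor).
    ``tau`` is the exponential time constant in seconds — 30 s by
    default so equilibration completes by ~100 s, as the annealing
    curves do.  ``dt`` is the 0.5-s integration time of the fluorimeter.
    """

    geometry: str = QUENCH_DOWN
    F0: float = 100.0
    tau: float = 30.0
    duration: float = 1800.0
    dt: float = 0.5
    sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.geometry not in (QUENCH_DOWN, RECOVER_UP):
            raise SimulationParameterError(f"unknown geometry {self.geometry!r}")
        if self.tau <= 0:
            raise SimulationParameterError(f"tau={self.tau} s must be positive")
        if self.dt <= 0:
            raise SimulationParameterError(f"dt={self.dt} s must be positive")
        if self.duration < self.dt:
            raise SimulationParameterError("duration must be at least one sample")
        if self.sigma < 0:
            raise SimulationParameterError(f"sigma={self.sigma} must be >= 0")


@dataclass(frozen=True)
class PanelSignalModel:
    """Map from match pattern to true normalized equilibrium signal.

    ``s_het`` is the heterologous baseline on the hom=1 scale;
    ``overrides`` pins named sequences to measured levels instead of the
    window-statistic prediction.
    """

    s_het: float = 0.1
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_het < 1.0:
            raise SimulationParameterError(f"s_het={self.s_het} outside [0, 1)")


@dataclass(frozen=True)
class FluorescenceTrace:
    """One simulated emission time course with its ground-truth metadata."""

    name: str
    times: np.ndarray
    emission: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.emission, dtype=float)
        if t.shape != e.shape or t.ndim != 1:
            raise SimulationParameterError("times and emission must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise SimulationParameterError("times must be strictly increasing")
        t.setflags(write=False)
        e.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "emission", e)


def simulate_trace(
    config: SimConfig, F_inf: float, name: str = "trace", F_start: float | None = None
) -> FluorescenceTrace:
    """Single-exponential approach to ``F_inf`` with Gaussian readout noise.

    F(t) = F_inf + (F_start - F_inf) exp(-t / tau) + eps,  eps ~ N(0, sigma^2).

    ``F_start`` defaults to ``config.F0``; sigma = 0 yields the exact
    exponential, and a fixed seed reproduces the trace bit-for-bit.
    """
    start = config.F0 if F_start is None else F_start
    n_samples = int(np.floor(config.duration / config.dt)) + 1
    times = np.arange(n_samples) * config.dt
    emission = F_inf + (start - F_inf) * np.exp(-times / config.tau)
    if config.sigma > 0:
        rng = np.random.default_rng(config.seed)
        emission = emission + rng.normal(0.0, config.sigma, size=n_samples)
    meta = {
        "geometry": config.geometry,
        "seed": config.seed,
        "F_start": float(start),
        "F_inf": float(F_inf),
        "tau": float(config.tau),
        "sigma": float(config.sigma),
    }
    return FluorescenceTrace(name=name, times=times, emission=emission, meta=meta)


def panel_signal(
    pattern: MatchPattern, model: PanelSignalModel, params: WindowParams
) -> float:
    """True normalized equilibrium signal of one pattern.

    Per-name overrides win; otherwise the signal interpolates linearly
    between the heterologous baseline (no passing windows) and 1 (every
    window passes, as for the homologous sequence).
    """
    if pattern.name in model.overrides:
        return float(model.overrides[pattern.name])
    n_windows = pattern.n - params.M + 1
    n_pass = count_passing_windows(pattern, params)
    return model.s_het + (1.0 - model.s_het) * n_pass / n_windows


def _plateau(signal: float, config: SimConfig) -> tuple[float, float]:
    """(F_start, F_inf) realizing a normalized signal in a geometry."""
    span = config.F0 * (1.0 - _FLOOR_FRACTION)
    if config.geometry == QUENCH_DOWN:
        return config.F0, config.F0 - span * signal
    return config.F0 * _FLOOR_FRACTION, config.F0 * _FLOOR_FRACTION + span * signal


def simulate_panel(
    panel: Mapping[str, MatchPattern],
    model: PanelSignalModel,
    config: SimConfig,
    params: WindowParams = WindowParams(8, 2),
) -> tuple[dict[str, FluorescenceTrace], dict[str, dict]]:
    """One seeded trace per panel pattern plus a ground-truth manifest.

    Each trace draws its own child seed from ``config.seed`` so the panel
    is a pure function of (panel, model, config, params).  The manifest
    records the generative signal and plateau of every trace.
    """
    root = np.random.default_rng(config.seed)
    traces: dict[str, FluorescenceTrace] = {}
    manifest: dict[str, dict] = {}
    for name, pattern in panel.items():
        signal = panel_signal(pattern, model, params)
        start, plateau = _plateau(signal, config)
        child_seed = int(root.integers(0, 2**31 - 1))
        trace_cfg = replace(config, seed=child_seed)
        traces[name] = simulate_trace(trace_cfg, plateau, name=name, F_start=start)
        manifest[name] = {
            "signal": signal,
            "F_start": start,
            "F_inf": plateau,
            "seed": child_seed,
            "geometry": config.geometry,
        }
    return traces, manifest
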