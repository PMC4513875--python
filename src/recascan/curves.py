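"""Asymptote estimation and normalization of fluorescence time courses.

Each trace is reduced to its equilibrium plateau by a three-parameter
exponential least-squares fit, F(t) = F_inf + (F0 - F_inf) exp(-t/tau);
a tail-mean estimate (mean of the final 10% of samples) is always
computed alongside as the model-free fallback, since published "final
values" may be tail means rather than fit asymptotes.  Plateaus are then
mapped onto the 0-1 scale used for the parameter scan by anchoring at
the homologous and heterologous references:

    v = (F_inf - F_inf^het) / (F_inf^hom - F_inf^het)

which sends het to 0 and hom to 1 in either geometry (the quench-down
sign flip is absorbed by the negative denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .fret import FluorescenceTrace

__all__ = [
    "AsymptoteFit",
    "NormalizedSignal",
    "TraceInputError",
    "NormalizationError",
    "fit_asymptote",
    "normalize_signal",
    "process_panel",
    "tail_mean",
]

_TAIL_FRACTION = 0.10
_RTOL = 1e-8


class TraceInputError(ValueError):
    """Trace unsuitable for asymptote estimation."""


class NormalizationError(ValueError):
    """Reference asymptotes cannot anchor a normalization."""


@dataclass(frozen=True)
class AsymptoteFit:
    """Result of the exponential plateau fit for one trace."""

    name: str
    F0_hat: float
    F_inf_hat: float
    tau_hat: float
    residual_rms: float
    converged: bool
    tail_mean: float
    method: str  # "fit" or "tail"


@dataclass(frozen=True)
class NormalizedSignal:
    """Plateau mapped onto the hom=1 / het=0 scale."""

    name: str
    value: float
    clipped: bool
    hom_reference: float
    het_reference: float


def tail_mean(trace: FluorescenceTrace, fraction: float = _TAIL_FRACTION) -> float:
    """Mean emission over the final ``fraction`` of samples."""
    k = max(1, int(round(fraction * len(trace.emission))))
    return float(np.mean(trace.emission[-k:]))


def _exponential(t, F_inf, F0, tau):
    return F_inf + (F0 - F_inf) * np.exp(-t / tau)


def fit_asymptote(trace: FluorescenceTrace) -> AsymptoteFit:
    """Three-parameter exponential fit of a trace's approach to equilibrium.

    Initialization: F_inf from the tail mean, F0 from the first sample,
    tau from the time at which half of the total change has occurred.
    Degenerate (flat) traces return the constant level with tau flagged
    unidentifiable; non-convergence falls back to the tail mean.
    """
    t, y = trace.times, trace.emission
    if len(y) < 10:
        raise TraceInputError(f"{trace.name!r}: need >= 10 samples, got {len(y)}")
    tail = tail_mean(trace)
    y0 = float(y[0])
    span = tail - y0
    scatter = float(np.std(y))
    if abs(span) < 1e-12 * max(1.0, abs(y0)) and scatter < 1e-12 * max(1.0, abs(y0)):
        # constant trace: plateau is the level, the time constant is meaningless
        return AsymptoteFit(
            name=trace.name,
            F0_hat=y0,
            F_inf_hat=y0,
            tau_hat=float("nan"),
            residual_rms=0.0,
            converged=False,
            tail_mean=tail,
            method="tail",
        )
    half = y0 + 0.5 * span
    crossed = np.nonzero((y - half) * np.sign(span) >= 0)[0]
    tau0 = float(t[crossed[0]]) if len(crossed) else float(t[-1] / 2)
    tau0 = max(tau0, float(t[1] - t[0]))
    if t[-1] < 3 * tau0:
        raise TraceInputError(
            f"{trace.name!r}: trace spans {t[-1]:.3g} s < 3 estimated time "
            f"constants ({tau0:.3g} s); plateau not identifiable"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _exponential,
                t,
                y,
                p0=[tail, y0, tau0],
                xtol=_RTOL,
                ftol=_RTOL,
                maxfev=10000,
            )
        F_inf_hat, F0_hat, tau_hat = (float(v) for v in popt)
        resid = y - _exponential(t, *popt)
        rms = float(np.sqrt(np.mean(resid**2)))
        lo, hi = float(np.min(y)), float(np.max(y))
        guard = 3.0 * max(rms, 1e-12)
        if not np.isfinite(F_inf_hat) or not (lo - guard <= F_inf_hat <= hi + guard):
            raise RuntimeError("fit plateau outside the observed emission range")
        return AsymptoteFit(
            name=trace.name,
            F0_hat=F0_hat,
            F_inf_hat=F_inf_hat,
            tau_hat=tau_hat,
            residual_rms=rms,
            converged=True,
            tail_mean=tail,
            method="fit",
        )
    except RuntimeError:
        return AsymptoteFit(
            name=trace.name,
            F0_hat=y0,
            F_inf_hat=tail,
            tau_hat=float("nan"),
            residual_rms=float("nan"),
            converged=False,
            tail_mean=tail,
            method="tail",
        )


def normalize_signal(
    fit: AsymptoteFit,
    hom_fit: AsymptoteFit,
    het_fit: AsymptoteFit,
    clip: tuple[float, float] = (-0.1, 1.1),
) -> NormalizedSignal:
    """Map a plateau onto the hom=1 / het=0 scale.

    Slightly out-of-range values from noise are clipped to ``clip`` and
    flagged; coincident references raise :class:`NormalizationError`.
    """
    span = hom_fit.F_inf_hat - het_fit.F_inf_hat
    scale = max(abs(hom_fit.F_inf_hat), abs(het_fit.F_inf_hat), 1.0)
    if abs(span) < 1e-9 * scale:
        raise NormalizationError(
            "homologous and heterologous reference plateaus coincide; "
            "cannot anchor normalization"
        )
    v = (fit.F_inf_hat - het_fit.F_inf_hat) / span
    lo, hi = clip
    clipped = bool(v < lo or v > hi)
    v = float(np.clip(v, lo, hi))
    return NormalizedSignal(
        name=fit.name,
        value=v,
        clipped=clipped,
        hom_reference=hom_fit.F_inf_hat,
        het_reference=het_fit.F_inf_hat,
    )


def process_panel(
    traces: Mapping[str, FluorescenceTrace],
    hom_name: str = "hom",
    het_name: str = "het",
) -> pd.DataFrame:
    """Fit and normalize a whole panel of traces.

    Returns one row per trace, in panel order, with the fit parameters,
    the tail-mean fallback and the normalized signal.  Requires the
    homologous and heterologous reference traces to be present.
    """
    missing = [k for k in (hom_name, het_name) if k not in traces]
    if missing:
        raise TraceInputError(f"panel lacks reference trace(s): {missing}")
    fits = {name: fit_asymptote(trace) for name, trace in traces.items()}
    hom_fit, het_fit = fits[hom_name], fits[het_name]
    rows = []
    for name, fit in fits.items():
        sig = normalize_signal(fit, hom_fit, het_fit)
        rows.append(
            {
                "name": name,
                "F0_hat": fit.F0_hat,
                "F_inf_hat": fit.F_inf_hat,
                "tau_hat": fit.tau_hat,
                "tail_mean": fit.tail_mean,
                "method": fit.method,
                "normalized": sig.value,
                "clipped": sig.clipped,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "F0_hat",
            "F_inf_hat",
            "tau_hat",
            "tail_mean",
            "method",
            "normalized",
            "clipped",
        ],
    )
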