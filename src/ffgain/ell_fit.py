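"""Application to the electrosensory lateral-line lobe (ELL) of the weakly
electric fish *Apteronotus leptorhynchus*.

Superficial pyramidal cells in vivo show divisive gain control of their
response to electric-field amplitude modulations (AMs), which disappears
when the parallel-fiber feedforward pathway from the eminentia granularis
is lesioned.  This module maps AM intensity ``E_AM`` (mV/cm) onto the model
bias through a Boltzmann electroreceptor-afferent tuning curve,

    mu(E_AM) = mu_0 + A / (1 + exp(-k (E_AM - h))),    A = tau_m G_aff r_max,

and predicts SP f-I curves for three conventions of the feedforward
strength: lesion (``G = 0``), constant control (``G = -0.65``), and an ad
hoc amplitude-dependent sigmoid ``G(E_AM) = G_0 + B/(1 + exp(-kappa E_AM))``
that turns net-excitatory at small AMs, as the baseline-rate data demand.
Default parameter values are the standard ELL set (tau_m = 6 ms,
tau_r = 0.8 ms, sigma = 0.01; mu_0 = -0.16, A = 2.31, k = 3 cm/mV, h = 0;
G_0 = 0.75, B = -1.4, kappa = 5).  No raw experimental data are fitted
here; the module evaluates the forward model only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import core_rates as cr
from .core_rates import FeedforwardParams, NeuronParams, RateCurve

__all__ = [
    "AfferentParams",
    "GSigmoidParams",
    "ELL_NEURON",
    "AM_REFERENCE_MV_PER_CM",
    "am_to_db",
    "db_to_am",
    "afferent_rate",
    "mu_of_am",
    "g_of_am",
    "predict_ell_curves",
    "ell_curve_frame",
]

#: Zero-decibel reference amplitude modulation.
AM_REFERENCE_MV_PER_CM = 2.0

#: LIF constants of the ELL pyramidal-cell model.
ELL_NEURON = NeuronParams(tau_m=6.0, tau_r=0.8, v_th=1.0, v_r=0.0, sigma=0.01)

#: Constant feedforward strength matching the control data at large AMs.
G_CONTROL_CONST = -0.65


@dataclass(frozen=True)
class AfferentParams:
    """Electroreceptor-afferent drive onto a pyramidal cell.

    ``a`` is the lumped gain ``tau_m * G_aff * r_max`` (bias units; the two
    factors are never needed separately), ``k`` the Boltzmann slope (cm/mV),
    ``h`` the half-activation AM (mV/cm), ``mu0`` the intrinsic bias.
    """

    a: float = 2.31
    k: float = 3.0
    h: float = 0.0
    mu0: float = -0.16

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("Boltzmann slope k must be > 0")


@dataclass(frozen=True)
class GSigmoidParams:
    """Amplitude-dependent feedforward strength
    ``G(E_AM) = g0 + b / (1 + exp(-kappa E_AM))``; ``b < 0`` makes the
    pathway net inhibitory at large amplitudes."""

    g0: float = 0.75
    b: float = -1.4
    kappa: float = 5.0

    def __post_init__(self) -> None:
        if self.g0 + self.b >= 0:
            raise ValueError("need g0 + b < 0 (net inhibitory at large AM)")


def am_to_db(e_am: np.ndarray | float) -> np.ndarray | float:
    """AM intensity to decibels: ``20 log10(E_AM / 2 mV/cm)``."""
    e_am = np.asarray(e_am, dtype=float)
    if np.any(e_am <= 0):
        raise ValueError("E_AM must be > 0 for the decibel scale")
    out = 20.0 * np.log10(e_am / AM_REFERENCE_MV_PER_CM)
    return float(out) if out.ndim == 0 else out


def db_to_am(db: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`am_to_db` (exact round trip)."""
    db = np.asarray(db, dtype=float)
    out = AM_REFERENCE_MV_PER_CM * 10.0 ** (db / 20.0)
    return float(out) if out.ndim == 0 else out


def afferent_rate(ap: AfferentParams, e_am: np.ndarray | float) -> np.ndarray | float:
    """Normalized afferent activation ``r_aff / r_max``: a Boltzmann sigmoid
    ``1 / (1 + exp(-k (E_AM - h)))`` with slope ``k/4`` at half-activation."""
    e_am = np.asarray(e_am, dtype=float)
    out = 1.0 / (1.0 + np.exp(-ap.k * (e_am - ap.h)))
    return float(out) if out.ndim == 0 else out


def mu_of_am(ap: AfferentParams, e_am: np.ndarray | float) -> np.ndarray | float:
    """Pyramidal-cell bias as a function of AM intensity:
    ``mu_0 + A * r_aff(E_AM)/r_max``."""
    out = ap.mu0 + ap.a * np.asarray(afferent_rate(ap, e_am))
    return float(out) if np.ndim(out) == 0 else out


def g_of_am(gp: GSigmoidParams, e_am: np.ndarray | float) -> np.ndarray | float:
    """Amplitude-dependent feedforward strength; decreasing in ``E_AM`` for
    ``b < 0`` and changing sign at a small positive amplitude."""
    e_am = np.asarray(e_am, dtype=float)
    out = gp.g0 + gp.b / (1.0 + np.exp(-gp.kappa * e_am))
    return float(out) if out.ndim == 0 else out


def default_am_grid(n: int = 80) -> np.ndarray:
    """Log-spaced AM grid from 0.01 to 20 mV/cm.

    The lower end sits below the sign change of the default ``G(E_AM)``
    (~0.03 mV/cm) so that the lesion/control crossing is on-grid.
    """
    return np.logspace(np.log10(0.01), np.log10(20.0), n)


def predict_ell_curves(
    ap: AfferentParams,
    gp: GSigmoidParams,
    p: NeuronParams = ELL_NEURON,
    mode: Literal["lesion", "control_constG", "control_sigmoidG"] = "lesion",
    e_grid: Sequence[float] | None = None,
    *,
    g_const: float = G_CONTROL_CONST,
    baseline_hz: float = 0.0,
) -> RateCurve:
    """Predicted SP f-I curve versus AM intensity.

    ``lesion`` removes the parallel fibers (``G = 0``), so the SP rate is
    the single-neuron rate at ``mu(E_AM)``; ``control_constG`` applies a
    fixed strength ``g_const``; ``control_sigmoidG`` applies the
    amplitude-dependent ``G(E_AM)``.  An optional baseline rate (Hz) can be
    added when comparing with experimental absolute rates; by default the
    curve is the bare model prediction.
    """
    if e_grid is None:
        e_grid = default_am_grid()
    e_grid = np.asarray(e_grid, dtype=float)
    rates = np.empty(e_grid.size)
    for i, e in enumerate(e_grid):
        mu = mu_of_am(ap, e)
        if mode == "lesion":
            g = 0.0
        elif mode == "control_constG":
            g = g_const
        elif mode == "control_sigmoidG":
            g = g_of_am(gp, e)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        ff = FeedforwardParams(g=g, n=1)
        rates[i] = cr.sp_rate(p, p, ff, mu)
    rates = rates + baseline_hz / 1e3
    return RateCurve(e_grid, rates, np.zeros_like(rates), "analytic",
                     tau_r=p.tau_r)


def ell_curve_frame(curve: RateCurve) -> pd.DataFrame:
    """Curve as a table with AM in mV/cm and dB, rates in Hz."""
    return pd.DataFrame(
        {
            "e_am_mv_per_cm": curve.x,
            "db": am_to_db(curve.x),
            "rate_hz": curve.rate * 1e3,
        }
    )
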