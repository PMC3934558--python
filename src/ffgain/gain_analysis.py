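"""Gain-regime machinery.

The feedforward circuit shows three qualitatively different modulations of
the SP f-I curve: a *subtractive* shift (noise-free neurons), a *divisive*
slope rescaling (noisy neurons, moderate inhibition) and a *non-monotonic*
curve with a maximum (noisy neurons, strong inhibition).  The boundary
between the last two is set by the maximum slope ``gamma`` of the DP f-I
curve: extrema of the effective bias ``mu_eff = mu + tau_m G r_D(mu)``
solve ``r_D'(mu) = -1/(tau_m G)``, and because ``r_D'`` is bell-shaped this
equation has two roots (a maximum then a minimum) exactly when
``gamma > 1/(tau_m |G|)``; the critical strength is ``|G|_c = 1/(tau_m
gamma)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from . import core_rates as cr
from .core_rates import FeedforwardParams, NeuronParams, RateCurve

__all__ = [
    "ExtremumRecord",
    "RegimeReport",
    "max_slope_gamma",
    "find_extrema",
    "critical_g",
    "classify_regime",
    "phase_diagram",
    "average_gain",
    "peak_position",
]


@dataclass(frozen=True)
class ExtremumRecord:
    """One extremum of the effective bias mu_eff(mu)."""

    mu_star: float
    kind: Literal["maximum", "minimum"]
    mu_eff_value: float


@dataclass
class RegimeReport:
    """Classification of one (sigma, G) point of the phase diagram."""

    sigma: float
    g: float
    regime: Literal["subtractive", "divisive", "non_monotonic"]
    gamma: float | None = None
    g_critical: float | None = None
    extrema: list[ExtremumRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "g": self.g,
            "regime": self.regime,
            "gamma": self.gamma,
            "g_critical": self.g_critical,
            "extrema": [
                {"mu_star": e.mu_star, "kind": e.kind,
                 "mu_eff_value": e.mu_eff_value}
                for e in self.extrema
            ],
        }


# ---------------------------------------------------------------------------
# scan range
# ---------------------------------------------------------------------------

def _scan_range(p: NeuronParams, g_abs: float = 1.0) -> tuple[float, float]:
    """Bias interval guaranteed to contain the bell of r_D'(mu).

    Starts at ``[V_r - 5 sigma, V_th + 5 sigma + 2]`` and widens until the
    gradient at both ends has decayed below 1% of the interior maximum, so
    every sign change of ``1 + tau_m G r_D'`` is bracketed inside.
    """
    lo = p.v_r - 5.0 * p.sigma
    hi = p.v_th + 5.0 * p.sigma + 2.0 / max(g_abs, 1.0)
    for _ in range(40):
        grid = np.linspace(lo, hi, 64)
        grads = np.array([cr.rate_gradient(p, m) for m in grid])
        peak = grads.max()
        if grads[0] < peak / 100.0 and grads[-1] < peak / 100.0:
            return lo, hi
        width = hi - lo
        if grads[0] >= peak / 100.0:
            lo -= 0.5 * width  # Gaussian tail: shrinks fast
        if grads[-1] >= peak / 100.0:
            hi += width  # algebraic tail (~1/mu^2): needs geometric growth
    raise RuntimeError("failed to bracket the gradient bell")


# ---------------------------------------------------------------------------
# gamma and the critical line
# ---------------------------------------------------------------------------

def _gamma_and_argmax(p_d: NeuronParams, n_grid: int = 256) -> tuple[float, float]:
    """(gamma, argmax mu) of the gradient bell: bracketing grid, a refining
    grid around the coarse argmax, then bounded scalar maximization."""
    if p_d.sigma <= 0:
        raise ValueError("gamma is defined for sigma > 0")
    lo, hi = _scan_range(p_d)
    grid = np.linspace(lo, hi, n_grid)
    grads = np.array([cr.rate_gradient(p_d, m) for m in grid])
    k = int(np.argmax(grads))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]
    fine = np.linspace(a, b, 32)
    fgrads = np.array([cr.rate_gradient(p_d, m) for m in fine])
    j = int(np.argmax(fgrads))
    a2 = fine[max(j - 1, 0)]
    b2 = fine[min(j + 1, fine.size - 1)]
    res = minimize_scalar(lambda m: -cr.rate_gradient(p_d, m),
                          bounds=(a2, b2), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError("gamma maximization failed to converge")
    return float(-res.fun), float(res.x)


def max_slope_gamma(p_d: NeuronParams, *, n_grid: int = 256) -> float:
    """Maximum slope ``gamma`` of the DP f-I curve (ms^-1 per bias unit)."""
    return _gamma_and_argmax(p_d, n_grid)[0]


def critical_g(p_d: NeuronParams) -> float:
    """Critical feedforward magnitude ``|G|_c = 1/(tau_m gamma)`` separating
    the divisive (no extrema) and non-monotonic (two extrema) regimes."""
    return 1.0 / (p_d.tau_m * max_slope_gamma(p_d))


# ---------------------------------------------------------------------------
# extrema of the effective bias
# ---------------------------------------------------------------------------

def find_extrema(
    p_d: NeuronParams,
    ff: FeedforwardParams,
    mu_range: tuple[float, float] | None = None,
    *,
    n_grid: int = 400,
) -> list[ExtremumRecord]:
    """Roots of ``d mu_eff / d mu = 1 + tau_m G r_D'(mu) = 0``.

    Because ``r_D'`` is a single bell of height ``gamma``, the equation has
    either no root (``gamma <= 1/(tau_m |G|)``, in particular ``G = 0``) or
    exactly two, one on each flank of the bell.  Each flank yields a
    sign-change bracket (``d mu_eff/d mu`` is positive at the scan-range
    ends and negative at the bell's argmax) polished by a bracketing root
    finder; roots are classified by the sign of the derivative on either
    side — positive-to-negative is a maximum of the effective bias,
    negative-to-positive a minimum.
    """
    if p_d.sigma <= 0:
        raise ValueError("find_extrema requires sigma > 0")
    if ff.g == 0.0:
        return []
    if mu_range is None:
        mu_range = _scan_range(p_d, abs(ff.g))
    gamma, mu_peak = _gamma_and_argmax(p_d)
    if 1.0 + p_d.tau_m * ff.g * gamma >= 0.0:
        return []

    def dmu_eff(m: float) -> float:
        return 1.0 + p_d.tau_m * ff.g * cr.rate_gradient(p_d, m)

    lo, hi = mu_range
    if not (dmu_eff(lo) > 0 and dmu_eff(hi) > 0):
        raise RuntimeError(
            "scan range does not bracket the gradient bell; widen mu_range"
        )
    records: list[ExtremumRecord] = []
    for a, b, kind in ((lo, mu_peak, "maximum"), (mu_peak, hi, "minimum")):
        root = brentq(dmu_eff, a, b, xtol=1e-10)
        records.append(
            ExtremumRecord(mu_star=float(root), kind=kind,
                           mu_eff_value=float(cr.effective_bias(p_d, ff, root)))
        )
    return records


def classify_regime(p_d: NeuronParams, ff: FeedforwardParams) -> RegimeReport:
    """Subtractive iff noise-free; otherwise non-monotonic iff the effective
    bias has extrema, else divisive."""
    if p_d.sigma == 0.0:
        return RegimeReport(sigma=0.0, g=ff.g, regime="subtractive")
    gamma = max_slope_gamma(p_d)
    extrema = find_extrema(p_d, ff)
    regime = "non_monotonic" if extrema else "divisive"
    return RegimeReport(sigma=p_d.sigma, g=ff.g, regime=regime,
                        gamma=gamma, g_critical=1.0 / (p_d.tau_m * gamma),
                        extrema=extrema)


def phase_diagram(
    sigma_grid: Sequence[float],
    p_template: NeuronParams = NeuronParams(),
) -> pd.DataFrame:
    """Critical line ``|G|_c(sigma)`` of the divisive/non-monotonic boundary
    as a table with columns ``sigma`` and ``g_critical``."""
    rows = []
    for sigma in sigma_grid:
        if sigma <= 0:
            raise ValueError("phase_diagram requires sigma > 0")
        p = NeuronParams(tau_m=p_template.tau_m, tau_r=p_template.tau_r,
                         v_th=p_template.v_th, v_r=p_template.v_r,
                         sigma=float(sigma))
        rows.append({"sigma": float(sigma), "g_critical": critical_g(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gains and peaks
# ---------------------------------------------------------------------------

def average_gain(
    curve: RateCurve,
    fit_fraction_range: tuple[float, float] = (0.10, 0.60),
) -> tuple[float, float]:
    """Average gain: OLS slope (with standard error) of the f-I curve over
    the sub-grid where the rate lies between the given fractions of the
    saturation rate 1/tau_r — the approximately linear mid-range."""
    if curve.tau_r is None:
        raise ValueError("curve must carry tau_r to window on rate fractions")
    lo, hi = fit_fraction_range
    rmax = 1.0 / curve.tau_r
    mask = (curve.rate >= lo * rmax) & (curve.rate <= hi * rmax)
    if np.count_nonzero(mask) < 3:
        raise ValueError(
            f"only {np.count_nonzero(mask)} grid points fall in the fit "
            f"window [{lo}, {hi}] of 1/tau_r; refine the grid"
        )
    x, y = curve.x[mask], curve.rate[mask]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = x.size - 2
    sxx = np.sum((x - x.mean()) ** 2)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else 0.0
    return float(slope), se


def peak_position(
    p_d: NeuronParams,
    p_s: NeuronParams,
    ff: FeedforwardParams,
) -> float:
    """Input ``mu`` at the SP f-I curve's maximum in the non-monotonic
    regime.

    Because the SP rate increases monotonically with the effective bias, the
    SP peak sits at the maximum-kind extremum of ``mu_eff``.  Raises if the
    circuit is not in the non-monotonic regime.
    """
    report = classify_regime(p_d, ff)
    if report.regime != "non_monotonic":
        raise ValueError(
            f"peak_position is defined in the non-monotonic regime only "
            f"(got {report.regime} at sigma={p_d.sigma}, G={ff.g})"
        )
    maxima = [e for e in report.extrema if e.kind == "maximum"]
    return maxima[0].mu_star
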