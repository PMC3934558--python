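"""Stationary firing-rate theory for the feedforward-inhibition circuit.

A population of "deep" (DP) leaky integrate-and-fire neurons receives a
constant sensory bias ``mu`` and drives, through an inhibitory pathway of
lumped strength ``G <= 0``, a "superficial" (SP) LIF cell that receives the
same bias.  In the mean-field (diffusion) limit the SP cell simply sees an
*effective bias*

    mu_eff = mu + tau_m * G * r_D(mu),

so its f-I curve is the single-neuron rate function evaluated at ``mu_eff``.
This module provides the single-neuron rate functions (deterministic
threshold formula and the exact Siegert/Tuckwell integral for white-noise
input), their ``mu``-derivative, the effective bias, the open-loop SP rate,
the self-consistent closed-loop rate used for comparison with recurrent
feedback models, and the near-onset linearization of the DP curve.

Units: time in ms throughout, rates internally in ms^-1 (so that
``tau_m * G * r`` is a dimensionless bias), voltages in dimensionless
resting-to-threshold units.  Serialized rate tables report Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import erfcx

__all__ = [
    "NeuronParams",
    "FeedforwardParams",
    "LinearOnsetFit",
    "RateCurve",
    "rate_deterministic",
    "rate_stochastic",
    "rate",
    "rate_gradient",
    "effective_bias",
    "sp_rate",
    "closed_loop_rate",
    "fit_onset_linearization",
    "dp_rate_curve",
    "sp_rate_curve",
    "SIGMA_DETERMINISTIC_CUTOFF",
]

_SQRT_PI = np.sqrt(np.pi)

#: Below this noise intensity the Siegert quadrature is ill-conditioned and
#: the deterministic formula is exact to well beyond float precision.
SIGMA_DETERMINISTIC_CUTOFF = 1e-4

#: |z| beyond which exp(z^2) overflows double precision; the rate there
#: underflows to zero anyway.
_Z_OVERFLOW = 26.0


@dataclass(frozen=True)
class NeuronParams:
    """Constants of one LIF population.

    Parameters
    ----------
    tau_m : membrane time constant (ms).
    tau_r : absolute refractory period (ms).
    v_th, v_r : spike threshold and reset (resting-to-threshold units).
    sigma : intrinsic white-noise intensity (same units as the bias).
    mu : default constant sensory bias, used by configuration plumbing;
        the rate functions take the bias explicitly.
    """

    tau_m: float = 10.0
    tau_r: float = 1.0
    v_th: float = 1.0
    v_r: float = 0.0
    sigma: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be > 0, got {self.tau_m}")
        if self.tau_r < 0:
            raise ValueError(f"tau_r must be >= 0, got {self.tau_r}")
        if not self.v_th > self.v_r:
            raise ValueError(f"v_th ({self.v_th}) must exceed v_r ({self.v_r})")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def rate_max(self) -> float:
        """Saturation rate 1/tau_r (ms^-1); inf when tau_r == 0."""
        return np.inf if self.tau_r == 0 else 1.0 / self.tau_r


@dataclass(frozen=True)
class FeedforwardParams:
    """Lumped DP -> SP feedforward pathway.

    ``G`` is the net pathway strength (inhibitory when negative), ``n`` the
    DP population size, ``kernel`` the synaptic filter shape, ``tau_s`` the
    synaptic time scale and ``tau_d`` the transmission delay (both ms).
    """

    g: float = 0.0
    n: int = 500
    kernel: Literal["delayed_alpha", "delta"] = "delayed_alpha"
    tau_s: float = 5.0
    tau_d: float = 10.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"population size n must be >= 1, got {self.n}")
        if self.kernel not in ("delayed_alpha", "delta"):
            raise ValueError(f"unknown kernel kind {self.kernel!r}")
        if self.kernel == "delayed_alpha" and self.tau_s <= 0:
            raise ValueError("tau_s must be > 0 for the delayed_alpha kernel")
        if self.tau_d < 0:
            raise ValueError(f"tau_d must be >= 0, got {self.tau_d}")


@dataclass(frozen=True)
class LinearOnsetFit:
    """Least-squares line ``r_D ~ C1*mu + C2`` near the DP firing onset."""

    c1: float
    c2: float
    fit_range: tuple[float, float]
    residual: float

    def __post_init__(self) -> None:
        lo, hi = self.fit_range
        if not hi > lo:
            raise ValueError("fit_range must be non-degenerate")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")

    def predict(self, mu: np.ndarray | float) -> np.ndarray | float:
        return self.c1 * np.asarray(mu) + self.c2


@dataclass
class RateCurve:
    """Tabulated f-I relation on an increasing input grid.

    ``x`` is the input grid (bias units, or mV/cm for the ELL module),
    ``rate`` the firing rate in ms^-1, ``stderr`` the per-point standard
    error (zeros for analytic curves).  ``tau_r`` of the generating neuron
    is kept so that slope fits can window on fractions of the saturation
    rate 1/tau_r.
    """

    x: np.ndarray
    rate: np.ndarray
    stderr: np.ndarray
    source: Literal["analytic", "simulated"]
    tau_r: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if not (self.x.shape == self.rate.shape == self.stderr.shape):
            raise ValueError("x, rate and stderr must have identical shapes")
        if self.x.size > 1 and not np.all(np.diff(self.x) > 0):
            raise ValueError("x grid must be strictly increasing")
        if np.any(self.rate < -1e-12):
            raise ValueError("rates must be non-negative")
        if self.source not in ("analytic", "simulated"):
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        """Tabular form with rates in Hz (1 ms^-1 = 1000 Hz)."""
        return pd.DataFrame(
            {
                "x": self.x,
                "rate_hz": self.rate * 1e3,
                "stderr_hz": self.stderr * 1e3,
                "source": self.source,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# single-neuron rates
# ---------------------------------------------------------------------------

def rate_deterministic(p: NeuronParams, mu: float) -> float:
    """Noise-free LIF rate: 0 below threshold, else the threshold-crossing
    time formula ``1 / (tau_r + tau_m * ln((V_r - mu)/(V_th - mu)))``.

    The onset is strict (``mu > v_th``); at ``mu == v_th`` the crossing time
    diverges and the rate is 0.
    """
    if mu <= p.v_th:
        return 0.0
    return 1.0 / (p.tau_r + p.tau_m * np.log((p.v_r - mu) / (p.v_th - mu)))


def _siegert_integral(z_r: float, z_th: float) -> float:
    """``integral_{z_r}^{z_th} sqrt(pi) e^{z^2} (1 + erf z) dz``.

    Evaluated through the numerically stable identity
    ``e^{z^2}(1 + erf z) = erfcx(-z)``.
    """
    val, abserr = quad(
        lambda z: _SQRT_PI * erfcx(-z),
        z_r,
        z_th,
        epsabs=1e-12,
        epsrel=1e-10,
        limit=500,
    )
    if not np.isfinite(val) or abserr > max(1e-7, 1e-6 * abs(val)):
        raise RuntimeError(
            f"Siegert quadrature failed to converge on [{z_r}, {z_th}] "
            f"(value {val}, abserr {abserr})"
        )
    return val


def rate_stochastic(p: NeuronParams, mu: float) -> float:
    """Exact stationary rate of a white-noise-driven LIF neuron
    (Siegert/Tuckwell formula).

    ``[tau_r + tau_m * I(z_r, z_th)]^{-1}`` with ``z = (V - mu)/sigma``
    evaluated at reset and threshold.  Strictly increasing in ``mu`` and
    bounded in ``(0, 1/tau_r)``.  For ``sigma`` below
    :data:`SIGMA_DETERMINISTIC_CUTOFF` the quadrature is ill-conditioned and
    the call delegates to :func:`rate_deterministic` (the exact limit).
    """
    if p.sigma <= 0:
        raise ValueError("rate_stochastic requires sigma > 0; "
                         "use rate_deterministic for the noise-free neuron")
    if p.sigma < SIGMA_DETERMINISTIC_CUTOFF:
        return rate_deterministic(p, mu)
    z_th = (p.v_th - mu) / p.sigma
    z_r = (p.v_r - mu) / p.sigma
    if z_th >= _Z_OVERFLOW:
        # so far below threshold that exp(z^2) overflows; the rate itself
        # underflows to zero
        return 0.0
    return 1.0 / (p.tau_r + p.tau_m * _siegert_integral(z_r, z_th))


def rate(p: NeuronParams, mu: float) -> float:
    """Dispatch on noise: deterministic formula at sigma == 0 (or below the
    quadrature cutoff), Siegert integral otherwise."""
    if p.sigma < SIGMA_DETERMINISTIC_CUTOFF:
        return rate_deterministic(p, mu)
    return rate_stochastic(p, mu)


def rate_gradient(p: NeuronParams, mu: float) -> float:
    """Derivative ``d r / d mu`` of the Siegert rate (ms^-1 per bias unit).

    Closed form from differentiating the rate integral:
    ``(sqrt(pi) * tau_m * r^2 / sigma) * [erfcx(-z_th) - erfcx(-z_r)]``;
    strictly positive, and bell-shaped in ``mu`` (vanishes at both ends of
    the bias axis).
    """
    r = rate_stochastic(p, mu)
    if r == 0.0:
        return 0.0
    z_th = (p.v_th - mu) / p.sigma
    z_r = (p.v_r - mu) / p.sigma
    return (_SQRT_PI * p.tau_m * r * r / p.sigma) * (erfcx(-z_th) - erfcx(-z_r))


# ---------------------------------------------------------------------------
# circuit-level quantities
# ---------------------------------------------------------------------------

def effective_bias(p_d: NeuronParams, ff: FeedforwardParams, mu: float) -> float:
    """Mean total drive to the SP cell: ``mu + tau_m * G * r_D(mu)``.

    Uses the deterministic or stochastic DP rate according to
    ``p_d.sigma``.  For ``G <= 0`` the result never exceeds ``mu``.
    """
    return mu + p_d.tau_m * ff.g * rate(p_d, mu)


def sp_rate(
    p_s: NeuronParams,
    p_d: NeuronParams,
    ff: FeedforwardParams,
    mu: float,
) -> float:
    """Open-loop SP firing rate: the single-neuron rate of the SP cell
    evaluated at the effective bias.

    With ``G == 0`` and identical parameters this is *the same code path*
    as the DP rate, so the two curves agree bit for bit.
    """
    return rate(p_s, effective_bias(p_d, ff, mu))


def closed_loop_rate(
    p: NeuronParams,
    ff: FeedforwardParams,
    mu: float,
    *,
    damping: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> float:
    """Self-consistent rate of a single pyramidal population inhibiting
    itself (closed-loop feedback), for comparison with the open-loop model.

    Solves ``nu = F(nu)`` where ``F(nu)`` is the Siegert rate at bias
    ``mu + tau_m * G * nu``, by damped fixed-point iteration
    ``nu <- (1 - a) nu + a F(nu)`` started at the ``G = 0`` rate.  For
    ``G < 0`` the map F is monotone decreasing in ``nu``, and damping makes
    the iteration contract in practice.
    """
    if p.sigma <= 0:
        raise ValueError("closed_loop_rate requires sigma > 0")
    if ff.g > 0:
        raise ValueError("closed_loop_rate assumes inhibitory feedback (G <= 0)")

    def F(nu: float) -> float:
        return rate_stochastic(p, mu + p.tau_m * ff.g * nu)

    nu = rate_stochastic(p, mu)
    for _ in range(max_iter):
        f_nu = F(nu)
        if abs(f_nu - nu) < tol:
            return f_nu
        nu = (1.0 - damping) * nu + damping * f_nu
    raise RuntimeError(
        f"closed-loop fixed point did not converge within {max_iter} "
        f"iterations (residual {abs(F(nu) - nu):.3e})"
    )


# ---------------------------------------------------------------------------
# near-onset linearization
# ---------------------------------------------------------------------------

def _find_mu_at_rate(p: NeuronParams, target: float) -> float:
    """Bias at which the stochastic rate equals ``target`` (bisection on the
    monotone rate function, with an expanding initial bracket)."""
    from scipy.optimize import brentq

    lo, hi = p.v_th - 10.0 * p.sigma - 1.0, p.v_th + 10.0 * p.sigma + 1.0
    while rate_stochastic(p, lo) > target:
        lo -= max(5.0 * p.sigma, 1.0)
        if lo < p.v_th - 1e3:
            raise RuntimeError("failed to bracket the onset from below")
    while rate_stochastic(p, hi) < target:
        hi += max(5.0 * p.sigma, 1.0)
        if hi > p.v_th + 1e4:
            raise RuntimeError("failed to bracket the onset from above")
    return brentq(lambda m: rate_stochastic(p, m) - target, lo, hi, xtol=1e-10)


def fit_onset_linearization(
    p_d: NeuronParams,
    mu_range: tuple[float, float] | None = None,
    *,
    n_points: int = 50,
    rate_fractions: tuple[float, float] = (0.02, 0.40),
) -> LinearOnsetFit:
    """Least-squares line ``r_D ~ C1 mu + C2`` over the near-onset region.

    Noise linearizes the DP f-I curve around its onset; this fit quantifies
    that linearization, and its slope ``C1`` predicts the divisive factor
    ``1 + C1 tau_m G`` relating SP and DP gains.  When ``mu_range`` is not
    given it defaults to the biases at which the rate equals
    ``rate_fractions`` (default 2% and 40%) of the saturation rate 1/tau_r.
    """
    if p_d.sigma <= 0:
        raise ValueError("the onset linearization is defined for sigma > 0")
    if mu_range is None:
        lo_frac, hi_frac = rate_fractions
        mu_lo = _find_mu_at_rate(p_d, lo_frac / p_d.tau_r)
        mu_hi = _find_mu_at_rate(p_d, hi_frac / p_d.tau_r)
    else:
        mu_lo, mu_hi = mu_range
    if not mu_hi > mu_lo:
        raise ValueError(f"degenerate fit range [{mu_lo}, {mu_hi}]")
    mus = np.linspace(mu_lo, mu_hi, n_points)
    rates = np.array([rate_stochastic(p_d, m) for m in mus])
    c1, c2 = np.polyfit(mus, rates, 1)
    residual = float(np.sqrt(np.mean((c1 * mus + c2 - rates) ** 2)))
    return LinearOnsetFit(c1=float(c1), c2=float(c2),
                          fit_range=(float(mu_lo), float(mu_hi)),
                          residual=residual)


# ---------------------------------------------------------------------------
# analytic curve builders
# ---------------------------------------------------------------------------

def dp_rate_curve(p_d: NeuronParams, mu_grid: Sequence[float]) -> RateCurve:
    """Analytic DP f-I curve on ``mu_grid``."""
    mu_grid = np.asarray(mu_grid, dtype=float)
    rates = np.array([rate(p_d, m) for m in mu_grid])
    return RateCurve(mu_grid, rates, np.zeros_like(rates), "analytic",
                     tau_r=p_d.tau_r)


def sp_rate_curve(
    p_s: NeuronParams,
    p_d: NeuronParams,
    ff: FeedforwardParams,
    mu_grid: Sequence[float],
) -> RateCurve:
    """Analytic open-loop SP f-I curve on ``mu_grid``."""
    mu_grid = np.asarray(mu_grid, dtype=float)
    rates = np.array([sp_rate(p_s, p_d, ff, m) for m in mu_grid])
    return RateCurve(mu_grid, rates, np.zeros_like(rates), "analytic",
                     tau_r=p_s.tau_r)
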