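"""Stochastic simulation of the DP population and the SP cell.

``N`` deep-pyramidal LIF neurons integrate the sensory bias (optionally a
fluctuating stimulus) with independent white noise.  Their pooled spike
train, filtered by a synaptic kernel ``s`` and scaled by ``tau_m * G / N``,
forms the feedforward signal ``f(t)`` injected into the superficial cell(s).
The circuit is strictly feedforward — the DP dynamics never see ``f`` — so
the simulator runs in two passes: (1) integrate the DP population and bin
its spikes, (2) convolve the binned population spike train with the kernel
(FFT convolution; identical to depositing each spike's kernel) and integrate
the SP cell(s) under ``mu + zeta + f``.

Every run is reproducible from a single seed: per-population RNG streams,
initial conditions and the stimulus realization are all derived from it.
Initial membrane potentials are drawn uniformly on ``[V_r, V_th)`` so that a
noise-free population starts desynchronized (with ``sigma = 0`` all neurons
would otherwise spike in lockstep and ``f(t)`` would be a pulse train rather
than an approximately constant drive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .core_rates import FeedforwardParams, NeuronParams, RateCurve
from ._integrator import integrate_lif_population

__all__ = [
    "SynapticKernel",
    "SimConfig",
    "SimResult",
    "build_kernel",
    "simulate",
    "estimate_rate",
    "fi_curve_simulated",
]


@dataclass(frozen=True)
class SynapticKernel:
    """Discretized synaptic filter on the ``dt`` grid.

    ``weights[j]`` approximates ``s(t_j)`` (ms^-1) at the bin center
    ``t_j = (j + 1/2) dt``; the discrete mass ``sum(weights) * dt`` is
    renormalized to exactly 1 so that each presynaptic spike delivers total
    charge ``tau_m * G / N`` into ``f``.
    """

    kind: str
    tau_s: float
    tau_d: float
    dt: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        mass = float(np.sum(self.weights) * self.dt)
        if abs(mass - 1.0) > 1e-6:
            raise ValueError(f"kernel mass {mass} deviates from unity")


@dataclass(frozen=True)
class SimConfig:
    """Integration window and step.

    ``t_total``/``t_transient`` in ms; spikes before ``t_transient`` are
    excluded from rate estimates.  ``dt`` defaults to 0.05 ms.
    """

    t_total: float
    t_transient: float = 0.0
    dt: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.t_transient < self.t_total):
            raise ValueError("need 0 <= t_transient < t_total")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))


@dataclass
class SimResult:
    """Output of one network run.

    ``dp_spikes`` is a list of per-neuron spike-time arrays (ms; ``None``
    when spike recording was disabled for speed), ``sp_spikes`` a list of
    per-SP-neuron spike-time arrays.  ``f_trace`` and ``mu_eff_trace``
    (= ``mu + zeta + f``) are sampled on the dt grid.  Rates are in ms^-1
    with standard errors.
    """

    dp_spikes: list[np.ndarray] | None
    sp_spikes: list[np.ndarray] | None
    f_trace: np.ndarray
    mu_eff_trace: np.ndarray
    dp_rate: tuple[float, float]
    sp_rate: tuple[float, float]
    seed: int

    def spikes_to_frame(self):
        """Two-column table (neuron_id, time_ms); SP neurons get ids
        ``-1, -2, ...``."""
        import pandas as pd

        ids: list[np.ndarray] = []
        times: list[np.ndarray] = []
        if self.dp_spikes is not None:
            for i, t in enumerate(self.dp_spikes):
                ids.append(np.full(t.size, i, dtype=int))
                times.append(t)
        if self.sp_spikes is not None:
            for i, t in enumerate(self.sp_spikes):
                ids.append(np.full(t.size, -(i + 1), dtype=int))
                times.append(t)
        if ids:
            return pd.DataFrame(
                {"neuron_id": np.concatenate(ids), "time_ms": np.concatenate(times)}
            )
        return pd.DataFrame({"neuron_id": [], "time_ms": []})


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def build_kernel(kind: str, tau_s: float, tau_d: float, dt: float) -> SynapticKernel:
    """Discretize the synaptic filter ``s``.

    ``delayed_alpha``: ``s(t) = ((t - tau_d)/tau_s^2) exp(-(t - tau_d)/tau_s)``
    for ``t > tau_d``, sampled at bin centers, truncated at
    ``tau_d + 20 tau_s`` and renormalized to unit mass.  Requires
    ``dt <= tau_s / 10``.

    ``delta``: all mass ``1/dt`` in the single bin containing ``tau_d``.
    """
    if kind == "delayed_alpha":
        if dt > tau_s / 10.0:
            raise ValueError(
                f"dt={dt} too coarse for the alpha kernel (need dt <= tau_s/10)"
            )
        n_bins = int(np.ceil((tau_d + 20.0 * tau_s) / dt))
        t = (np.arange(n_bins) + 0.5) * dt
        w = np.where(t > tau_d,
                     (t - tau_d) / tau_s**2 * np.exp(-(t - tau_d) / tau_s),
                     0.0)
        w = w / (np.sum(w) * dt)
    elif kind == "delta":
        j = int(round(tau_d / dt))
        w = np.zeros(j + 1)
        w[j] = 1.0 / dt
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    return SynapticKernel(kind=kind, tau_s=tau_s, tau_d=tau_d, dt=dt, weights=w)


# ---------------------------------------------------------------------------
# seeds and rate estimation
# ---------------------------------------------------------------------------

def _derive_seeds(seed: int, n: int, *key: int) -> list[int]:
    """Deterministic sub-seeds (< 2^31) from a master seed and an optional
    mixing key (e.g. a grid index)."""
    ss = np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key))
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def estimate_rate(
    spikes: Sequence[float] | np.ndarray,
    t_transient: float,
    t_total: float,
) -> tuple[float, float]:
    """Empirical rate over ``(t_transient, t_total]`` with a Poisson-style
    standard error ``sqrt(count) / window``."""
    if t_total <= t_transient:
        raise ValueError("need t_total > t_transient")
    spikes = np.asarray(spikes, dtype=float)
    window = t_total - t_transient
    count = int(np.count_nonzero((spikes > t_transient) & (spikes <= t_total)))
    return count / window, np.sqrt(count) / window


def _rate_from_counts(counts: np.ndarray, window: float) -> tuple[float, float]:
    """Population rate estimate from per-neuron post-transient counts: mean
    rate with SEM across neurons (Poisson error for a single neuron)."""
    rates = counts / window
    mean = float(np.mean(rates))
    if counts.size > 1:
        se = float(np.std(rates, ddof=1) / np.sqrt(counts.size))
    else:
        se = float(np.sqrt(max(counts[0], 0)) / window)
    return mean, se


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def _stimulus_trace(stimulus, n_steps: int, dt: float, seed: int) -> tuple[float, np.ndarray | None]:
    """Split a stimulus into (constant bias, fluctuation trace or None)."""
    if np.isscalar(stimulus):
        return float(stimulus), None
    # duck-typed StimulusSpec (kept loose to avoid an import cycle)
    from .stimulus_delay import realize_fluctuation

    zeta = realize_fluctuation(stimulus, n_steps=n_steps, dt=dt, seed=seed)
    return float(stimulus.mu), zeta


def simulate(
    p_d: NeuronParams,
    p_s: NeuronParams,
    ff: FeedforwardParams,
    stimulus,
    cfg: SimConfig,
    *,
    record_spikes: bool = True,
    n_sp: int = 1,
) -> SimResult:
    """Euler–Maruyama integration of the full circuit.

    ``stimulus`` is either a constant bias (float) or a
    :class:`~ffgain.stimulus_delay.StimulusSpec`; in the latter case the
    low-pass fluctuation ``zeta(t)`` is shared by every DP neuron and the SP
    cell(s), while the intrinsic white noises stay independent.
    ``n_sp`` independent SP neurons (all seeing the same ``f`` and ``zeta``)
    can be integrated to tighten the SP rate estimate.
    """
    n_steps = cfg.n_steps
    dt = cfg.dt
    seeds = _derive_seeds(cfg.seed, 4)
    dp_seed, sp_seed, init_seed, stim_seed = seeds

    mu0, zeta = _stimulus_trace(stimulus, n_steps, dt, stim_seed)
    common = np.full(n_steps, mu0) if zeta is None else mu0 + zeta

    rng_init = np.random.default_rng(init_seed)
    v0_d = p_d.v_r + (p_d.v_th - p_d.v_r) * rng_init.random(ff.n)
    v0_s = p_s.v_r + (p_s.v_th - p_s.v_r) * rng_init.random(n_sp)

    ref_steps_d = int(round(p_d.tau_r / dt))
    ref_steps_s = int(round(p_s.tau_r / dt))
    n_transient = int(round(cfg.t_transient / dt))

    def cap(n: int, ref_steps: int) -> int:
        return n * (n_steps // (ref_steps + 1) + 2)

    counts_bin, counts_d, td, idd, overflow_d, v_d = integrate_lif_population(
        common, ff.n, dt, p_d.tau_m, ref_steps_d, p_d.sigma,
        p_d.v_th, p_d.v_r, v0_d, dp_seed, n_transient,
        record_spikes, cap(ff.n, ref_steps_d) if record_spikes else 1,
    )
    if np.any(np.isnan(v_d)):
        raise FloatingPointError("NaN in DP membrane potentials (dt too large?)")

    kernel = build_kernel(ff.kernel, ff.tau_s, ff.tau_d, dt)
    amp = p_d.tau_m * ff.g / ff.n
    f_trace = amp * fftconvolve(counts_bin.astype(float), kernel.weights)[:n_steps]
    if ff.g == 0.0:
        f_trace = np.zeros(n_steps)

    sp_drive = common + f_trace
    _, counts_s, ts, ids_s, overflow_s, v_s = integrate_lif_population(
        sp_drive, n_sp, dt, p_s.tau_m, ref_steps_s, p_s.sigma,
        p_s.v_th, p_s.v_r, v0_s, sp_seed, n_transient,
        True, cap(n_sp, ref_steps_s),
    )
    if np.any(np.isnan(v_s)):
        raise FloatingPointError("NaN in SP membrane potential (dt too large?)")
    if overflow_d or overflow_s:
        raise RuntimeError("spike buffer overflow; raise the capacity")

    window = cfg.t_total - cfg.t_transient
    dp_rate = _rate_from_counts(np.asarray(counts_d), window)
    sp_rate = _rate_from_counts(np.asarray(counts_s), window)

    dp_spikes = None
    if record_spikes:
        dp_spikes = [np.sort(td[idd == i]) for i in range(ff.n)]
    sp_spikes = [np.sort(ts[ids_s == i]) for i in range(n_sp)]

    return SimResult(
        dp_spikes=dp_spikes,
        sp_spikes=sp_spikes,
        f_trace=f_trace,
        mu_eff_trace=sp_drive,
        dp_rate=dp_rate,
        sp_rate=sp_rate,
        seed=cfg.seed,
    )


def fi_curve_simulated(
    p_d: NeuronParams,
    p_s: NeuronParams,
    ff: FeedforwardParams,
    mu_grid: Sequence[float],
    cfg: SimConfig,
    *,
    n_sp: int = 1,
) -> RateCurve:
    """Empirical SP f-I curve: one independent network run per grid point,
    with per-point seeds derived deterministically from ``cfg.seed`` and the
    grid index (reordering the grid cannot silently reuse a stream)."""
    mu_grid = np.asarray(mu_grid, dtype=float)
    rates = np.empty(mu_grid.size)
    errs = np.empty(mu_grid.size)
    for i, mu in enumerate(mu_grid):
        seed_i = _derive_seeds(cfg.seed, 1, i)[0]
        cfg_i = SimConfig(t_total=cfg.t_total, t_transient=cfg.t_transient,
                          dt=cfg.dt, seed=seed_i)
        res = simulate(p_d, p_s, ff, mu, cfg_i, record_spikes=False, n_sp=n_sp)
        rates[i], errs[i] = res.sp_rate
    return RateCurve(mu_grid, rates, errs, "simulated", tau_r=p_s.tau_r)
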