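"""Euler–Maruyama integration of a LIF population (numba inner loop).

``integrate_lif_population`` advances ``n`` independent LIF neurons driven
by a shared bias trace plus independent white noise.  The discrete update
of the membrane equation is

    V <- V + (dt/tau_m) * (mu_t - V) + sigma * sqrt(dt/tau_m) * N(0, 1),

whose stationary subthreshold variance is the Ornstein–Uhlenbeck value
sigma^2 / 2 (the unit-test anchor for the noise convention).  A threshold
crossing registers a spike at the end of the step; the voltage is reset and
clamped at V_r, input ignored, for the refractory period.

Noise is pre-generated in fixed-size chunks by numpy's PCG64 generator and
consumed by the compiled stepper — much faster than drawing one normal per
neuron-step inside the loop, and reproducible for a given seed because the
chunk size is a constant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: steps per noise chunk (fixed: part of the reproducibility contract)
_CHUNK_STEPS = 8192

_EMPTY_NOISE = np.zeros((0, 0), dtype=np.float32)


@njit(cache=True)
def _advance_chunk(
    mu_trace,       # float64[n_steps]: full bias trace
    noise,          # float64[chunk_len, n] scaled noise increments (or 0x0)
    has_noise,      # bool
    t_start,        # first global step of this chunk
    chunk_len,
    n, dt, tau_m, ref_steps, v_th, v_r, b,
    v, ref,         # state, mutated in place
    counts_bin, counts_neuron, n_transient,
    record, times, ids, n_rec, max_spikes,
):
    a = dt / tau_m
    overflow = False
    for s in range(chunk_len):
        t = t_start + s
        m = mu_trace[t]
        for i in range(n):
            if ref[i] > 0:
                ref[i] -= 1
                continue
            vi = v[i] + a * (m - v[i])
            if has_noise:
                vi += b * noise[s, i]
            if vi >= v_th:
                counts_bin[t] += 1
                if t >= n_transient:
                    counts_neuron[i] += 1
                if record:
                    if n_rec < max_spikes:
                        times[n_rec] = (t + 1) * dt
                        ids[n_rec] = i
                        n_rec += 1
                    else:
                        overflow = True
                v[i] = v_r
                ref[i] = ref_steps
            else:
                v[i] = vi
    return n_rec, overflow


def integrate_lif_population(
    mu_trace: np.ndarray,
    n: int,
    dt: float,
    tau_m: float,
    ref_steps: int,
    sigma: float,
    v_th: float,
    v_r: float,
    v0: np.ndarray,
    seed: int,
    n_transient: int,
    record: bool,
    max_spikes: int,
):
    """Returns ``(counts_bin, counts_neuron, times, ids, overflow, v_final)``.

    ``counts_bin[t]``    -- population spike count in step t (for kernel
                            convolution into f(t)),
    ``counts_neuron[i]`` -- spikes of neuron i after the transient,
    ``times``/``ids``    -- individual spikes (end-of-step times, ms) when
                            ``record`` is set.
    """
    mu_trace = np.ascontiguousarray(mu_trace, dtype=np.float64)
    n_steps = mu_trace.shape[0]
    counts_bin = np.zeros(n_steps, dtype=np.int32)
    counts_neuron = np.zeros(n, dtype=np.int64)
    cap = max_spikes if record else 1
    times = np.empty(cap, dtype=np.float64)
    ids = np.empty(cap, dtype=np.int32)
    v = np.ascontiguousarray(v0, dtype=np.float64).copy()
    ref = np.zeros(n, dtype=np.int32)

    b = sigma * np.sqrt(dt / tau_m)
    rng = np.random.default_rng(seed) if b > 0.0 else None

    n_rec = 0
    overflow = False
    t_start = 0
    while t_start < n_steps:
        chunk_len = min(_CHUNK_STEPS, n_steps - t_start)
        if rng is not None:
            noise = rng.standard_normal((chunk_len, n), dtype=np.float32)
            has_noise = True
        else:
            noise = _EMPTY_NOISE
            has_noise = False
        n_rec, ovf = _advance_chunk(
            mu_trace, noise, has_noise, t_start, chunk_len,
            n, dt, tau_m, ref_steps, v_th, v_r, b,
            v, ref, counts_bin, counts_neuron, n_transient,
            record, times, ids, n_rec, cap,
        )
        overflow = overflow or ovf
        t_start += chunk_len
    return counts_bin, counts_neuron, times[:n_rec], ids[:n_rec], overflow, v
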