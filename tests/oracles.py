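"""Independent brute-force oracle for the pre-centered nearest-neighbor rule.

Enumerates, for every presynaptic spike, the nearest postsynaptic events
by direct search over the full event lists, then replays all pair
contributions grouped by integration step.  Entirely independent of the
streaming implementation in :mod:`gcplast.plasticity`.
"""

from __future__ import annotations

import numpy as np


def brute_force_weights(
    pre_streams: list[np.ndarray],
    post_streams: list[np.ndarray],
    duration: float,
    dt: float,
    a_p: float,
    a_d: float,
    tau_p: float,
    tau_d: float,
    w0: np.ndarray,
    max_change: float = 1.0,
    lapse: float | None = None,
) -> np.ndarray:
    """Final weights under constant amplitudes.

    Post streams are assumed already debounced (events farther apart
    than the refractory interval).
    """
    if lapse is None:
        lapse = 5.0 * tau_p
    n_steps = int(round(duration / dt))
    n = len(pre_streams)
    w = np.asarray(w0, dtype=float).copy()
    w0 = np.asarray(w0, dtype=float)

    def step_of(t):
        # events in ((k)dt, (k+1)dt] belong to step k
        return max(0, int(np.ceil(t / dt)) - 1)

    # per synapse, per step: summed window contributions
    contrib_p: list[dict[int, float]] = [dict() for _ in range(n)]
    contrib_d: list[dict[int, float]] = [dict() for _ in range(n)]
    for s in range(n):
        posts = np.asarray(post_streams[s], dtype=float)
        for t_pre in np.asarray(pre_streams[s], dtype=float):
            before = posts[posts <= t_pre]
            after = posts[posts > t_pre]
            if len(before) and before[-1] < t_pre:
                k = step_of(t_pre)
                contrib_d[s][k] = contrib_d[s].get(k, 0.0) + np.exp(
                    (before[-1] - t_pre) / tau_d
                )
            if len(after):
                d = after[0] - t_pre
                if d <= lapse:
                    k = step_of(after[0])
                    contrib_p[s][k] = contrib_p[s].get(k, 0.0) + np.exp(-d / tau_p)

    for k in range(n_steps):
        for s in range(n):
            dwp = contrib_p[s].get(k, 0.0)
            dwd = contrib_d[s].get(k, 0.0)
            if dwp or dwd:
                lo = max(w0[s] * (1.0 - max_change), 1e-12 * w0[s])
                hi = w0[s] * (1.0 + max_change)
                w[s] = min(max(w[s] * (1.0 + a_p * dwp - a_d * dwd), lo), hi)
    return w


def random_streams(rng: np.random.Generator, duration: float, debounce: float = 5.0):
    """One random pre stream and a debounced random post stream."""
    n_pre = int(rng.integers(0, 12))
    pre = np.sort(rng.uniform(0.0, duration, size=n_pre))
    n_post = int(rng.integers(0, 8))
    raw = np.sort(rng.uniform(0.0, duration, size=n_post))
    post = []
    last = -np.inf
    for t in raw:
        if t - last > debounce + 0.5:
            post.append(t)
            last = t
    return pre, np.asarray(post)
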