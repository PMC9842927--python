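"""Low-level Euler-Maruyama integration kernel.

Compiled with numba when available; the same code runs as plain Python
otherwise (slow, but identical numerics).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(func):
            return func

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def integrate_em(x, y, C, rowsum, a, omega, G, beta, dt, burn_steps, steps_per_sample, n_samples, noise):
    """Integrate the coupled system in place and record x at each sample.

    noise has shape (n_steps, 2, N) with n_steps = burn_steps +
    (n_samples - 1) * steps_per_sample.  Returns (out, bad) where bad is
    the index of the first non-finite retained sample, or -1 if all are
    finite.  Sample 0 is the state at the end of the burn-in.
    """
    N = x.shape[0]
    out = np.empty((n_samples, N))
    amp = beta * np.sqrt(dt)
    xn = np.empty(N)
    yn = np.empty(N)
    k = 0
    for _ in range(burn_steps):
        cx = np.dot(C, x)
        cy = np.dot(C, y)
        for i in range(N):
            r2 = x[i] * x[i] + y[i] * y[i]
            xn[i] = x[i] + dt * ((a[i] - r2) * x[i] - omega[i] * y[i] + G * (cx[i] - rowsum[i] * x[i])) + amp * noise[k, 0, i]
            yn[i] = y[i] + dt * ((a[i] - r2) * y[i] + omega[i] * x[i] + G * (cy[i] - rowsum[i] * y[i])) + amp * noise[k, 1, i]
        for i in range(N):
            x[i] = xn[i]
            y[i] = yn[i]
        k += 1
    for i in range(N):
        out[0, i] = x[i]
        if not (np.isfinite(x[i]) and np.isfinite(y[i])):
            return out, 0
    for s in range(1, n_samples):
        for _ in range(steps_per_sample):
            cx = np.dot(C, x)
            cy = np.dot(C, y)
            for i in range(N):
                r2 = x[i] * x[i] + y[i] * y[i]
                xn[i] = x[i] + dt * ((a[i] - r2) * x[i] - omega[i] * y[i] + G * (cx[i] - rowsum[i] * x[i])) + amp * noise[k, 0, i]
                yn[i] = y[i] + dt * ((a[i] - r2) * y[i] + omega[i] * x[i] + G * (cy[i] - rowsum[i] * y[i])) + amp * noise[k, 1, i]
            for i in range(N):
                x[i] = xn[i]
                y[i] = yn[i]
            k += 1
        ok = True
        for i in range(N):
            out[s, i] = x[i]
            if not (np.isfinite(x[i]) and np.isfinite(y[i])):
                ok = False
        if not ok:
            return out, s
    return out, -1
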