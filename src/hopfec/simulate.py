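"""Stochastic simulation of diffusively coupled Stuart-Landau oscillators.

Each node obeys the normal form of a supercritical Hopf bifurcation,

    dx_i = [(a_i - x_i^2 - y_i^2) x_i - w_i y_i + G sum_j C_ij (x_j - x_i)] dt
           + beta sqrt(dt) eta_i
    dy_i = [(a_i - x_i^2 - y_i^2) y_i + w_i x_i + G sum_j C_ij (y_j - y_i)] dt
           + beta sqrt(dt) eta_i'

integrated with the Euler-Maruyama scheme.  ``x`` is the signal read-out;
``y`` only shapes the dynamics.  ``C[i, j]`` couples source ``j`` into
target ``i`` (column-to-row convention).
"""

from __future__ import annotations

import numpy as np

from ._kernels import integrate_em
from .datatypes import BoldTimeseries, ConnectivityMatrix, HopfParameters, OscillatorState
from .errors import NumericalDivergenceError

__all__ = ["step_oscillators", "simulate_hopf"]

DEFAULT_BURN_IN = 200.0  # seconds discarded before the first retained sample
INIT_HALF_WIDTH = 0.1  # initial coordinates drawn uniform in [-0.1, 0.1]


def _coupling_matrix(ec, n: int) -> np.ndarray:
    """Validate and extract an N x N coupling array with zero diagonal."""
    C = ec.values if isinstance(ec, ConnectivityMatrix) else np.asarray(ec, dtype=float)
    C = np.array(C, dtype=float, copy=True)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("coupling matrix must be square")
    if C.shape[0] != n:
        raise ValueError(
            f"coupling matrix is {C.shape[0]}x{C.shape[0]} but the parameter set has {n} nodes"
        )
    np.fill_diagonal(C, 0.0)  # self-coupling is meaningless in the diffusive form
    return C


def step_oscillators(
    state: OscillatorState,
    ec,
    params: HopfParameters,
    noise: tuple[np.ndarray, np.ndarray] | None = None,
) -> OscillatorState:
    """Advance the network by a single Euler-Maruyama step.

    Parameters
    ----------
    state : OscillatorState
        Current (x, y, t).
    ec : ConnectivityMatrix or array_like
        Coupling matrix ``C`` with ``C[i, j]`` from source j to target i.
    params : HopfParameters
        Node and integration parameters; ``params.dt`` is the step taken.
    noise : pair of ndarray, optional
        Per-node standard-normal draws ``(eta_x, eta_y)``.  Omitted or
        with ``params.beta == 0`` the step is deterministic.

    Returns
    -------
    OscillatorState
        The state after one step of length ``params.dt``.
    """
    n = state.n
    if params.n != n:
        raise ValueError("state dimension does not match parameter set")
    C = _coupling_matrix(ec, n)
    rowsum = C.sum(axis=1)
    x, y = state.x, state.y
    r2 = x * x + y * y
    dx = (params.a - r2) * x - params.omega * y + params.G * (C @ x - rowsum * x)
    dy = (params.a - r2) * y + params.omega * x + params.G * (C @ y - rowsum * y)
    amp = params.beta * np.sqrt(params.dt)
    if noise is None:
        eta_x = np.zeros(n)
        eta_y = np.zeros(n)
    else:
        eta_x = np.asarray(noise[0], dtype=float)
        eta_y = np.asarray(noise[1], dtype=float)
        if eta_x.shape != (n,) or eta_y.shape != (n,):
            raise ValueError("noise vectors must have one draw per node")
    new_x = x + params.dt * dx + amp * eta_x
    new_y = y + params.dt * dy + amp * eta_y
    if not (np.all(np.isfinite(new_x)) and np.all(np.isfinite(new_y))):
        raise NumericalDivergenceError(0, "non-finite state after one step; reduce dt")
    return OscillatorState(x=new_x, y=new_y, t=state.t + params.dt)


def simulate_hopf(
    ec,
    params: HopfParameters,
    n_volumes: int,
    burn_in: float = DEFAULT_BURN_IN,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    initial_state: OscillatorState | None = None,
    region_ids: list[str] | None = None,
    subject_id: str | None = None,
    session_id: str | None = None,
) -> BoldTimeseries:
    """Simulate the coupled system and return the sampled x read-out.

    The system is integrated at step ``params.dt``; the first ``burn_in``
    seconds are discarded and ``x`` is retained at every ``params.tr``
    thereafter (the first retained sample is the state at the end of the
    burn-in).  Output is bit-identical for identical inputs and seed.

    Raises
    ------
    NumericalDivergenceError
        If the state becomes non-finite; the error carries the index of
        the first affected retained sample.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    n = params.n
    C = _coupling_matrix(ec, n)
    rowsum = np.ascontiguousarray(C.sum(axis=1))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if initial_state is None:
        init = rng.uniform(-INIT_HALF_WIDTH, INIT_HALF_WIDTH, size=(2, n))
        x0, y0 = init[0].copy(), init[1].copy()
    else:
        if initial_state.n != n:
            raise ValueError("initial state dimension mismatch")
        x0, y0 = initial_state.x.copy(), initial_state.y.copy()

    spt = params.steps_per_sample
    burn_steps = int(round(burn_in / params.dt))
    n_steps = burn_steps + (n_volumes - 1) * spt
    if params.beta > 0:
        noise = rng.standard_normal(size=(n_steps, 2, n))
    else:
        noise = np.zeros((max(n_steps, 1), 2, n))

    out, bad = integrate_em(
        x0,
        y0,
        np.ascontiguousarray(C),
        rowsum,
        np.ascontiguousarray(params.a),
        np.ascontiguousarray(params.omega),
        float(params.G),
        float(params.beta),
        float(params.dt),
        burn_steps,
        spt,
        int(n_volumes),
        noise,
    )
    if bad >= 0:
        raise NumericalDivergenceError(bad)

    if region_ids is None:
        if isinstance(ec, ConnectivityMatrix):
            region_ids = list(ec.region_ids)
        else:
            region_ids = [f"n{i}" for i in range(n)]
    return BoldTimeseries(
        data=out.T.copy(),
        tr=params.tr,
        region_ids=region_ids,
        subject_id=subject_id,
        session_id=session_id,
    )
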