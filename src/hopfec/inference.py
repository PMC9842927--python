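"""Recovery of the directed effective-connectivity matrix.

The fit alternates simulation of the coupled-oscillator model with an
error-correcting update of each coupling entry,

    C_ij <- C_ij + eps * [(FC_emp_ij - FC_sim_ij) + (FCtau_emp_ij - FCtau_sim_ij)]

followed by clamping to [0, ec_cap].  Entries the data do not support are
driven to zero by the clamp; the lagged term is what breaks the symmetry
and assigns direction.  Iteration stops when the combined fit metric (the
off-diagonal Pearson correlation of simulated vs. empirical FC plus the
same for the lagged FC) stops improving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ConnectivityMatrix, HopfParameters
from .errors import FitDivergenceError
from .metrics import DEFAULT_BAND, bandpass_filter, functional_connectivity, lagged_functional_connectivity
from .simulate import simulate_hopf

__all__ = [
    "FitConfig",
    "FitResult",
    "initialize_ec",
    "ec_update_step",
    "fit_metric",
    "fit_effective_connectivity",
]


@dataclass
class FitConfig:
    """Hyper-parameters of the effective-connectivity fit.

    ``sc_mask`` (optional) is a boolean/0-1 matrix of allowed links;
    entries outside it stay exactly zero.  ``pairing`` (optional) is an
    index involution mapping each region to its opposite-hemisphere
    counterpart; when given, the update applied to a link is also applied
    to the mirrored link (used when starting from a tractography matrix,
    which under-detects cross-hemisphere connections).
    """

    epsilon: float = 0.005
    tau: float = 2.0
    ec_cap: float = 0.2
    max_iters: int = 300
    conv_window: int = 10
    conv_tol: float = 1e-4
    sim_volumes: int = 9000
    burn_in: float = 200.0
    band: tuple[float, float] = DEFAULT_BAND
    sc_mask: np.ndarray | None = None
    pairing: np.ndarray | None = None
    eps_decay: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.ec_cap <= 0:
            raise ValueError("ec_cap must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.conv_window < 1:
            raise ValueError("conv_window must be >= 1")
        if self.sc_mask is not None:
            self.sc_mask = np.asarray(self.sc_mask) != 0
        if self.pairing is not None:
            p = np.asarray(self.pairing, dtype=int)
            if not np.array_equal(p[p], np.arange(p.size)):
                raise ValueError("pairing must be an involution")
            self.pairing = p


@dataclass
class FitResult:
    """Outcome of :func:`fit_effective_connectivity`."""

    ec: ConnectivityMatrix
    metric_history: np.ndarray  # (iterations, 2): corr_fc, corr_fc_tau
    iterations: int
    converged: bool
    final_fc_corr: float
    final_fc_tau_corr: float
    best_iteration: int = 0
    epsilon_final: float = field(default=float("nan"))


def initialize_ec(
    n_regions: int,
    mode: str = "zeros",
    sc: ConnectivityMatrix | None = None,
    init_scale: float = 0.2,
    region_ids: list[str] | None = None,
) -> ConnectivityMatrix:
    """Starting coupling matrix: all zeros, or a rescaled structural matrix.

    In ``from_sc`` mode the structural matrix (e.g. streamline counts) is
    scaled so its maximum equals ``init_scale`` and the diagonal zeroed.
    """
    if mode == "zeros":
        ids = region_ids or (list(sc.region_ids) if sc is not None else [f"n{i}" for i in range(n_regions)])
        return ConnectivityMatrix(np.zeros((n_regions, n_regions)), kind="EC", region_ids=ids)
    if mode == "from_sc":
        if sc is None:
            raise ValueError("from_sc initialization requires a structural matrix")
        v = np.array(sc.values, dtype=float, copy=True)
        np.fill_diagonal(v, 0.0)
        peak = v.max()
        if peak > 0:
            v = v * (init_scale / peak)
        return ConnectivityMatrix(v, kind="EC", region_ids=list(sc.region_ids))
    raise ValueError(f"unknown initialization mode {mode!r}")


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)


def ec_update_step(
    ec: ConnectivityMatrix,
    fc_emp,
    fc_tau_emp,
    fc_sim,
    fc_tau_sim,
    config: FitConfig,
) -> ConnectivityMatrix:
    """One error-correcting update of every coupling entry.

    Adds ``epsilon`` times the summed FC and lagged-FC errors to each
    entry, mirrors the update onto the homotopic counterpart link when a
    pairing is configured, then clamps to ``[0, ec_cap]``, re-zeroes
    masked links and the diagonal.
    """
    c = np.array(_values(ec), dtype=float, copy=True)
    mats = [_values(m) for m in (fc_emp, fc_tau_emp, fc_sim, fc_tau_sim)]
    for m in mats:
        if m.shape != c.shape:
            raise ValueError("matrix dimension mismatch in update step")
    fce, fcte, fcs, fcts = mats
    delta = config.epsilon * ((fce - fcs) + (fcte - fcts))
    if config.pairing is not None:
        p = config.pairing
        delta = delta + delta[np.ix_(p, p)]
    c += delta
    np.clip(c, 0.0, config.ec_cap, out=c)
    if config.sc_mask is not None:
        c[~config.sc_mask] = 0.0
    np.fill_diagonal(c, 0.0)
    ids = ec.region_ids if isinstance(ec, ConnectivityMatrix) else [f"n{i}" for i in range(c.shape[0])]
    return ConnectivityMatrix(c, kind="EC", region_ids=list(ids))


def fit_metric(fc_sim, fc_emp, fc_tau_sim, fc_tau_emp) -> tuple[float, float]:
    """Off-diagonal Pearson correlation of simulated vs. empirical matrices.

    Returns the correlation for the zero-lag pair and for the lagged pair
    separately.
    """
    a, b, c, d = (_values(m) for m in (fc_sim, fc_emp, fc_tau_sim, fc_tau_emp))
    if not (a.shape == b.shape == c.shape == d.shape):
        raise ValueError("matrix dimension mismatch in fit metric")
    mask = ~np.eye(a.shape[0], dtype=bool)
    return _offdiag_corr(a, b, mask), _offdiag_corr(c, d, mask)


def _offdiag_corr(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    x, y = a[mask], b[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) matrix in fit metric")
    return float(np.corrcoef(x, y)[0, 1])


def _pair_score(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Correlation when defined, else an error-based similarity in (-inf, 1].

    Symmetric 2x2 matrices have a single repeated off-diagonal value, so
    the correlation is undefined; the loop then tracks 1 - mean|error|,
    which shares the 'higher is better, 1 is perfect' orientation.
    """
    x, y = a[mask], b[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0 - float(np.mean(np.abs(x - y)))
    return float(np.corrcoef(x, y)[0, 1])


def fit_effective_connectivity(
    fc_emp: ConnectivityMatrix,
    fc_tau_emp: ConnectivityMatrix,
    params: HopfParameters,
    config: FitConfig,
    ec_init: ConnectivityMatrix | None = None,
) -> FitResult:
    """Iterate simulate -> measure -> update until the fit plateaus.

    Each iteration simulates the model from the current coupling estimate
    (with a fresh sub-stream of the configured seed), band-limits the
    signals, measures FC and lagged FC, scores them against the empirical
    matrices and updates every entry.  The coupling from the
    best-scoring iteration is returned, which makes the result robust to
    the stochastic jitter of the per-iteration metric.

    Raises
    ------
    FitDivergenceError
        If the metric decreases for ``3 * conv_window`` consecutive
        iterations.
    """
    n = fc_emp.n
    if fc_tau_emp.n != n:
        raise ValueError("empirical matrices differ in size")
    if fc_emp.region_ids != fc_tau_emp.region_ids:
        raise ValueError("empirical matrices differ in region ordering")
    if params.n != n:
        raise ValueError("parameter set does not match matrix size")
    shift = config.tau / params.tr
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(f"tau={config.tau} s is not an integer multiple of tr={params.tr} s")

    ec = ec_init.copy() if ec_init is not None else initialize_ec(n, "zeros", region_ids=list(fc_emp.region_ids))
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(config.max_iters)

    eps = config.epsilon
    cfg = config
    history: list[tuple[float, float]] = []
    best_metric = -np.inf
    best_ec = ec.copy()
    best_iter = 0
    best_pair = (np.nan, np.nan)
    last_improve = 0
    decline = 0
    converged = False

    for it in range(config.max_iters):
        ts = simulate_hopf(ec, params, cfg.sim_volumes, burn_in=cfg.burn_in, seed=seeds[it])
        filtered = bandpass_filter(ts, *cfg.band)
        fc_sim = functional_connectivity(filtered)
        fc_tau_sim = lagged_functional_connectivity(filtered, cfg.tau)
        mask = ~np.eye(n, dtype=bool)
        corr_fc = _pair_score(fc_sim.values, fc_emp.values, mask)
        corr_tau = _pair_score(fc_tau_sim.values, fc_tau_emp.values, mask)
        metric = corr_fc + corr_tau
        history.append((corr_fc, corr_tau))

        if history and len(history) > 1 and metric < sum(history[-2]):
            decline += 1
        else:
            decline = 0
        if decline >= 3 * cfg.conv_window:
            raise FitDivergenceError(np.asarray(history))

        if metric > best_metric + cfg.conv_tol:
            last_improve = it
        if metric > best_metric:
            best_metric = metric
            best_ec = ec.copy()
            best_iter = it
            best_pair = (corr_fc, corr_tau)
        elif cfg.eps_decay and it - best_iter >= cfg.conv_window // 2:
            eps = max(eps * 0.5, config.epsilon / 64.0)

        if it - last_improve >= cfg.conv_window:
            converged = True
            break

        step_cfg = cfg if eps == cfg.epsilon else _with_epsilon(cfg, eps)
        ec = ec_update_step(ec, fc_emp, fc_tau_emp, fc_sim, fc_tau_sim, step_cfg)

    return FitResult(
        ec=best_ec,
        metric_history=np.asarray(history),
        iterations=len(history),
        converged=converged,
        final_fc_corr=float(best_pair[0]),
        final_fc_tau_corr=float(best_pair[1]),
        best_iteration=best_iter,
        epsilon_final=eps,
    )


def _with_epsilon(config: FitConfig, eps: float) -> FitConfig:
    cfg = FitConfig(**{**config.__dict__, "epsilon": eps})
    return cfg
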