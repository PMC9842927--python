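"""Core value types shared across the package.

Conventions
-----------
All square matrices are read *from column to row*: entry ``M[i, j]`` refers
to the link from source region ``j`` to target region ``i``.  Every module
in the package shares this orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MATRIX_KINDS = ("EC", "SC", "FC", "FC_tau", "DIFF")

_TOL = 1e-6


@dataclass
class HopfParameters:
    """Node-level and global parameters of the coupled-oscillator model.

    Parameters
    ----------
    a : ndarray, shape (N,)
        Per-node bifurcation parameter.  Negative values give a noisy
        fixed point, positive values a limit cycle of radius ``sqrt(a)``.
    f : ndarray, shape (N,)
        Per-node intrinsic frequency in Hz; the angular velocity is
        ``omega = 2 * pi * f``.
    G : float
        Global coupling weight (>= 0) scaling the diffusive input.
    beta : float
        Standard deviation of the additive Gaussian noise (>= 0).
    dt : float
        Integration step in seconds.
    tr : float
        Output sampling interval in seconds; must be a positive integer
        multiple of ``dt``, and every ``f`` must be below ``1 / (2 * tr)``.
    """

    a: np.ndarray
    f: np.ndarray
    G: float = 1.0
    beta: float = 0.02
    dt: float = 0.1
    tr: float = 1.0

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        if self.a.shape != self.f.shape or self.a.ndim != 1:
            raise ValueError("a and f must be 1-d vectors of equal length")
        if self.G < 0:
            raise ValueError("G must be >= 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.dt <= 0 or self.tr <= 0:
            raise ValueError("dt and tr must be positive")
        if self.dt > self.tr + 1e-12:
            raise ValueError("dt must not exceed tr")
        ratio = self.tr / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("tr must be an integer multiple of dt")
        nyquist = 1.0 / (2.0 * self.tr)
        if np.any(self.f <= 0) or np.any(self.f >= nyquist):
            raise ValueError(f"all intrinsic frequencies must lie in (0, {nyquist}) Hz")

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def omega(self) -> np.ndarray:
        return 2.0 * np.pi * self.f

    @property
    def steps_per_sample(self) -> int:
        return int(round(self.tr / self.dt))

    def with_nodes(self, a: np.ndarray, f: np.ndarray) -> "HopfParameters":
        """Return a copy with different per-node parameters."""
        return HopfParameters(a=a, f=f, G=self.G, beta=self.beta, dt=self.dt, tr=self.tr)


@dataclass
class OscillatorState:
    """Instantaneous state of the oscillator network.

    ``x`` is the simulated signal read-out; ``y`` is the auxiliary
    coordinate that shapes the dynamics but is never read out.
    """

    x: np.ndarray
    y: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d vectors of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("state contains non-finite values")

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass
class BoldTimeseries:
    """Region-by-time signal matrix with its sampling interval."""

    data: np.ndarray
    tr: float
    region_ids: list[str]
    subject_id: str | None = None
    session_id: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.region_ids = [str(r) for r in self.region_ids]
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-d (regions x time) array")
        if self.data.shape[0] != len(self.region_ids):
            raise ValueError("row count does not match number of region labels")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("timeseries contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "BoldTimeseries":
        return BoldTimeseries(
            data=data,
            tr=self.tr,
            region_ids=list(self.region_ids),
            subject_id=self.subject_id,
            session_id=self.session_id,
        )


@dataclass
class ConnectivityMatrix:
    """Square region-by-region matrix tagged by kind.

    ``kind`` is one of ``EC`` (directed effective coupling, non-negative,
    zero diagonal), ``SC`` (structural evidence), ``FC`` (zero-lag Pearson
    correlation, symmetric with unit diagonal) or ``FC_tau`` (lagged
    correlation, generally asymmetric).  ``tau`` is the lag in seconds and
    is only meaningful for ``FC_tau``.
    """

    values: np.ndarray
    kind: str
    region_ids: list[str]
    tau: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = [str(r) for r in self.region_ids]
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.values.shape[0] != len(self.region_ids):
            raise ValueError("matrix size does not match number of region labels")
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"kind must be one of {MATRIX_KINDS}, got {self.kind!r}")
        v = self.values
        if self.kind == "FC":
            if not np.allclose(v, v.T, atol=_TOL):
                raise ValueError("FC matrix must be symmetric")
            if not np.allclose(np.diag(v), 1.0, atol=_TOL):
                raise ValueError("FC matrix must have unit diagonal")
        if self.kind in ("FC", "FC_tau"):
            if np.any(np.abs(v) > 1.0 + _TOL):
                raise ValueError("correlation entries must lie in [-1, 1]")
        if self.kind == "EC":
            if np.any(np.abs(np.diag(v)) > 0):
                raise ValueError("EC matrix must have a zero diagonal")
            if np.any(v < -_TOL):
                raise ValueError("EC entries must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def offdiagonal(self) -> np.ndarray:
        """Flattened off-diagonal entries (row-major order)."""
        mask = ~np.eye(self.n, dtype=bool)
        return self.values[mask]

    def copy(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            values=self.values.copy(),
            kind=self.kind,
            region_ids=list(self.region_ids),
            tau=self.tau,
        )

    def reorder(self, region_ids: list[str]) -> "ConnectivityMatrix":
        """Return a copy with rows/columns permuted to the given labels."""
        region_ids = [str(r) for r in region_ids]
        if sorted(region_ids) != sorted(self.region_ids):
            raise ValueError("requested labels are not a permutation of the matrix labels")
        idx = [self.region_ids.index(r) for r in region_ids]
        return ConnectivityMatrix(
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
            region_ids=region_ids,
            tau=self.tau,
        )


@dataclass
class Parcellation:
    """Region labels with hemisphere and group annotation."""

    region_ids: list[str]
    names: list[str]
    hemisphere: list[str]
    group: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.region_ids = [str(r) for r in self.region_ids]
        n = len(self.region_ids)
        if len(set(self.region_ids)) != n:
            raise ValueError("region ids must be unique")
        if len(self.names) != n or len(self.hemisphere) != n:
            raise ValueError("names/hemisphere length mismatch")
        if not self.group:
            self.group = ["G1"] * n
        if len(self.group) != n:
            raise ValueError("group length mismatch")
        for h in self.hemisphere:
            if h not in ("L", "R", "none"):
                raise ValueError("hemisphere labels must be 'L', 'R' or 'none'")

    @property
    def n(self) -> int:
        return len(self.region_ids)

    def homotopic_pairing(self) -> np.ndarray:
        """Index map to the same-named region in the opposite hemisphere.

        Returns an involution ``p`` with ``p[p[i]] == i``; regions with
        hemisphere ``none`` map to themselves.
        """
        p = np.arange(self.n)
        lookup = {
            (nm, h): i for i, (nm, h) in enumerate(zip(self.names, self.hemisphere))
        }
        for i, (nm, h) in enumerate(zip(self.names, self.hemisphere)):
            if h == "L":
                p[i] = lookup.get((nm, "R"), i)
            elif h == "R":
                p[i] = lookup.get((nm, "L"), i)
        return p

    @classmethod
    def bilateral(cls, n_regions: int, prefix: str = "R") -> "Parcellation":
        """Balanced two-hemisphere layout with matched names.

        The first ``n_regions // 2`` regions form the left hemisphere and
        the second half mirrors them on the right; groups split each
        hemisphere in two.
        """
        if n_regions % 2 != 0 or n_regions < 2:
            raise ValueError("bilateral layouts need an even region count >= 2")
        half = n_regions // 2
        names = [f"{prefix}{k + 1}" for k in range(half)] * 2
        hemis = ["L"] * half + ["R"] * half
        ids = [f"{nm}_{h}" for nm, h in zip(names, hemis)]
        groups = []
        for h in ("L", "R"):
            groups += ["G1"] * (half - half // 2) + ["G2"] * (half // 2)
        return cls(region_ids=ids, names=names, hemisphere=hemis, group=groups)
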