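"""Band-limiting, intrinsic-frequency estimation and (lagged) functional
connectivity.

The lagged correlation matrix follows the column-to-row convention used
throughout the package: entry ``[i, j]`` correlates source region ``j`` at
time ``t`` with target region ``i`` at time ``t + tau``, so a source that
leads its target raises the entry in the target's row.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal

from .datatypes import BoldTimeseries, ConnectivityMatrix
from .errors import DegenerateSignalError

__all__ = [
    "bandpass_filter",
    "estimate_intrinsic_frequencies",
    "functional_connectivity",
    "lagged_functional_connectivity",
    "average_connectivity",
]

DEFAULT_BAND = (0.008, 0.08)  # Hz
_MIN_PERIODS = 6  # series must span this many cycles of the slowest band edge


def _check_variance(ts: BoldTimeseries) -> None:
    flat = np.ptp(ts.data, axis=1) == 0
    if np.any(flat):
        raise DegenerateSignalError([ts.region_ids[i] for i in np.flatnonzero(flat)])


def bandpass_filter(ts: BoldTimeseries, f_lo: float, f_hi: float) -> BoldTimeseries:
    """Zero-phase band-limit each region and remove its mean.

    A 2nd-order Butterworth band-pass is applied forward-backward after a
    linear detrend.  The series must span at least six periods of the
    low-frequency edge so that filter edge effects stay contained.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0 < f_lo < f_hi < nyquist):
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz infeasible for sampling interval tr={ts.tr} s"
        )
    min_len = int(math.ceil(_MIN_PERIODS / (f_lo * ts.tr)))
    if ts.n_timepoints < min_len:
        raise ValueError(
            f"series too short for the band: need >= {min_len} samples, got {ts.n_timepoints}"
        )
    x = signal.detrend(ts.data, axis=1, type="linear")
    sos = signal.butter(2, [f_lo, f_hi], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=1)
    y = y - y.mean(axis=1, keepdims=True)
    return ts.copy_with(y)


def estimate_intrinsic_frequencies(
    cohort_ts: list[BoldTimeseries],
    band: tuple[float, float] = DEFAULT_BAND,
) -> np.ndarray:
    """Per-region peak frequency of the narrowband signals, averaged over runs.

    For each run the signals are band-limited, a Welch spectrum is taken
    (segments of a quarter of the series, 50% overlap) and the in-band
    peak located per region; peaks are then averaged across runs and
    clamped to the band.

    Returns
    -------
    ndarray, shape (N,)
        Estimated intrinsic frequency of each region in Hz.
    """
    if not cohort_ts:
        raise ValueError("empty cohort")
    f_lo, f_hi = band
    ref = cohort_ts[0]
    peaks = []
    for ts in cohort_ts:
        if ts.region_ids != ref.region_ids or ts.tr != ref.tr:
            raise ValueError("all series must share region ordering and tr")
        _check_variance(ts)
        filtered = bandpass_filter(ts, f_lo, f_hi)
        nperseg = max(16, filtered.n_timepoints // 4)
        freqs, psd = signal.welch(
            filtered.data, fs=1.0 / ts.tr, nperseg=nperseg, noverlap=nperseg // 2, axis=1
        )
        in_band = (freqs >= f_lo) & (freqs <= f_hi)
        if not np.any(in_band):
            raise ValueError("no spectral bins inside the band; series too short")
        fb = freqs[in_band]
        peaks.append(fb[np.argmax(psd[:, in_band], axis=1)])
    return np.clip(np.mean(peaks, axis=0), f_lo, f_hi)


def functional_connectivity(ts: BoldTimeseries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation matrix of the region signals."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    _check_variance(ts)
    r = np.corrcoef(ts.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, kind="FC", region_ids=list(ts.region_ids), tau=0.0)


def lagged_functional_connectivity(ts: BoldTimeseries, tau: float) -> ConnectivityMatrix:
    """Correlation of each source at time t with each target at time t + tau.

    ``tau`` must be a non-negative integer multiple of the sampling
    interval; ``tau = 0`` reduces to the ordinary (symmetric) correlation
    on the full series.
    """
    shift_f = tau / ts.tr
    shift = int(round(shift_f))
    if tau < 0 or abs(shift_f - shift) > 1e-9:
        raise ValueError(f"tau={tau} s is not a non-negative integer multiple of tr={ts.tr} s")
    t_len = ts.n_timepoints - shift
    if t_len < 3:
        raise ValueError("series too short for the requested lag")
    _check_variance(ts)
    later = ts.data[:, shift:]  # targets, at t + tau
    earlier = ts.data[:, : ts.n_timepoints - shift]  # sources, at t
    za = _zscore_rows(later, ts.region_ids)
    zb = _zscore_rows(earlier, ts.region_ids)
    m = np.clip((za @ zb.T) / t_len, -1.0, 1.0)
    return ConnectivityMatrix(values=m, kind="FC_tau", region_ids=list(ts.region_ids), tau=tau)


def _zscore_rows(x: np.ndarray, region_ids) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    bad = sd[:, 0] == 0
    if np.any(bad):
        raise DegenerateSignalError([region_ids[i] for i in np.flatnonzero(bad)])
    return (x - mu) / sd


def average_connectivity(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of matrices of one kind and ordering."""
    if not mats:
        raise ValueError("need at least one matrix")
    ref = mats[0]
    for m in mats[1:]:
        if m.kind != ref.kind:
            raise ValueError(f"kind mismatch: {m.kind} vs {ref.kind}")
        if m.region_ids != ref.region_ids:
            raise ValueError("region ordering mismatch")
        if m.tau != ref.tau:
            raise ValueError("lag mismatch")
    mean = np.mean([m.values for m in mats], axis=0)
    if ref.kind == "FC":
        np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(values=mean, kind=ref.kind, region_ids=list(ref.region_ids), tau=ref.tau)
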