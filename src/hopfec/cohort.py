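"""Synthetic ground-truth networks and multi-subject "resting-state" cohorts.

Stands in for a real multi-session fMRI cohort: a sparse directed coupling
matrix with strong homotopic (contralateral-counterpart) links generates
band-limited oscillatory signals for many subjects and sessions, with
per-subject parameter jitter.  Everything is reproducible from a single
master seed via hierarchical sub-seeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BoldTimeseries, ConnectivityMatrix, HopfParameters, Parcellation
from .metrics import DEFAULT_BAND, average_connectivity, bandpass_filter, functional_connectivity, lagged_functional_connectivity
from .simulate import simulate_hopf

__all__ = [
    "GroundTruth",
    "generate_ground_truth_ec",
    "structural_mask_from_ec",
    "simulate_cohort",
    "empirical_pair_from_cohort",
]

EC_CAP = 0.2
F_RANGE = (0.02, 0.06)  # Hz, default intrinsic-frequency draw, inside the band
DEFAULT_A = -0.02


@dataclass
class GroundTruth:
    """A known generative network plus its population parameters."""

    ec_true: ConnectivityMatrix
    params: HopfParameters
    pairing: np.ndarray
    parcellation: Parcellation


def generate_ground_truth_ec(
    n_regions: int,
    density: float,
    weight_range: tuple[float, float] = (0.05, 0.15),
    homotopic_boost: float = 1.5,
    seed: int = 0,
) -> GroundTruth:
    """Sparse asymmetric non-negative coupling matrix on a bilateral layout.

    The expected off-diagonal non-zero fraction equals ``density``.
    Homotopic links (between same-named regions of opposite hemispheres)
    are always present when the density budget allows, with weights
    scaled by ``homotopic_boost`` (capped at 0.2); the remaining density
    budget is spread uniformly over the other directed pairs, each drawn
    independently per direction so the matrix is asymmetric.
    """
    if not (0 <= density <= 1):
        raise ValueError("density must lie in [0, 1]")
    lo, hi = weight_range
    if not (0 < lo <= hi <= EC_CAP):
        raise ValueError(f"weight range must satisfy 0 < lo <= hi <= {EC_CAP}")
    parc = Parcellation.bilateral(n_regions)
    pairing = parc.homotopic_pairing()
    rng = np.random.default_rng(seed)
    n = n_regions
    v = np.zeros((n, n))
    if density > 0:
        n_off = n * (n - 1)
        n_homo = n  # ordered homotopic pairs (i, pairing[i])
        homo = np.zeros((n, n), dtype=bool)
        homo[np.arange(n), pairing] = True
        expected = density * n_off
        if expected >= n_homo:
            p_homo = 1.0
            p_bg = (expected - n_homo) / (n_off - n_homo)
        else:
            p_homo = expected / n_homo
            p_bg = 0.0
        draw = rng.random((n, n))
        present = np.where(homo, draw < p_homo, draw < p_bg)
        np.fill_diagonal(present, False)
        w = rng.uniform(lo, hi, size=(n, n))
        w[homo] = np.minimum(w[homo] * homotopic_boost, EC_CAP)
        v = np.where(present, w, 0.0)
        np.fill_diagonal(v, 0.0)
    ec = ConnectivityMatrix(v, kind="EC", region_ids=list(parc.region_ids))
    f = rng.uniform(*F_RANGE, size=n)
    params = HopfParameters(a=np.full(n, DEFAULT_A), f=f)
    return GroundTruth(ec_true=ec, params=params, pairing=pairing, parcellation=parc)


def structural_mask_from_ec(
    gt: GroundTruth,
    contra_dropout: float = 0.0,
    extra_edges: float = 0.0,
    seed: int = 0,
) -> ConnectivityMatrix:
    """Symmetric binary mask emulating a tractography-derived link set.

    Starts from the symmetric closure of the true links, removes each
    cross-hemisphere undirected edge with probability ``contra_dropout``
    (tractography under-detects contralateral connections) and adds each
    absent ipsilateral undirected pair with probability ``extra_edges``.
    """
    if not (0 <= contra_dropout <= 1 and 0 <= extra_edges <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = gt.ec_true.n
    support = (gt.ec_true.values > 0)
    support = support | support.T
    hemi = np.array(gt.parcellation.hemisphere)
    cross = hemi[:, None] != hemi[None, :]
    iu = np.triu_indices(n, k=1)
    keep = np.ones((n, n), dtype=bool)
    drop = rng.random(len(iu[0])) < contra_dropout
    for k in np.flatnonzero(drop):
        i, j = iu[0][k], iu[1][k]
        if cross[i, j]:
            keep[i, j] = keep[j, i] = False
    mask = support & keep
    add = rng.random(len(iu[0])) < extra_edges
    for k in np.flatnonzero(add):
        i, j = iu[0][k], iu[1][k]
        if not cross[i, j] and not mask[i, j]:
            mask[i, j] = mask[j, i] = True
    np.fill_diagonal(mask, False)
    return ConnectivityMatrix(mask.astype(float), kind="SC", region_ids=list(gt.ec_true.region_ids))


def simulate_cohort(
    gt: GroundTruth,
    n_subjects: int,
    n_sessions: int = 4,
    n_volumes: int = 900,
    subject_jitter: float = 0.0,
    seed: int = 0,
) -> list[BoldTimeseries]:
    """Simulate a multi-subject, multi-session cohort from the ground truth.

    Each subject draws its node parameters by multiplicative Gaussian
    jitter (sd ``subject_jitter``) around the population values, with
    intrinsic frequencies truncated to stay inside the band; sessions are
    independent runs of the generator.  Hierarchical sub-seeding makes
    the whole cohort a deterministic function of ``seed``.
    """
    if n_subjects < 1 or n_sessions < 1:
        raise ValueError("counts must be >= 1")
    master = np.random.SeedSequence(seed)
    runs: list[BoldTimeseries] = []
    f_lo, f_hi = DEFAULT_BAND
    for s_idx, sub_ss in enumerate(master.spawn(n_subjects)):
        sub_id = f"sub-{s_idx + 1:03d}"
        jitter_rng = np.random.default_rng(sub_ss)
        if subject_jitter > 0:
            scale_a = jitter_rng.normal(1.0, subject_jitter, size=gt.params.n)
            scale_f = jitter_rng.normal(1.0, subject_jitter, size=gt.params.n)
        else:
            scale_a = scale_f = np.ones(gt.params.n)
        a = gt.params.a * scale_a
        f = np.clip(gt.params.f * scale_f, f_lo * 1.5, f_hi * 0.95)
        subj_params = gt.params.with_nodes(a=a, f=f)
        for k_idx, ses_ss in enumerate(sub_ss.spawn(n_sessions)):
            runs.append(
                simulate_hopf(
                    gt.ec_true,
                    subj_params,
                    n_volumes,
                    seed=ses_ss,
                    subject_id=sub_id,
                    session_id=f"ses-{k_idx + 1}",
                )
            )
    return runs


def empirical_pair_from_cohort(
    cohort: list[BoldTimeseries],
    band: tuple[float, float] = DEFAULT_BAND,
    tau: float = 2.0,
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Group FC and lagged-FC matrices from a cohort of runs.

    Each run is band-limited and its FC / lagged FC computed; matrices
    are averaged within subject across sessions, then across subjects.
    """
    if not cohort:
        raise ValueError("empty cohort")
    ref = cohort[0]
    by_subject: dict[str, list[BoldTimeseries]] = {}
    for ts in cohort:
        if ts.region_ids != ref.region_ids:
            raise ValueError("inconsistent region ordering across the cohort")
        by_subject.setdefault(ts.subject_id or "sub-001", []).append(ts)
    fc_subj, fct_subj = [], []
    for runs in by_subject.values():
        fcs, fcts = [], []
        for ts in runs:
            filtered = bandpass_filter(ts, *band)
            fcs.append(functional_connectivity(filtered))
            fcts.append(lagged_functional_connectivity(filtered, tau))
        fc_subj.append(average_connectivity(fcs))
        fct_subj.append(average_connectivity(fcts))
    return average_connectivity(fc_subj), average_connectivity(fct_subj)
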