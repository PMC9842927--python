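"""Reporting computations on fitted connectivity matrices.

Directional differences, display thresholding, per-ROI connectivity
profile comparison (two-way ANOVA interaction) and ipsi-/contralateral
strength summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ConnectivityMatrix

__all__ = [
    "RoiComparison",
    "direction_difference",
    "threshold_matrix",
    "roi_profile_anova",
    "ipsi_contra_ratio",
]


@dataclass
class RoiComparison:
    """Interaction test between two ROI connectivity profiles."""

    roi_a: str
    roi_b: str
    f_stat: float
    p_value: float
    p_bonferroni: float
    n_subjects: int
    n_targets: int


def direction_difference(ec: ConnectivityMatrix, display_threshold: float = 0.0) -> ConnectivityMatrix:
    """Signed difference of the two directions of every link.

    ``D[i, j] = C[i, j] - C[j, i]`` is exactly antisymmetric before
    thresholding; entries with ``|D| < display_threshold`` are zeroed in
    the returned display copy (pass ``display_threshold=0`` for the raw
    difference).  The result carries kind ``DIFF``.
    """
    v = ec.values
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("input must be square")
    d = v - v.T
    if display_threshold > 0:
        d = np.where(np.abs(d) >= display_threshold, d, 0.0)
    return ConnectivityMatrix(d, kind="DIFF", region_ids=list(ec.region_ids))


def threshold_matrix(m: ConnectivityMatrix, threshold: float) -> ConnectivityMatrix:
    """Zero entries below ``threshold``; entries at or above it are kept
    unchanged (boundary inclusive)."""
    v = np.where(m.values >= threshold, m.values, 0.0)
    if m.kind == "FC":
        np.fill_diagonal(v, 1.0)  # keep the unit diagonal valid for display
    return ConnectivityMatrix(v, kind=m.kind, region_ids=list(m.region_ids), tau=m.tau)


def roi_profile_anova(
    per_subject_ec: list[ConnectivityMatrix],
    roi_a: str,
    roi_b: str,
    n_pairs_for_correction: int = 1,
) -> RoiComparison:
    """Interaction F of a two-way ANOVA on two ROI connectivity profiles.

    For each subject, the incoming-connectivity row of each ROI (links
    *to* the ROI *from* every other region, the two ROI columns excluded)
    forms one profile; the balanced two-way design is ROI (2 levels) x
    target region, with subjects as replicates.  A large interaction term
    means the two ROIs have differently shaped profiles.  The Bonferroni
    p multiplies by ``n_pairs_for_correction`` and caps at 1.
    """
    if len(per_subject_ec) < 2:
        raise ValueError("need at least 2 subjects")
    if roi_a == roi_b:
        raise ValueError("rois must be distinct")
    ref = per_subject_ec[0]
    ia, ib = ref.region_ids.index(roi_a), ref.region_ids.index(roi_b)
    targets = [k for k in range(ref.n) if k not in (ia, ib)]
    rows = []
    for m in per_subject_ec:
        if m.region_ids != ref.region_ids:
            raise ValueError("inconsistent region ordering across subjects")
        rows.append(np.stack([m.values[ia, targets], m.values[ib, targets]]))
    y = np.stack(rows)  # (subjects, 2, T)
    n_sub, n_roi, n_tgt = y.shape

    grand = y.mean()
    mean_rt = y.mean(axis=0)  # (2, T) cell means
    mean_r = y.mean(axis=(0, 2))  # (2,)
    mean_t = y.mean(axis=(0, 1))  # (T,)
    ss_int = n_sub * float(((mean_rt - mean_r[:, None] - mean_t[None, :] + grand) ** 2).sum())
    ss_err = float(((y - mean_rt[None]) ** 2).sum())
    df_int = (n_roi - 1) * (n_tgt - 1)
    df_err = n_roi * n_tgt * (n_sub - 1)
    if ss_err == 0:
        raise ValueError("zero within-cell variance; ANOVA undefined")
    f_stat = (ss_int / df_int) / (ss_err / df_err)
    p = float(stats.f.sf(f_stat, df_int, df_err))
    return RoiComparison(
        roi_a=roi_a,
        roi_b=roi_b,
        f_stat=float(f_stat),
        p_value=p,
        p_bonferroni=min(1.0, p * n_pairs_for_correction),
        n_subjects=n_sub,
        n_targets=n_tgt,
    )


def ipsi_contra_ratio(ec_ipsi: ConnectivityMatrix, ec_contra: ConnectivityMatrix) -> float:
    """Contralateral strength as a percentage of ipsilateral strength.

    Computed as the ratio of the means of the positive off-diagonal
    entries (ratio of means, not mean of ratios).
    """
    if ec_ipsi.values.shape != ec_contra.values.shape:
        raise ValueError("matrices must share shape")

    def _mean_positive(v: np.ndarray) -> float:
        mask = ~np.eye(v.shape[0], dtype=bool)
        vals = v[mask]
        vals = vals[vals > 0]
        return float(vals.mean()) if vals.size else 0.0

    ipsi = _mean_positive(ec_ipsi.values)
    contra = _mean_positive(ec_contra.values)
    if ipsi == 0:
        raise ValueError("zero ipsilateral connectivity mass; ratio undefined")
    return 100.0 * contra / ipsi
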