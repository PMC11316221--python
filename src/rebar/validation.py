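"""Independent checks on inferred bias components and corrected fitnesses.

The SVD oracle exploits the rank-one structure delta_f = u * lambda directly:
on a variant-by-assay matrix of fitness errors for an equal-fitness group,
the first left singular vector estimates susceptibilities and the first right
singular vector the per-assay prevalence trends, with no iterative inference
involved. Replicate agreement and an equal-variance test quantify whether
corrections tighten fitness estimates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fitting import FitSet

__all__ = [
    "svd_bias_oracle",
    "ReplicateAgreement",
    "replicate_agreement",
    "EqualVarianceResult",
    "equal_variance_test",
]


def svd_bias_oracle(errors: np.ndarray, center: bool = True):
    """Rank-one decomposition of a (group variants x assays) fitness-error matrix.

    Columns are centered on the group mean (consistent with the definition of
    the errors) before taking the SVD. Returns ``(u_est, lambda_est)`` scaled
    so that RMS(u_est) = 1 and u_est x lambda_est reproduces the leading
    singular component, with the largest-|u| entry positive.
    """
    E = np.asarray(errors, dtype=float)
    if E.ndim != 2 or E.shape[0] < 2 or E.shape[1] < 2:
        raise ValueError("error matrix must be at least 2 x 2")
    if not np.all(np.isfinite(E)):
        raise ValueError("error matrix must be finite")
    if center:
        E = E - E.mean(axis=0)
    m = E.shape[0]
    if not np.any(E):
        warnings.warn("zero error matrix; no bias mode", RuntimeWarning, stacklevel=2)
        return np.zeros(m), np.zeros(E.shape[1])
    U, s, Vt = np.linalg.svd(E, full_matrices=False)
    u_est = U[:, 0] * np.sqrt(m)
    lam_est = s[0] * Vt[0] / np.sqrt(m)
    k = int(np.argmax(np.abs(u_est)))
    if u_est[k] < 0:
        u_est = -u_est
        lam_est = -lam_est
    return u_est, lam_est


@dataclass(frozen=True)
class ReplicateAgreement:
    variant_ids: tuple[str, ...]
    discrepancy: np.ndarray  # f_rep1 - f_rep2 per shared variant
    rms: float
    correlation: float


def replicate_agreement(
    fits_rep1: FitSet,
    fits_rep2: FitSet,
    assay1: str | None = None,
    assay2: str | None = None,
) -> ReplicateAgreement:
    """Per-variant fitness discrepancy between two replicate assays.

    Each FitSet contributes one assay (by id, or its only assay); variants
    are matched by id and NaN fits dropped pairwise.
    """

    def _column(fits: FitSet, assay_id):
        if assay_id is None:
            if len(fits.assays) != 1:
                raise ValueError("FitSet has multiple assays; specify which one")
            j = 0
        else:
            j = fits.assay_index(assay_id)
        return {v: fits.slope[i, j] for i, v in enumerate(fits.variant_ids)}

    f1 = _column(fits_rep1, assay1)
    f2 = _column(fits_rep2, assay2)
    shared = [v for v in f1 if v in f2]
    if not shared:
        raise ValueError("replicates share no variants")
    a = np.array([f1[v] for v in shared])
    b = np.array([f2[v] for v in shared])
    ok = np.isfinite(a) & np.isfinite(b)
    shared = [v for v, o in zip(shared, ok) if o]
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("fewer than 2 shared variants with finite fits")
    d = a - b
    corr = float(np.corrcoef(a, b)[0, 1]) if np.std(a) > 0 and np.std(b) > 0 else 1.0
    return ReplicateAgreement(
        variant_ids=tuple(shared),
        discrepancy=d,
        rms=float(np.sqrt(np.mean(d**2))),
        correlation=corr,
    )


@dataclass(frozen=True)
class EqualVarianceResult:
    statistic: float
    pvalue: float


def equal_variance_test(*groups, center: str = "median") -> EqualVarianceResult:
    """Brown-Forsythe (median-centered Levene) test for equal variances.

    Used to judge whether correction tightened the spread of fitness
    estimates within a putatively equal-fitness group. Degenerate input with
    zero within-group deviation everywhere returns W=0, p=1 by convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if g.size < 3:
            raise ValueError("each group needs at least 3 values")
        if not np.all(np.isfinite(g)):
            raise ValueError("groups must be finite")
    centerfun = np.median if center == "median" else np.mean
    if all(np.allclose(g, centerfun(g)) for g in arrays):
        return EqualVarianceResult(statistic=0.0, pvalue=1.0)
    stat, p = stats.levene(*arrays, center=center)
    if not np.isfinite(stat):
        return EqualVarianceResult(statistic=0.0, pvalue=1.0)
    return EqualVarianceResult(statistic=float(stat), pvalue=float(p))
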