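"""Per-variant, per-assay log-linear trajectory fits.

Under exponential change of relative abundance, a variant's log-counts are
linear in assay time; the OLS slope estimates its relative fitness. The
residual projector of each assay (orthogonal complement of span{1, t}) is the
algebraic core shared with the bias-inference stage.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AssayDesign, LogCountMatrix

__all__ = [
    "FitSet",
    "FitnessErrors",
    "residual_projector",
    "fit_loglinear",
    "control_fitness_errors",
]


def residual_projector(timepoints) -> np.ndarray:
    """Projector onto the orthogonal complement of span{1, t}.

    Applying it to a trajectory leaves exactly the residuals of an
    (unweighted) OLS line fit against the timepoints.
    """
    t = np.asarray(timepoints, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    hat = X @ np.linalg.solve(X.T @ X, X.T)
    return np.eye(t.size) - hat


@dataclass(frozen=True)
class FitSet:
    """Slopes (fitness per assay-time unit), intercepts and residuals of
    log-linear fits, one per (variant, assay). Entries are NaN where a
    variant-assay had no usable data."""

    variant_ids: tuple[str, ...]
    assays: tuple[AssayDesign, ...]
    slope: np.ndarray       # (n_variants, n_assays)
    intercept: np.ndarray   # (n_variants, n_assays)
    residuals: np.ndarray   # (n_variants, n_samples)
    n_points: np.ndarray    # (n_variants, n_assays)
    projectors: tuple[np.ndarray, ...]

    @property
    def assay_ids(self) -> tuple[str, ...]:
        return tuple(a.assay_id for a in self.assays)

    def assay_index(self, assay_id: str) -> int:
        try:
            return self.assay_ids.index(str(assay_id))
        except ValueError:
            raise KeyError(f"no assay {assay_id!r} in fit set") from None

    def variant_index(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in ids if v not in lookup]
        if missing:
            raise KeyError(f"variants not in fit set: {missing[:5]}")
        return np.asarray([lookup[v] for v in ids])

    def to_frame(self) -> pd.DataFrame:
        """Long-format fitness table: variant_id, assay_id, fitness, intercept, n_points."""
        rows = []
        for j, assay in enumerate(self.assays):
            for i, v in enumerate(self.variant_ids):
                rows.append(
                    {
                        "variant_id": v,
                        "assay_id": assay.assay_id,
                        "fitness": self.slope[i, j],
                        "intercept": self.intercept[i, j],
                        "n_points": int(self.n_points[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FitnessErrors:
    """Fitness misestimates delta_f per (variant, assay), relative either to a
    group mean over an equal-fitness set or to known true fitnesses."""

    variant_ids: tuple[str, ...]
    assay_ids: tuple[str, ...]
    delta_f: np.ndarray  # (n_group, n_assays)
    reference: str = "group-mean"


def fit_loglinear(log_counts: LogCountMatrix) -> FitSet:
    """OLS line fit of every variant's log-count trajectory, per assay."""
    values = log_counts.values
    n_var = len(log_counts.variant_ids)
    slices = log_counts.assay_slices()
    n_assay = len(slices)
    n_samp = values.shape[1]

    slope = np.full((n_var, n_assay), np.nan)
    intercept = np.full((n_var, n_assay), np.nan)
    residuals = np.full((n_var, n_samp), np.nan)
    n_points = np.zeros((n_var, n_assay), dtype=int)
    projectors = []

    for j, (assay, cols) in enumerate(slices):
        t = assay.times()
        X = np.column_stack([np.ones_like(t), t])
        Y = values[:, cols]
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (2, n_var)
        intercept[:, j] = beta[0]
        slope[:, j] = beta[1]
        residuals[:, cols] = Y - (X @ beta).T
        n_points[:, j] = t.size
        projectors.append(residual_projector(t))

    if log_counts.observed is not None:
        excl = ~log_counts.observed
        slope[excl] = np.nan
        intercept[excl] = np.nan
        n_points[excl] = 0
        for j, (_, cols) in enumerate(slices):
            residuals[np.ix_(excl[:, j].nonzero()[0], cols)] = np.nan

    return FitSet(
        variant_ids=log_counts.variant_ids,
        assays=log_counts.assays,
        slope=slope,
        intercept=intercept,
        residuals=residuals,
        n_points=n_points,
        projectors=tuple(projectors),
    )


def control_fitness_errors(fits: FitSet, control_ids) -> FitnessErrors:
    """Center control-set fitness estimates on their per-assay group mean.

    For an equal-fitness control set, the centered values approximate each
    variant's fitness misestimate delta_f (the group mean stands in for the
    unknown shared true fitness).
    """
    control_ids = tuple(str(v) for v in control_ids)
    if len(control_ids) < 2:
        raise ValueError("control set must contain at least 2 variants")
    idx = fits.variant_index(control_ids)
    sub = fits.slope[idx, :]
    if np.isnan(sub).any():
        n_bad = int(np.isnan(sub).sum())
        warnings.warn(
            f"{n_bad} control variant-assay fits are missing and are excluded "
            "from the group mean",
            RuntimeWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(sub, axis=0)
    delta = sub - means
    return FitnessErrors(
        variant_ids=control_ids,
        assay_ids=fits.assay_ids,
        delta_f=delta,
        reference="group-mean",
    )
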